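"""Multilocus haplotype frequency estimation by expectation-maximisation.

Unphased genotypes over a small set of linked loci (a haplotype block) are
phase-ambiguous: an individual heterozygous at h loci is compatible with
2^(h-1) unordered haplotype pairs.  The EM algorithm treats the pair as the
latent variable.  The E-step distributes each individual over its compatible
pairs with weight proportional to ``Pi * Pj`` (doubled for heterozygous
pairs, the two orderings); the M-step re-estimates each haplotype frequency
as its expected copy count over ``2N`` chromosomes.  The observed-data
log-likelihood is nondecreasing across iterations and is asserted to be so.

Haplotypes are encoded as tuples of 0/1 over the block's loci (0 = major
allele, 1 = minor allele); ``HaplotypeSet.labels`` renders them as allele
strings.  Blocks are short (2-12 loci), so pair enumeration is exhaustive.

The per-individual posterior over pairs also yields a hard phase assignment:
an individual is assigned its best pair only when that pair's posterior
exceeds a cut-point (0.95 by default), and the expected copy number of any
single haplotype is available as a fractional dosage for association tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeTable, PhenotypeTable

logger = logging.getLogger(__name__)

PRUNE_FREQ = 1e-10


@dataclass
class HaplotypeSet:
    """EM-estimated haplotype frequencies over a block of loci."""

    loci: list[str]
    haplotypes: list[tuple[int, ...]]   # 0 = major, 1 = minor allele
    freqs: np.ndarray                   # Pi, on the simplex
    loglik: float
    n_iter: int
    converged: bool
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.haplotypes) != len(self.freqs):
            raise ValueError("haplotypes and freqs length mismatch")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if (self.freqs < 0).any():
            raise ValueError("haplotype frequencies must be nonnegative")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotypes")

    def labels(self) -> list[str]:
        """Haplotypes as allele strings (e.g. 'AG'), falling back to 0/1."""
        if self.alleles is None:
            return ["".join(map(str, h)) for h in self.haplotypes]
        return ["".join(self.alleles[k][h[k]] for k in range(len(self.loci)))
                for h in self.haplotypes]

    def freq_of(self, label: str) -> float:
        try:
            return float(self.freqs[self.labels().index(label)])
        except ValueError:
            return 0.0

    def pruned(self, min_freq: float = PRUNE_FREQ) -> "HaplotypeSet":
        keep = self.freqs >= min_freq
        f = self.freqs[keep]
        return HaplotypeSet(self.loci,
                            [h for h, k in zip(self.haplotypes, keep) if k],
                            f / f.sum(), self.loglik, self.n_iter,
                            self.converged, self.alleles)


@dataclass
class PhaseAssignment:
    """Hard phase call for one individual at the posterior cut-point."""

    sample_id: str
    pair: tuple[tuple[int, ...], tuple[int, ...]] | None
    posterior: float

    @property
    def assigned(self) -> bool:
        return self.pair is not None


def enumerate_phases(genotype: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs compatible with one genotype vector.

    With h heterozygous loci there are exactly ``max(1, 2**(h-1))`` pairs;
    every returned pair sums elementwise to the genotype.  Missing genotypes
    are not allowed here (handled upstream by exclusion).
    """
    g = np.asarray(genotype)
    if ((g < 0) | (g > 2)).any():
        raise ValueError("genotype must be complete with dosages in {0,1,2}")
    het = np.flatnonzero(g == 1)
    base = (g // 2).astype(int)
    if len(het) == 0:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    # fix the first heterozygous locus to break the hap1/hap2 symmetry
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        h1 = base.copy()
        h2 = base.copy()
        assignment = (0,) + bits
        for locus, bit in zip(het, assignment):
            h1[locus] = bit
            h2[locus] = 1 - bit
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def _pair_arrays(dosage: np.ndarray):
    """Collapse complete genotype rows to unique patterns and enumerate pairs.

    Returns (hap_list, pair_i, pair_j, pair_coef, pair_geno, geno_counts,
    row_geno) where pair_* are flat arrays over all (genotype, pair) items.
    """
    patterns, row_geno, counts = np.unique(dosage, axis=0,
                                           return_inverse=True,
                                           return_counts=True)
    hap_index: dict[tuple[int, ...], int] = {}
    pair_i, pair_j, pair_coef, pair_geno = [], [], [], []
    for g_idx, pattern in enumerate(patterns):
        for h1, h2 in enumerate_phases(pattern):
            i = hap_index.setdefault(h1, len(hap_index))
            j = hap_index.setdefault(h2, len(hap_index))
            pair_i.append(i)
            pair_j.append(j)
            pair_coef.append(1.0 if h1 == h2 else 2.0)
            pair_geno.append(g_idx)
    haps = [h for h, _ in sorted(hap_index.items(), key=lambda kv: kv[1])]
    return (haps, np.array(pair_i), np.array(pair_j), np.array(pair_coef),
            np.array(pair_geno), counts.astype(float), row_geno)


def _em_run(freqs, pair_i, pair_j, pair_coef, pair_geno, counts,
            n_hap, tol, max_iter):
    """One EM run from a given start; returns (freqs, loglik, n_iter, conv)."""
    two_n = 2.0 * counts.sum()
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        lik = pair_coef * freqs[pair_i] * freqs[pair_j]
        geno_lik = np.bincount(pair_geno, weights=lik, minlength=len(counts))
        ll = float(np.dot(counts, np.log(np.maximum(geno_lik, 1e-300))))
        assert ll >= prev_ll - 1e-7, "EM log-likelihood decreased"
        if abs(ll - prev_ll) < tol:
            return freqs, ll, it, True
        prev_ll = ll
        w = lik / np.maximum(geno_lik[pair_geno], 1e-300) * counts[pair_geno]
        hap_counts = (np.bincount(pair_i, weights=w, minlength=n_hap)
                      + np.bincount(pair_j, weights=w, minlength=n_hap))
        freqs = hap_counts / two_n
    return freqs, prev_ll, max_iter, False


def em_frequencies(genotypes: GenotypeTable, loci: list[str] | None = None,
                   tol: float = 1e-8, max_iter: int = 1000,
                   n_restarts: int = 5, seed: int | None = None,
                   init: np.ndarray | None = None) -> HaplotypeSet:
    """Estimate block haplotype frequencies by EM.

    Individuals missing any of the block's loci are excluded from estimation
    (their count is logged).  The first start is the linkage-equilibrium
    product of allele frequencies; the remaining ``n_restarts - 1`` starts
    are random Dirichlet draws.  The run with the best final log-likelihood
    wins.  ``init`` adds one extra user-supplied start (e.g. the truth, for
    oracle comparisons).
    """
    block = genotypes if loci is None else genotypes.subset_snps(loci)
    complete = (block.dosage != MISSING).all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("excluding %d individuals with missing block genotypes",
                    n_excluded)
    dosage = block.dosage[complete]
    if dosage.shape[0] == 0:
        raise ValueError("no individuals with complete genotypes at the block loci")

    haps, pair_i, pair_j, pair_coef, pair_geno, counts, _ = _pair_arrays(dosage)
    n_hap = len(haps)
    hap_mat = np.array(haps, dtype=float)          # n_hap x L in 0/1
    minor_freq = dosage.mean(axis=0) / 2.0

    # linkage-equilibrium start
    le = np.prod(np.where(hap_mat == 1, minor_freq, 1.0 - minor_freq), axis=1)
    le = np.maximum(le, 1e-12)
    starts = [le / le.sum()]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.dirichlet(np.ones(n_hap)))
    if init is not None:
        starts.append(np.asarray(init, float) / np.asarray(init, float).sum())

    best = None
    for start in starts:
        result = _em_run(start.copy(), pair_i, pair_j, pair_coef, pair_geno,
                         counts, n_hap, tol, max_iter)
        if best is None or result[1] > best[1]:
            best = result
    freqs, ll, n_iter, converged = best
    freqs = np.maximum(freqs, 0.0)
    freqs = freqs / freqs.sum()
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    hset = HaplotypeSet(list(block.snp_ids), haps, freqs, ll, n_iter,
                        converged, list(block.alleles))
    return hset.pruned()


def effective_haplotype_count(freqs) -> float:
    """Effective number of haplotypes, n_e = 1 / sum(Pi^2) (inverse Simpson)."""
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency vector")
    return float(1.0 / np.sum(f**2))


def _pair_weights(genotype: np.ndarray, hapset: HaplotypeSet):
    """Unnormalized E-step weights of each compatible pair under the set."""
    freq = dict(zip(hapset.haplotypes, hapset.freqs))
    pairs = enumerate_phases(genotype)
    weights = np.array([(1.0 if h1 == h2 else 2.0)
                        * freq.get(h1, 0.0) * freq.get(h2, 0.0)
                        for h1, h2 in pairs])
    return pairs, weights


def assign_phase(genotype: np.ndarray, hapset: HaplotypeSet,
                 sample_id: str = "", cutpoint: float = 0.95) -> PhaseAssignment:
    """Assign the maximum-posterior haplotype pair if it clears the cut-point.

    The posterior of each compatible pair is its E-step weight normalized
    over the individual's compatible pairs.  An individual whose genotype is
    incompatible with every positive-frequency haplotype is unassigned with
    posterior 0.
    """
    pairs, weights = _pair_weights(np.asarray(genotype), hapset)
    total = weights.sum()
    if total <= 0:
        return PhaseAssignment(sample_id, None, 0.0)
    post = weights / total
    k = int(np.argmax(post))
    if post[k] > cutpoint:
        return PhaseAssignment(sample_id, pairs[k], float(post[k]))
    return PhaseAssignment(sample_id, None, float(post[k]))


def expected_hap_dosage(genotypes: GenotypeTable, hapset: HaplotypeSet,
                        haplotype: str | tuple[int, ...]) -> np.ndarray:
    """Per-individual EM-expected copy number of one haplotype.

    Fractional values arise for phase-ambiguous individuals; individuals
    with a missing genotype at any block locus get NaN.
    """
    block = genotypes.subset_snps(hapset.loci)
    target = _resolve_haplotype(hapset, haplotype)
    out = np.full(block.n_samples, np.nan)
    cache: dict[tuple, float] = {}
    for i in range(block.n_samples):
        g = block.dosage[i]
        if (g == MISSING).any():
            continue
        key = tuple(g)
        if key not in cache:
            pairs, weights = _pair_weights(g, hapset)
            total = weights.sum()
            if total <= 0:
                cache[key] = np.nan
            else:
                copies = np.array([(h1 == target) + (h2 == target)
                                   for h1, h2 in pairs], dtype=float)
                cache[key] = float(np.dot(weights / total, copies))
        out[i] = cache[key]
    return out


def _resolve_haplotype(hapset: HaplotypeSet, haplotype) -> tuple[int, ...]:
    if isinstance(haplotype, str):
        labels = hapset.labels()
        if haplotype not in labels:
            raise KeyError(f"haplotype {haplotype!r} not in set {labels}")
        return hapset.haplotypes[labels.index(haplotype)]
    h = tuple(int(x) for x in haplotype)
    if h not in hapset.haplotypes:
        raise KeyError(f"haplotype {h} not in set")
    return h


@dataclass
class ExpectedHaplotypeCounts:
    """EM-expected chromosome counts of one haplotype by case status.

    ``case_count + case_rest`` equals twice the number of cases with
    complete block genotypes (likewise controls); fractional values arise
    from phase ambiguity, as in expected-count haplotype tables.
    """

    haplotype: str
    case_count: float
    case_rest: float
    control_count: float
    control_rest: float

    def format_ratio(self) -> str:
        """'case: case_rest, control: control_rest' at one decimal."""
        return (f"{self.case_count:.1f}: {self.case_rest:.1f}, "
                f"{self.control_count:.1f}: {self.control_rest:.1f}")


def expected_counts(genotypes: GenotypeTable, phenotypes: PhenotypeTable,
                    hapset: HaplotypeSet, haplotype,
                    assigned_only: bool = False,
                    cutpoint: float = 0.95) -> ExpectedHaplotypeCounts:
    """Case/control expected chromosome counts of one haplotype.

    Default mode sums each individual's EM-expected copy number (fractional
    totals); ``assigned_only`` instead tallies hard phase assignments at the
    cut-point and ignores unassigned individuals.
    """
    phen = phenotypes.aligned_to(genotypes)
    target = _resolve_haplotype(hapset, haplotype)
    label = hapset.labels()[hapset.haplotypes.index(target)]
    block = genotypes.subset_snps(hapset.loci)
    complete = (block.dosage != MISSING).all(axis=1)
    if assigned_only:
        dos = np.full(block.n_samples, np.nan)
        for i in np.flatnonzero(complete):
            a = assign_phase(block.dosage[i], hapset, cutpoint=cutpoint)
            if a.assigned:
                dos[i] = (a.pair[0] == target) + (a.pair[1] == target)
    else:
        dos = expected_hap_dosage(genotypes, hapset, target)
    case = phen.is_case
    ok = ~np.isnan(dos)
    case_n = float(np.nansum(dos[case & ok]))
    ctrl_n = float(np.nansum(dos[~case & ok]))
    case_tot = 2.0 * int((case & ok).sum())
    ctrl_tot = 2.0 * int((~case & ok).sum())
    return ExpectedHaplotypeCounts(label, case_n, case_tot - case_n,
                                   ctrl_n, ctrl_tot - ctrl_n)
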