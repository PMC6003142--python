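"""Two-locus linkage disequilibrium and Gabriel-style haplotype blocks.

Pairwise haplotype frequencies come from the two-locus EM (phase is latent
in unphased data), giving the raw coefficient D, the standardised D' and
r^2.  The confidence interval on D' is obtained by profiling the genotype
likelihood over a D' grid at the EM allele frequencies — the convention used
by block-finding software in this field — and blocks are contiguous runs of
SNPs whose informative pairs are overwhelmingly in strong LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeTable
from .em import em_frequencies

#: Gabriel et al. confidence-interval thresholds (block-software defaults)
STRONG_LOW = 0.70    # lower CI bound must exceed this
STRONG_HIGH = 0.98   # upper CI bound must reach this
RECOMB_HIGH = 0.90   # upper bound below this = strong recombination evidence
INFORMATIVE_FRACTION = 0.95

_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class PairLD:
    snp_i: str
    snp_j: str
    D: float
    Dprime: float
    r2: float
    ci_low: float
    ci_high: float

    @property
    def strong_ld(self) -> bool:
        return self.ci_low > STRONG_LOW and self.ci_high >= STRONG_HIGH

    @property
    def strong_recombination(self) -> bool:
        return self.ci_high < RECOMB_HIGH

    @property
    def informative(self) -> bool:
        return self.strong_ld or self.strong_recombination


@dataclass
class Block:
    """Contiguous run of SNP indices forming a haplotype block."""

    start: int  # inclusive
    stop: int   # inclusive

    @property
    def members(self) -> list[int]:
        return list(range(self.start, self.stop + 1))

    def __len__(self) -> int:
        return self.stop - self.start + 1


def _hap_freqs_from_d(q1: float, q2: float, d: np.ndarray) -> np.ndarray:
    """4-haplotype frequencies (bb, bB, Bb, BB in minor-allele coding) as a
    function of the raw coefficient d, at fixed allele frequencies."""
    f11 = q1 * q2 + d              # minor-minor
    f10 = q1 * (1 - q2) - d
    f01 = (1 - q1) * q2 - d
    f00 = (1 - q1) * (1 - q2) + d  # major-major
    return np.stack([f00, f01, f10, f11], axis=-1)


def _genotype_loglik(counts9: np.ndarray, hapfreqs: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of the 9 two-locus genotype categories.

    ``hapfreqs`` has shape (..., 4) ordered (00, 01, 10, 11) in minor-allele
    dosage per locus; categories index as 3*g1 + g2.
    """
    f = np.maximum(hapfreqs, 0.0)
    probs = np.zeros(f.shape[:-1] + (9,))
    hap_dosage = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for a, (d1a, d2a) in enumerate(hap_dosage):
        for b, (d1b, d2b) in enumerate(hap_dosage):
            probs[..., 3 * (d1a + d1b) + (d2a + d2b)] += f[..., a] * f[..., b]
    return (counts9 * np.log(np.maximum(probs, 1e-300))).sum(axis=-1)


def pair_ld(genotypes: GenotypeTable, snp_i: str, snp_j: str,
            conf: float = 0.90, seed: int | None = 0) -> PairLD:
    """LD statistics for one SNP pair from unphased genotypes.

    D is computed on the minor-minor haplotype; D' = |D| / Dmax with Dmax
    the tightest margin-allowed excursion in D's direction; r^2 = D^2
    normalised by all four allele frequencies.  The D' confidence interval
    (default 90%, two-sided) profiles the genotype likelihood over a
    0..1 grid of D' at step 0.001 with the sign fixed at the MLE's.
    """
    pair = genotypes.subset_snps([snp_i, snp_j])
    for j in range(2):
        col = pair.dosage[:, j]
        valid = col[col >= 0]
        if len(np.unique(valid)) < 2 and not (1 in valid):
            raise ValueError(f"SNP {pair.snp_ids[j]} is monomorphic; LD undefined")
    hset = em_frequencies(pair, n_restarts=3, seed=seed)
    freq = {h: f for h, f in zip(hset.haplotypes, hset.freqs)}
    f = np.array([freq.get((0, 0), 0.0), freq.get((0, 1), 0.0),
                  freq.get((1, 0), 0.0), freq.get((1, 1), 0.0)])
    q1 = f[2] + f[3]   # minor allele freq, locus i
    q2 = f[1] + f[3]   # minor allele freq, locus j
    if min(q1, 1 - q1, q2, 1 - q2) <= 0:
        raise ValueError("monomorphic haplotype margin; LD undefined")
    d = f[3] - q1 * q2
    if d >= 0:
        dmax = min(q1 * (1 - q2), (1 - q1) * q2)
    else:
        dmax = min(q1 * q2, (1 - q1) * (1 - q2))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d**2 / (q1 * (1 - q1) * q2 * (1 - q2))

    # profile likelihood over the D' grid, sign fixed at the MLE's
    complete = (pair.dosage >= 0).all(axis=1)
    dos = pair.dosage[complete]
    counts9 = np.bincount(3 * dos[:, 0] + dos[:, 1], minlength=9).astype(float)
    sign = 1.0 if d >= 0 else -1.0
    d_grid = sign * _GRID * dmax
    ll = _genotype_loglik(counts9, _hap_freqs_from_d(q1, q2, d_grid))
    post = np.exp(ll - ll.max())
    post /= post.sum()
    cum = np.cumsum(post)
    alpha = (1.0 - conf) / 2.0
    ci_low = float(_GRID[np.searchsorted(cum, alpha)])
    ci_high = float(_GRID[np.searchsorted(cum, 1.0 - alpha)])
    return PairLD(snp_i, snp_j, float(d), float(min(dprime, 1.0)),
                  float(min(r2, 1.0)), ci_low, ci_high)


def ld_matrix(genotypes: GenotypeTable, max_span: int | None = None,
              seed: int = 0) -> dict[tuple[int, int], PairLD]:
    """All pairwise LD results keyed by position-ordered index pairs.

    ``max_span`` limits computation to pairs at most that many SNPs apart
    (block finding only needs local pairs).  Monomorphic pairs are skipped.
    """
    out: dict[tuple[int, int], PairLD] = {}
    m = genotypes.n_snps
    for i in range(m):
        stop = m if max_span is None else min(m, i + max_span + 1)
        for j in range(i + 1, stop):
            try:
                out[(i, j)] = pair_ld(genotypes, genotypes.snp_ids[i],
                                      genotypes.snp_ids[j], seed=seed)
            except ValueError:
                continue
    return out


def find_blocks(pairs: dict[tuple[int, int], PairLD], n_snps: int,
                informative_fraction: float = INFORMATIVE_FRACTION,
                min_size: int = 2) -> list[Block]:
    """Gabriel-rule haplotype blocks from a pairwise LD map.

    A candidate region is a contiguous index span whose outermost pair is in
    strong LD; it is accepted when at least ``informative_fraction`` of its
    informative pairs (strong LD or strong recombination) are strong-LD.
    Accepted candidates are taken greedily longest-first, non-overlapping.
    Depends only on SNP order and LD, never on id strings.
    """
    candidates = []
    for (i, j), p in pairs.items():
        if j - i + 1 < min_size or not p.strong_ld:
            continue
        strong = informative = 0
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                q = pairs.get((a, b))
                if q is None or not q.informative:
                    continue
                informative += 1
                strong += q.strong_ld
        if informative and strong / informative >= informative_fraction:
            candidates.append(Block(i, j))
    candidates.sort(key=lambda b: (-len(b), b.start))
    taken: list[Block] = []
    used = np.zeros(n_snps, dtype=bool)
    for cand in candidates:
        if not used[cand.start:cand.stop + 1].any():
            taken.append(cand)
            used[cand.start:cand.stop + 1] = True
    taken.sort(key=lambda b: b.start)
    return taken
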