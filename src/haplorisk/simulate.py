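"""Synthetic case-control cohorts with LD-blocked haplotypes.

The generator emulates the statistical structure the analysis assumes: a
candidate-gene SNP panel whose loci fall in a few haplotype blocks plus
inter-block SNPs in linkage equilibrium; a rare risk haplotype (control
frequency ~0.006, case frequency ~0.05); age/sex/smoking/drinking
covariates; and a logistic disease model optionally carrying a
haplotype-by-drinking interaction.  Sampling is retrospective: individuals
are drawn from a population model and kept until the case and control
quotas fill, as in a case-control design.

The default pools place the rare two-SNP haplotype block in the regime of a
candidate-gene study of ~829 cases and ~765 controls (per-block control
haplotype frequencies 0.654/0.341/0.006 after rescaling); block sizes are
4, 4 and 2 loci among 164 SNPs.  The truth record retains every latent
haplotype draw so downstream estimates can be checked against the
generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeTable, PhenotypeTable, VariantAnnotation


@dataclass
class BlockSpec:
    """One haplotype block: locus ids and a pool of haplotypes with
    control-population frequencies on the simplex."""

    loci: list[str]
    haplotypes: list[str]       # allele strings, one char per locus
    freqs: list[float]

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("block pool frequencies must sum to 1")
        if any(len(h) != len(self.loci) for h in self.haplotypes):
            raise ValueError("haplotype length must match locus count")
        self.freqs = list(f / f.sum())

    def allele_pairs(self) -> list[tuple[str, str]]:
        """Per-locus (major, minor) alleles by pooled marginal frequency."""
        out = []
        f = np.asarray(self.freqs)
        for k in range(len(self.loci)):
            letters = {}
            for h, p in zip(self.haplotypes, f):
                letters[h[k]] = letters.get(h[k], 0.0) + p
            ranked = sorted(letters, key=lambda a: (-letters[a], a))
            if len(ranked) == 1:
                ranked.append("N")
            out.append((ranked[0], ranked[1]))
        return out


def _default_blocks() -> list[BlockSpec]:
    return [
        # pools are chain-like (any locus pair shows at most three gametes)
        # so pairwise D' = 1 within a block, as high-LD blocks require
        BlockSpec(
            loci=["rs12037962", "rs11587", "rs41307753", "rs3810989"],
            haplotypes=["GGCA", "GGTG", "AATG", "GGCG"],
            freqs=[0.45, 0.20, 0.30, 0.05],
        ),
        BlockSpec(
            loci=["rs2273041", "rs2273040", "rs2273038", "rs55930553"],
            haplotypes=["CCCG", "CCTA", "TTTA", "CCCA"],
            freqs=[0.45, 0.20, 0.30, 0.05],
        ),
        BlockSpec(
            loci=["rs12564469", "rs9434711"],
            haplotypes=["AA", "GG", "AG"],
            freqs=[0.654 / 1.001, 0.341 / 1.001, 0.006 / 1.001],
        ),
    ]


@dataclass
class SimulationConfig:
    """Generating parameters of the synthetic cohort.

    The logistic risk model is
        logit P(case) = b0 + b_hap * n_risk + b_age (age - 50) + b_sex male
                        + b_smoke + b_drink + b_hap_x_drink * n_risk * drink
    with n_risk the individual's copy count of the risk haplotype.  The
    default effect b_hap = ln 9 puts the risk haplotype's allelic odds
    ratio at 9, the regime of a rare haplotype moving from control
    frequency ~0.006 to case frequency ~0.05.
    """

    n_cases: int = 829
    n_controls: int = 765
    blocks: list[BlockSpec] = field(default_factory=_default_blocks)
    risk_block: int = 2
    risk_haplotype: str = "AG"
    n_equilibrium_snps: int = 154
    equilibrium_freq_range: tuple[float, float] = (0.1, 0.5)
    b0: float = -5.0            # baseline log-odds; rare disease, so the
                                # case-frequency enrichment tracks the OR
    b_hap: float = float(np.log(9.0))
    b_hap_x_drink: float = 0.0
    b_age: float = 0.05         # per year, centred at 50
    b_sex: float = 0.6          # male vs female
    b_smoke: float = 0.6
    b_drink: float = 0.6
    male_rate: float = 0.66
    smoke_rate: float = 0.27
    drink_rate: float = 0.24
    genotype_missing_rate: float = 0.01
    covariate_missing_rate: float = 0.04
    max_batches: int = 2000
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.risk_haplotype not in self.blocks[self.risk_block].haplotypes:
            raise ValueError("risk haplotype not in its block's pool")


def interaction_config(**overrides) -> SimulationConfig:
    """Preset: risk restricted to drinkers (haplotype-by-drinking synergy).

    The main haplotype effect is off; drinkers carrying the risk haplotype
    get a strong per-copy effect, and drinking retains its own moderate
    marginal effect — the regime in which a two-factor interaction model
    should beat any single factor.  The other covariates are risk-neutral
    here so the synergy is the dominant signal.
    """
    kw = dict(b_hap=0.0, b_hap_x_drink=3.5, b_age=0.0, b_sex=0.0,
              b_smoke=0.0)
    kw.update(overrides)
    cfg = SimulationConfig(**kw)
    return cfg


def simulate_cohort(config: SimulationConfig):
    """Draw a retrospective cohort; returns (genotypes, phenotypes, truth).

    Individuals are sampled from the population model and assigned
    case/control status from the logistic risk; sampling continues until
    both quotas are filled (error if the quotas are unreachable within
    ``max_batches`` draws of 4096).  The truth record keeps the latent
    haplotype indices per block and all generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    n_target = config.n_cases + config.n_controls
    batch = 4096

    kept_haps = []          # per accepted individual: list of (h1,h2) per block
    kept_cov = []
    kept_case = []
    n_case = n_ctrl = 0
    for _ in range(config.max_batches):
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
        age = np.clip(rng.normal(50.0, 12.0, batch), 18.0, 90.0)
        male = rng.random(batch) < config.male_rate
        smoke = rng.random(batch) < config.smoke_rate
        drink = rng.random(batch) < config.drink_rate
        hap_draws = [rng.choice(len(b.haplotypes), size=(batch, 2), p=b.freqs)
                     for b in config.blocks]
        risk_idx = config.blocks[config.risk_block].haplotypes.index(
            config.risk_haplotype)
        n_risk = (hap_draws[config.risk_block] == risk_idx).sum(axis=1)
        logit = (config.b0 + config.b_hap * n_risk
                 + config.b_age * (age - 50.0) + config.b_sex * male
                 + config.b_smoke * smoke + config.b_drink * drink
                 + config.b_hap_x_drink * n_risk * drink)
        p_case = 1.0 / (1.0 + np.exp(-logit))
        is_case = rng.random(batch) < p_case
        for i in range(batch):
            if is_case[i] and n_case < config.n_cases:
                n_case += 1
            elif not is_case[i] and n_ctrl < config.n_controls:
                n_ctrl += 1
            else:
                continue
            kept_haps.append([hd[i] for hd in hap_draws])
            kept_cov.append((age[i], male[i], smoke[i], drink[i]))
            kept_case.append(bool(is_case[i]))
    if n_case < config.n_cases or n_ctrl < config.n_controls:
        raise RuntimeError("case/control quotas unreachable; risk model too "
                           "extreme for the draw budget")

    order = rng.permutation(n_target)
    kept_haps = [kept_haps[i] for i in order]
    kept_cov = [kept_cov[i] for i in order]
    kept_case = [kept_case[i] for i in order]
    sample_ids = [f"S{i + 1:05d}" for i in range(n_target)]

    # assemble the SNP panel: block loci followed by equilibrium SNPs,
    # blocks separated by equilibrium stretches
    snp_cols = []
    snp_ids = []
    alleles = []
    eq_freqs = rng.uniform(*config.equilibrium_freq_range,
                           config.n_equilibrium_snps)
    n_blocks = len(config.blocks)
    eq_per_gap = np.array_split(np.arange(config.n_equilibrium_snps),
                                n_blocks + 1)
    block_haps_latent = {}

    def add_equilibrium(idx_list):
        bases = ["A", "C", "G", "T"]
        for j in idx_list:
            p = eq_freqs[j]
            dos = rng.binomial(2, p, n_target).astype(np.int8)
            snp_cols.append(dos)
            snp_ids.append(f"snp{j + 1:04d}")
            major, minor = rng.choice(bases, size=2, replace=False)
            alleles.append((str(major), str(minor)))

    for b_idx, block in enumerate(config.blocks):
        add_equilibrium(eq_per_gap[b_idx])
        pairs = block.allele_pairs()
        h1 = np.array([kh[b_idx][0] for kh in kept_haps])
        h2 = np.array([kh[b_idx][1] for kh in kept_haps])
        block_haps_latent[b_idx] = np.stack([h1, h2], axis=1)
        hap_alleles = np.array([[1 if h[k] == pairs[k][1] else 0
                                 for k in range(len(block.loci))]
                                for h in block.haplotypes])
        for k, locus in enumerate(block.loci):
            dos = (hap_alleles[h1, k] + hap_alleles[h2, k]).astype(np.int8)
            snp_cols.append(dos)
            snp_ids.append(locus)
            alleles.append(pairs[k])
    add_equilibrium(eq_per_gap[n_blocks])

    dosage = np.stack(snp_cols, axis=1)
    if config.genotype_missing_rate > 0:
        miss = rng.random(dosage.shape) < config.genotype_missing_rate
        dosage = np.where(miss, MISSING, dosage).astype(np.int8)

    age = np.array([c[0] for c in kept_cov])
    male = np.array([c[1] for c in kept_cov])
    smoke = np.array([c[2] for c in kept_cov], dtype=object)
    drink = np.array([c[3] for c in kept_cov], dtype=object)
    smoke_lbl = np.where(smoke.astype(bool), "ever", "never").astype(object)
    drink_lbl = np.where(drink.astype(bool), "ever", "never").astype(object)
    if config.covariate_missing_rate > 0:
        smoke_lbl[rng.random(n_target) < config.covariate_missing_rate] = np.nan
        drink_lbl[rng.random(n_target) < config.covariate_missing_rate] = np.nan
    phen = pd.DataFrame({
        "sample_id": sample_ids,
        "status": np.where(kept_case, "case", "control"),
        "age": np.round(age, 1),
        "sex": np.where(male, "male", "female"),
        "smoking": smoke_lbl,
        "drinking": drink_lbl,
    })

    genotypes = GenotypeTable(sample_ids, snp_ids, dosage, alleles,
                              chrom=np.array(["1"] * len(snp_ids), object),
                              pos=np.arange(1, len(snp_ids) + 1) * 1000)
    phenotypes = PhenotypeTable(phen)

    is_case = np.array(kept_case)
    risk_idx = config.blocks[config.risk_block].haplotypes.index(
        config.risk_haplotype)
    latent = block_haps_latent[config.risk_block]
    n_risk = (latent == risk_idx).sum(axis=1)
    truth = {
        "config": config,
        "block_haplotypes": block_haps_latent,
        "risk_copies": n_risk,
        "case_risk_freq": float(n_risk[is_case].sum() / (2 * is_case.sum())),
        "control_risk_freq": float(n_risk[~is_case].sum() / (2 * (~is_case).sum())),
    }
    return genotypes, phenotypes, truth


# annotation values that pass every filter comfortably / planted failures
_PASS = dict(hwe=(0.05, 1.0), depth=(20.0, 60.0), gap=(50.0, 500.0))
_FAIL = dict(hwe=(0.0, 1e-5), depth=(1.0, 8.0), gap=(0.0, 10.0))


def simulate_annotations(snp_ids, fail_plan: dict[str, list[str]] | None = None,
                         seed: int | None = 0) -> VariantAnnotation:
    """QC annotation fixture with planted filter failures.

    ``fail_plan`` maps SNP id -> criteria to trigger (subset of hwe,
    duplicated_reads, low_depth, near_gap, cnv); all other SNPs pass every
    criterion comfortably.
    """
    rng = np.random.default_rng(seed)
    fail_plan = fail_plan or {}
    unknown = set(fail_plan) - set(snp_ids)
    if unknown:
        raise ValueError(f"fail_plan names unknown SNPs: {sorted(unknown)[:5]}")
    rows = []
    for sid in snp_ids:
        plan = fail_plan.get(sid, [])
        hwe = rng.uniform(*(_FAIL if "hwe" in plan else _PASS)["hwe"])
        depth = rng.uniform(*(_FAIL if "low_depth" in plan else _PASS)["depth"])
        gap = float(np.floor(
            rng.uniform(*(_FAIL if "near_gap" in plan else _PASS)["gap"]) + 1e-9))
        cnv = int(rng.integers(2, 5)) if "cnv" in plan else int(rng.integers(0, 2))
        rows.append({"snp_id": sid, "hwe_p": hwe,
                     "dup_flag": "duplicated_reads" in plan,
                     "depth": depth, "gap_distance": gap, "cnv_count": cnv})
    return VariantAnnotation(pd.DataFrame(rows))
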