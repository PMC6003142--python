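"""End-to-end study pipeline: qc -> phase -> ld -> assoc -> permute ->
qq/fprp -> mdr, driven by one config, with a hashed output manifest.

Each stage writes a tab-separated table under the output directory; the
manifest records every file with a SHA-256 content hash plus the seeds
used, so a rerun with the same config and seeds reproduces the hashes.
Multi-cohort (discovery/replication/combined) designs are supported by
concatenating cohorts and pooling 2x2 counts; pooled tables are the
elementwise sums of the per-cohort tables, while EM haplotype counts for
the combined cohort are re-estimated on the union.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import em as em_mod
from . import ld as ld_mod
from . import mdr as mdr_mod
from . import permutation as perm_mod
from . import qc as qc_mod
from . import qq_fprp as qf_mod
from .core import MISSING, GenotypeTable, PhenotypeTable, VariantAnnotation
from .io import (read_annotations, read_ped_map, read_phenotypes, read_vcf,
                 write_table)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "haplorisk_out"
    # inputs (either PED/MAP or VCF; ignored when objects are passed directly)
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    phenotypes: str | None = None
    annotations: str | None = None
    # qc
    hwe_sample: str = "controls"          # or "pooled"
    qc_thresholds: qc_mod.FilterThresholds = field(
        default_factory=qc_mod.FilterThresholds)
    # ld / blocks
    blocks: str | list[list[str]] = "auto"
    ld_max_span: int = 12
    # association
    adjust: tuple[str, ...] = ("age", "sex", "smoking", "drinking")
    strata: tuple[str, ...] = ("age", "sex", "smoking", "drinking")
    # permutation
    permutation_B: int = 1000
    # fprp
    fprp_priors: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)
    fprp_target_or: float = 1.5
    # mdr
    mdr_kmax: int = 5
    mdr_splits: int = 100
    mdr_perms: int = 0                    # 0 skips the MDR permutation test
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = raw.pop("qc_thresholds", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) and k in
                     ("adjust", "strata", "fprp_priors") else v
                     for k, v in raw.items()})
        if th:
            cfg.qc_thresholds = qc_mod.FilterThresholds(**th)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}; rerun with "
                         f"`haplorisk {stage} ...` to replay it standalone")
        self.stage = stage


def _load_inputs(config: PipelineConfig, genotypes, phenotypes, annotations):
    if genotypes is None:
        if config.ped and config.map:
            genotypes = read_ped_map(config.ped, config.map)
        elif config.vcf:
            genotypes = read_vcf(config.vcf)
        else:
            raise PipelineError("qc", "no genotype input configured")
    if phenotypes is None:
        if not config.phenotypes:
            raise PipelineError("qc", "no phenotype input configured")
        phenotypes = read_phenotypes(config.phenotypes)
    if annotations is None and config.annotations:
        annotations = read_annotations(config.annotations)
    return genotypes, phenotypes.aligned_to(genotypes), annotations


def run_pipeline(config: PipelineConfig,
                 genotypes: GenotypeTable | None = None,
                 phenotypes: PhenotypeTable | None = None,
                 annotations: VariantAnnotation | None = None) -> dict:
    """Execute all stages in order and return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}, "stages": []}

    def emit(stage: str, name: str, frame: pd.DataFrame):
        path = out / name
        write_table(frame, path)
        manifest["files"][name] = _sha256(path)
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)

    genotypes, phenotypes, annotations = _load_inputs(
        config, genotypes, phenotypes, annotations)

    # --- qc ---------------------------------------------------------------
    ann_frame = (annotations.frame.copy() if annotations is not None
                 else pd.DataFrame({"snp_id": genotypes.snp_ids}))
    if "hwe_p" not in ann_frame.columns:
        mask = (None if config.hwe_sample == "pooled"
                else ~phenotypes.is_case)
        ann_frame["hwe_p"] = qc_mod.hwe_from_genotypes(genotypes, mask)
    reports = qc_mod.apply_filters(VariantAnnotation(ann_frame),
                                   config.qc_thresholds)
    emit("qc", "qc_report.tsv", qc_mod.report_frame(reports))
    genotypes = qc_mod.filter_genotypes(genotypes, reports)
    if genotypes.n_snps == 0:
        raise PipelineError("qc", "no SNPs pass the filters")

    # --- ld + blocks ------------------------------------------------------
    if config.blocks == "auto":
        pairs = ld_mod.ld_matrix(genotypes, max_span=config.ld_max_span,
                                 seed=config.seed)
        emit("ld", "ld.tsv", pd.DataFrame(
            [{"snp_i": p.snp_i, "snp_j": p.snp_j, "D": p.D,
              "Dprime": p.Dprime, "r2": p.r2, "ci_low": p.ci_low,
              "ci_high": p.ci_high} for p in pairs.values()]))
        blocks = ld_mod.find_blocks(pairs, genotypes.n_snps)
        block_loci = [[genotypes.snp_ids[i] for i in b.members] for b in blocks]
    else:
        block_loci = [list(b) for b in config.blocks]
    emit("ld", "blocks.tsv", pd.DataFrame(
        [{"block": i + 1, "n_snps": len(loci), "snps": ",".join(loci)}
         for i, loci in enumerate(block_loci)]))

    # --- phase (EM per block) --------------------------------------------
    hapsets = []
    hap_rows = []
    for bi, loci in enumerate(block_loci):
        hset = em_mod.em_frequencies(genotypes, loci, seed=config.seed + bi)
        hapsets.append(hset)
        ne = em_mod.effective_haplotype_count(hset.freqs)
        for label, fr in zip(hset.labels(), hset.freqs):
            hap_rows.append({"block": bi + 1, "haplotype": label,
                             "freq": fr, "n_e": ne,
                             "loglik": hset.loglik,
                             "converged": hset.converged})
    emit("phase", "haplotype_freqs.tsv", pd.DataFrame(hap_rows))

    # --- association ------------------------------------------------------
    bonf = assoc_mod.bonferroni_threshold(0.05, genotypes.n_snps)
    snp_rows = []
    snp_exposures = np.where(genotypes.dosage == MISSING, np.nan,
                             genotypes.dosage.astype(float)).T
    for j, sid in enumerate(genotypes.snp_ids):
        tab = assoc_mod.allele_table(genotypes, phenotypes, sid)
        t, p = assoc_mod.chisq_2x2(tab)
        orr, lo, hi = assoc_mod.crude_or(tab)
        snp_rows.append({"snp_id": sid, "a": tab.a, "b": tab.b, "c": tab.c,
                         "d": tab.d, "chi2": t, "p": p, "or": orr,
                         "or_ci_low": lo, "or_ci_high": hi,
                         "significant_bonferroni": p < bonf})
    snp_assoc = pd.DataFrame(snp_rows)

    hap_assoc_rows = []
    hap_exposures = []
    hap_marker_ids = []
    for bi, hset in enumerate(hapsets):
        for label in hset.labels():
            counts = em_mod.expected_counts(genotypes, phenotypes, hset, label)
            tab = assoc_mod.haplotype_table(counts)
            t, p = assoc_mod.chisq_2x2(tab)
            dosage = em_mod.expected_hap_dosage(genotypes, hset, label)
            try:
                or_adj, p_adj = assoc_mod.adjusted_association(
                    dosage, phenotypes, config.adjust)
            except ValueError:
                or_adj, p_adj = np.nan, np.nan
            hap_assoc_rows.append({
                "block": bi + 1, "haplotype": label,
                "ratio_counts": counts.format_ratio(),
                "case_freq": counts.case_count /
                             (counts.case_count + counts.case_rest),
                "control_freq": counts.control_count /
                                (counts.control_count + counts.control_rest),
                "chi2": t, "p": p, "or_adjusted": or_adj,
                "p_adjusted": p_adj})
            hap_exposures.append(dosage)
            hap_marker_ids.append(f"block{bi + 1}:{label}")
    hap_assoc = pd.DataFrame(hap_assoc_rows)

    # --- permutation (max(T) over the SNP family, then haplotypes) --------
    perm_snp = perm_mod.maxT(snp_exposures, phenotypes,
                             B=config.permutation_B, seed=config.seed,
                             marker_ids=list(genotypes.snp_ids))
    snp_assoc["p_permutation"] = perm_snp.p_empirical
    emit("assoc", "assoc_snps.tsv", snp_assoc)
    if hap_exposures:
        perm_hap = perm_mod.maxT(np.array(hap_exposures), phenotypes,
                                 B=config.permutation_B, seed=config.seed + 1,
                                 marker_ids=hap_marker_ids)
        hap_assoc["p_permutation"] = perm_hap.p_empirical
    emit("assoc", "assoc_haplotypes.tsv", hap_assoc)
    emit("permute", "permutation.tsv", pd.DataFrame(
        {"marker": perm_snp.marker_ids, "T_obs": perm_snp.observed_T,
         "p_empirical": perm_snp.p_empirical, "B": perm_snp.B}))

    # --- qq ---------------------------------------------------------------
    qq = qf_mod.qq_points(snp_assoc["chi2"].to_numpy(), reference="chisq1")
    emit("qq", "qq.tsv", pd.DataFrame(
        {"expected": qq.expected, "observed": qq.observed}))

    # --- top haplotype: stratified analysis + fprp ------------------------
    if len(hap_assoc):
        top = hap_assoc.sort_values("p").iloc[0]
        top_block = int(top["block"]) - 1
        top_label = str(top["haplotype"])
        dosage = em_mod.expected_hap_dosage(genotypes, hapsets[top_block],
                                            top_label)
        strat_frames = []
        fprp_analyses = {}
        counts = em_mod.expected_counts(genotypes, phenotypes,
                                        hapsets[top_block], top_label)
        fprp_analyses["overall"] = (assoc_mod.haplotype_table(counts),
                                    float(top["p"]))
        for var in config.strata:
            sf = assoc_mod.stratified_analysis(dosage, phenotypes, var)
            sf.insert(0, "variable", var)
            strat_frames.append(sf)
            for level, mask in assoc_mod.stratify_mask(phenotypes, var):
                ok = mask & ~np.isnan(dosage)
                case = phenotypes.is_case & ok
                ctrl = ~phenotypes.is_case & ok
                if case.sum() == 0 or ctrl.sum() == 0:
                    continue
                a = float(dosage[case].sum())
                c = float(dosage[ctrl].sum())
                tab = assoc_mod.TwoByTwoTable(a, 2.0 * case.sum() - a,
                                              c, 2.0 * ctrl.sum() - c)
                _, p_stratum = assoc_mod.chisq_2x2(tab)
                fprp_analyses[f"{var}:{level}"] = (tab, p_stratum)
        emit("assoc", "stratified.tsv", pd.concat(strat_frames,
                                                  ignore_index=True))
        grid = qf_mod.fprp_grid(fprp_analyses, priors=config.fprp_priors,
                                target_or=config.fprp_target_or)
        emit("fprp", "fprp.tsv", grid)

        # --- mdr ----------------------------------------------------------
        factors = mdr_mod.build_factor_table(phenotypes, dosage,
                                             carrier_rule="dosage")
        models = mdr_mod.mdr_search(factors, k_max=config.mdr_kmax,
                                    n_splits=config.mdr_splits,
                                    seed=config.seed)
        if config.mdr_perms > 0:
            p_perm = mdr_mod.mdr_permutation_p(
                factors, k_max=config.mdr_kmax, B=config.mdr_perms,
                n_splits=config.mdr_splits, seed=config.seed)
            mdr_mod.best_model(models).p_permutation = p_perm
        emit("mdr", "mdr.tsv", mdr_mod.report_frame(models))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def pool_2x2(tables) -> assoc_mod.TwoByTwoTable:
    """Elementwise sum of per-cohort 2x2 tables (the combined-study table)."""
    a = sum(t.a for t in tables)
    b = sum(t.b for t in tables)
    c = sum(t.c for t in tables)
    d = sum(t.d for t in tables)
    return assoc_mod.TwoByTwoTable(a, b, c, d)


def concat_cohorts(cohorts) -> tuple[GenotypeTable, PhenotypeTable]:
    """Union of cohorts sharing one SNP panel (combined-study input).

    Sample ids are prefixed per cohort to stay unique; EM on the union is
    the combined-study estimate (not generally the sum of per-cohort EM
    fractional counts).
    """
    base = cohorts[0][0]
    ids, frames, dosages = [], [], []
    for ci, (gt, ph) in enumerate(cohorts):
        if gt.snp_ids != base.snp_ids:
            raise ValueError("cohorts must share an identical SNP panel")
        prefix = f"c{ci + 1}_"
        ids.extend(prefix + s for s in gt.sample_ids)
        dosages.append(gt.dosage)
        fr = ph.aligned_to(gt).frame.copy()
        fr["sample_id"] = prefix + fr["sample_id"].astype(str)
        frames.append(fr)
    genotypes = GenotypeTable(ids, list(base.snp_ids),
                              np.vstack(dosages), list(base.alleles),
                              base.chrom.copy(), base.pos.copy())
    phenotypes = PhenotypeTable(pd.concat(frames, ignore_index=True))
    return genotypes, phenotypes


def _serializable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _serializable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
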