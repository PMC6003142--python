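import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import chi2

from haplorisk import (PhenotypeTable, TwoByTwoTable, adjusted_association,
                       allele_table, bonferroni_threshold, chisq_2x2,
                       crude_or, haplotype_table, pi_ratio,
                       stratified_analysis)
from haplorisk.em import ExpectedHaplotypeCounts


class TestChisq2x2:
    @pytest.mark.parametrize("cells,expected_t", [
        # replication and combined allele-count tables of the two block-3 SNPs
        ((659, 289, 570, 298), 3.065),
        ((341, 629, 309, 579), 0.026),
        ((1003, 431, 857, 445), 5.328),
        ((511, 953, 460, 868), 0.022),
    ])
    def test_integer_allele_tables(self, cells, expected_t):
        t, p = chisq_2x2(TwoByTwoTable(*cells))
        assert t == pytest.approx(expected_t, abs=5e-4)
        assert 0 <= p <= 1

    def test_no_association(self):
        t, p = chisq_2x2(TwoByTwoTable(10, 20, 10, 20))
        assert t == 0.0 and p == 1.0

    def test_degenerate_margin(self):
        t, p = chisq_2x2(TwoByTwoTable(5, 0, 3, 0))
        assert t == 0.0 and p == 1.0

    def test_row_and_column_swap_invariance(self):
        t0, _ = chisq_2x2(TwoByTwoTable(12, 5, 7, 20))
        t1, _ = chisq_2x2(TwoByTwoTable(20, 7, 5, 12))  # both swapped
        assert t1 == pytest.approx(t0, rel=1e-12)

    def test_scales_linearly_with_table(self):
        base = TwoByTwoTable(12, 5, 7, 20)
        t0, _ = chisq_2x2(base)
        t3, _ = chisq_2x2(TwoByTwoTable(36, 15, 21, 60))
        assert t3 == pytest.approx(3 * t0, rel=1e-12)

    def test_p_matches_numerical_tail_integral(self):
        t, p = chisq_2x2(TwoByTwoTable(30, 70, 50, 50))
        tail, _ = quad(lambda x: chi2.pdf(x, 1), t, np.inf)
        assert p == pytest.approx(tail, abs=1e-10)

    def test_fractional_cells_accepted(self):
        t, _ = chisq_2x2(TwoByTwoTable(26.2, 467.8, 2.2, 437.8))
        assert t > 0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)


class TestAlleleTable:
    def test_hand_tally(self, toy_genotypes, toy_phenotypes):
        # rs1 dosages: cases (S0,S1,S4) = 0,1,1; controls (S2,S3) = 2,0
        tab = allele_table(toy_genotypes, toy_phenotypes, "rs1")
        assert (tab.a, tab.b, tab.c, tab.d) == (4, 2, 2, 2)

    def test_minor_convention_flip(self, toy_genotypes, toy_phenotypes):
        tab = allele_table(toy_genotypes, toy_phenotypes, "rs1",
                           count_minor=True)
        assert (tab.a, tab.b, tab.c, tab.d) == (2, 4, 2, 2)

    def test_missing_dosages_excluded(self, toy_genotypes, toy_phenotypes):
        # rs3 has one missing call (S3, control)
        tab = allele_table(toy_genotypes, toy_phenotypes, "rs3")
        assert tab.a + tab.b == 6  # 3 cases x 2 alleles
        assert tab.c + tab.d == 2  # 1 control after exclusion

    def test_all_missing_rejected(self, toy_phenotypes):
        from haplorisk import GenotypeTable
        gt = GenotypeTable([f"S{i}" for i in range(5)], ["rs1"],
                           np.full((5, 1), -1, dtype=np.int8), [("A", "G")])
        with pytest.raises(ValueError, match="missing"):
            allele_table(gt, toy_phenotypes, "rs1")

    def test_counts_reconcile_with_dosage_sums(self, study_cohort):
        gt, ph, _ = study_cohort
        sid = "rs12564469"
        tab = allele_table(gt, ph, sid, count_minor=True)
        j = gt.snp_index(sid)
        ok = gt.dosage[:, j] >= 0
        assert tab.a + tab.c == gt.dosage[ok, j].sum()
        assert tab.a + tab.b + tab.c + tab.d == 2 * ok.sum()


def test_haplotype_table_from_expected_counts():
    c = ExpectedHaplotypeCounts("AG", 26.2, 467.8, 2.2, 437.8)
    tab = haplotype_table(c)
    t, _ = chisq_2x2(tab)
    assert t == pytest.approx(18.2, abs=0.1)


class TestCrudeOr:
    def test_null_table(self):
        orr, lo, hi = crude_or(TwoByTwoTable(10, 10, 10, 10))
        assert orr == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_closed_form_ci(self):
        orr, lo, hi = crude_or(TwoByTwoTable(20, 10, 10, 20))
        assert orr == pytest.approx(4.0)
        se = np.sqrt(0.1 + 0.1 + 0.05 + 0.05)
        assert lo == pytest.approx(4.0 * np.exp(-1.959963985 * se), rel=1e-6)
        assert hi == pytest.approx(4.0 * np.exp(1.959963985 * se), rel=1e-6)

    def test_zero_cell_continuity_corrected(self):
        orr, lo, hi = crude_or(TwoByTwoTable(0, 10, 5, 5))
        assert np.isfinite(orr) and np.isfinite(lo) and np.isfinite(hi)


def _newton_logistic_oracle(X, y, tol=1e-12):
    """Direct Newton solve of the logistic log-likelihood."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        grad = X.T @ (y - mu)
        hess = (X * (mu * (1 - mu))[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestAdjustedAssociation:
    def _phen(self, n, rng, status):
        return PhenotypeTable(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "status": np.where(status, "case", "control"),
            "age": rng.normal(50, 10, n).round(1),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "smoking": np.where(rng.random(n) < 0.3, "ever", "never"),
            "drinking": np.where(rng.random(n) < 0.3, "ever", "never"),
        }))

    def test_matches_newton_oracle_on_small_data(self):
        rng = np.random.default_rng(3)
        n = 40
        expo = rng.integers(0, 3, n).astype(float)
        age = rng.normal(50, 10, n)
        status = rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.5 * expo)))
        ph = PhenotypeTable(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "status": np.where(status, "case", "control"),
            "age": age}))
        or_adj, p_adj = adjusted_association(expo, ph, covariates=("age",))
        beta = _newton_logistic_oracle(np.column_stack([expo, age]),
                                       status.astype(float))
        assert np.log(or_adj) == pytest.approx(beta[1], abs=1e-6)

    def test_collapses_to_crude_when_covariates_independent(self):
        rng = np.random.default_rng(11)
        n = 4000
        expo = rng.binomial(2, 0.3, n).astype(float)
        status = rng.random(n) < 1 / (1 + np.exp(-(-0.8 + 0.4 * expo)))
        ph = self._phen(n, rng, status)
        or_adj, p_adj = adjusted_association(expo, ph)
        ok = ~ph.frame[["smoking", "drinking"]].isna().any(axis=1).to_numpy()
        a = expo[status & ok].sum()
        c = expo[~status & ok].sum()
        tab = TwoByTwoTable(a, 2 * (status & ok).sum() - a,
                            c, 2 * (~status & ok).sum() - c)
        orr, _, _ = crude_or(tab)
        assert or_adj == pytest.approx(orr, rel=0.05)

    def test_recovers_true_adjusted_or_under_confounding(self):
        # confounder drives both exposure and outcome; the adjusted model
        # should land near the generating conditional OR of 2
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(30):
            n = 1500
            conf = rng.random(n) < 0.4
            expo = rng.binomial(1, np.where(conf, 0.6, 0.2)).astype(float)
            lin = -1.5 + np.log(2.0) * expo + 1.2 * conf
            status = rng.random(n) < 1 / (1 + np.exp(-lin))
            ph = PhenotypeTable(pd.DataFrame({
                "sample_id": [f"S{i}" for i in range(n)],
                "status": np.where(status, "case", "control"),
                "smoking": np.where(conf, "ever", "never")}))
            or_adj, _ = adjusted_association(expo, ph,
                                             covariates=("smoking",))
            import statsmodels.api as sm
            X = sm.add_constant(np.column_stack([expo, conf.astype(float)]))
            fit = sm.Logit(status.astype(float), X).fit(disp=0)
            ci = fit.conf_int()[1]
            hits += ci[0] <= np.log(2.0) <= ci[1]
        assert hits >= 27  # ~95% coverage over 30 replicates

    def test_separation_flagged(self):
        n = 60
        expo = np.array([2.0] * 30 + [0.0] * 30)
        ph = PhenotypeTable(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "status": ["case"] * 30 + ["control"] * 30,
            "age": [50.0] * n}))
        or_adj, p_adj = adjusted_association(expo, ph, covariates=("age",))
        assert np.isnan(or_adj) and np.isnan(p_adj)

    def test_too_few_complete_cases(self):
        ph = PhenotypeTable(pd.DataFrame({
            "sample_id": ["S1", "S2"], "status": ["case", "control"],
            "age": [50.0, 60.0]}))
        with pytest.raises(ValueError, match="complete"):
            adjusted_association(np.array([1.0, 0.0]), ph, covariates=("age",))


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 164, 0.05 / 164),   # displayed as 0.0003
        (0.05, 1, 0.05),
        (0.05, 10, 0.005),         # the 10-haplotype family threshold
    ])
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)
        assert bonferroni_threshold(0.05, 164) == pytest.approx(0.0003, abs=1e-5)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestStratified:
    @pytest.mark.parametrize("p1,p2,expected", [
        (1.18e-4, 6.04e-8, 5.12e-4),
        (0.029, 9.43e-8, 3.25e-6),
        (0.5, 0.5, 1.0),
    ])
    def test_pi_ratio(self, p1, p2, expected):
        assert pi_ratio(p1, p2) == pytest.approx(expected, rel=5e-3)

    def test_pi_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            pi_ratio(0.0, 0.5)

    def test_stratified_structure_and_pi(self, study_cohort):
        from haplorisk import em_frequencies, expected_hap_dosage
        gt, ph, _ = study_cohort
        hs = em_frequencies(gt, ["rs12564469", "rs9434711"], seed=0)
        dos = expected_hap_dosage(gt, hs, "AG")
        out = stratified_analysis(dos, ph.aligned_to(gt), "drinking")
        assert list(out["stratum"]) == ["never", "ever"]
        assert np.isfinite(out.loc[1, "pi_ratio"])
        assert out.loc[1, "pi_ratio"] == pytest.approx(
            out.loc[1, "p"] / out.loc[0, "p"])

    def test_age_strata_partition(self, study_cohort):
        gt, ph, _ = study_cohort
        phen = ph.aligned_to(gt)
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.2, gt.n_samples).astype(float)
        out = stratified_analysis(dos, phen, "age")
        assert out["n"].sum() == gt.n_samples  # age never missing here

    def test_unknown_stratum_variable(self, study_cohort):
        gt, ph, _ = study_cohort
        with pytest.raises(ValueError, match="stratum"):
            stratified_analysis(np.zeros(gt.n_samples), ph.aligned_to(gt),
                                "height")
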