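import itertools

import numpy as np
import pytest

from haplorisk import (GenotypeTable, PhenotypeTable, assign_phase,
                       effective_haplotype_count, em_frequencies,
                       enumerate_phases, expected_counts,
                       expected_hap_dosage)
from haplorisk.em import ExpectedHaplotypeCounts, HaplotypeSet
import pandas as pd


def _table(dosage, snp_ids=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    m = dosage.shape[1]
    snp_ids = snp_ids or [f"rs{j}" for j in range(m)]
    return GenotypeTable([f"S{i}" for i in range(dosage.shape[0])],
                         snp_ids, dosage,
                         [("A", "G")] * m)


class TestEnumeratePhases:
    def test_fully_homozygous_single_pair(self):
        pairs = enumerate_phases([0, 0])
        assert pairs == [((0, 0), (0, 0))]
        assert enumerate_phases([2, 0]) == [((1, 0), (1, 0))]

    def test_double_heterozygote_cis_trans(self):
        pairs = {frozenset(p) for p in enumerate_phases([1, 1])}
        assert pairs == {frozenset({(0, 0), (1, 1)}),
                         frozenset({(0, 1), (1, 0)})}

    @pytest.mark.parametrize("h", [0, 1, 2, 3, 4])
    def test_pair_count_and_sum_against_brute_force(self, h):
        # genotype: h heterozygous loci plus one homozygous of each kind
        g = np.array([1] * h + [0, 2])
        pairs = enumerate_phases(g)
        assert len(pairs) == max(1, 2 ** (h - 1))
        for h1, h2 in pairs:
            np.testing.assert_array_equal(np.add(h1, h2), g)
        # brute force: all ordered haplotype pairs over the loci
        L = len(g)
        brute = set()
        for h1 in itertools.product((0, 1), repeat=L):
            for h2 in itertools.product((0, 1), repeat=L):
                if np.array_equal(np.add(h1, h2), g):
                    brute.add(frozenset([h1, h2]))
        assert {frozenset(p) for p in pairs} == brute

    def test_missing_genotype_rejected(self):
        with pytest.raises(ValueError):
            enumerate_phases([0, -1])


def _simplex_grid_loglik_oracle(dosage, step_coarse=0.01, step_fine=0.001):
    """Exhaustive observed-data likelihood over the 3-simplex of the four
    2-locus haplotypes: coarse grid then local refinement."""
    counts9 = np.bincount(3 * dosage[:, 0] + dosage[:, 1], minlength=9)
    hap_dos = [(0, 0), (0, 1), (1, 0), (1, 1)]

    def loglik(f):
        probs = np.zeros((f.shape[0], 9))
        for a, (x1, y1) in enumerate(hap_dos):
            for b, (x2, y2) in enumerate(hap_dos):
                probs[:, 3 * (x1 + x2) + (y1 + y2)] += f[:, a] * f[:, b]
        return (counts9 * np.log(np.maximum(probs, 1e-300))).sum(axis=1)

    def grid(lo, hi, step):
        axes = [np.arange(lo[k], hi[k] + step / 2, step) for k in range(3)]
        pts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
        keep = pts.sum(axis=1) <= 1 + 1e-12
        pts = pts[keep]
        return np.column_stack([pts, 1 - pts.sum(axis=1)])

    f = grid([0, 0, 0], [1, 1, 1], step_coarse)
    best = f[np.argmax(loglik(f))]
    lo = np.maximum(best[:3] - 2 * step_coarse, 0)
    hi = np.minimum(best[:3] + 2 * step_coarse, 1)
    f = grid(lo, hi, step_fine)
    return f[np.argmax(loglik(f))]


class TestEmFrequencies:
    def test_single_locus_fixed_point_at_allele_freqs(self):
        gt = _table([[0], [1], [2]])
        hs = em_frequencies(gt, seed=0)
        freqs = dict(zip(hs.haplotypes, hs.freqs))
        assert freqs[(0,)] == pytest.approx(0.5)
        assert freqs[(1,)] == pytest.approx(0.5)

    def test_unambiguous_data_recovers_exact_proportions(self):
        # all individuals doubly homozygous: no phase ambiguity
        gt = _table([[0, 0]] * 5 + [[2, 2]] * 3 + [[0, 2]] * 2)
        hs = em_frequencies(gt, seed=0)
        freqs = dict(zip(hs.haplotypes, hs.freqs))
        assert freqs[(0, 0)] == pytest.approx(0.5)
        assert freqs[(1, 1)] == pytest.approx(0.3)
        assert freqs[(0, 1)] == pytest.approx(0.2)
        # log-likelihood equals the multinomial maximum
        expected_ll = sum(n * np.log(p) for n, p in
                          [(5, 0.25), (3, 0.09), (2, 2 * 0.5 * 0.3 * 0 + 0.2**2)]
                          if p > 0)
        # genotype (0,2): only pair is (0,1)/(0,1) with prob 0.2^2
        assert hs.loglik == pytest.approx(expected_ll, abs=1e-6)

    def test_matches_exhaustive_likelihood_grid(self):
        rng = np.random.default_rng(5)
        true = np.array([0.4, 0.3, 0.2, 0.1])
        haps = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
        draws = rng.choice(4, size=(20, 2), p=true)
        dosage = haps[draws[:, 0]] + haps[draws[:, 1]]
        gt = _table(dosage)
        hs = em_frequencies(gt, seed=0, n_restarts=8)
        est = {h: f for h, f in zip(hs.haplotypes, hs.freqs)}
        oracle = _simplex_grid_loglik_oracle(dosage)
        for k, h in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            assert est.get(h, 0.0) == pytest.approx(oracle[k], abs=2e-3)

    def test_missing_locus_individuals_excluded(self):
        gt = _table([[0, 0], [2, 2], [1, -1]])
        hs = em_frequencies(gt, seed=0)
        freqs = dict(zip(hs.haplotypes, hs.freqs))
        assert freqs[(0, 0)] == pytest.approx(0.5)
        assert freqs[(1, 1)] == pytest.approx(0.5)

    def test_no_complete_individuals_fatal(self):
        gt = _table([[0, -1], [-1, 1]])
        with pytest.raises(ValueError, match="complete"):
            em_frequencies(gt, seed=0)

    def test_truth_init_never_beaten_by_random_starts(self):
        rng = np.random.default_rng(9)
        true = np.array([0.65, 0.29, 0.05, 0.01])
        haps = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
        draws = rng.choice(4, size=(200, 2), p=true)
        gt = _table(haps[draws[:, 0]] + haps[draws[:, 1]])
        with_truth = em_frequencies(gt, seed=1, n_restarts=3, init=true)
        random_only = em_frequencies(gt, seed=1, n_restarts=3)
        assert with_truth.loglik >= random_only.loglik - 1e-7

    def test_frequencies_on_simplex(self, small_cohort):
        gt, _, _ = small_cohort
        hs = em_frequencies(gt, ["rs12564469", "rs9434711"], seed=0)
        assert hs.freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (hs.freqs >= 0).all()
        assert len(set(hs.haplotypes)) == len(hs.haplotypes)


class TestAssignPhase:
    def _hapset(self, freqs):
        return HaplotypeSet(["rs1", "rs2"],
                            [(0, 0), (0, 1), (1, 0), (1, 1)],
                            np.asarray(freqs), 0.0, 1, True,
                            [("A", "G"), ("A", "G")])

    def test_homozygous_always_assigned(self):
        a = assign_phase([0, 2], self._hapset([0.25, 0.25, 0.25, 0.25]))
        assert a.assigned and a.posterior == pytest.approx(1.0)
        assert a.pair == ((0, 1), (0, 1))

    def test_double_het_with_only_cis_support(self):
        a = assign_phase([1, 1], self._hapset([0.5, 0.0, 0.0, 0.5]))
        assert a.assigned and a.posterior == pytest.approx(1.0)
        assert frozenset(a.pair) == frozenset({(0, 0), (1, 1)})

    def test_balanced_cis_trans_unassigned(self):
        # cis weight 2*(0.4*0.1) equals trans weight 2*(0.4*0.1)
        a = assign_phase([1, 1], self._hapset([0.4, 0.1, 0.4, 0.1]))
        assert not a.assigned
        assert a.posterior == pytest.approx(0.5)

    def test_incompatible_genotype_zero_posterior(self):
        a = assign_phase([2, 2], self._hapset([0.5, 0.5, 0.0, 0.0]))
        assert not a.assigned and a.posterior == 0.0


class TestEffectiveHaplotypeCount:
    @pytest.mark.parametrize("freqs,expected", [
        ([1.0], 1.0),
        ([0.25, 0.25, 0.25, 0.25], 4.0),
        ([0.5, 0.3, 0.2], 1 / 0.38),
    ])
    def test_values(self, freqs, expected):
        assert effective_haplotype_count(freqs) == pytest.approx(expected)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = rng.dirichlet(np.ones(6))
            ne = effective_haplotype_count(f)
            assert 1.0 - 1e-9 <= ne <= 6.0 + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            effective_haplotype_count([])


class TestExpectedCounts:
    def test_unambiguous_counts_are_integer_tallies(self):
        gt = _table([[0, 0], [2, 2], [0, 0], [2, 2]])
        ph = PhenotypeTable(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(4)],
            "status": ["case", "case", "control", "control"]}))
        hs = em_frequencies(gt, seed=0)
        c = expected_counts(gt, ph, hs, (1, 1))
        assert (c.case_count, c.case_rest) == (2.0, 2.0)
        assert (c.control_count, c.control_rest) == (2.0, 2.0)

    def test_ratio_format_contract(self):
        c = ExpectedHaplotypeCounts("AG", 26.2, 467.8, 2.2, 437.8)
        assert c.format_ratio() == "26.2: 467.8, 2.2: 437.8"

    def test_counts_conserve_chromosomes(self, small_cohort):
        gt, ph, _ = small_cohort
        hs = em_frequencies(gt, ["rs12564469", "rs9434711"], seed=0)
        case_totals = set()
        ctrl_totals = set()
        for lab in hs.labels():
            c = expected_counts(gt, ph, hs, lab)
            case_totals.add(round(c.case_count + c.case_rest, 6))
            ctrl_totals.add(round(c.control_count + c.control_rest, 6))
        # every haplotype sees the same 2 * (complete individuals) total
        assert len(case_totals) == 1 and len(ctrl_totals) == 1
        assert case_totals.pop() % 2 == 0

    def test_planted_risk_haplotype_frequency_recovered(self, study_cohort):
        gt, ph, truth = study_cohort
        hs = em_frequencies(gt, ["rs12564469", "rs9434711"], seed=0)
        c = expected_counts(gt, ph, hs, "AG")
        est_case_freq = c.case_count / (c.case_count + c.case_rest)
        n_chrom = c.case_count + c.case_rest
        true_freq = truth["case_risk_freq"]
        sd = np.sqrt(true_freq * (1 - true_freq) / n_chrom)
        assert abs(est_case_freq - true_freq) < 3 * sd + 0.002

    def test_unknown_haplotype_rejected(self, small_cohort):
        gt, ph, _ = small_cohort
        hs = em_frequencies(gt, ["rs12564469", "rs9434711"], seed=0)
        with pytest.raises(KeyError):
            expected_counts(gt, ph, hs, "ZZ")


def test_expected_dosage_sums_match_counts(small_cohort):
    gt, ph, _ = small_cohort
    hs = em_frequencies(gt, ["rs12564469", "rs9434711"], seed=0)
    dos = expected_hap_dosage(gt, hs, "AG")
    c = expected_counts(gt, ph, hs, "AG")
    case = ph.aligned_to(gt).is_case
    assert np.nansum(dos[case]) == pytest.approx(c.case_count)
    assert np.nansum(dos[~case]) == pytest.approx(c.control_count)
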