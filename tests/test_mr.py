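"""Mendelian-randomization engine: estimator oracles, robustness and
invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crosstrait.ldref import LDBlock, LDReference
from crosstrait.mr import (InstrumentSet, MRError, bonferroni_filter,
                           classify_bw_instruments, clump_instruments, ivw,
                           make_instrument_set, max_likelihood, mr_egger,
                           mr_power_binary, mr_presso, mvmr_ivw,
                           weighted_median, instrument_sets_from_labels)
from crosstrait.simulate import simulate_bw_instrument_panel

from conftest import make_sumstats


def _inst(bx, by, sy, sx=None, **kw):
    bx = np.asarray(bx, dtype=float)
    return InstrumentSet(
        rsid=np.array([f"rs{i + 1}" for i in range(len(bx))]),
        bx=bx, sx=np.full_like(bx, 0.01) if sx is None else np.asarray(sx),
        by=np.asarray(by, dtype=float), sy=np.asarray(sy, dtype=float), **kw)


class TestClumping:
    @pytest.fixture
    def clump_ld(self):
        R = np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
        return LDReference([
            LDBlock(chrom=1, rsids=["rsA", "rsB"],
                    positions=np.array([100_000, 110_000]), R=R),
            LDBlock(chrom=2, rsids=["rsC"], positions=np.array([100_000]),
                    R=np.eye(1)),
        ])

    def test_no_candidates_below_threshold(self, clump_ld):
        s = make_sumstats(["rsA", "rsB", "rsC"], [0.01] * 3, [0.05] * 3,
                          chrom=[1, 1, 2], pos=[100_000, 110_000, 100_000])
        assert clump_instruments(s, clump_ld, p_thresh=5e-8) == []

    def test_greedy_three_snp_example(self, clump_ld):
        z = [stats.norm.isf(p / 2) for p in (1e-10, 1e-9, 1e-8)]
        betas = [zz * 0.05 for zz in z]
        s = make_sumstats(["rsA", "rsB", "rsC"], betas, [0.05] * 3,
                          chrom=[1, 1, 2], pos=[100_000, 110_000, 100_000])
        picked = clump_instruments(s, clump_ld, p_thresh=5e-8,
                                   r2_thresh=0.1, window_bp=1_000_000)
        assert picked == ["rsA", "rsC"]

    def test_uncovered_snps_treated_independent(self, clump_ld):
        z = stats.norm.isf(1e-10 / 2)
        s = make_sumstats(["rsA", "rsX"], [z * 0.05] * 2, [0.05] * 2,
                          chrom=[1, 1], pos=[100_000, 101_000])
        picked = clump_instruments(s, clump_ld, p_thresh=5e-8,
                                   r2_thresh=0.1)
        assert set(picked) == {"rsA", "rsX"}


class TestClassification:
    def test_sign_rule(self):
        # rs1 significant in both with opposite signs; rs2 null in both
        fetal = make_sumstats(["rs1", "rs2"], [0.1, 0.001], [0.01, 0.01])
        maternal = make_sumstats(["rs1", "rs2"], [-0.1, 0.001], [0.01, 0.01])
        labels = classify_bw_instruments(fetal, maternal, ["rs1", "rs2"],
                                         sig_thresh=5e-8)
        assert labels["rs1"] == "both_opposite_direction"
        assert labels["rs2"] == "unclassified"

    def test_missing_rsid_unclassified(self):
        fetal = make_sumstats(["rs1"], [0.1], [0.01])
        maternal = make_sumstats(["rs1"], [0.1], [0.01])
        labels = classify_bw_instruments(fetal, maternal, ["rs1", "rs9"])
        assert labels["rs9"] == "unclassified"

    def test_panel_composition_counts(self, rng):
        """Classification recovers the planted instrument-table layout:
        the fetal set combines fetal-specific and shared SNPs, the
        maternal set likewise."""
        fetal, maternal, truth = simulate_bw_instrument_panel(rng=rng)
        labels = classify_bw_instruments(fetal, maternal, list(truth.index))
        counts = labels.value_counts()
        assert counts["fetal_specific"] == 63
        assert counts["maternal_specific"] == 31
        assert counts["both_same_direction"] == 26
        assert counts["both_opposite_direction"] == 15
        assert counts["unclassified"] == 71
        sets = instrument_sets_from_labels(labels)
        assert len(sets["fetal"]) == 104
        assert len(sets["maternal"]) == 72


class TestIVW:
    def test_single_instrument_wald_ratio(self):
        est = ivw(_inst([0.2], [0.1], [0.02]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_exact_proportionality(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = ivw(_inst(bx, 0.5 * bx, [0.01, 0.05, 0.02]))
        assert est.beta == pytest.approx(0.5)
        assert est.extras["cochran_q"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle(self):
        bx = np.array([0.10, 0.20, 0.30])
        by = np.array([0.04, 0.11, 0.14])
        sy = np.array([0.01, 0.02, 0.01])
        est = ivw(_inst(bx, by, sy))
        oracle = sm.WLS(by, bx, weights=1 / sy ** 2).fit()
        assert est.beta == pytest.approx(oracle.params[0], abs=1e-10)

    def test_all_zero_exposure_rejected(self):
        with pytest.raises(MRError):
            ivw(_inst([0.0, 0.0], [0.1, 0.2], [0.01, 0.01]))

    def test_order_invariance_and_sign_equivariance(self, rng):
        bx = rng.normal(0.1, 0.05, 10)
        by = 0.3 * bx + rng.normal(0, 0.01, 10)
        sy = rng.uniform(0.01, 0.03, 10)
        base = ivw(_inst(bx, by, sy))
        perm = rng.permutation(10)
        assert ivw(_inst(bx[perm], by[perm], sy[perm])).beta == \
            pytest.approx(base.beta, abs=1e-12)
        flip = rng.choice([-1, 1], 10)
        assert ivw(_inst(bx * flip, by * flip, sy)).beta == \
            pytest.approx(base.beta, abs=1e-12)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.linspace(0.05, 0.3, 6)
        est = mr_egger(_inst(bx, 0.02 + 0.5 * bx, np.full(6, 0.02)))
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert est.extras["intercept"] == pytest.approx(0.02, abs=1e-9)

    def test_too_few_instruments(self):
        with pytest.raises(MRError):
            mr_egger(_inst([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_planted_directional_pleiotropy_recovered(self, rng):
        intercepts, power = [], 0
        for _ in range(30):
            J = 100
            bx = np.abs(rng.normal(0.1, 0.03, J))
            by = 0.3 * bx + 0.03 + rng.normal(0, 0.01, J)
            est = mr_egger(_inst(bx, by, np.full(J, 0.01),
                                 sx=np.full(J, 0.005)))
            intercepts.append(est.extras["intercept"])
            power += est.extras["intercept_pval"] < 0.05
        assert np.mean(intercepts) == pytest.approx(0.03, abs=0.01)
        assert power / 30 > 0.8

    def test_no_pleiotropy_intercept_calibrated(self, rng):
        hits = 0
        for _ in range(60):
            J = 30
            bx = np.abs(rng.normal(0.1, 0.03, J))
            by = 0.3 * bx + rng.normal(0, 0.01, J)
            est = mr_egger(_inst(bx, by, np.full(J, 0.01)))
            hits += est.extras["intercept_pval"] < 0.05
        assert hits / 60 < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)


class TestWeightedMedian:
    def test_equal_weight_interpolation_example(self):
        est = weighted_median(_inst([1.0, 1.0, 1.0], [0.1, 0.2, 0.9],
                                    [1.0, 1.0, 1.0]), seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = weighted_median(_inst(bx, 0.7 * bx, np.full(3, 0.01)), seed=0)
        assert est.beta == pytest.approx(0.7, abs=1e-9)
        assert est.se < 0.2

    def test_robust_to_forty_percent_invalid(self, rng):
        estimates = []
        for _ in range(30):
            J = 50
            n_bad = 20
            bx = np.abs(rng.normal(0.1, 0.02, J))
            by = 0.3 * bx + rng.normal(0, 0.002, J)
            by[:n_bad] += rng.uniform(0.05, 0.15, n_bad)  # huge pleiotropy
            est = weighted_median(_inst(bx, by, np.full(J, 0.002)),
                                  n_boot=200, seed=int(rng.integers(2**31)))
            estimates.append(est.beta)
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.05)

    def test_bootstrap_seeded(self):
        inst = _inst([0.1, 0.2, 0.3], [0.05, 0.11, 0.14],
                     [0.01, 0.02, 0.01])
        a = weighted_median(inst, seed=42)
        b = weighted_median(inst, seed=42)
        assert a.se == b.se


class TestMaxLikelihood:
    def test_exact_proportional_data(self):
        bx = np.linspace(0.05, 0.3, 8)
        est = max_likelihood(_inst(bx, 0.5 * bx, np.full(8, 0.02)))
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_single_instrument_equals_wald(self):
        est = max_likelihood(_inst([0.2], [0.1], [0.02]))
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_agrees_with_ivw_asymptotically(self, rng):
        J = 80
        bx_t = rng.normal(0.1, 0.03, J)
        inst = _inst(bx_t + rng.normal(0, 0.002, J),
                     0.3 * bx_t + rng.normal(0, 0.005, J),
                     np.full(J, 0.005), sx=np.full(J, 0.002))
        ml = max_likelihood(inst)
        iv = ivw(inst)
        assert abs(ml.beta - iv.beta) < 2 * iv.se


class TestPresso:
    def _clean(self, rng, J=30):
        bx = rng.normal(0.1, 0.03, J)
        by = 0.3 * bx + rng.normal(0, 0.01, J)
        return _inst(bx, by, np.full(J, 0.01), sx=np.full(J, 0.005))

    def test_no_outliers_corrected_equals_uncorrected(self, rng):
        res = mr_presso(self._clean(rng), n_sim=500, seed=0)
        if not res.outlier_rsids:
            assert res.corrected.beta == res.uncorrected.beta

    def test_planted_outlier_flagged(self, rng):
        found = 0
        for rep in range(10):
            inst = self._clean(rng)
            inst.by[7] += 10 * 0.01
            res = mr_presso(inst, n_sim=1000, seed=rep)
            found += "rs8" in res.outlier_rsids
        assert found >= 9

    def test_clean_global_p_not_extreme(self, rng):
        ps = [mr_presso(self._clean(rng), n_sim=300, seed=i).global_p
              for i in range(20)]
        assert np.mean(ps) > 0.2  # roughly uniform, far from 0

    def test_few_instruments_global_only(self, rng):
        inst = self._clean(rng, J=3)
        res = mr_presso(inst, n_sim=200, seed=0)
        assert res.outlier_pvals is None


class TestMVMR:
    def test_exact_two_exposure_fit(self):
        X = np.column_stack([np.linspace(0.1, 0.5, 6),
                             [0.2, 0.1, 0.3, 0.15, 0.4, 0.05]])
        y = 0.3 * X[:, 0] + 0.2 * X[:, 1]
        inst = InstrumentSet(rsid=np.array([f"r{i}" for i in range(6)]),
                             bx=X, sx=np.full((6, 2), 0.01),
                             by=y, sy=np.full(6, 0.01),
                             exposure_labels=["e1", "e2"])
        est = mvmr_ivw(inst)
        assert est[0].beta == pytest.approx(0.3, abs=1e-10)
        assert est[1].beta == pytest.approx(0.2, abs=1e-10)

    def test_degenerate_exposure_rejected(self):
        X = np.column_stack([np.linspace(0.1, 0.5, 6), np.zeros(6)])
        inst = InstrumentSet(rsid=np.array([f"r{i}" for i in range(6)]),
                             bx=X, sx=np.full((6, 2), 0.01),
                             by=np.ones(6), sy=np.full(6, 0.01),
                             exposure_labels=["e1", "e2"])
        with pytest.raises(MRError, match="e2"):
            mvmr_ivw(inst)

    def test_single_exposure_reduces_to_ivw(self, rng):
        bx = rng.normal(0.1, 0.05, 12)
        by = 0.4 * bx + rng.normal(0, 0.01, 12)
        sy = rng.uniform(0.01, 0.02, 12)
        inst = _inst(bx, by, sy)
        iv = ivw(inst)
        mv = mvmr_ivw(inst)[0]
        assert mv.beta == pytest.approx(iv.beta, abs=1e-12)
        assert mv.se == pytest.approx(iv.se, rel=1e-9)


class TestBonferroni:
    def test_all_ones_unchanged(self):
        inst = _inst([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        out, removed = bonferroni_filter(inst, [1.0, 1.0])
        assert removed == [] and out.n_instruments == 2

    def test_threshold_arithmetic(self):
        inst = _inst(np.full(3, 0.1), np.full(3, 0.05), np.full(3, 0.01))
        out, removed = bonferroni_filter(inst, [1e-6, 0.01, 0.9], m=100)
        assert removed == ["rs1"]  # threshold 5e-4

    def test_m_one_reduces_to_alpha(self):
        inst = _inst(np.full(2, 0.1), np.full(2, 0.05), np.full(2, 0.01))
        out, removed = bonferroni_filter(inst, [0.04, 0.06], m=1)
        assert removed == ["rs1"]


class TestPower:
    def test_null_or_gives_half_alpha(self):
        assert mr_power_binary(1e5, 0.5, 0.01, 1.0, alpha=0.05) == \
            pytest.approx(0.025, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(1e4, 1e6), st.floats(0.1, 0.9), st.floats(0.001, 0.05),
           st.floats(1.05, 1.5))
    def test_monotone_in_each_argument(self, n, k, r2, orr):
        base = mr_power_binary(n, k, r2, orr)
        assert mr_power_binary(n * 2, k, r2, orr) >= base
        assert mr_power_binary(n, k, r2 * 1.5, orr) >= base
        assert mr_power_binary(n, k, r2, orr * 1.2) >= base

    def test_invalid_parameters_rejected(self):
        with pytest.raises(MRError):
            mr_power_binary(1e5, 1.5, 0.01, 0.9)
        with pytest.raises(MRError):
            mr_power_binary(1e5, 0.5, 0.0, 0.9)


def test_make_instrument_set_drops_missing_rsids():
    e = make_sumstats(["rs1", "rs2"], [0.1, 0.2], [0.01, 0.01])
    o = make_sumstats(["rs1"], [0.05], [0.01])
    inst = make_instrument_set(e, o, ["rs1", "rs2"])
    assert list(inst.rsid) == ["rs1"]
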