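"""Synthetic-data generators: determinism, QC-cleanliness and moment
fidelity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from crosstrait.ldref import LDError
from crosstrait.mr import ivw, make_instrument_set
from crosstrait.simulate import (ChainConfig, SimulationConfig,
                                 SimulationError, plant_pleiotropic_genes,
                                 simulate_bw_instrument_panel,
                                 simulate_causal_chain,
                                 simulate_fetal_maternal,
                                 simulate_ld_reference,
                                 simulate_mixture_pvalues,
                                 simulate_paired_sumstats)
from crosstrait.sumstats import GeneAnnotation, qc_sumstats


class TestLDReference:
    def test_zero_rho_gives_unit_ld_scores(self):
        ld = simulate_ld_reference(60, 6, 0.0)
        assert np.allclose(ld.ld_scores().values, 1.0)

    def test_middle_snp_ld_score_ar1_half(self):
        ld = simulate_ld_reference(3, 1, 0.5)
        # middle SNP: 1 + 0.25 + 0.25
        assert ld.ld_scores().iloc[1] == pytest.approx(1.5)

    def test_deterministic(self):
        a = simulate_ld_reference(100, 4, (0.1, 0.8), seed=7)
        b = simulate_ld_reference(100, 4, (0.1, 0.8), seed=7)
        for ba, bb in zip(a.blocks, b.blocks):
            np.testing.assert_array_equal(ba.R, bb.R)
            assert ba.rsids == bb.rsids

    def test_rho_out_of_range_rejected(self):
        with pytest.raises((SimulationError, LDError)):
            simulate_ld_reference(10, 2, 1.0)

    def test_blocks_cover_22_pseudochromosomes(self):
        ld = simulate_ld_reference(440, 44, 0.2)
        assert set(ld.snp_table()["chrom"]) == set(range(1, 23))


@pytest.fixture(scope="module")
def small_ld():
    return simulate_ld_reference(1000, 10, (0.0, 0.9))


@pytest.fixture(scope="module")
def ld10k():
    return simulate_ld_reference(10_000, 100, 0.0)


class TestPairedSumstats:
    def test_same_seed_bit_identical(self, small_ld):
        cfg = SimulationConfig(m_snps=1000, n_blocks=10, seed=3)
        a1, a2 = simulate_paired_sumstats(small_ld, cfg)
        b1, b2 = simulate_paired_sumstats(small_ld, cfg)
        pd.testing.assert_frame_equal(a1.data, b1.data)
        pd.testing.assert_frame_equal(a2.data, b2.data)

    def test_output_passes_qc(self, small_ld):
        cfg = SimulationConfig(m_snps=1000, n_blocks=10, seed=3)
        s1, s2 = simulate_paired_sumstats(small_ld, cfg)
        out, rep = qc_sumstats(s1)
        assert rep.n_no_rsid == rep.n_duplicated == 0
        assert len(out) == 1000

    def test_null_rg_product_moment_near_zero(self, small_ld, rng):
        cfg = SimulationConfig(m_snps=1000, n_blocks=10, rg_true=0.0,
                               h2_1=0.2, h2_2=0.2)
        ell = small_ld.ld_scores().values
        slopes = []
        for _ in range(40):
            s1, s2 = simulate_paired_sumstats(small_ld, cfg, rng)
            prod = s1.data["z"].values * s2.data["z"].values
            slopes.append(np.polyfit(ell, prod, 1)[0])
        mc_se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * mc_se + 1e-12

    def test_perfect_correlation_degenerate(self, small_ld, rng):
        cfg = SimulationConfig(m_snps=1000, n_blocks=10, rg_true=1.0,
                               h2_1=0.4, h2_2=0.4)
        s1, s2 = simulate_paired_sumstats(small_ld, cfg, rng)
        # with rg = 1 and equal h2, the two z-vectors share their genetic
        # part: correlation well above the noise-only level
        r = np.corrcoef(s1.data["z"], s2.data["z"])[0, 1]
        assert r > 0.5

    def test_overlap_term_induces_null_correlation(self, small_ld, rng):
        cfg = SimulationConfig(m_snps=1000, n_blocks=10, rg_true=0.0,
                               h2_1=0.0, h2_2=0.0, n_overlap=50_000,
                               rho_pheno=0.8)
        corrs = []
        for _ in range(20):
            s1, s2 = simulate_paired_sumstats(small_ld, cfg, rng)
            corrs.append(np.corrcoef(s1.data["z"], s2.data["z"])[0, 1])
        assert np.mean(corrs) == pytest.approx(0.8, abs=0.05)


class TestFetalMaternal:
    @pytest.mark.parametrize("fm_corr", [-0.6, 0.0])
    def test_effect_correlation_matches_target(self, ld10k, fm_corr, rng):
        cfg = SimulationConfig(m_snps=10_000, n_blocks=100, fm_corr=fm_corr)
        sf, sm = simulate_fetal_maternal(ld10k, cfg, rng)
        r = np.corrcoef(sf.data["beta"], sm.data["beta"])[0, 1]
        assert r == pytest.approx(fm_corr, abs=0.05)

    def test_perfect_correlation_proportional(self, ld10k, rng):
        cfg = SimulationConfig(m_snps=10_000, n_blocks=100, fm_corr=1.0)
        sf, sm = simulate_fetal_maternal(ld10k, cfg, rng)
        r = np.corrcoef(sf.data["beta"], sm.data["beta"])[0, 1]
        assert r > 0.97


class TestPlantedGenes:
    def _genes(self, n=50, k=10):
        return [GeneAnnotation(gene_id=f"G{i}", chrom=1, start=1 + i * k,
                               end=(i + 1) * k,
                               snp_ids=[f"rs{i * k + j}" for j in range(k)])
                for i in range(n)]

    def test_labels_partition_genes(self, rng):
        cfg = SimulationConfig()
        planted = plant_pleiotropic_genes(self._genes(), 0.1, +1, cfg, rng)
        counts = planted.truth["label"].value_counts()
        assert counts.sum() == 50
        assert set(counts.index) <= {"H00", "H01", "H10", "H11"}
        assert counts.get("H11", 0) == 5

    def test_no_shared_fraction_means_no_pleiotropic_genes(self, rng):
        cfg = SimulationConfig()
        planted = plant_pleiotropic_genes(self._genes(), 0.0, +1, cfg, rng)
        assert (planted.truth["label"] != "H11").all()

    def test_planted_local_correlation_sign(self, rng):
        cfg = SimulationConfig(gene_effect_corr=0.8)
        genes = self._genes(n=20, k=50)
        planted = plant_pleiotropic_genes(genes, 1.0, +1, cfg, rng)
        for g in genes:
            b1 = planted.beta1.loc[g.snp_ids]
            b2 = planted.beta2.loc[g.snp_ids]
            r = np.corrcoef(b1, b2)[0, 1]
            assert r == pytest.approx(0.8, abs=0.25)
            assert r > 0


class TestCausalChain:
    def test_total_effect_matches_path_product(self, rng):
        cfg = ChainConfig(theta_xy=0.0)
        truth = cfg.theta_xm1 * cfg.theta_m1m2 * cfg.theta_m2y
        estimates, ses = [], []
        for _ in range(20):
            chain = simulate_causal_chain(cfg, rng)
            x_inst = list(chain.x.data.loc[
                chain.x.data["pval"] < 5e-8, "rsid"])
            est = ivw(make_instrument_set(chain.x, chain.y, x_inst))
            estimates.append(est.beta)
            ses.append(est.se)
        gap = abs(np.mean(estimates) - truth)
        assert gap < 2 * np.mean(ses) / np.sqrt(20) + 0.002

    def test_global_null_gives_null_estimates(self, rng):
        cfg = ChainConfig(theta_xm1=0, theta_m1m2=0, theta_m2y=0,
                          theta_xy=0)
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            chain = simulate_causal_chain(cfg, rng)
            x_inst = list(chain.x.data.loc[
                chain.x.data["pval"] < 5e-8, "rsid"])
            est = ivw(make_instrument_set(chain.x, chain.y, x_inst))
            rejections += est.pval < 0.05
        # type-I error near alpha
        assert rejections / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_outliers_planted_on_named_snps(self, rng):
        cfg = ChainConfig(outlier_frac=0.1, outlier_scale=10)
        chain = simulate_causal_chain(cfg, rng)
        assert len(chain.truth["outlier_rsids"]) == 10

    def test_deterministic_with_seed(self):
        cfg = ChainConfig()
        a = simulate_causal_chain(cfg, seed=11)
        b = simulate_causal_chain(cfg, seed=11)
        pd.testing.assert_frame_equal(a.y.data, b.y.data)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(SimulationError):
            ChainConfig(n_inst_x=2)


class TestInstrumentPanel:
    def test_panel_composition_is_planted_truth(self, rng):
        fetal, maternal, truth = simulate_bw_instrument_panel(rng=rng)
        assert truth.value_counts().to_dict() == {
            "unclassified": 71, "fetal_specific": 63,
            "maternal_specific": 31, "both_same_direction": 26,
            "both_opposite_direction": 15}
        assert len(fetal) == len(maternal) == 206


def test_mixture_pvalues_label_proportions(rng):
    p1, p2, lab = simulate_mixture_pvalues(20_000, (0.85, 0.07, 0.07, 0.01),
                                           rng=rng)
    frac = np.bincount(lab, minlength=4) / 20_000
    np.testing.assert_allclose(frac, [0.85, 0.07, 0.07, 0.01], atol=0.01)
    # null margins are uniform
    null1 = p1[(lab == 0) | (lab == 1)]
    assert abs(null1.mean() - 0.5) < 0.02
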