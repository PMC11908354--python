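"""Trio simulator: genetics, effect-size conversions, generative moments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ftsem.data import HIDDEN_COLUMNS
from ftsem.simulate import (MRSimPair, SimConfig, alpha_from_pve,
                            effect_from_pve, genotype_variance,
                            gwas_study_config, mendelian_transmit,
                            mr_study_configs, sim_founder_genotypes,
                            sim_gwas_dataset, sim_mr_pair, true_params)


class TestEffectSizeConversions:
    @pytest.mark.parametrize("maf,expected", [(0.0, 0.0), (0.5, 0.5),
                                              (0.3, 0.42), (1.0, 0.0)])
    def test_genotype_variance(self, maf, expected):
        assert genotype_variance(maf) == pytest.approx(expected, abs=1e-12)

    def test_genotype_variance_rejects_bad_frequency(self):
        with pytest.raises(ValueError):
            genotype_variance(1.2)

    @pytest.mark.parametrize("pve,var,expected", [
        (0.002, 0.42, 0.069),   # offspring effect, GWAS alternative
        (0.005, 0.42, 0.109),   # parental effects, GWAS dynastic scenario
        (0.05, 0.25, 0.447),    # stratification variable, GWAS (L in {1,2})
        (0.30, 1.00, 0.548),    # person-level confounder, GWAS / MR outcome
        (0.10, 0.42, 0.488),    # offspring effect on the MR exposure
        (0.20, 1.00, 0.447),    # confounder, MR exposure
        (0.025, 0.42, 0.244),   # parental effects, MR exposure (DE)
        (0.004, 0.42, 0.098),   # parental effects, MR outcome (DE)
        (0.05, 1.00, 0.224),    # standardized L, MR exposure (RPS)
        (0.10, 1.00, 0.316),    # standardized L, MR outcome (RPS)
    ])
    def test_study_condition_effect_sizes(self, pve, var, expected):
        assert effect_from_pve(pve, var) == pytest.approx(expected,
                                                          abs=5e-4)

    def test_zero_pve_gives_zero_effect(self):
        assert effect_from_pve(0.0, 0.42) == 0.0

    @pytest.mark.parametrize("pve,var", [(-0.1, 0.42), (0.1, 0.0),
                                         (0.1, -1.0)])
    def test_invalid_arguments_raise(self, pve, var):
        with pytest.raises(ValueError):
            effect_from_pve(pve, var)

    def test_causal_effect_from_pve_ratio(self):
        assert alpha_from_pve(0.10, 0.002) == pytest.approx(0.141, abs=5e-4)
        assert alpha_from_pve(0.10, 0.0) == 0.0
        with pytest.raises(ValueError):
            alpha_from_pve(0.0, 0.002)


class TestGenotypeMachinery:
    def test_founder_moments_match_binomial(self, rng):
        g = sim_founder_genotypes(0.3, 200_000, rng)
        assert g.mean() == pytest.approx(0.6, abs=0.005)
        assert g.var() == pytest.approx(0.42, abs=0.005)

    def test_founder_degenerate_frequencies(self, rng):
        assert (sim_founder_genotypes(0.0, 100, rng) == 0).all()
        assert (sim_founder_genotypes(1.0, 100, rng) == 2).all()

    def test_homozygote_transmission_is_deterministic(self, rng):
        n = 500
        zeros = np.zeros(n, dtype=int)
        twos = np.full(n, 2)
        assert (mendelian_transmit(zeros, zeros, rng) == 0).all()
        assert (mendelian_transmit(twos, twos, rng) == 2).all()
        assert (mendelian_transmit(zeros, twos, rng) == 1).all()

    def test_het_cross_segregates_1_2_1(self, rng):
        # enumeration oracle: each het parent transmits 0/1 with prob 1/2,
        # so the child dosage distribution is (1/4, 1/2, 1/4)
        ones = np.ones(40_000, dtype=int)
        child = mendelian_transmit(ones, ones, rng)
        freqs = np.bincount(child, minlength=3) / len(child)
        assert freqs == pytest.approx([0.25, 0.5, 0.25], abs=0.01)

    def test_invalid_dosage_rejected(self, rng):
        with pytest.raises(ValueError):
            mendelian_transmit(np.array([3]), np.array([0]), rng)


class TestSimConfig:
    def test_rps_needs_two_frequencies(self):
        with pytest.raises(ValueError):
            SimConfig("RPS", n_trios=100, maf=0.3)
        with pytest.raises(ValueError):
            SimConfig("DE", n_trios=100, maf=(0.25, 0.35))

    def test_total_pve_must_leave_residual_variance(self):
        with pytest.raises(ValueError):
            SimConfig("DE", n_trios=100, maf=0.3, pve_oe=0.5, pve_u=0.5)

    def test_stratification_pve_requires_rps(self):
        with pytest.raises(ValueError):
            SimConfig("DE", n_trios=100, maf=0.3, pve_le=0.05)

    def test_yaml_round_trip(self, tmp_path):
        cfg = gwas_study_config("RPS", 500, rho=0.3, pve_oe=0.002, seed=9)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg


class TestGwasDataset:
    @pytest.mark.parametrize("scenario,pve_oe", [("DE", 0.0), ("DE", 0.002),
                                                 ("RPS", 0.002),
                                                 ("NONE", 0.0)])
    def test_every_trio_is_mendelian_feasible(self, scenario, pve_oe):
        cfg = gwas_study_config(scenario, 3000, pve_oe=pve_oe, seed=3)
        sim_gwas_dataset(cfg).validate()

    def test_pure_noise_limit(self):
        cfg = SimConfig("NONE", n_trios=50_000, maf=0.3, seed=4)
        data = sim_gwas_dataset(cfg)
        for z in (data.ZF, data.ZM, data.ZO):
            assert z.mean() == pytest.approx(0.0, abs=0.02)
            assert z.var() == pytest.approx(1.0, abs=0.03)
        corr = np.corrcoef(data.ZO, data.O)[0, 1]
        assert abs(corr) < 0.02

    def test_phenotype_variance_is_one_under_null(self):
        cfg = gwas_study_config("DE", 100_000, rho=0.6, seed=5)
        data = sim_gwas_dataset(cfg)
        for z in (data.ZF, data.ZM, data.ZO):
            assert z.var() == pytest.approx(1.0, abs=0.02)

    def test_residual_correlation_recovered(self):
        cfg = gwas_study_config("DE", 100_000, rho=0.6, pve_oe=0.002,
                                seed=6)
        data = sim_gwas_dataset(cfg)
        b = cfg.effects()
        h = data.hidden
        resid_f = (data.ZF - b["oe"] * data.F - b["fe"] * h["GF1"]
                   - b["me"] * h["GM1"] - b["ue"] * h["UF"])
        resid_o = (data.ZO - b["oe"] * data.O - b["fe"] * data.F
                   - b["me"] * data.M - b["ue"] * h["UO"])
        assert np.corrcoef(resid_f, resid_o)[0, 1] == pytest.approx(
            0.6, abs=0.02)

    def test_confounded_vs_adjusted_regression_limits(self):
        # with a null offspring effect, ZO ~ O alone converges to
        # 0.5*(beta_fe + beta_me) while adjusting for (F, M) removes it
        cfg = gwas_study_config("DE", 100_000, rho=0.6, seed=7)
        data = sim_gwas_dataset(cfg)
        b = cfg.effects()
        slope = np.cov(data.ZO, data.O)[0, 1] / np.var(data.O)
        assert slope == pytest.approx(0.5 * (b["fe"] + b["me"]), abs=0.02)
        x = np.column_stack([np.ones(data.n_trios), data.O, data.F, data.M])
        coef = np.linalg.lstsq(x, data.ZO, rcond=None)[0]
        assert coef[1] == pytest.approx(0.0, abs=0.02)

    def test_rps_pooled_allele_frequency(self):
        cfg = gwas_study_config("RPS", 100_000, seed=8)
        data = sim_gwas_dataset(cfg)
        pooled = np.concatenate([data.F, data.M]).mean() / 2
        assert pooled == pytest.approx(0.30, abs=0.01)
        assert set(np.unique(data.hidden["L"])) == {1.0, 2.0}

    def test_standardized_l_coding(self):
        cfg_x, _, _ = mr_study_configs("RPS", 2000, seed=9)
        data = sim_gwas_dataset(cfg_x)
        assert set(np.unique(data.hidden["L"])) == {-1.0, 1.0}

    def test_seeded_runs_are_reproducible(self):
        cfg = gwas_study_config("RPS", 500, pve_oe=0.002, seed=10)
        a = sim_gwas_dataset(cfg)
        b = sim_gwas_dataset(cfg)
        assert np.array_equal(a.observed(), b.observed())
        c = sim_gwas_dataset(gwas_study_config("RPS", 500, pve_oe=0.002,
                                               seed=11))
        assert not np.array_equal(a.observed(), c.observed())

    def test_public_view_hides_generative_columns(self):
        data = sim_gwas_dataset(gwas_study_config("DE", 200, seed=1))
        assert data.hidden is not None
        public = data.public_view()
        assert public.hidden is None
        frame = public.to_frame(include_hidden=True)
        assert not set(HIDDEN_COLUMNS) & set(frame.columns)

    def test_true_params_reject_rps_mixture(self):
        with pytest.raises(ValueError):
            true_params(gwas_study_config("RPS", 100))


class TestMRPair:
    def test_samples_are_disjoint_equal_halves(self):
        cfg_x, cfg_y, alpha = mr_study_configs("DE", 2001, pve_gy=0.002,
                                               seed=12)
        pair = sim_mr_pair(cfg_x, cfg_y, alpha)
        assert isinstance(pair, MRSimPair)
        assert pair.sample1.n_trios == pair.sample2.n_trios == 1000
        ids1 = set(pair.sample1.family_ids)
        ids2 = set(pair.sample2.family_ids)
        assert not ids1 & ids2
        assert pair.true_alpha == pytest.approx(0.1414, abs=5e-4)

    def test_mismatched_cohort_settings_raise(self):
        cfg_x, cfg_y, alpha = mr_study_configs("DE", 2000, seed=1)
        bad = gwas_study_config("DE", 1000, seed=1)
        with pytest.raises(ValueError):
            sim_mr_pair(cfg_x, bad, alpha)

    def test_causal_chain_reaches_the_outcome_sample(self):
        # nuisance-free cohort: the SNP-outcome slope in sample 2 converges
        # to alpha times the SNP-exposure slope (vertical pleiotropy only)
        cfg_x = SimConfig("NONE", n_trios=60_000, maf=0.3, pve_oe=0.10,
                          seed=13)
        cfg_y = SimConfig("NONE", n_trios=60_000, maf=0.3, seed=13)
        alpha = 0.5
        pair = sim_mr_pair(cfg_x, cfg_y, alpha)
        bx = np.cov(pair.sample1.ZO, pair.sample1.O)[0, 1] \
            / np.var(pair.sample1.O)
        by = np.cov(pair.sample2.ZO, pair.sample2.O)[0, 1] \
            / np.var(pair.sample2.O)
        assert bx == pytest.approx(effect_from_pve(0.10, 0.42), abs=0.02)
        assert by == pytest.approx(alpha * bx, abs=0.02)


@given(seed=st.integers(0, 10_000))
def test_mendelian_feasibility_property(seed):
    cfg = SimConfig("DE", n_trios=200, maf=0.2, pve_fe=0.01, pve_me=0.01,
                    pve_u=0.2, rho=0.3, seed=seed)
    data = sim_gwas_dataset(cfg)
    assert data.mendelian_valid().all()
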