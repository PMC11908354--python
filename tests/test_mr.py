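"""Two-sample MR: harmonization, instrument filtering, five estimators."""

import numpy as np
import pandas as pd
import pytest

from ftsem.mr import (HarmonizedInstrument, NoInstrumentsError,
                      f_statistic_filter, harmonize, ivw, mr_egger,
                      ratio_estimate, run_mr, weighted_median, weighted_mode)


def inst(bx, by, sx=0.03, sy=0.03, snp="rs"):
    return HarmonizedInstrument(snp_id=snp, beta_x=bx, se_x=sx,
                                beta_y=by, se_y=sy)


@pytest.fixture
def instrument_panel(rng):
    """25 instruments consistent with a causal effect of 0.3."""
    bx = rng.normal(0.5, 0.1, 25)
    by = 0.3 * bx + rng.normal(0, 0.02, 25)
    return [inst(b, c, sx=0.02, sy=0.02, snp=f"rs{i}")
            for i, (b, c) in enumerate(zip(bx, by))]


class TestFStatisticFilter:
    def test_strong_instrument_retained(self):
        kept = f_statistic_filter([inst(0.488, 0.1, sx=0.0488)])
        assert len(kept) == 1
        assert kept[0].f_statistic == pytest.approx(100.0)

    def test_weak_instrument_excluded(self):
        strong, weak = inst(0.488, 0.1, sx=0.0488), inst(0.03, 0.1, sx=0.01)
        assert weak.f_statistic == pytest.approx(9.0)
        assert f_statistic_filter([strong, weak]) == [strong]

    def test_all_excluded_signalled_distinctly(self):
        with pytest.raises(NoInstrumentsError):
            f_statistic_filter([inst(0.03, 0.1, sx=0.01)])


class TestHarmonize:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["snp", "ea", "oa", "beta", "se"])

    def test_same_alleles_pass_through(self):
        exp = self.frame([("rs1", "A", "G", 0.5, 0.05)])
        out = self.frame([("rs1", "A", "G", 0.1, 0.05)])
        insts, reasons = harmonize(exp, out)
        assert insts[0].beta_y == pytest.approx(0.1)
        assert reasons == {}

    def test_swapped_alleles_flip_outcome_sign(self):
        exp = self.frame([("rs1", "A", "G", 0.5, 0.05)])
        out = self.frame([("rs1", "G", "A", 0.1, 0.05)])
        insts, _ = harmonize(exp, out)
        assert insts[0].beta_y == pytest.approx(-0.1)

    def test_palindromic_snp_dropped(self):
        exp = self.frame([("rs1", "A", "T", 0.5, 0.05),
                          ("rs2", "C", "G", 0.5, 0.05),
                          ("rs3", "A", "G", 0.5, 0.05)])
        out = self.frame([("rs1", "A", "T", 0.1, 0.05),
                          ("rs2", "C", "G", 0.1, 0.05),
                          ("rs3", "A", "G", 0.1, 0.05)])
        insts, reasons = harmonize(exp, out)
        assert [i.snp_id for i in insts] == ["rs3"]
        assert reasons == {"palindromic": 2}

    def test_incompatible_alleles_dropped_with_reason(self):
        exp = self.frame([("rs1", "A", "G", 0.5, 0.05),
                          ("rs2", "A", "G", 0.5, 0.05)])
        out = self.frame([("rs1", "A", "C", 0.1, 0.05),
                          ("rs2", "A", "G", 0.1, 0.05)])
        insts, reasons = harmonize(exp, out)
        assert reasons == {"incompatible_alleles": 1}
        assert len(insts) == 1

    def test_opposite_strand_same_orientation(self):
        exp = self.frame([("rs1", "A", "G", 0.5, 0.05)])
        out = self.frame([("rs1", "T", "C", 0.1, 0.05)])
        insts, _ = harmonize(exp, out)
        assert insts[0].beta_y == pytest.approx(0.1)

    def test_empty_intersection_raises(self):
        exp = self.frame([("rs1", "A", "G", 0.5, 0.05)])
        out = self.frame([("rs9", "A", "G", 0.1, 0.05)])
        with pytest.raises(NoInstrumentsError):
            harmonize(exp, out)


class TestRatio:
    def test_strong_instrument_ratio_value(self):
        res = ratio_estimate(inst(0.488, 0.0690))
        assert res.estimate == pytest.approx(0.141, abs=5e-4)

    def test_null_numerator_gives_zero(self):
        assert ratio_estimate(inst(0.488, 0.0)).estimate == 0.0

    def test_first_order_delta_se(self):
        res = ratio_estimate(inst(0.5, 0.02, sy=0.01))
        assert res.se == pytest.approx(0.02)

    def test_second_order_se_is_larger(self):
        first = ratio_estimate(inst(0.5, 0.2, sx=0.1, sy=0.01))
        second = ratio_estimate(inst(0.5, 0.2, sx=0.1, sy=0.01),
                                second_order=True)
        assert second.se > first.se

    def test_null_denominator_rejected(self):
        with pytest.raises(ValueError):
            ratio_estimate(inst(0.0, 0.1))


class TestIVW:
    def test_single_instrument_reduces_to_ratio(self):
        one = inst(0.488, 0.0690, sx=0.03, sy=0.025)
        r, i = ratio_estimate(one), ivw([one])
        assert i.estimate == pytest.approx(r.estimate, abs=1e-15)
        assert i.se == pytest.approx(r.se, abs=1e-15)

    def test_equal_weight_instruments_average_the_ratios(self):
        insts = [inst(0.5, 0.10), inst(0.5, 0.20)]
        expected = np.mean([0.10 / 0.5, 0.20 / 0.5])
        assert ivw(insts).estimate == pytest.approx(expected)

    def test_k_copies_shrink_se_by_sqrt_k(self):
        one = inst(0.5, 0.1)
        single, quad = ivw([one]), ivw([one] * 4)
        assert quad.estimate == pytest.approx(single.estimate)
        assert quad.se == pytest.approx(single.se / 2.0)

    def test_coverage_of_simulated_instruments(self, rng):
        # summary-level simulation: 25 instruments, alpha = 0.141
        alpha, hits = 0.141, 0
        for _ in range(500):
            bx_true = rng.normal(0.488, 0.05, 25)
            bx = bx_true + rng.normal(0, 0.03, 25)
            by = alpha * bx_true + rng.normal(0, 0.03, 25)
            res = ivw([inst(b, c, sx=0.03, sy=0.03) for b, c in
                       zip(bx, by)])
            hits += res.ci_low <= alpha <= res.ci_high
        assert 0.91 <= hits / 500 <= 0.985


class TestEgger:
    def test_intercept_shift_identity(self, instrument_panel):
        base = mr_egger(instrument_panel)
        shifted = [inst(i.beta_x, i.beta_y + 0.05, i.se_x, i.se_y)
                   for i in instrument_panel]
        res = mr_egger(shifted)
        assert res.intercept == pytest.approx(base.intercept + 0.05,
                                              abs=1e-9)
        assert res.estimate == pytest.approx(base.estimate, abs=1e-9)

    def test_slope_unbiased_without_pleiotropy(self, instrument_panel):
        res = mr_egger(instrument_panel)
        assert res.estimate == pytest.approx(0.3, abs=3 * res.se)
        assert res.intercept_p > 0.01

    def test_constant_exposure_effects_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            mr_egger([inst(0.5, 0.1), inst(0.5, 0.2), inst(0.5, 0.3)])

    def test_needs_three_instruments(self):
        with pytest.raises(NoInstrumentsError):
            mr_egger([inst(0.5, 0.1), inst(0.4, 0.1)])


class TestMedianAndMode:
    def test_equal_weight_median_interpolates(self):
        insts = [inst(1.0, 0.1), inst(1.0, 0.2), inst(1.0, 0.9)]
        res = weighted_median(insts, n_boot=50)
        assert res.estimate == pytest.approx(0.2, abs=1e-12)

    def test_identical_ratios_are_a_fixed_point(self):
        insts = [inst(0.4, 0.2), inst(0.8, 0.4), inst(1.0, 0.5)]
        assert weighted_median(insts, n_boot=50).estimate == \
            pytest.approx(0.5)
        assert weighted_mode(insts, n_boot=50).estimate == \
            pytest.approx(0.5)

    def test_mode_finds_the_majority_cluster(self, rng):
        cluster = [inst(0.5, 0.5 * 0.3 + rng.normal(0, 0.005))
                   for _ in range(12)]
        outliers = [inst(0.5, 0.45), inst(0.5, 0.5)]
        res = weighted_mode(cluster + outliers, n_boot=50)
        assert res.estimate == pytest.approx(0.3, abs=0.03)

    def test_bootstrap_se_is_seed_reproducible(self, instrument_panel):
        a = weighted_median(instrument_panel, n_boot=200, seed=7)
        b = weighted_median(instrument_panel, n_boot=200, seed=7)
        c = weighted_median(instrument_panel, n_boot=200, seed=8)
        assert a.se == b.se
        assert a.se != c.se

    def test_insufficient_instruments(self):
        with pytest.raises(NoInstrumentsError):
            weighted_median([inst(0.5, 0.1)] * 2)
        with pytest.raises(NoInstrumentsError):
            weighted_mode([inst(0.5, 0.1)] * 2)


class TestSignEquivariance:
    def test_negating_outcomes_negates_every_estimate(self, instrument_panel):
        flipped = [inst(i.beta_x, -i.beta_y, i.se_x, i.se_y)
                   for i in instrument_panel]
        for method, tol in (
                (ivw, 1e-12), (mr_egger, 1e-12),
                (lambda x: weighted_median(x, n_boot=50), 1e-9),
                (lambda x: weighted_mode(x, n_boot=50), 5e-3)):
            assert method(flipped).estimate == pytest.approx(
                -method(instrument_panel).estimate, abs=tol)


class TestRunMr:
    def test_dispatch_and_result_frame(self, instrument_panel):
        results = run_mr(instrument_panel,
                         methods=("ivw", "egger", "wmedian"))
        assert [r.method for r in results] == ["IVW", "EGGER", "WMEDIAN"]
        for r in results:
            assert r.ci_low <= r.estimate <= r.ci_high
            assert 0 <= r.p <= 1

    def test_ratio_requires_single_instrument(self, instrument_panel):
        with pytest.raises(ValueError):
            run_mr(instrument_panel, methods=("ratio",))
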