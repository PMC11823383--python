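import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoprobit import (
    FixedRatioDesign,
    PotencyEstimate,
    additive_nonparallel,
    additive_parallel,
    dose_equivalent_a_of_b,
    dose_equivalent_b_of_a,
    fit_probit_line,
    inverse_probit,
    isobologram_coordinates,
    probit,
)
from isoprobit import test_parallelism as parallelism_test

parallelism_test.__test__ = False
from isoprobit.probit_core import ProbitLineFit

from conftest import probit_noise_dataset


def exact_fit(slope, intercept, se_slope=0.0, n=50, label=""):
    x_bar = 1.5  # nominal centre of the log-dose design
    return ProbitLineFit(
        slope_b=slope,
        intercept_a=intercept,
        r_squared=1.0,
        se_slope=se_slope,
        se_intercept=abs(x_bar) * se_slope,
        cov_ab=-x_bar * se_slope**2,
        n_items=n,
        n_doses=6,
        label=label,
    )


def est_of(fit, n=None):
    ic50 = 10.0 ** ((5.0 - fit.intercept_a) / fit.slope_b)
    return PotencyEstimate(ic50, 0.0, n or fit.n_items, fit.label)


class TestParallelism:
    def test_identical_fits_are_parallel(self):
        fit = exact_fit(2.0, 1.0, se_slope=0.1)
        res = parallelism_test(fit, fit)
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.is_parallel

    def test_clearly_different_slopes_reject(self):
        res = parallelism_test(
            exact_fit(2.0, 1.0, se_slope=0.01), exact_fit(4.0, 1.0, se_slope=0.01)
        )
        assert abs(res.t_stat) > 100
        assert not res.is_parallel

    def test_degenerate_zero_variance_unequal_slopes(self):
        res = parallelism_test(exact_fit(2.0, 1.0), exact_fit(3.0, 1.0))
        assert res.p_value == 0.0
        assert res.degenerate_variance
        assert not res.is_parallel

    def test_type_i_error_near_alpha_under_own_assumptions(self):
        # same true slope, homoscedastic probit noise: rejection rate ≈ α
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            fa = fit_probit_line(probit_noise_dataset("a", 2.3, 1.0, rng))
            fb = fit_probit_line(probit_noise_dataset("b", 2.3, 0.5, rng))
            rejections += not parallelism_test(fa, fb).is_parallel
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_refuses_inverted_fit(self):
        good = exact_fit(2.0, 1.0, se_slope=0.1)
        bad = ProbitLineFit(-1.0, 8.0, 0.9, 0.1, 0.1, 0.0, 30, 6, inverted=True)
        with pytest.raises(ValueError):
            parallelism_test(good, bad)


class TestAdditiveParallel:
    def test_symmetry_of_equal_potencies(self):
        a = PotencyEstimate(10.0, 1.0, 48)
        b = PotencyEstimate(10.0, 1.0, 48)
        pred = additive_parallel(a, b, FixedRatioDesign(0.5))
        assert pred.lower_ic50_add == pytest.approx(10.0)
        assert pred.upper_ic50_add == pytest.approx(10.0)
        assert pred.parallel_case

    def test_vanishing_partner_potency_limit(self):
        # one drug ~3 orders of magnitude more potent: the additive total is
        # dominated by half the weaker drug's IC50 (49.86/2 ≈ 24.93)
        a = PotencyEstimate(49.86, 2.0, 72)
        b = PotencyEstimate(5e-3, 1e-4, 68)
        pred = additive_parallel(a, b, FixedRatioDesign(0.5))
        assert pred.lower_ic50_add == pytest.approx(24.93, abs=0.01)
        assert pred.n_add == 140

    def test_sem_combines_in_quadrature(self):
        a = PotencyEstimate(30.0, 3.0, 48)
        b = PotencyEstimate(20.0, 4.0, 48)
        pred = additive_parallel(a, b, FixedRatioDesign(0.5))
        assert pred.sem_lower == pytest.approx(2.5)

    @given(
        a50=st.floats(0.1, 100), b50=st.floats(0.1, 100),
        sa=st.floats(0, 5), sb=st.floats(0, 5), f=st.floats(0.05, 0.95),
    )
    @settings(max_examples=100, deadline=None)
    def test_exchange_symmetry(self, a50, b50, sa, sb, f):
        a = PotencyEstimate(a50, sa, 10)
        b = PotencyEstimate(b50, sb, 20)
        p1 = additive_parallel(a, b, FixedRatioDesign(f))
        p2 = additive_parallel(b, a, FixedRatioDesign(1.0 - f))
        assert p1.lower_ic50_add == pytest.approx(p2.lower_ic50_add, rel=1e-12)
        assert p1.sem_lower == pytest.approx(p2.sem_lower, rel=1e-12, abs=1e-15)
        assert p1.n_add == p2.n_add


class TestDoseEquivalence:
    def test_parallel_lines_give_constant_potency_ratio(self):
        fa, fb = exact_fit(2.0, 1.0), exact_fit(2.0, 3.0)
        a50, b50 = est_of(fa).ic50, est_of(fb).ic50
        for dose in (0.5, 5.0, 50.0):
            assert dose_equivalent_b_of_a(fa, fb, dose) == pytest.approx(
                dose * b50 / a50, rel=1e-12
            )

    def test_ic50_maps_to_ic50(self):
        fa, fb = exact_fit(3.0, -1.0), exact_fit(1.5, 2.0)
        a50, b50 = est_of(fa).ic50, est_of(fb).ic50
        assert dose_equivalent_b_of_a(fa, fb, a50) == pytest.approx(b50, rel=1e-12)

    @given(
        sa=st.floats(0.5, 5), ia=st.floats(-3, 3),
        sb=st.floats(0.5, 5), ib=st.floats(-3, 3),
        dose=st.floats(0.01, 500),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_effect_matching_oracle(self, sa, ia, sb, ib, dose):
        # oracle: push the dose through A's line to an effect, then invert
        # through B's line
        fa, fb = exact_fit(sa, ia), exact_fit(sb, ib)
        y = sa * math.log10(dose) + ia
        effect = inverse_probit(y)
        if not 1e-6 < effect < 1 - 1e-6:
            return  # round-trip through Φ loses precision in the far tails
        oracle = 10.0 ** ((probit(effect) - ib) / sb)
        assert dose_equivalent_b_of_a(fa, fb, dose) == pytest.approx(
            oracle, rel=1e-8
        )


def grid_scan_bounds(fit_a, fit_b, design, n_grid=1_000_000):
    """Independent oracle: locate each isobole-ray intersection by scanning
    a dense log-spaced grid of total doses for the residual sign change."""
    a50 = 10.0 ** ((5.0 - fit_a.intercept_a) / fit_a.slope_b)
    b50 = 10.0 ** ((5.0 - fit_b.intercept_a) / fit_b.slope_b)
    f = design.fraction_f
    s = f * a50 + (1.0 - f) * b50
    t = np.logspace(
        math.log10(min(a50, b50) * 1e-4), math.log10(a50 + b50), n_grid
    )
    a = t * f * a50 / s
    b = t * (1.0 - f) * b50 / s
    b_eq = 10.0 ** (
        (fit_a.slope_b * np.log10(a) + fit_a.intercept_a - fit_b.intercept_a)
        / fit_b.slope_b
    )
    a_eq = 10.0 ** (
        (fit_b.slope_b * np.log10(b) + fit_b.intercept_a - fit_a.intercept_a)
        / fit_a.slope_b
    )
    roots = []
    for resid in (b + b_eq - b50, a + a_eq - a50):
        idx = int(np.argmax(resid > 0))
        roots.append(0.5 * (t[idx - 1] + t[idx]))
    return min(roots), max(roots)


class TestAdditiveNonParallel:
    def test_equal_slopes_reduce_to_parallel_value(self):
        fa, fb = exact_fit(2.0, 1.0), exact_fit(2.0, 3.0)
        ea, eb = est_of(fa), est_of(fb)
        design = FixedRatioDesign(0.5)
        pred = additive_nonparallel(fa, fb, ea, eb, design)
        straight = additive_parallel(ea, eb, design)
        assert pred.lower_ic50_add == pytest.approx(
            straight.lower_ic50_add, rel=1e-6
        )
        assert pred.upper_ic50_add == pytest.approx(
            straight.lower_ic50_add, rel=1e-6
        )

    def test_curved_bounds_bracket_the_straight_line(self):
        fa = exact_fit(4.35, 5.0 - 4.35 * math.log10(85.0))
        fb = exact_fit(1.5, 5.0 - 1.5 * math.log10(5e-3))
        ea, eb = est_of(fa), est_of(fb)
        design = FixedRatioDesign(0.5)
        pred = additive_nonparallel(fa, fb, ea, eb, design)
        straight = additive_parallel(ea, eb, design).lower_ic50_add
        assert pred.lower_ic50_add < straight < pred.upper_ic50_add

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_grid_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sa, sb = rng.uniform(0.8, 5.0, 2)
        a50 = 10.0 ** rng.uniform(-1.0, 2.0)
        b50 = 10.0 ** rng.uniform(-1.0, 2.0)
        f = rng.uniform(0.2, 0.8)
        fa = exact_fit(sa, 5.0 - sa * math.log10(a50))
        fb = exact_fit(sb, 5.0 - sb * math.log10(b50))
        design = FixedRatioDesign(f)
        pred = additive_nonparallel(fa, fb, est_of(fa), est_of(fb), design)
        lo, hi = grid_scan_bounds(fa, fb, design, n_grid=200_000)
        assert pred.lower_ic50_add == pytest.approx(lo, rel=1e-4)
        assert pred.upper_ic50_add == pytest.approx(hi, rel=1e-4)

    def test_bounds_ordered_and_n_add_summed(self):
        fa, fb = exact_fit(3.0, -1.0, n=48), exact_fit(1.2, 4.0, n=40)
        pred = additive_nonparallel(
            fa, fb, est_of(fa), est_of(fb), FixedRatioDesign(0.5)
        )
        assert 0 < pred.lower_ic50_add <= pred.upper_ic50_add
        assert pred.n_add == 88
        assert not pred.parallel_case


class TestIsobologramCoordinates:
    def test_parallel_curves_coincide_and_hit_intercepts(self):
        a = PotencyEstimate(50.0, 2.0, 48)
        b = PotencyEstimate(10.0, 1.0, 48)
        design = FixedRatioDesign(0.5)
        pred = additive_parallel(a, b, design)
        mix = PotencyEstimate(28.0, 2.0, 48)
        pts = isobologram_coordinates(a, b, pred, mix, design, resolution=50)
        lower = [(p.dose_a, p.dose_b) for p in pts if p.curve_id == "additive_lower"]
        upper = [(p.dose_a, p.dose_b) for p in pts if p.curve_id == "additive_upper"]
        assert lower == upper
        assert lower[0] == pytest.approx((50.0, 0.0))
        assert lower[-1] == pytest.approx((0.0, 10.0))

    def test_mix_point_lies_on_fixed_ratio_ray(self):
        a = PotencyEstimate(50.0, 2.0, 48)
        b = PotencyEstimate(10.0, 1.0, 48)
        design = FixedRatioDesign(0.5)
        pred = additive_parallel(a, b, design)
        mix = PotencyEstimate(28.0, 2.0, 48)
        pts = isobologram_coordinates(a, b, pred, mix, design)
        m = next(p for p in pts if p.curve_id == "experimental_mix")
        assert m.dose_a / m.dose_b == pytest.approx(
            (design.fraction_f * a.ic50) / ((1 - design.fraction_f) * b.ic50)
        )
        assert m.dose_a + m.dose_b == pytest.approx(mix.ic50)

    def test_nonparallel_curve_endpoints_equal_axis_intercepts(self):
        fa = exact_fit(3.0, 5.0 - 3.0 * math.log10(50.0))
        fb = exact_fit(1.5, 5.0 - 1.5 * math.log10(10.0))
        ea, eb = est_of(fa), est_of(fb)
        design = FixedRatioDesign(0.5)
        pred = additive_nonparallel(fa, fb, ea, eb, design)
        mix = PotencyEstimate(28.0, 2.0, 48)
        pts = isobologram_coordinates(
            ea, eb, pred, mix, design, fit_a=fa, fit_b=fb, resolution=40
        )
        for cid in ("additive_lower", "additive_upper"):
            curve = [p for p in pts if p.curve_id == cid]
            ends = {
                (round(curve[0].dose_a, 6), round(curve[0].dose_b, 6)),
                (round(curve[-1].dose_a, 6), round(curve[-1].dose_b, 6)),
            }
            assert (50.0, 0.0) in ends and (0.0, 10.0) in ends
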