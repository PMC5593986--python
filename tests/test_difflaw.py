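"""Diffusion-law fitting: regime lines, crossover search, classification,
domain sizing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spotvar import (
    DiffusionLawPoint,
    DomainSizeError,
    RegimeFit,
    classify_regime,
    domain_size,
    fit_crossover,
    fit_line,
)
from spotvar.difflaw import FREE, GEL_MESHWORK, TRAPPED, _domain_size_se

from conftest import law_points_on_line

EIGHT_LN2 = 8 * np.log(2)


def slope_for_D(D):
    """ms/nm^2 slope of the diffusion law at diffusivity D (um^2/s)."""
    return 1e-3 / (EIGHT_LN2 * D)


class TestFitLine:
    def test_exact_line_recovered_to_machine_precision(self):
        pts = law_points_on_line(slope_for_D(2.0), 0.0,
                                 [80, 100, 120, 160, 200, 240])
        fit = fit_line(pts)
        assert fit.D_eff == pytest.approx(2.0, rel=1e-12)
        assert fit.t0 == pytest.approx(0.0, abs=1e-12)

    def test_two_points_rejected(self):
        pts = law_points_on_line(1e-4, 0.0, [80, 240])
        with pytest.raises(ValueError):
            fit_line(pts)

    def test_intercept_coverage_on_noisy_lines(self):
        # 2-sigma interval covers the true t0 in >= 90% of replicates
        hits = 0
        for seed in range(100):
            pts = law_points_on_line(
                slope_for_D(2.0), 0.3,
                [80, 100, 120, 140, 160, 180, 210, 240],
                noise=0.03, seed=seed,
            )
            fit = fit_line(pts)
            hits += abs(fit.t0 - 0.3) <= 2 * fit.se_t0
        assert hits >= 90

    def test_negative_slope_flagged(self):
        pts = [DiffusionLawPoint(d, 10.0 - 0.0001 * d ** 2 * 0.1, None)
               for d in (80, 120, 160, 200)]
        fit = fit_line(pts)
        assert np.isnan(fit.D_eff)


class TestCrossover:
    def test_single_exact_line_stays_single(self):
        pts = law_points_on_line(slope_for_D(1.5), 0.0,
                                 [80, 100, 120, 140, 160, 180, 210, 240])
        fit = fit_crossover(pts)
        assert not fit.segmented
        assert fit.xi is None
        assert fit.labels == [FREE]

    def test_exact_breakpoint_recovered(self):
        # two lines intersecting at d = 140 nm, 5 + 5 points; effective
        # diffusion faster below the crossover as in the published tables
        s_lo, s_hi = slope_for_D(3.19), slope_for_D(1.14)
        x_star = 140.0 ** 2
        t_hi = 0.0
        t_lo = (s_hi - s_lo) * x_star + t_hi
        pts = (law_points_on_line(s_lo, t_lo, [80, 95, 110, 125, 138])
               + law_points_on_line(s_hi, t_hi, [145, 165, 185, 210, 240]))
        fit = fit_crossover(pts)
        assert fit.segmented
        assert fit.xi_rule == "intersection"
        assert fit.xi == pytest.approx(140.0, rel=1e-9)
        # recovered partition is the generating partition
        assert fit.selection["split_index"] == 5
        assert fit.regimes[0].n_points == 5

    def test_selection_record_is_complete(self):
        pts = law_points_on_line(slope_for_D(2.0), 0.0,
                                 [80, 100, 120, 140, 160, 180, 210, 240],
                                 noise=0.02, seed=1)
        fit = fit_crossover(pts)
        sel = fit.selection
        for key in ("rss_single", "rss_segmented", "p_value", "f_stat",
                    "bic_single", "bic_segmented", "selected",
                    "n_candidate_partitions"):
            assert key in sel

    def test_too_few_points_rejected(self):
        pts = law_points_on_line(1e-4, 0.0, [80, 100, 120, 140, 160])
        with pytest.raises(ValueError):
            fit_crossover(pts)

    def test_crossover_tolerant_to_noise(self):
        # two regimes as published for high-cholesterol bilayers: faster
        # effective diffusion below the crossover, slower above; 3% noise,
        # break at 140 nm; xi recovered within 15%
        s_lo, s_hi = slope_for_D(3.19), slope_for_D(1.14)
        x_star = 140.0 ** 2
        t_hi = 0.0
        t_lo = t_hi + (s_hi - s_lo) * x_star
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            pts = (law_points_on_line(s_lo, t_lo, [80, 95, 110, 125, 138],
                                      noise=0.03, seed=2 * seed)
                   + law_points_on_line(s_hi, t_hi, [145, 165, 185, 210, 240],
                                        noise=0.03, seed=2 * seed + 1))
            fit = fit_crossover(pts)
            if fit.segmented and abs(fit.xi - 140.0) <= 0.15 * 140.0:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestClassification:
    @pytest.mark.parametrize(
        "t0,se,label",
        [
            (0.0, 0.05, FREE),
            (0.29, 0.05, TRAPPED),   # DOPC:Chl(1:1) S below crossover
            (-2.27, 0.1, GEL_MESHWORK),  # DOPC:Chl(1:1) S above crossover
            (0.08, 0.05, FREE),
        ],
    )
    def test_significance_classification(self, t0, se, label):
        fit = RegimeFit(slope=1e-4, t0=t0, se_slope=1e-6, se_t0=se,
                        n_points=5, d2_range=(6400, 57600))
        assert classify_regime(fit) == label

    def test_degenerate_se_classified_by_sign(self):
        fit = RegimeFit(slope=1e-4, t0=-0.5, se_slope=0.0, se_t0=0.0,
                        n_points=5, d2_range=(6400, 57600))
        with pytest.warns(UserWarning):
            assert classify_regime(fit) == GEL_MESHWORK


class TestDomainSize:
    def test_table_values(self):
        # printed regime parameters reproduce the published domain sizes
        assert domain_size(1.14, -2.27) == pytest.approx(119.8, abs=0.05)
        assert domain_size(0.96, -1.77) == pytest.approx(97.1, abs=0.05)

    def test_positive_intercept_refused(self):
        with pytest.raises(DomainSizeError):
            domain_size(1.0, 0.2)
        with pytest.raises(DomainSizeError):
            domain_size(1.0, 0.0)

    @given(st.floats(0.05, 10.0), st.floats(-5.0, -0.01))
    @settings(max_examples=60, derandomize=True)
    def test_zero_crossing_identity(self, D_eff, t0):
        # the fitted line evaluated at d^2 = omega^2 returns tau = 0
        omega = domain_size(D_eff, t0)
        slope = 1e-3 / (EIGHT_LN2 * D_eff)
        assert slope * omega ** 2 + t0 == pytest.approx(0.0, abs=1e-9)

    def test_error_propagation_scales(self):
        fit = RegimeFit(slope=slope_for_D(1.14), t0=-2.27,
                        se_slope=0.05 * slope_for_D(1.14), se_t0=0.1,
                        n_points=5, d2_range=(6400, 57600))
        se = _domain_size_se(fit)
        om = domain_size(fit.D_eff, fit.t0)
        rel = 0.5 * np.sqrt((0.1 / 2.27) ** 2 + 0.05 ** 2)
        assert se == pytest.approx(om * rel, rel=1e-6)

    def test_unit_coherence_with_spot_diffusivity(self):
        # a zero-intercept regime's D_eff equals the per-spot conversion
        from spotvar import spot_diffusivity

        pts = law_points_on_line(slope_for_D(1.7), 0.0, [80, 120, 200])
        fit = fit_line(pts)
        p = pts[1]
        assert fit.D_eff == pytest.approx(spot_diffusivity(p.tau_D, p.d), rel=1e-9)
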