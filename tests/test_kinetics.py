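"""Population-level kinetics: summaries, cv statistic, Bell–Evans fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sawtooth import presets
from sawtooth.curves import analyze_curve
from sawtooth.kinetics import (
    SpeedPoint,
    compare_conditions,
    cv_per_curve,
    fit_bell_evans,
    force_summary,
)
from sawtooth.models import BellParams, evans_force, rupture_force_distribution
from sawtooth.simulate import NoiseModel, PullingProtocol, simulate_constant_loading, simulate_pull

RII_KINETICS = BellParams(0.003, 0.2)


class TestForceSummary:
    def test_mean_and_sample_sd(self):
        s = force_summary([300.0, 350.0, 400.0], "mean")
        assert s.representative == 350.0
        assert s.sd == pytest.approx(50.0)
        assert s.n == 3

    def test_constant_sample_has_zero_sd(self):
        assert force_summary([250.0] * 5, "mean").sd == 0.0

    def test_mode_requires_twenty_forces(self):
        with pytest.raises(ValueError):
            force_summary(np.arange(19.0) + 100.0, "mode")

    def test_mode_matches_analytic_distribution(self):
        forces = simulate_constant_loading(RII_KINETICS, 1.5e5, 10_000, seed=8)
        s = force_summary(forces, "mode")
        dist = rupture_force_distribution(1.5e5, RII_KINETICS)
        assert s.representative == pytest.approx(dist.mode, abs=5.0)


def _table(curve_id, forces, label="RII"):
    return pd.DataFrame(
        {"curve_id": curve_id, "Fu_pN": forces, "label": label}
    )


class TestCvPerCurve:
    def test_equal_forces_give_zero_cv(self):
        stats = cv_per_curve(_table("a", [300.0] * 6), min_peaks=5)
        assert stats.per_curve["cv"].iloc[0] == 0.0

    def test_hand_computed_cv(self):
        stats = cv_per_curve(_table("a", [300.0, 350.0, 400.0]), min_peaks=3)
        assert stats.per_curve["cv"].iloc[0] == pytest.approx(50.0 / 350.0)

    def test_only_repeat_labels_counted(self):
        t = pd.concat(
            [_table("a", [300.0] * 5), _table("a", [90.0], label="GFP")],
            ignore_index=True,
        )
        stats = cv_per_curve(t, min_peaks=5)
        assert stats.per_curve["n_forces"].iloc[0] == 5

    def test_no_qualifying_curves_flagged_empty(self):
        stats = cv_per_curve(_table("a", [300.0, 310.0]), min_peaks=5)
        assert stats.n_curves == 0
        assert math.isnan(stats.cv_mean)

    @given(scale=st.floats(0.1, 10.0))
    def test_cv_scale_invariant(self, scale):
        base = np.array([280.0, 310.0, 330.0, 355.0, 390.0])
        a = cv_per_curve(_table("a", base), min_peaks=5)
        b = cv_per_curve(_table("a", scale * base), min_peaks=5)
        assert a.cv_mean == pytest.approx(b.cv_mean, rel=1e-9)

    def test_heterogeneous_kinetics_raise_cv(self):
        """Per-domain rate spread widens the within-curve force spread."""
        rng = np.random.default_rng(3)
        r = 1.5e5
        homogeneous, mixed = [], []
        multipliers = np.exp(1.5 * np.array([-1.4, -1.0, -0.5, -0.1, 0.1, 0.5, 1.0, 1.4]))
        for c in range(30):
            f_hom = simulate_constant_loading(RII_KINETICS, r, 8, rng)
            homogeneous.append(_table(f"h{c}", f_hom))
            f_mix = np.concatenate(
                [
                    simulate_constant_loading(
                        BellParams(RII_KINETICS.k_u0 * m, RII_KINETICS.x_u), r, 1, rng
                    )
                    for m in multipliers
                ]
            )
            mixed.append(_table(f"m{c}", f_mix))
        cv_hom = cv_per_curve(homogeneous, min_peaks=5).cv_mean
        cv_mix = cv_per_curve(mixed, min_peaks=5).cv_mean
        assert cv_mix > cv_hom


class TestBellEvansFit:
    def test_exact_points_recover_parameters(self):
        speeds = [50.0, 200.0, 1000.0, 4880.0]
        pts = [
            SpeedPoint(v, 150.0, evans_force(150.0 * v, RII_KINETICS), 1.0, 100)
            for v in speeds
        ]
        params, stderr = fit_bell_evans(pts)
        assert params.x_u == pytest.approx(0.2, rel=1e-9)
        assert params.k_u0 == pytest.approx(0.003, rel=1e-6)
        assert stderr["x_u_nm"] == pytest.approx(0.0, abs=1e-9)

    def test_two_point_series_exact_line(self):
        pts = [
            SpeedPoint(v, 150.0, evans_force(150.0 * v, RII_KINETICS), 1.0, 10)
            for v in (100.0, 2000.0)
        ]
        params, _ = fit_bell_evans(pts)
        assert params.x_u == pytest.approx(0.2, rel=1e-9)

    def test_negative_slope_rejected(self):
        pts = [
            SpeedPoint(100.0, 150.0, 300.0, 1.0, 10),
            SpeedPoint(1000.0, 150.0, 200.0, 1.0, 10),
        ]
        with pytest.raises(ValueError):
            fit_bell_evans(pts)

    def test_single_rate_rejected(self):
        pts = [SpeedPoint(100.0, 150.0, 300.0, 1.0, 10)] * 3
        with pytest.raises(ValueError):
            fit_bell_evans(pts)

    def test_recovery_from_sampled_modes(self):
        speeds = [50.0, 200.0, 1000.0, 4880.0]
        pts = []
        for i, v in enumerate(speeds):
            forces = simulate_constant_loading(RII_KINETICS, 150.0 * v, 2000, seed=40 + i)
            s = force_summary(forces, "mode")
            pts.append(SpeedPoint(v, 150.0, s.representative, s.sd, s.n))
        params, _ = fit_bell_evans(pts)
        assert params.x_u == pytest.approx(0.2, rel=0.15)
        assert 0.0015 <= params.k_u0 <= 0.006

    def test_end_to_end_speed_series_recovers_xu(self):
        """Pull, analyze, fit: x_u within 25% despite WLC-loading nonlinearity.

        The fit uses the nominal loading rate k_c*v while the true rate
        is reduced by chain compliance; the reduction is nearly uniform
        in ln(r), so the slope (hence x_u) survives, unlike k_u0.
        """
        noise = NoiseModel(force_noise_sd=8.0, adhesion_amplitude=0.0)
        pts = []
        for i, v in enumerate([50.0, 200.0, 1000.0, 4880.0]):
            protocol = PullingProtocol(speed=v, ramp_length=420.0)
            forces = []
            for s in range(25):
                curve, _ = simulate_pull(
                    presets.rii8(), protocol, noise, seed=7000 + 100 * i + s
                )
                table = analyze_curve(curve)
                forces += list(table.loc[table["label"] == "RII", "Fu_pN"])
            summary = force_summary(np.array(forces), "mode")
            pts.append(SpeedPoint(v, 150.0, summary.representative, summary.sd, summary.n))
        params, _ = fit_bell_evans(pts)
        assert params.x_u == pytest.approx(0.2, rel=0.25)


class TestCompareConditions:
    def test_identical_inputs_zero_difference(self):
        c = compare_conditions([300.0, 310.0], [300.0, 310.0])
        assert c.force_difference == 0.0

    def test_difference_sign_matches_construction(self):
        strong = simulate_constant_loading(RII_KINETICS, 1.5e5, 500, seed=1)
        weak = simulate_constant_loading(BellParams(0.22, 0.2), 1.5e5, 500, seed=2)
        c = compare_conditions(strong, weak)
        assert c.force_difference > 0

    def test_pooled_se_agrees_with_bootstrap(self):
        rng = np.random.default_rng(11)
        a = rng.normal(340.0, 40.0, 60)
        b = rng.normal(240.0, 55.0, 45)
        c = compare_conditions(a, b)
        boots = [
            rng.choice(a, a.size).mean() - rng.choice(b, b.size).mean()
            for _ in range(2000)
        ]
        assert c.pooled_se == pytest.approx(np.std(boots), rel=0.10)
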