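"""Curve analysis: baseline, peak detection, WLC fits, classification."""

import numpy as np
import pandas as pd
import pytest

from sawtooth import presets
from sawtooth.curves import (
    CurveMeta,
    ForceCurve,
    PeakCall,
    analyze_curve,
    detect_peaks,
    estimate_baseline,
    event_table,
    fit_wlc_peak,
    sawtooth_filter,
)
from sawtooth.models import WLCParams, wlc_force
from sawtooth.simulate import NoiseModel, PullingProtocol, simulate_pull

META = CurveMeta(speed_nm_s=1000.0, k_N_m=0.15, curve_id="t")


def _curve(x, f):
    return ForceCurve(np.asarray(x, float), np.asarray(f, float), META)


class TestBaseline:
    def test_constant_zero_curve(self):
        c = _curve(np.linspace(0, 100, 200), np.zeros(200))
        assert estimate_baseline(c) == 0.0

    def test_offset_recovered_from_tail(self):
        noise = NoiseModel(force_noise_sd=0.0, adhesion_amplitude=0.0)
        curve, _ = simulate_pull(presets.rii8(), PullingProtocol(), noise, seed=1)
        shifted = ForceCurve(curve.extension, curve.force + 12.5, curve.metadata)
        assert estimate_baseline(shifted) == pytest.approx(12.5, abs=0.5)

    def test_pure_noise_curve(self):
        rng = np.random.default_rng(0)
        n = 2000
        c = _curve(np.linspace(0, 1000, n), rng.normal(0, 8.0, n))
        assert abs(estimate_baseline(c)) < 3 * 8.0 / np.sqrt(0.1 * n)


class TestDetection:
    def test_flat_noise_curve_has_no_peaks(self):
        rng = np.random.default_rng(1)
        c = _curve(np.linspace(0, 1000, 3000), rng.normal(0, 8.0, 3000))
        assert detect_peaks(c) == []

    def test_simulated_octamer_events_all_found(self, rii8_batch):
        hits = total = 0
        for curve, log in rii8_batch[:30]:
            peaks = detect_peaks(curve)
            px = np.array([p.peak_extension for p in peaks])
            for e in log.events:
                total += 1
                x_evt = e.piezo - e.force / curve.metadata.k_pn_nm
                hits += int(np.any(np.abs(px - x_evt) <= 10.0))
        assert hits / total >= 0.95

    def test_unfolding_force_is_peak_minus_baseline(self, rii8_batch):
        curve, _ = rii8_batch[0]
        for p in detect_peaks(curve):
            assert p.unfolding_force == pytest.approx(
                p.peak_force_raw - p.baseline, rel=1e-12
            )
            assert p.unfolding_force >= 0


class TestWLCFitting:
    def test_noiseless_segment_recovered_to_0p1_percent(self):
        chain = WLCParams(0.3, 40.0)
        x = np.linspace(0.0, 36.0, 200)
        f = wlc_force(x, chain)
        curve = _curve(x, f)
        peak = PeakCall(199, x[-1], f[-1], 0.0)
        fit = fit_wlc_peak(curve, peak)
        assert fit.valid
        assert fit.contour_length == pytest.approx(40.0, rel=1e-3)
        assert fit.persistence_length == pytest.approx(0.3, rel=1e-3)

    def test_short_window_is_flagged_not_fitted(self):
        chain = WLCParams(0.3, 40.0)
        x = np.linspace(0.0, 30.0, 5)
        curve = _curve(x, wlc_force(x, chain))
        fit = fit_wlc_peak(curve, PeakCall(4, x[-1], 10.0, 0.0))
        assert not fit.valid

    def test_fitted_persistence_length_in_plausible_band(self, rii8_batch):
        lps = []
        for curve, _ in rii8_batch[:30]:
            table = analyze_curve(curve)
            lps += list(table.loc[table["label"] != "adhesion", "Lp_nm"].dropna())
        assert 0.1 <= np.mean(lps) <= 0.5  # generated at 0.3 nm

    def test_contour_length_increases_along_curve(self, rii8_batch):
        for curve, _ in rii8_batch[:20]:
            table = analyze_curve(curve)
            lc = table.loc[table["label"] != "adhesion", "Lc_nm"].dropna().to_numpy()
            assert np.all(np.diff(lc) > 0)

    def test_unfolding_length_below_contour_increment(self, rii8_batch):
        """dL < dL_c: rupture happens before full extension of the released contour."""
        both = []
        for curve, _ in rii8_batch[:20]:
            table = analyze_curve(curve)
            # the pair ending at the detachment peak is not an unfolding:
            # extension runs far up the final contour before the tether breaks
            sub = table[table["label"] != "detach"].dropna(subset=["dL_nm", "dLc_nm"])
            both += list(zip(sub["dL_nm"], sub["dLc_nm"]))
        assert both
        frac = np.mean([dl < dlc for dl, dlc in both])
        assert frac > 0.9  # allow rare noise-driven inversions


class TestEventTable:
    def test_unfolding_length_arithmetic(self):
        x = np.linspace(0, 120, 400)
        curve = _curve(x, np.zeros(400))
        exts = [30.0, 63.2, 96.4]
        peaks = [PeakCall(int(e / 120 * 399), e, 300.0, 0.0) for e in exts]
        from sawtooth.curves import WLCFitResult

        fits = [WLCFitResult(e + 8.0, 0.3, 0.1, (0, 1)) for e in exts]
        table = event_table(curve, peaks, fits)
        assert list(table["dL_nm"].dropna()) == pytest.approx([33.2, 33.2])
        assert list(table["dLc_nm"].dropna()) == pytest.approx([33.2, 33.2])

    def test_single_peak_curve_has_no_increments(self):
        x = np.linspace(0, 120, 50)
        curve = _curve(x, np.zeros(50))
        from sawtooth.curves import WLCFitResult

        table = event_table(
            curve, [PeakCall(25, 60.0, 200.0, 0.0)], [WLCFitResult(70.0, 0.3, 0.1, (0, 25))]
        )
        assert table["dL_nm"].isna().all()


class TestClassification:
    def test_gfp_peak_labelled_once_and_first(self):
        noise = NoiseModel(
            force_noise_sd=4.0, adhesion_amplitude=0.0, gfp_misfold_probability=0.0
        )
        found = 0
        for seed in range(6):
            curve, log = simulate_pull(presets.rii8_gfp(), PullingProtocol(), noise, seed=seed)
            if not any(e.domain == "GFP" for e in log.events):
                continue
            table = analyze_curve(curve)
            labels = list(table["label"])
            if labels.count("GFP") == 1:
                found += 1
                gfp_pos = labels.index("GFP")
                assert all(lab != "RII" for lab in labels[:gfp_pos])
        assert found >= 4

    def test_no_gfp_labels_without_gfp_domain(self, rii8_batch):
        for curve, _ in rii8_batch[:20]:
            table = analyze_curve(curve)
            assert (table["label"] != "GFP").all()

    def test_misfolded_gfp_curves_show_no_gfp_peak(self):
        noise = NoiseModel(
            force_noise_sd=4.0, adhesion_amplitude=0.0, gfp_misfold_probability=1.0
        )
        for seed in range(4):
            curve, log = simulate_pull(presets.rii8_gfp(), PullingProtocol(), noise, seed=seed)
            assert not any(e.domain == "GFP" for e in log.events)
            table = analyze_curve(curve)
            assert (table["label"] != "GFP").all()

    def test_adhesion_artifact_not_counted_as_molecular_peak(self):
        rng = np.random.default_rng(7)
        n = 3000
        x = np.linspace(0, 1000, n)
        f = rng.normal(0, 8.0, n) + 180.0 * np.exp(-0.5 * ((x - 12.0) / 7.0) ** 2)
        curve = _curve(x, f)
        table = analyze_curve(curve)
        assert (table["label"] != "RII").all()


class TestSawtoothFilter:
    def test_min_peaks_one_keeps_all_curves_with_peaks(self):
        t1 = pd.DataFrame({"label": ["RII"], "curve_id": ["a"]})
        t0 = pd.DataFrame({"label": [], "curve_id": []})
        assert sawtooth_filter([t1, t0], min_peaks=1) == [t1]

    def test_retained_set_matches_ground_truth(self):
        # tether weak enough to detach mid-curve: unfold counts vary 0..8
        from sawtooth.models import BellParams

        noise = NoiseModel(
            force_noise_sd=8.0,
            adhesion_amplitude=0.0,
            tether_kinetics=BellParams(k_u0=5e-4, x_u=0.15),
        )
        tables, truth = [], []
        for seed in range(25):
            curve, log = simulate_pull(
                presets.rii8(), PullingProtocol(), noise, seed=seed, curve_id=f"c{seed}"
            )
            tables.append(analyze_curve(curve))
            truth.append(f"c{seed}" if log.unfold_count >= 5 else None)
        kept_ids = {
            t["curve_id"].iloc[0] for t in sawtooth_filter(tables, min_peaks=5) if len(t)
        }
        assert kept_ids == {c for c in truth if c is not None}

    def test_min_peaks_above_construct_size_empty(self, rii8_batch):
        tables = [analyze_curve(c) for c, _ in rii8_batch[:5]]
        assert sawtooth_filter(tables, min_peaks=12) == []
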