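"""Force-extension curve analysis.

Baseline estimation, rupture-peak detection, per-peak worm-like-chain
fits, event tables (unfolding force F_u, contour-length increment
dL_c, peak-to-peak unfolding length dL) and peak classification.

An unfolding force is defined as the height of the rupture peak minus
the baseline.  dL_c is the difference between the fitted contour
lengths of consecutive peaks; dL is the difference in extension between
consecutive peaks.  Event tables are plain :class:`pandas.DataFrame`
objects with the columns in :data:`EVENT_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .constants import DEFAULT_TEMPERATURE, N_PER_M_TO_PN_PER_NM
from .models import WLCParams, wlc_force

__all__ = [
    "CurveMeta",
    "ForceCurve",
    "PeakCall",
    "WLCFitResult",
    "AnalysisSettings",
    "EVENT_COLUMNS",
    "estimate_baseline",
    "detect_peaks",
    "fit_wlc_peak",
    "event_table",
    "classify_peaks",
    "analyze_curve",
    "sawtooth_filter",
]

#: Columns of an event table (one row per detected rupture peak).
EVENT_COLUMNS = [
    "curve_id",
    "peak_idx",
    "extension_nm",
    "Fu_pN",
    "Lc_nm",
    "Lp_nm",
    "residual_rms",
    "dLc_nm",
    "dL_nm",
    "label",
    "speed_nm_s",
    "k_N_m",
]


@dataclass(frozen=True)
class CurveMeta:
    """Acquisition metadata attached to a force curve."""

    speed_nm_s: float
    k_N_m: float
    temperature_K: float = DEFAULT_TEMPERATURE
    curve_id: str = "curve"

    @property
    def k_pn_nm(self) -> float:
        return self.k_N_m * N_PER_M_TO_PN_PER_NM


@dataclass(frozen=True)
class ForceCurve:
    """One pulling ramp: tip-sample separation (nm) vs force (pN).

    Extension is the tip-sample separation x = z - F/k_c, not the raw
    piezo position; it must be (noise-tolerance) non-decreasing.
    """

    extension: np.ndarray
    force: np.ndarray
    metadata: CurveMeta

    def __post_init__(self) -> None:
        x = np.asarray(self.extension, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "extension", x)
        object.__setattr__(self, "force", f)
        if x.ndim != 1 or f.ndim != 1 or x.size != f.size:
            raise ValueError("extension and force must be 1-D and equal length")
        if x.size < 2:
            raise ValueError("a force curve needs at least 2 samples")
        if np.any(np.diff(x) < -0.5):
            raise ValueError("extension must be non-decreasing")

    def __len__(self) -> int:
        return self.extension.size


@dataclass(frozen=True)
class PeakCall:
    """One detected rupture peak; F_u = raw peak force - baseline."""

    peak_index: int
    peak_extension: float
    peak_force_raw: float
    baseline: float

    @property
    def unfolding_force(self) -> float:
        return self.peak_force_raw - self.baseline


@dataclass(frozen=True)
class WLCFitResult:
    """Per-peak WLC fit: contour length, persistence length, residual rms."""

    contour_length: float
    persistence_length: float
    residual_rms: float
    window: tuple[int, int]
    valid: bool = True

    @classmethod
    def flagged(cls, window: tuple[int, int]) -> "WLCFitResult":
        return cls(np.nan, np.nan, np.nan, window, valid=False)


@dataclass(frozen=True)
class AnalysisSettings:
    """Thresholds for detection, fitting and classification.

    The defaults are chosen so the weakest domain expected in these
    constructs (GFP, ~88 pN) clears the detection threshold above
    typical AFM force noise while baseline wander does not.
    """

    min_force: float = 50.0        # pN above baseline for a peak
    min_drop: float = 50.0         # pN drop required after the peak
    min_separation: float = 10.0   # nm between peaks / drop search window
    min_peaks: int = 5             # sawtooth filter threshold
    tail_fraction: float = 0.1     # extension fraction used for the baseline
    min_window_points: int = 8     # minimum samples for a WLC fit
    gfp_band: tuple[float, float] = (60.0, 90.0)  # nm, dL or dLc of a GFP event
    gfp_force_max: float = 150.0   # pN, GFP/repeat discrimination threshold
    adhesion_cutoff: float = 25.0  # nm from the surface for adhesion artifacts
    repeat_label: str = "RII"      # label given to ordinary repeat unfoldings


def estimate_baseline(curve: ForceCurve, tail_fraction: float = 0.1) -> float:
    """Median force over the post-detachment tail of the curve.

    The final ``tail_fraction`` of the extension range is used when it
    is flat (spread compatible with the point-to-point noise);
    otherwise the estimator falls back to the mode of a force
    histogram, which is dominated by baseline samples in typical
    curves.
    """
    x, f = curve.extension, curve.force
    span = x[-1] - x[0]
    tail = f[x >= x[-1] - tail_fraction * span]
    noise_sd = float(np.std(np.diff(f)) / np.sqrt(2)) if f.size > 2 else 0.0
    if tail.size >= 4 and float(np.std(tail)) <= max(3.0 * noise_sd, 1e-12):
        return float(np.median(tail))
    counts, edges = np.histogram(f, bins="fd" if f.size > 10 else 10)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def detect_peaks(
    curve: ForceCurve,
    min_force: float = 50.0,
    min_drop: float = 50.0,
    min_separation: float = 10.0,
    baseline: float | None = None,
    tail_fraction: float = 0.1,
) -> list[PeakCall]:
    """Detect rupture peaks: maxima above baseline followed by a sharp drop.

    A local maximum qualifies when it exceeds ``baseline + min_force``
    and the force falls by at least ``min_drop`` within
    ``min_separation`` nm after it.  Peaks closer than
    ``min_separation`` keep only the higher one.  Returned in order of
    increasing extension.
    """
    if baseline is None:
        baseline = estimate_baseline(curve, tail_fraction)
    x, f = curve.extension, curve.force
    idx, _ = find_peaks(f, height=baseline + min_force)
    kept: list[PeakCall] = []
    for i in idx:
        after = (x > x[i]) & (x <= x[i] + min_separation)
        if not np.any(after):
            continue
        if f[i] - np.min(f[after]) < min_drop:
            continue
        call = PeakCall(int(i), float(x[i]), float(f[i]), float(baseline))
        if kept and call.peak_extension - kept[-1].peak_extension < min_separation:
            if call.peak_force_raw > kept[-1].peak_force_raw:
                kept[-1] = call
            continue
        kept.append(call)
    return kept


def fit_wlc_peak(
    curve: ForceCurve,
    peak: PeakCall,
    prev_peak: PeakCall | None = None,
    min_window_points: int = 8,
) -> WLCFitResult:
    """Least-squares WLC fit to the rising edge ending at a rupture peak.

    The fit window starts at the force minimum after the preceding peak
    (or the start of the curve) and ends at the peak; both L_c and L_p
    are free.  Fits that fail to converge, or that place L_c at or
    below the peak extension, come back flagged and are excluded from
    downstream statistics.
    """
    x, f = curve.extension, curve.force
    lo = prev_peak.peak_index + 1 if prev_peak is not None else 0
    hi = peak.peak_index + 1
    if hi - lo > 2:
        lo = lo + int(np.argmin(f[lo:hi - 1]))
    window = (lo, hi)
    if hi - lo < min_window_points:
        return WLCFitResult.flagged(window)
    xw = x[lo:hi]
    fw = f[lo:hi] - peak.baseline
    x_max = float(xw[-1])
    if x_max <= x[0] + 1e-9:
        return WLCFitResult.flagged(window)
    T = curve.metadata.temperature_K

    def model(xv, lp, lc):
        t = np.clip(xv / lc, 0.0, 1.0 - 1e-9)
        return wlc_force(t * lc, WLCParams(lp, lc, T))

    try:
        popt, _ = curve_fit(
            model,
            xw,
            fw,
            p0=[0.36, x_max * 1.2],
            bounds=([1e-3, x_max * (1 + 1e-6)], [20.0, max(5.0 * x_max, x_max + 500.0)]),
            maxfev=10000,
        )
    except RuntimeError:
        return WLCFitResult.flagged(window)
    resid = float(np.sqrt(np.mean((model(xw, *popt) - fw) ** 2)))
    lp, lc = float(popt[0]), float(popt[1])
    if lc <= peak.peak_extension:
        return WLCFitResult.flagged(window)
    return WLCFitResult(lc, lp, resid, window)


def event_table(
    curve: ForceCurve,
    peaks: list[PeakCall],
    fits: list[WLCFitResult],
) -> pd.DataFrame:
    """Assemble peaks and fits into an event table for one curve.

    dL_c is the successive difference of valid fitted contour lengths
    and dL the successive difference of peak extensions; the first row
    and rows following a flagged fit carry NaN.
    """
    if len(peaks) != len(fits):
        raise ValueError("peaks and fits must align")
    meta = curve.metadata
    rows = []
    for j, (p, w) in enumerate(zip(peaks, fits)):
        rows.append(
            {
                "curve_id": meta.curve_id,
                "peak_idx": j,
                "extension_nm": p.peak_extension,
                "Fu_pN": p.unfolding_force,
                "Lc_nm": w.contour_length if w.valid else np.nan,
                "Lp_nm": w.persistence_length if w.valid else np.nan,
                "residual_rms": w.residual_rms if w.valid else np.nan,
                "dLc_nm": np.nan,
                "dL_nm": np.nan,
                "label": "",
                "speed_nm_s": meta.speed_nm_s,
                "k_N_m": meta.k_N_m,
            }
        )
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(table) > 1:
        table["dL_nm"] = table["extension_nm"].diff()
        table["dLc_nm"] = table["Lc_nm"].diff()
    return table


def classify_peaks(
    table: pd.DataFrame,
    curve: ForceCurve | None = None,
    settings: AnalysisSettings = AnalysisSettings(),
) -> pd.DataFrame:
    """Label each peak as repeat unfolding, GFP, adhesion or detachment.

    GFP: the gap to the next peak (in extension or fitted contour
    length) falls in ``gfp_band`` and the peak force is below
    ``gfp_force_max``.  Adhesion: close to the surface
    (``adhesion_cutoff``) without a WLC-consistent rising edge.
    Detachment: the final peak after which the force stays at baseline
    (requires ``curve``).  Everything else is a repeat unfolding.
    """
    table = table.copy()
    n = len(table)
    labels = [settings.repeat_label] * n
    ext = table["extension_nm"].to_numpy()
    fu = table["Fu_pN"].to_numpy()
    lc = table["Lc_nm"].to_numpy()
    lp = table["Lp_nm"].to_numpy()
    resid = table["residual_rms"].to_numpy()
    noise_sd = 0.0
    if curve is not None and len(curve) > 2:
        noise_sd = float(np.std(np.diff(curve.force)) / np.sqrt(2))
    lo_band, hi_band = settings.gfp_band
    for j in range(n):
        # adhesion: near-surface peak without a believable WLC edge
        if ext[j] <= settings.adhesion_cutoff:
            consistent = (
                np.isfinite(lc[j])
                and 0.05 <= lp[j] <= 5.0
                and resid[j] <= max(3.0 * noise_sd, 15.0)
            )
            if not consistent:
                labels[j] = "adhesion"
                continue
        if j + 1 < n and fu[j] < settings.gfp_force_max:
            gap_x = ext[j + 1] - ext[j]
            gap_lc = lc[j + 1] - lc[j] if np.isfinite(lc[j + 1]) and np.isfinite(lc[j]) else np.nan
            if lo_band <= gap_x <= hi_band or (
                np.isfinite(gap_lc) and lo_band <= gap_lc <= hi_band
            ):
                labels[j] = "GFP"
    if n > 0 and curve is not None:
        baseline = estimate_baseline(curve, settings.tail_fraction)
        last_idx = int(np.searchsorted(curve.extension, ext[-1]))
        after = curve.force[min(last_idx + 1, len(curve)):]
        if after.size == 0 or np.max(after) < baseline + settings.min_force:
            if labels[-1] != "adhesion":
                labels[-1] = "detach"
    table["label"] = labels
    # recompute increments across molecular peaks only: adhesion artifacts
    # carry no contour information and must not enter the differences
    keep = [j for j, lab in enumerate(labels) if lab != "adhesion"]
    table["dL_nm"] = np.nan
    table["dLc_nm"] = np.nan
    for prev, cur in zip(keep, keep[1:]):
        row = table.index[cur]
        table.loc[row, "dL_nm"] = ext[cur] - ext[prev]
        table.loc[row, "dLc_nm"] = lc[cur] - lc[prev]
    return table


def analyze_curve(
    curve: ForceCurve, settings: AnalysisSettings = AnalysisSettings()
) -> pd.DataFrame:
    """Full per-curve pipeline: baseline, peaks, WLC fits, labels."""
    baseline = estimate_baseline(curve, settings.tail_fraction)
    peaks = detect_peaks(
        curve,
        min_force=settings.min_force,
        min_drop=settings.min_drop,
        min_separation=settings.min_separation,
        baseline=baseline,
        tail_fraction=settings.tail_fraction,
    )
    fits = [
        fit_wlc_peak(
            curve,
            p,
            prev_peak=peaks[j - 1] if j > 0 else None,
            min_window_points=settings.min_window_points,
        )
        for j, p in enumerate(peaks)
    ]
    table = event_table(curve, peaks, fits)
    return classify_peaks(table, curve, settings)


def sawtooth_filter(
    tables: list[pd.DataFrame],
    min_peaks: int = 5,
    label: str = "RII",
) -> list[pd.DataFrame]:
    """Keep event tables with at least ``min_peaks`` repeat-labelled peaks."""
    if min_peaks < 1:
        raise ValueError("min_peaks must be at least 1")
    return [t for t in tables if int((t["label"] == label).sum()) >= min_peaks]
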