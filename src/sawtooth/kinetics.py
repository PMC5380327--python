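"""Population-level dynamic force spectroscopy analysis.

Force summaries (mean or histogram-mode), the per-curve relative force
spread cv = sigma/mu, the Bell–Evans fit of unfolding force against
log loading rate (loading rate defined as k_c * v, cantilever
stiffness times pulling speed, exactly as the estimator it reproduces),
and descriptive comparison of experimental conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import thermal_energy, DEFAULT_TEMPERATURE
from .models import BellParams

__all__ = [
    "SpeedPoint",
    "ForceSummary",
    "CurveStats",
    "ConditionContrast",
    "force_summary",
    "cv_per_curve",
    "fit_bell_evans",
    "compare_conditions",
]


@dataclass(frozen=True)
class SpeedPoint:
    """Per-speed summary for a Bell–Evans fit.

    ``spring_constant`` is in pN/nm so the loading rate k_c*v comes
    out in pN/s.
    """

    speed: float
    spring_constant: float
    force: float
    force_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.spring_constant <= 0:
            raise ValueError("speed and spring_constant must be positive")
        if self.n < 1:
            raise ValueError("n must be at least 1")

    @property
    def loading_rate(self) -> float:
        return self.spring_constant * self.speed


@dataclass(frozen=True)
class ForceSummary:
    representative: float
    sd: float
    n: int
    estimator: str


@dataclass(frozen=True)
class CurveStats:
    """Per-curve cv = sigma/mu rows plus the across-curve aggregate."""

    per_curve: pd.DataFrame  # columns: curve_id, n_forces, mean_pN, sd_pN, cv
    cv_mean: float
    cv_sd: float
    n_curves: int


@dataclass(frozen=True)
class ConditionContrast:
    """Descriptive difference between two conditions (a minus b)."""

    force_difference: float
    pooled_se: float
    cv_difference: float


def force_summary(forces, estimator: str = "mean") -> ForceSummary:
    """Representative force of a rupture-force sample.

    ``mean`` reports the arithmetic mean with the sample (n-1) sd.
    ``mode`` fits a Gaussian to the upper half of a Freedman–Diaconis
    histogram (rupture-force distributions are left-skewed, so the
    region around the peak is the robust part); it requires n >= 20.
    """
    f = np.asarray(forces, dtype=float)
    if f.size < 1:
        raise ValueError("at least one force is required")
    sd = float(f.std(ddof=1)) if f.size > 1 else 0.0
    if estimator == "mean":
        return ForceSummary(float(f.mean()), sd, f.size, "mean")
    if estimator != "mode":
        raise ValueError(f"unknown estimator {estimator!r}")
    if f.size < 20:
        raise ValueError("mode estimation requires at least 20 forces")
    counts, edges = np.histogram(f, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    top = counts >= 0.5 * counts.max()
    mode = float(centers[np.argmax(counts)])
    if top.sum() >= 3:
        try:
            popt, _ = curve_fit(
                lambda x, a, m, s: a * np.exp(-0.5 * ((x - m) / s) ** 2),
                centers[top],
                counts[top],
                p0=[counts.max(), mode, max(f.std(), 1.0)],
                maxfev=5000,
            )
            if edges[0] <= popt[1] <= edges[-1]:
                mode = float(popt[1])
        except RuntimeError:
            pass  # fall back to the argmax bin centre
    return ForceSummary(mode, sd, f.size, "mode")


def cv_per_curve(
    tables: pd.DataFrame | list[pd.DataFrame],
    min_peaks: int = 5,
    label: str = "RII",
) -> CurveStats:
    """Relative force spread cv = sigma/mu per qualifying curve.

    Only ``label``-classified peaks count, and only curves with at
    least ``min_peaks`` of them qualify.  The aggregate is the mean and
    sample sd of cv across qualifying curves; with no qualifying
    curves the aggregate is NaN and the per-curve frame empty.
    """
    if isinstance(tables, list):
        tables = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["curve_id", "label", "Fu_pN"])
        )
    rows = []
    for curve_id, group in tables.groupby("curve_id"):
        forces = group.loc[group["label"] == label, "Fu_pN"].to_numpy()
        if forces.size < min_peaks:
            continue
        mu = float(forces.mean())
        sigma = float(forces.std(ddof=1))
        rows.append(
            {
                "curve_id": curve_id,
                "n_forces": forces.size,
                "mean_pN": mu,
                "sd_pN": sigma,
                "cv": sigma / mu,
            }
        )
    per_curve = pd.DataFrame(rows, columns=["curve_id", "n_forces", "mean_pN", "sd_pN", "cv"])
    if len(per_curve):
        cvs = per_curve["cv"].to_numpy()
        cv_mean = float(cvs.mean())
        cv_sd = float(cvs.std(ddof=1)) if cvs.size > 1 else math.nan
    else:
        cv_mean = math.nan
        cv_sd = math.nan
    return CurveStats(per_curve, cv_mean, cv_sd, len(per_curve))


def fit_bell_evans(
    series: list[SpeedPoint],
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[BellParams, dict]:
    """Bell parameters from force vs log loading rate.

    Ordinary least squares of F on ln(k_c v):

        slope = k_BT / x_u
        intercept = slope * ln( x_u / (k_BT k_u0) )

    so x_u = k_BT/slope and k_u0 = (x_u/k_BT) exp(-intercept/slope).
    Standard errors come from first-order propagation of the OLS
    slope/intercept covariance.  A non-positive slope (forces not
    increasing with loading rate) is unphysical and raises.
    """
    rates = np.array([p.loading_rate for p in series], dtype=float)
    if np.unique(rates).size < 2:
        raise ValueError("at least two distinct loading rates are required")
    forces = np.array([p.force for p in series], dtype=float)
    lnr = np.log(rates)
    if len(series) > 2:
        (slope, intercept), cov = np.polyfit(lnr, forces, 1, cov=True)
    else:
        slope, intercept = np.polyfit(lnr, forces, 1)
        cov = np.zeros((2, 2))
    if slope <= 0:
        raise ValueError("non-positive slope: x_u would be unphysical")
    kT = thermal_energy(temperature)
    x_u = kT / slope
    k_u0 = (x_u / kT) * math.exp(-intercept / slope)
    # first-order propagation through (slope, intercept)
    d_xu = np.array([-kT / slope**2, 0.0])
    dk_ds = k_u0 * (-1.0 / slope + intercept / slope**2)
    dk_db = k_u0 * (-1.0 / slope)
    d_ku0 = np.array([dk_ds, dk_db])
    se_xu = float(np.sqrt(d_xu @ cov @ d_xu))
    se_ku0 = float(np.sqrt(d_ku0 @ cov @ d_ku0))
    stderr = {
        "slope": float(slope),
        "intercept": float(intercept),
        "x_u_nm": se_xu,
        "k_u0_per_s": se_ku0,
    }
    return BellParams(k_u0=k_u0, x_u=x_u, temperature=temperature), stderr


def compare_conditions(
    forces_a,
    forces_b,
    cv_a: float = math.nan,
    cv_b: float = math.nan,
) -> ConditionContrast:
    """Descriptive contrast of two force samples (a minus b).

    The pooled standard error is sqrt(sa^2/na + sb^2/nb) on the
    difference of means; cv_difference contrasts the per-curve spread
    aggregates when given.
    """
    a = np.asarray(forces_a, dtype=float)
    b = np.asarray(forces_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both force samples must be non-empty")
    va = a.var(ddof=1) / a.size if a.size > 1 else 0.0
    vb = b.var(ddof=1) / b.size if b.size > 1 else 0.0
    return ConditionContrast(
        force_difference=float(a.mean() - b.mean()),
        pooled_se=float(np.sqrt(va + vb)),
        cv_difference=float(cv_a - cv_b),
    )
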