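"""Thermal-tune cantilever calibration.

The cantilever's thermal-noise power spectrum is fitted with a damped
simple-harmonic-oscillator (SHO) response

    A(nu) = A_0 + A_DC * nu_0^4 / ((nu_0^2 - nu^2)^2 + nu_0^2 nu^2 / Q^2)

where A_0 is a white baseline, A_DC the zero-frequency amplitude, nu_0
the resonance frequency and Q the quality factor.  The area P under the
resonance term (baseline excluded) equals the mean-square deflection
<z^2>, and equipartition gives the spring constant k = k_BT / P.

The resonance-term area has the closed form P = (pi/2) A_DC nu_0 Q,
used here instead of numerical quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE, N_PER_M_TO_PN_PER_NM, thermal_energy

__all__ = [
    "PowerSpectrum",
    "SHOFit",
    "CalibrationResult",
    "AggregateCalibration",
    "ResonanceFitError",
    "sho_amplitude",
    "fit_resonance",
    "peak_power",
    "spring_constant",
    "calibrate",
    "aggregate_calibrations",
    "simulate_thermal_spectrum",
    "sho_for_spring_constant",
    "read_spectrum",
    "write_spectrum",
]


class ResonanceFitError(RuntimeError):
    """Resonance fit failed; ``best`` carries the last parameter iterate."""

    def __init__(self, message: str, best: "SHOFit | None" = None) -> None:
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class PowerSpectrum:
    """Thermal-noise spectrum: frequencies in Hz, amplitudes in nm^2/Hz."""

    frequencies: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "amplitudes", a)
        if f.ndim != 1 or a.ndim != 1 or f.size != a.size:
            raise ValueError("frequencies and amplitudes must be 1-D and equal length")
        if f.size < 16:
            raise ValueError("spectrum needs at least 16 points")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class SHOFit:
    """Fitted SHO response parameters (see module docstring for the model)."""

    baseline: float
    dc_amplitude: float
    resonance_freq: float
    quality_factor: float
    fit_residual: float = math.nan
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.resonance_freq <= 0:
            raise ValueError("resonance_freq must be positive")
        if self.quality_factor <= 0:
            raise ValueError("quality_factor must be positive")
        if self.dc_amplitude < 0:
            raise ValueError("dc_amplitude must be non-negative")


@dataclass(frozen=True)
class CalibrationResult:
    """Spring constant (N/m) with the peak power P = <z^2> (nm^2) behind it."""

    spring_constant: float
    peak_power: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.peak_power <= 0:
            raise ValueError("peak_power must be positive")


@dataclass(frozen=True)
class AggregateCalibration:
    """Mean of repeated calibrations with their relative spread (sd/mean)."""

    spring_constant: float
    relative_spread: float
    n: int
    temperature: float = DEFAULT_TEMPERATURE


def sho_amplitude(frequency, baseline, dc_amplitude, resonance_freq, quality_factor):
    """Evaluate the damped-SHO thermal response at given frequencies."""
    nu = np.asarray(frequency, dtype=float)
    f0 = resonance_freq
    denom = (f0**2 - nu**2) ** 2 + (f0 * nu / quality_factor) ** 2
    out = baseline + dc_amplitude * f0**4 / denom
    return out if out.ndim else float(out)


def fit_resonance(spectrum: PowerSpectrum, init: SHOFit | None = None) -> SHOFit:
    """Least-squares SHO fit to a thermal-noise spectrum.

    Initialisation (unless ``init`` is given): resonance frequency from
    the spectrum argmax, baseline from the high-frequency median, Q = 2,
    peak amplitude from the argmax height.  A spectrum without a
    resolvable peak raises :class:`ResonanceFitError`; a resonance
    fitted at the edge of the frequency range is flagged.
    """
    f = spectrum.frequencies
    a = spectrum.amplitudes
    if init is not None:
        p0 = [init.baseline, init.dc_amplitude, init.resonance_freq, init.quality_factor]
    else:
        i_peak = int(np.argmax(a))
        a0 = float(np.median(a[int(0.9 * f.size):]))
        q0 = 2.0
        adc0 = max((a[i_peak] - a0) / q0**2, 1e-30)
        p0 = [a0, adc0, float(f[i_peak]), q0]
        if a[i_peak] <= 1.5 * max(np.median(a), 1e-300):
            raise ResonanceFitError(
                "no resonance peak above the baseline",
                best=SHOFit(p0[0], p0[1], p0[2], p0[3]),
            )
    bounds = ([0.0, 0.0, f[0] * 0.5, 0.05], [np.inf, np.inf, f[-1] * 2.0, 1e5])
    try:
        popt, _ = curve_fit(
            sho_amplitude, f, a, p0=p0, bounds=bounds, maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise ResonanceFitError(
            f"resonance fit did not converge: {exc}",
            best=SHOFit(p0[0], max(p0[1], 0.0), p0[2], p0[3]),
        ) from exc
    resid = float(np.sum((sho_amplitude(f, *popt) - a) ** 2))
    at_boundary = not (f[0] < popt[2] < f[-1])
    return SHOFit(
        baseline=float(popt[0]),
        dc_amplitude=float(popt[1]),
        resonance_freq=float(popt[2]),
        quality_factor=float(popt[3]),
        fit_residual=resid,
        at_boundary=at_boundary,
    )


def peak_power(fit: SHOFit) -> float:
    """Area under the fitted resonance term (baseline excluded), in nm^2.

    Analytic: integral over [0, inf) of the resonance Lorentzian-like
    term equals (pi/2) * A_DC * nu_0 * Q.
    """
    return 0.5 * math.pi * fit.dc_amplitude * fit.resonance_freq * fit.quality_factor


def spring_constant(peak_power_nm2: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Equipartition spring constant k = k_BT / P, returned in N/m."""
    if peak_power_nm2 <= 0:
        raise ValueError("peak power must be positive")
    k_pn_nm = thermal_energy(temperature) / peak_power_nm2
    return k_pn_nm / N_PER_M_TO_PN_PER_NM


def calibrate(
    spectrum: PowerSpectrum, temperature: float = DEFAULT_TEMPERATURE
) -> CalibrationResult:
    """Full thermal-tune pipeline: fit resonance, integrate, equipartition."""
    fit = fit_resonance(spectrum)
    P = peak_power(fit)
    return CalibrationResult(
        spring_constant=spring_constant(P, temperature),
        peak_power=P,
        temperature=temperature,
    )


def aggregate_calibrations(results: list[CalibrationResult]) -> AggregateCalibration:
    """Average repeated calibrations; spread is the sample sd over the mean.

    A single calibration has an undefined spread (reported as NaN).
    """
    if not results:
        raise ValueError("at least one calibration result is required")
    ks = np.array([r.spring_constant for r in results], dtype=float)
    mean = float(ks.mean())
    spread = float(ks.std(ddof=1) / mean) if ks.size > 1 else math.nan
    return AggregateCalibration(
        spring_constant=mean,
        relative_spread=spread,
        n=ks.size,
        temperature=results[0].temperature,
    )


def sho_for_spring_constant(
    k_n_per_m: float,
    resonance_freq: float = 3000.0,
    quality_factor: float = 2.0,
    baseline: float = 1e-7,
    temperature: float = DEFAULT_TEMPERATURE,
) -> SHOFit:
    """SHO parameters whose peak power corresponds to a target spring constant."""
    if k_n_per_m <= 0:
        raise ValueError("spring constant must be positive")
    P = thermal_energy(temperature) / (k_n_per_m * N_PER_M_TO_PN_PER_NM)
    adc = 2.0 * P / (math.pi * resonance_freq * quality_factor)
    return SHOFit(baseline, adc, resonance_freq, quality_factor)


def simulate_thermal_spectrum(
    fit: SHOFit,
    noise_level: float = 0.0,
    seed: int | np.random.Generator | None = None,
    frequencies: np.ndarray | None = None,
) -> PowerSpectrum:
    """Synthesise a thermal-noise spectrum from SHO parameters.

    ``noise_level`` is the relative sd of multiplicative Gaussian noise
    applied per frequency bin (0 reproduces the model exactly).
    Deterministic for a fixed seed.
    """
    if frequencies is None:
        f0 = fit.resonance_freq
        frequencies = np.linspace(0.02 * f0, 4.0 * f0, 600)
    f = np.asarray(frequencies, dtype=float)
    a = sho_amplitude(
        f, fit.baseline, fit.dc_amplitude, fit.resonance_freq, fit.quality_factor
    )
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        a = a * np.clip(1.0 + noise_level * rng.standard_normal(f.size), 0.0, None)
    return PowerSpectrum(frequencies=f, amplitudes=np.asarray(a))


def write_spectrum(spectrum: PowerSpectrum, path, metadata: dict | None = None) -> None:
    """Write a spectrum as 2-column delimited text with ``#key=value`` headers."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"#{key}={value}\n")
        fh.write("#columns=frequency_Hz\tamplitude_nm2_per_Hz\n")
        for f, a in zip(spectrum.frequencies, spectrum.amplitudes):
            fh.write(f"{f:.17g}\t{a:.17g}\n")


def read_spectrum(path) -> tuple[PowerSpectrum, dict]:
    """Read a spectrum file written by :func:`write_spectrum`."""
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, value = line[1:].split("=", 1)
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            rows.append((float(parts[0]), float(parts[1])))
    data = np.array(rows, dtype=float)
    return PowerSpectrum(frequencies=data[:, 0], amplitudes=data[:, 1]), meta
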