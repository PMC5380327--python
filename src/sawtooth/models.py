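"""Closed-form single-molecule mechanics models.

Worm-like-chain (WLC) entropic elasticity, Bell force-activated
unfolding kinetics, the Bell–Evans most-probable rupture force under a
constant loading rate, the analytic rupture-force distribution it
implies, contour-length accounting for unfolded protein domains, and
free-calcium bookkeeping for EDTA-buffered samples.

All functions use the package unit system (nm, pN, s, pN·nm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE, thermal_energy

__all__ = [
    "WLCParams",
    "BellParams",
    "ContourAccounting",
    "OutOfRegimeWarning",
    "wlc_force",
    "wlc_extension",
    "bell_rate",
    "evans_force",
    "RuptureForceDistribution",
    "rupture_force_distribution",
    "contour_per_aa",
    "free_calcium",
]


class OutOfRegimeWarning(UserWarning):
    """Loading rate too small for a positive most-probable rupture force."""


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters.

    Attributes
    ----------
    persistence_length : float
        Bending stiffness length scale L_p in nm.
    contour_length : float
        Fully stretched backbone length L_c in nm.
    temperature : float
        Bath temperature in K.
    """

    persistence_length: float
    contour_length: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.contour_length <= 0:
            raise ValueError("contour_length must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def thermal_energy(self) -> float:
        """k_B*T in pN·nm."""
        return thermal_energy(self.temperature)


@dataclass(frozen=True)
class BellParams:
    """Bell-model unfolding kinetics.

    Attributes
    ----------
    k_u0 : float
        Unfolding rate at zero force in 1/s.  Any attempt-frequency
        prefactor and activation energy are absorbed into this single
        rate constant.
    x_u : float
        Distance from the folded state to the transition state along
        the pulling coordinate, in nm.
    temperature : float
        Bath temperature in K.
    """

    k_u0: float
    x_u: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.k_u0 <= 0:
            raise ValueError("k_u0 must be positive")
        if self.x_u <= 0:
            raise ValueError("x_u must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def thermal_energy(self) -> float:
        """k_B*T in pN·nm."""
        return thermal_energy(self.temperature)


@dataclass(frozen=True)
class ContourAccounting:
    """Bookkeeping for the contour length released by one unfolding.

    The fully unfolded monomer length is ``delta_Lc + d_NC``: the
    measured contour-length increment plus the N-to-C distance the
    folded domain already contributed to the stretched chain.
    """

    delta_Lc: float
    d_NC: float
    n_aa: int

    def __post_init__(self) -> None:
        if self.delta_Lc < 0:
            raise ValueError("delta_Lc must be non-negative")
        if self.d_NC < 0:
            raise ValueError("d_NC must be non-negative")
        if self.n_aa < 1:
            raise ValueError("n_aa must be at least 1")

    @property
    def unfolded_length(self) -> float:
        """Total backbone length of the unfolded monomer in nm."""
        return self.delta_Lc + self.d_NC


def wlc_force(extension, params: WLCParams):
    """WLC interpolation-formula force at a given extension.

    F(x) = (k_BT/L_p) * [ 1/4 (1 - x/L_c)^-2 - 1/4 + x/L_c ]

    Strictly increasing on [0, L_c), zero at zero extension, divergent
    as x -> L_c.  Accepts scalars or arrays; extensions outside
    [0, L_c) raise ``ValueError``.
    """
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0) or np.any(x >= params.contour_length):
        raise ValueError(
            f"extension must lie in [0, contour_length={params.contour_length}), "
            f"got values in [{x.min() if x.size else 'nan'}, {x.max() if x.size else 'nan'}]"
        )
    t = x / params.contour_length
    f = (params.thermal_energy / params.persistence_length) * (
        0.25 / (1.0 - t) ** 2 - 0.25 + t
    )
    return f if f.ndim else float(f)


def wlc_extension(force: float, params: WLCParams) -> float:
    """Numerical inverse of :func:`wlc_force` (extension at a force).

    Bracketed root finding on [0, L_c); the round trip
    ``wlc_force(wlc_extension(F)) == F`` holds to well below 1e-6 pN.
    """
    F = float(force)
    if F < 0:
        raise ValueError("force must be non-negative")
    if F == 0.0:
        return 0.0
    Lc = params.contour_length
    hi = Lc * (1.0 - 1e-13)
    if wlc_force(hi, params) <= F:  # pragma: no cover - astronomically stiff
        return hi
    return brentq(
        lambda x: wlc_force(x, params) - F,
        0.0,
        hi,
        xtol=1e-13 * Lc,
        maxiter=200,
    )


def bell_rate(force, params: BellParams):
    """Force-dependent unfolding rate k_u(F) = k_u0 * exp(F x_u / k_BT)."""
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    with np.errstate(over="ignore"):
        rate = params.k_u0 * np.exp(F * params.x_u / params.thermal_energy)
    return rate if rate.ndim else float(rate)


def evans_force(loading_rate: float, params: BellParams) -> float:
    """Most-probable rupture force at a constant loading rate.

    F* = (k_BT/x_u) * ln( r x_u / (k_BT k_u0) )

    Linear in ln(r) with slope k_BT/x_u.  When the log argument is <= 1
    the model predicts no positive most-probable force; 0 is returned
    and an :class:`OutOfRegimeWarning` is issued.
    """
    r = float(loading_rate)
    if r <= 0:
        raise ValueError("loading_rate must be positive")
    kT = params.thermal_energy
    arg = r * params.x_u / (kT * params.k_u0)
    if arg <= 1.0:
        warnings.warn(
            "loading rate below the Bell–Evans regime; "
            "most-probable force clamped to 0",
            OutOfRegimeWarning,
            stacklevel=2,
        )
        return 0.0
    return (kT / params.x_u) * math.log(arg)


class RuptureForceDistribution:
    """Rupture-force distribution of a Bell process under constant loading.

    For loading rate r the survival probability is

        S(F) = exp[ -(k_u0 k_BT / (x_u r)) * (exp(F x_u / k_BT) - 1) ]

    whose density mode coincides with :func:`evans_force` whenever that
    force is in regime.  Sampling is by exact inverse-CDF transformation,
    which makes this object the independent oracle for the Monte Carlo
    pulling simulator.
    """

    def __init__(self, loading_rate: float, params: BellParams) -> None:
        if loading_rate <= 0:
            raise ValueError("loading_rate must be positive")
        self.loading_rate = float(loading_rate)
        self.params = params
        kT = params.thermal_energy
        self._beta = params.x_u / kT  # 1/pN
        self._a = params.k_u0 * kT / (params.x_u * self.loading_rate)

    def survival(self, force):
        F = np.asarray(force, dtype=float)
        with np.errstate(over="ignore"):
            s = np.exp(-self._a * np.expm1(self._beta * F))
        return s if s.ndim else float(s)

    def cdf(self, force):
        return 1.0 - self.survival(force)

    def pdf(self, force):
        F = np.asarray(force, dtype=float)
        rate = bell_rate(F, self.params)
        p = (rate / self.loading_rate) * self.survival(F)
        return p if np.ndim(p) else float(p)

    @property
    def mode(self) -> float:
        """Most-probable force; equals :func:`evans_force` in regime."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OutOfRegimeWarning)
            return evans_force(self.loading_rate, self.params)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. rupture forces by inverse-CDF sampling."""
        if n < 1:
            raise ValueError("n must be at least 1")
        u = rng.uniform(size=n)
        return np.log1p(-np.log(u) / self._a) / self._beta


def rupture_force_distribution(
    loading_rate: float, params: BellParams
) -> RuptureForceDistribution:
    """Construct the analytic rupture-force distribution at a loading rate."""
    return RuptureForceDistribution(loading_rate, params)


def contour_per_aa(acct: ContourAccounting, decimals: int | None = None) -> float:
    """Contour-length increase per amino acid, L_aa = (ΔL_c + d_N;C)/N_aa.

    Full precision by default; pass ``decimals=2`` for the conventional
    reporting precision.
    """
    value = acct.unfolded_length / acct.n_aa
    return round(value, decimals) if decimals is not None else value


def free_calcium(total_ca: float, edta: float) -> float:
    """Free Ca2+ after 1:1 chelation by EDTA, in the strong-binding limit.

    EDTA binds calcium essentially stoichiometrically at the working pH,
    so free calcium is max(total - EDTA, 0).  Units follow the inputs
    (conventionally mM).
    """
    if total_ca < 0:
        raise ValueError("total_ca must be non-negative")
    if edta < 0:
        raise ValueError("edta must be non-negative")
    return max(total_ca - edta, 0.0)
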