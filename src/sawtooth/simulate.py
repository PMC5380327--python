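"""Monte Carlo simulation of constant-speed AFM pulling on polyproteins.

The tethered construct is modelled as a worm-like chain in series with
a Hookean cantilever pulled quasi-statically: at piezo displacement
z = v*t the force follows from the series balance

    z = x_wlc(F; L_c) + F / k_c

solved by bracketed root finding, where the instantaneous contour
length L_c is the linker plus the folded N-to-C spacers of still-folded
domains plus the full unfolded contour of unfolded ones.  Each folded
domain unfolds stochastically with the Bell hazard at the current
force; unfolding adds its contour increment and the force relaxes at
fixed z.  The tip-protein tether ruptures by the same mechanism and
terminates the trace.  Gaussian force noise, baseline drift and a
nonspecific surface-adhesion artifact are added after the mechanics.

Time stepping is adaptive: sub-steps shrink so that no per-step hazard
exceeds 0.1, bounding discretisation bias near ruptures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE
from .curves import CurveMeta, ForceCurve
from .models import (
    BellParams,
    RuptureForceDistribution,
    WLCParams,
    bell_rate,
    wlc_force,
)

__all__ = [
    "DomainSpec",
    "ConstructSpec",
    "PullingProtocol",
    "NoiseModel",
    "Event",
    "EventLog",
    "simulate_pull",
    "simulate_experiment",
    "simulate_constant_loading",
]

#: Hazard cap per sub-step; steps subdivide until below this.
MAX_STEP_HAZARD = 0.1


@dataclass(frozen=True)
class DomainSpec:
    """One domain of a tandem construct.

    ``unfolded_contour`` is the full backbone contour of the unfolded
    monomer; while folded, the domain contributes only its N-to-C
    distance ``folded_NC`` to the stretched chain, so the contour
    increment on unfolding is ``unfolded_contour - folded_NC``.
    """

    name: str
    n_residues: int
    folded_NC: float
    unfolded_contour: float
    kinetics: BellParams

    def __post_init__(self) -> None:
        if self.folded_NC < 0:
            raise ValueError("folded_NC must be non-negative")
        if self.unfolded_contour <= self.folded_NC:
            raise ValueError("unfolded_contour must exceed folded_NC")
        if self.n_residues < 1:
            raise ValueError("n_residues must be at least 1")

    @property
    def delta_Lc(self) -> float:
        """Contour-length increment released by one unfolding, in nm."""
        return self.unfolded_contour - self.folded_NC


@dataclass(frozen=True)
class ConstructSpec:
    """Ordered tandem construct (N- to C-terminal) plus linker elasticity."""

    domains: tuple[DomainSpec, ...]
    linker_contour: float = 15.0
    persistence_length: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        if len(self.domains) < 1:
            raise ValueError("a construct needs at least one domain")
        if self.linker_contour < 0:
            raise ValueError("linker_contour must be non-negative")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")

    def c_terminal(self, n_domains: int) -> "ConstructSpec":
        """Contiguous C-terminal sub-construct of ``n_domains`` domains."""
        if not 1 <= n_domains <= len(self.domains):
            raise ValueError("n_domains out of range")
        return replace(self, domains=self.domains[-n_domains:])


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-speed ramp parameters.

    ``sample_interval`` of None resolves to ~3000 samples per ramp.
    ``cantilever_k`` is in pN/nm (0.15 N/m = 150 pN/nm).
    """

    speed: float = 1000.0
    ramp_length: float = 1000.0
    sample_interval: float | None = None
    cantilever_k: float = 150.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.ramp_length <= 0 or self.cantilever_k <= 0:
            raise ValueError("speed, ramp_length and cantilever_k must be positive")
        if self.sample_interval is not None and self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    @property
    def dt(self) -> float:
        if self.sample_interval is not None:
            return self.sample_interval
        return (self.ramp_length / self.speed) / 3000.0


#: Effectively unbreakable tip-protein attachment (for clean fixtures).
UNBREAKABLE_TETHER = BellParams(k_u0=1e-30, x_u=1e-6)

#: Default tip-protein attachment: holds to ~800 pN at 1 um/s loading.
DEFAULT_TETHER = BellParams(k_u0=1e-6, x_u=0.1)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument artifacts layered onto the clean mechanics.

    ``adhesion_amplitude``/``adhesion_range`` shape a nonspecific
    tip-surface adhesion bump at small extensions; ``pickup_probability``
    is the per-ramp chance of tethering a molecule (the small fraction
    of ramps showing sawtooth patterns); ``gfp_misfold_probability`` is
    the chance that an interior GFP domain never folded and therefore
    contributes unfolded contour from the start without any peak.
    """

    force_noise_sd: float = 8.0
    baseline_drift: float = 0.0
    adhesion_amplitude: float = 120.0
    adhesion_range: float = 20.0
    tether_kinetics: BellParams = DEFAULT_TETHER
    pickup_probability: float = 0.03
    gfp_misfold_probability: float = 0.5

    def __post_init__(self) -> None:
        for name in ("force_noise_sd", "baseline_drift", "adhesion_amplitude", "adhesion_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("pickup_probability", "gfp_misfold_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def quiet(cls) -> "NoiseModel":
        """No noise, no adhesion, unbreakable tether, deterministic GFP."""
        return cls(
            force_noise_sd=0.0,
            adhesion_amplitude=0.0,
            tether_kinetics=UNBREAKABLE_TETHER,
            gfp_misfold_probability=0.0,
        )


@dataclass(frozen=True)
class Event:
    """One ground-truth event: an unfolding or the final detachment."""

    time: float
    piezo: float
    force: float
    domain: str
    kind: str  # "unfold" | "detach"


@dataclass(frozen=True)
class EventLog:
    """Time-ordered ground-truth events of one simulated pull."""

    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be time-ordered")
        kinds = [e.kind for e in self.events]
        if kinds.count("detach") > 1:
            raise ValueError("at most one detach event")
        if "detach" in kinds and kinds[-1] != "detach":
            raise ValueError("detach must be the last event")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def unfold_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "unfold")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "time_s": e.time,
                    "piezo_nm": e.piezo,
                    "force_pN": e.force,
                    "domain": e.domain,
                    "type": e.kind,
                }
                for e in self.events
            ],
            columns=["time_s", "piezo_nm", "force_pN", "domain", "type"],
        )


def _solve_balance(
    z: float,
    chain: WLCParams,
    k_c: float,
    x_lo: float,
) -> tuple[float, float]:
    """Solve z = x + F(x)/k_c for the chain extension x and force F.

    ``x_lo`` is a known lower bound for the root (extension never
    decreases along a ramp at fixed or growing contour length).
    """
    if z <= 0:
        return 0.0, 0.0
    Lc = chain.contour_length
    hi = Lc * (1.0 - 1e-12)

    def h(x: float) -> float:
        return x + wlc_force(x, chain) / k_c - z

    if h(hi) <= 0.0:
        # force beyond the WLC divergence resolution; chain is at full stretch
        return hi, (z - hi) * k_c
    lo = min(max(x_lo, 0.0), hi * (1.0 - 1e-9))
    if h(lo) > 0.0:
        lo = 0.0
    try:
        x = brentq(h, lo, hi, xtol=1e-10 * max(Lc, 1.0), maxiter=200)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"force-balance bracket failure at z={z:.3f} nm") from exc
    return x, float(wlc_force(x, chain))


def simulate_pull(
    construct: ConstructSpec,
    protocol: PullingProtocol,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator | None = 0,
    curve_id: str = "sim",
) -> tuple[ForceCurve, EventLog]:
    """Simulate one constant-speed pull; returns the curve and ground truth.

    Deterministic for a fixed seed.  The recorded extension is the
    tip-sample separation computed from the noise-free force (z after
    detachment), so it is non-decreasing by construction; noise,
    drift and the adhesion artifact perturb only the force channel.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k_c = protocol.cantilever_k
    v = protocol.speed
    T = protocol.temperature

    folded = []
    for d in construct.domains:
        misfolded = (
            d.name.upper().startswith("GFP")
            and rng.uniform() < noise.gfp_misfold_probability
        )
        folded.append(not misfolded)
    folded = list(folded)

    def total_contour() -> float:
        return construct.linker_contour + sum(
            d.folded_NC if ok else d.unfolded_contour
            for d, ok in zip(construct.domains, folded)
        )

    Lc = total_contour()
    chain = WLCParams(construct.persistence_length, Lc, T)

    dt = protocol.dt
    n_steps = max(2, int(round(protocol.ramp_length / v / dt)))
    times = np.arange(n_steps + 1) * dt
    forces = np.zeros(n_steps + 1)
    ext = np.zeros(n_steps + 1)

    events: list[Event] = []
    detached = False
    t_now = 0.0
    x_now = 0.0
    F_now = 0.0

    for k in range(1, n_steps + 1):
        t_target = times[k]
        while not detached and t_now < t_target - 1e-15:
            rates = [
                bell_rate(F_now, d.kinetics) if ok else 0.0
                for d, ok in zip(construct.domains, folded)
            ]
            tether_rate = bell_rate(F_now, noise.tether_kinetics)
            total = sum(rates) + tether_rate
            dt_sub = t_target - t_now
            if not math.isfinite(total):
                total = 1e30
            if total > 0 and total * dt_sub > MAX_STEP_HAZARD:
                dt_sub = MAX_STEP_HAZARD / total
            t_now += dt_sub
            z = v * t_now
            x_now, F_now = _solve_balance(z, chain, k_c, x_now)
            if total > 0 and rng.uniform() < -math.expm1(-total * dt_sub):
                pick = rng.uniform() * total
                acc = tether_rate
                if pick < acc:
                    events.append(Event(t_now, z, F_now, "tether", "detach"))
                    detached = True
                    break
                chosen = None
                for i, r in enumerate(rates):
                    acc += r
                    if pick < acc:
                        chosen = i
                        break
                if chosen is None:  # numerical edge: attribute to last active
                    chosen = max(i for i, r in enumerate(rates) if r > 0)
                d = construct.domains[chosen]
                events.append(Event(t_now, z, F_now, d.name, "unfold"))
                folded[chosen] = False
                Lc = total_contour()
                chain = WLCParams(construct.persistence_length, Lc, T)
                x_now, F_now = _solve_balance(z, chain, k_c, x_now)
        z_k = v * times[k]
        if detached:
            forces[k] = 0.0
            ext[k] = z_k
        else:
            # t_now lands on the grid point exactly unless an event broke out
            if abs(t_now - times[k]) > 1e-12:
                x_now, F_now = _solve_balance(z_k, chain, k_c, x_now)
                t_now = times[k]
            forces[k] = F_now
            ext[k] = z_k - F_now / k_c

    noisy = forces.copy()
    if noise.force_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, noise.force_noise_sd, forces.size)
    if noise.baseline_drift != 0:
        noisy = noisy + noise.baseline_drift * ext
    if noise.adhesion_amplitude > 0:
        amp = noise.adhesion_amplitude * rng.uniform(0.3, 1.7)
        x0 = rng.uniform(0.0, noise.adhesion_range)
        width = max(noise.adhesion_range / 3.0, 1.0)
        noisy = noisy + amp * np.exp(-0.5 * ((ext - x0) / width) ** 2)

    meta = CurveMeta(
        speed_nm_s=v,
        k_N_m=k_c / 1000.0,
        temperature_K=T,
        curve_id=curve_id,
    )
    curve = ForceCurve(extension=ext, force=noisy, metadata=meta)
    return curve, EventLog(tuple(events))


def _noise_only_trace(
    protocol: PullingProtocol,
    noise: NoiseModel,
    rng: np.random.Generator,
    curve_id: str,
) -> tuple[ForceCurve, EventLog]:
    dt = protocol.dt
    n_steps = max(2, int(round(protocol.ramp_length / protocol.speed / dt)))
    z = np.arange(n_steps + 1) * dt * protocol.speed
    f = np.zeros(n_steps + 1)
    if noise.force_noise_sd > 0:
        f = f + rng.normal(0.0, noise.force_noise_sd, f.size)
    if noise.baseline_drift != 0:
        f = f + noise.baseline_drift * z
    if noise.adhesion_amplitude > 0:
        amp = noise.adhesion_amplitude * rng.uniform(0.3, 1.7)
        x0 = rng.uniform(0.0, noise.adhesion_range)
        width = max(noise.adhesion_range / 3.0, 1.0)
        f = f + amp * np.exp(-0.5 * ((z - x0) / width) ** 2)
    meta = CurveMeta(
        speed_nm_s=protocol.speed,
        k_N_m=protocol.cantilever_k / 1000.0,
        temperature_K=protocol.temperature,
        curve_id=curve_id,
    )
    return ForceCurve(extension=z, force=f, metadata=meta), EventLog(())


def simulate_experiment(
    construct: ConstructSpec,
    protocol: PullingProtocol,
    noise: NoiseModel = NoiseModel(),
    n_ramps: int = 2000,
    seed: int | None = 0,
) -> list[tuple[ForceCurve, EventLog]]:
    """Simulate a full approach-retract session of ``n_ramps`` ramps.

    Each ramp picks up a molecule with ``pickup_probability``; on
    pickup, a uniformly random contiguous C-terminal sub-construct is
    tethered (the tip grabs a random position along the chain, while
    the C-terminus is covalently attached to the surface).  Ramps
    without pickup yield noise-only traces.
    """
    if n_ramps < 1:
        raise ValueError("n_ramps must be at least 1")
    streams = np.random.SeedSequence(seed).spawn(n_ramps)
    out: list[tuple[ForceCurve, EventLog]] = []
    n_dom = len(construct.domains)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cid = f"ramp_{i:04d}"
        if rng.uniform() < noise.pickup_probability:
            n_teth = int(rng.integers(1, n_dom + 1))
            out.append(
                simulate_pull(construct.c_terminal(n_teth), protocol, noise, rng, cid)
            )
        else:
            out.append(_noise_only_trace(protocol, noise, rng, cid))
    return out


def simulate_constant_loading(
    params: BellParams,
    loading_rate: float,
    n: int,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Sample ``n`` i.i.d. rupture forces at a fixed loading rate.

    Idealised sampler (exact inverse-CDF draw from the analytic
    rupture-force distribution) matching the regime where the
    Bell–Evans relation is exact.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return RuptureForceDistribution(loading_rate, params).sample(n, rng)
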