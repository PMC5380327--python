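"""Construct presets for the adhesin pulling experiments.

Geometry (residue counts, folded N-to-C distances, unfolded contour
lengths) follows the published structural values for the MpAFP RII
repeat (104 aa, d_N;C = 4.8 nm, unfolded monomer length 38.0 nm), the
MhLap RII homology model (97 aa, 3.38 nm, 36.98 nm), GFP (239 aa) and
titin I27.  Bell kinetics for MpAFP RII are the experimentally
estimated x_u = 0.2 nm and k_u0 = 0.003 1/s; the remaining domains'
kinetics are presets calibrated so simulated mean rupture forces at
1 um/s approximate the reported unfolding forces (GFP ~88 pN,
MhLap ~306 pN, I27 ~218 pN) — they are this package's defaults, not
measured parameters.

MhLap repeats 2-5 and 21-24 are similar but not identical (~78%
sequence identity); the preset emulates that heterogeneity with a
fixed per-repeat spread of zero-force rates, which widens the
within-curve force spread (the cv statistic).  The low-calcium MpAFP
preset weakens the kinetics (~100 pN lower forces) and adds a larger
rate spread, emulating partially folded repeats with variable numbers
of bound calcium ions.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .models import BellParams
from .simulate import ConstructSpec, DomainSpec

__all__ = [
    "RII",
    "GFP",
    "I27",
    "rii8",
    "rii8_gfp",
    "rii8_low_calcium",
    "mhlap_rii8",
    "i27_8",
    "PRESETS",
]

#: MpAFP RII extender domain: measured Bell kinetics, crystal geometry.
RII = DomainSpec(
    name="MpAFP_RII",
    n_residues=104,
    folded_NC=4.8,
    unfolded_contour=38.0,
    kinetics=BellParams(k_u0=0.003, x_u=0.2),
)

#: GFP internal force standard; kinetics preset for ~88 pN at 1 um/s.
GFP = DomainSpec(
    name="GFP",
    n_residues=239,
    folded_NC=3.0,
    unfolded_contour=80.0,
    kinetics=BellParams(k_u0=0.021, x_u=0.5),
)

#: Titin I27 reference domain; kinetics preset for ~218 pN at 1 um/s.
I27 = DomainSpec(
    name="I27",
    n_residues=89,
    folded_NC=4.3,
    unfolded_contour=31.6,
    kinetics=BellParams(k_u0=3.8e-4, x_u=0.25),
)

# Fixed per-repeat rate multipliers: exp(sigma * z) on standardised
# offsets z, giving a reproducible lognormal-like spread of k_u0.
_Z8 = (-1.4, -1.0, -0.5, -0.1, 0.1, 0.5, 1.0, 1.4)


def _spread_repeats(base: DomainSpec, sigma: float) -> tuple[DomainSpec, ...]:
    out = []
    for i, z in enumerate(_Z8):
        kin = replace(base.kinetics, k_u0=base.kinetics.k_u0 * math.exp(sigma * z))
        out.append(replace(base, name=f"{base.name}_{i + 1}", kinetics=kin))
    return tuple(out)


def rii8() -> ConstructSpec:
    """Eight identical MpAFP RII repeats (high-calcium conditions)."""
    return ConstructSpec(domains=(RII,) * 8)


def rii8_gfp() -> ConstructSpec:
    """Two RII tetra-tandemers separated by an interior GFP domain."""
    return ConstructSpec(domains=(RII,) * 4 + (GFP,) + (RII,) * 4)


def rii8_low_calcium() -> ConstructSpec:
    """MpAFP RII octamer at 30 uM free calcium: weaker, heterogeneous.

    Zero-force rates are raised so mean forces drop by ~100 pN and
    spread per repeat (partially occupied calcium sites), which
    substantially increases the within-curve cv.
    """
    weak = replace(RII, kinetics=BellParams(k_u0=0.22, x_u=0.2))
    return ConstructSpec(domains=_spread_repeats(weak, sigma=0.8))


def mhlap_rii8() -> ConstructSpec:
    """MhLap RII octamer: homologous repeats with moderate heterogeneity."""
    base = DomainSpec(
        name="MhLap_RII",
        n_residues=97,
        folded_NC=3.38,
        unfolded_contour=36.98,
        kinetics=BellParams(k_u0=1.4e-4, x_u=0.2),
    )
    return ConstructSpec(domains=_spread_repeats(base, sigma=2.2))


def i27_8() -> ConstructSpec:
    """Octameric titin I27 reference construct."""
    return ConstructSpec(domains=(I27,) * 8)


PRESETS = {
    "rii8": rii8,
    "rii8_gfp": rii8_gfp,
    "rii8_low_calcium": rii8_low_calcium,
    "mhlap_rii8": mhlap_rii8,
    "i27_8": i27_8,
}
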