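# Methods

## Scope and units

The package implements the analysis chain of a constant-speed AFM
single-molecule force spectroscopy (SMFS) experiment on tandem
polyproteins, plus a Monte Carlo simulator that emulates the raw data such
experiments produce.  Units are fixed package-wide: nm, pN, s, pN·nm for
energy, and pN/nm for spring constants internally (file headers carry N/m;
1 N/m = 1000 pN/nm).  Temperature defaults to 298 K (room-temperature AFM),
giving k_BT = 4.114 pN·nm; it is overridable everywhere.

## Physical models

**WLC elasticity.**  The interpolation formula
F(x) = (k_BT/L_p)[¼(1−x/L_c)⁻² − ¼ + x/L_c] on 0 ≤ x < L_c.  Its numerical
inverse (bracketed Brent root finding) is used by the simulator's force
balance; the round trip is exact to below 1e−6 pN.

**Bell kinetics.**  k_u(F) = k_u⁰·exp(F·x_u/k_BT).  Any attempt-frequency
prefactor, transmission coefficient and activation energy are absorbed into
the single zero-force rate k_u⁰; they are never identifiable separately
from pulling data.

**Bell–Evans.**  Under constant loading rate r the most-probable rupture
force is F* = (k_BT/x_u)·ln(r·x_u/(k_BT·k_u⁰)), linear in ln r with slope
k_BT/x_u.  When the log argument is ≤ 1 the model admits no positive mode;
the function returns 0 with an `OutOfRegimeWarning` rather than a negative
force.  The analytic rupture-force distribution
S(F) = exp[−(k_u⁰k_BT/(x_u·r))(e^{F·x_u/k_BT} − 1)] serves as the
independent oracle for all Monte Carlo sampling; its density mode equals
F* whenever in regime.

**Contour accounting.**  L_aa = (ΔL_c + d_N;C)/N_aa: the unfolded monomer
length is the measured contour increment plus the N-to-C distance the
folded domain already spanned.  Full precision internally; the conventional
2-decimal rounding is applied only at reporting.

**Free calcium.**  EDTA is treated as an infinite-affinity 1:1 chelator:
free Ca²⁺ = max(total − EDTA, 0).  No dissociation constant enters; at the
working pH and millimolar scales the approximation is exact to the
reporting precision.

## Thermal-tune calibration

The cantilever thermal-noise spectrum is fitted with the damped-SHO
response A(ν) = A₀ + A_DC·ν₀⁴/((ν₀²−ν²)² + ν₀²ν²/Q²) (baseline, zero-
frequency amplitude, resonance frequency, quality factor).  Initialisation
is automatic: ν₀ from the spectrum argmax, A₀ from the high-frequency
median, Q = 2, A_DC from the peak height.  The power under the resonance
term has the closed form P = (π/2)·A_DC·ν₀·Q (verified against adaptive
quadrature in the tests), and equipartition gives k = k_BT/P.  The baseline
is excluded from P by construction.  A spectrum without a resolvable peak
raises rather than silently returning a fit; a resonance at the edge of the
frequency range is flagged.  No mode-shape or optical-lever corrections are
applied.  Repeated calibrations are combined by arithmetic mean with the
sample-sd/mean relative spread.

## The simulator and what it emulates

One ramp is quasi-static: at piezo position z = v·t the force solves
z = x_wlc(F; L_c) + F/k_c, with the chain contour L_c equal to the linker
plus folded N-to-C spacers plus the unfolded contours of already-unfolded
domains.  Per time step each folded domain unfolds with hazard
1 − exp(−k_u(F)Δt); steps subdivide automatically so no per-step hazard
exceeds 0.1.  Unfolding adds the domain's contour increment and the force
relaxes at fixed z; the tip–protein tether ruptures by the same mechanism
(default parameters hold to ~800 pN at 1 μm/s loading, well above repeat
unfolding forces) and terminates the trace.  Gaussian force noise (default
sd 8 pN), optional baseline drift, and a Gaussian-bump adhesion artifact at
small extensions (default amplitude 120 pN within ~20 nm of the surface)
are added to the force channel afterwards; the recorded extension is the
tip–sample separation computed from the noise-free mechanics, so it is
non-decreasing by construction.

A full session (`simulate_experiment`) draws, per ramp, a pickup with
probability 0.03 (the observed few-percent yield of sawtooth ramps); on
pickup a uniformly random contiguous C-terminal sub-construct is tethered,
emulating the covalent C-terminal gold attachment with a random tip grab
position.  Interior GFP domains misfold with probability 0.5 and then
contribute unfolded contour from the start without producing a peak.

Construct presets: MpAFP RII (104 aa, d_N;C 4.8 nm, unfolded length
38.0 nm) carries the experimentally estimated kinetics x_u = 0.2 nm,
k_u⁰ = 0.003 s⁻¹.  GFP (239 aa), I27 and MhLap RII have no published Bell
parameters; their preset rates were calibrated once, by short simulations,
so the simulated mean rupture forces at 1 μm/s match the reported values
(≈88, 218 and 306 pN respectively).  MhLap's eight repeats receive a fixed
lognormal-like spread of k_u⁰ (σ = 2.2 in log-rate) calibrated to the
reported within-curve cv̄ ≈ 14%; the low-calcium MpAFP preset weakens the
kinetics to sit ~100 pN below the high-calcium simulation and spreads rates
(σ = 0.8) to emulate variable calcium occupancy.

Two systematic effects make simulated mean forces sit below the idealized
Bell–Evans mode at the nominal loading rate k_c·v: hazard competition among
m identical folded domains shifts early ruptures down by up to
(k_BT/x_u)·ln m, and the series WLC compliance makes the true loading rate
smaller than k_c·v (most strongly at long contour).  For the MpAFP octamer
this places the simulated mean near 220 pN against the idealized mode of
302 pN.  The same gap exists in the source data: the published rounded Bell
parameters cannot reproduce the published mean force even in the idealized
limit.  Consequently the within-curve cv of the weakened low-calcium preset
(~33%) overshoots the reported 25.9%, since the absolute force spread is
roughly conserved while the mean drops — a known limitation of anchoring
that preset to the ~100 pN condition contrast rather than to the printed
mean.

## Curve analysis choices

*Baseline*: median force over the final 10% of the extension range when
that tail is flat (spread within 3× the point-to-point noise estimate);
otherwise the mode of a Freedman–Diaconis force histogram.  The unfolding
force F_u is the raw peak height minus this baseline, exactly.

*Peak detection*: local maxima exceeding baseline + 50 pN followed within
10 nm by a force drop of ≥ 50 pN; peaks closer than 10 nm keep the higher
one.  The thresholds leave the weakest expected domain (GFP, ~88 pN)
detectable above the default noise.

*WLC fits*: least squares over the rising edge from the force minimum after
the preceding peak to the current peak, both L_c and L_p free (the
experiment reports an L_p distribution, so L_p is not fixed globally);
windows of fewer than 8 points, non-convergent fits, and fits with
L_c ≤ peak extension are flagged and excluded, never imputed.

*Classification*: a peak is **GFP** when the gap to the next peak (in
extension or fitted contour) falls in 60–90 nm and its force is below
150 pN; **adhesion** when within 25 nm of the surface without a
WLC-consistent rising edge (valid fit, L_p in 0.05–5 nm, residual within
3× the noise floor); **detachment** when it is the last peak and the force
never returns above threshold afterwards; otherwise a repeat unfolding.
ΔL_c and ΔL are successive differences between consecutive non-adhesion
peaks — adhesion artifacts carry no contour information and would poison
the increments.

*Sawtooth filter*: curves qualify with ≥ 5 repeat-classified peaks,
matching the selection used for the per-curve cv statistic.

## Kinetics choices

The loading rate entering Bell–Evans fits is r = k_c·v — deliberately the
nominal estimator rather than the instantaneous WLC loading rate, for
fidelity to how such fits are performed on real data.  Because the
compliance reduction of the true rate is nearly uniform in ln r across the
speed range, the slope (hence x_u) survives this approximation while k_u⁰
absorbs the bias; the end-to-end test budgets 25% on x_u accordingly,
versus 15% for the idealized constant-loading sampler.  The representative
force per speed defaults to the histogram mode (the quantity the
Bell–Evans formula describes), fitted as a Gaussian to the upper half of a
Freedman–Diaconis histogram; means with sample (n−1) standard deviations
are used for condition comparisons.  Condition contrasts are descriptive
(difference of means with pooled standard error); no hypothesis-testing
machinery is attached.

## Problem sizes in the tests

The suites run simulated experiments at desk scale: 200 pulls for the
end-to-end recovery checks, 2000 rupture samples per speed for Bell–Evans
recovery, 50 seeds for the calibration round trip, 10⁴ draws for
distributional oracles, 25–40 pulls for behavioral properties.  These sizes
were chosen so every stochastic assertion holds with comfortable margin
across seeds while the whole suite completes in a couple of minutes.

## Known limitations

- Quasi-static mechanics: no cantilever/fluid dynamics, no refolding during
  the ramp, single tether only.
- The adhesion artifact is a smooth bump plus noise; real nonspecific
  adhesion can be far more structured.
- Gaussian force noise; real traces show 1/f drift components beyond the
  linear drift term provided.
- Preset kinetics for GFP/I27/MhLap are calibrated stand-ins, not measured
  parameters, and the low-calcium preset reproduces the force contrast but
  overshoots the reported cv (see above).
- The inconsistency between the published Bell parameters and the published
  mean force noted above means absolute simulated means for MpAFP sit ~35%
  below the reported 348 pN;
  analyses that depend only on contrasts, orderings, slopes and recovery of
  generative parameters are unaffected.
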