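# sawtooth

Simulation and analysis of AFM single-molecule force spectroscopy (SMFS)
experiments on tandem polyproteins — the kind of experiment used to measure
the mechanical stability of bacterial adhesin extender domains (MpAFP RII,
MhLap RII), titin I27 and GFP.

When an AFM tip picks up one polyprotein chain and retracts at constant
speed, each domain unfolding releases hidden backbone contour and the force
trace shows a characteristic sawtooth: a worm-like-chain (WLC) rise, a sharp
rupture, and the next rise.  This package provides

- **physical models** — WLC elasticity
  `F(x) = (k_BT/L_p)[¼(1−x/L_c)⁻² − ¼ + x/L_c]`,
  Bell unfolding kinetics `k_u(F) = k_u⁰ exp(F·x_u/k_BT)`, the Bell–Evans
  most-probable rupture force
  `F*(r) = (k_BT/x_u) ln(r·x_u / (k_BT·k_u⁰))` at loading rate `r = k_c·v`,
  the analytic rupture-force distribution under constant loading, the
  contour-length accounting `L_aa = (ΔL_c + d_N;C)/N_aa`, and free-calcium
  bookkeeping for EDTA-buffered samples;
- **thermal-tune calibration** — damped simple-harmonic-oscillator fit of the
  cantilever thermal-noise spectrum, analytic peak power, and the
  equipartition spring constant `k = k_BT/⟨z²⟩`;
- **a Monte Carlo simulator** of constant-speed pulling: WLC chain in series
  with a Hookean cantilever, stochastic Bell unfolding of each folded domain,
  tether detachment, force noise, baseline drift, nonspecific surface
  adhesion, variable pickup position and misfolded interior GFP — with
  ground-truth event logs for validating the analysis;
- **curve analysis** — baseline estimation, rupture-peak detection, per-peak
  WLC fits (`F_u`, `L_c`, `L_p`), contour increments `ΔL_c`, unfolding
  lengths `ΔL`, peak classification (repeat / GFP / adhesion / detachment)
  and the ≥5-peak sawtooth filter;
- **population kinetics** — force histograms (mean or histogram mode), the
  per-curve relative spread `cv = σ/μ`, Bell–Evans fits of force against
  log loading rate recovering `x_u` and `k_u⁰`, and condition contrasts
  (e.g. high vs low calcium).

## Worked example

Simulate one pull of the MpAFP RII octamer at 1 μm/s (cantilever
0.15 N/m) and run the analysis pipeline on it:

```python
from sawtooth import presets
from sawtooth.simulate import simulate_pull, PullingProtocol, NoiseModel
from sawtooth.curves import analyze_curve
from sawtooth.kinetics import cv_per_curve

curve, truth = simulate_pull(presets.rii8(), PullingProtocol(), NoiseModel(), seed=7)
table = analyze_curve(curve)
print(table[["peak_idx", "extension_nm", "Fu_pN", "Lc_nm", "Lp_nm", "dLc_nm", "label"]]
      .round(2).to_string(index=False))
```

```
 peak_idx  extension_nm  Fu_pN  Lc_nm  Lp_nm  dLc_nm    label
        0          3.32  72.59    NaN    NaN     NaN adhesion
        1         46.55 211.62  53.48   0.30     NaN      RII
        2         75.27 200.95  86.43   0.31   32.95      RII
        3        104.25 218.97 119.05   0.32   32.62      RII
        4        133.82 233.44 153.16   0.30   34.11      RII
        5        162.23 222.30 185.06   0.32   31.90      RII
        6        190.00 204.98 219.16   0.30   34.10      RII
        7        217.43 185.05 254.36   0.28   35.20      RII
        8        251.98 250.46 285.85   0.30   31.49      RII
```

The near-surface adhesion artifact is labelled and excluded; the eight
repeat unfoldings and the final tether detachment are recovered.  The mean
contour increment `dLc` is 33.2 nm — the generative value for this repeat —
the persistence length sits at the 0.3 nm it was generated with, and the
within-curve spread is `cv = 9.4%`:

```
mean F_u  = 216 pN   (ground truth events: 8)
mean dLc  = 33.2 nm
cv        = 9.4%
```

The same stages are scriptable from the shell:

```sh
sawtooth simulate --config run.json --out-dir out/
sawtooth analyze --in-dir out/curves --out events.csv --min-peaks 5
sawtooth kinetics events_*.csv --out bell.json
sawtooth calibrate spectra/*.tsv
sawtooth report events.csv
```

`run.json` is a strictly validated JSON configuration (seed, construct
preset or explicit domain list, pulling protocol, noise model, analysis
thresholds); identical config + seed reproduces byte-identical outputs.

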