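# optopore

Membrane resealing kinetics and diffusion-limited macromolecule loading
after gold-nanoparticle-mediated photoporation.

When a nanosecond laser pulse fires on membrane-bound gold nanoparticles,
transient pores open in the cell membrane. A voltage-sensitive dye reports
the event: the relative fluorescence ΔF/F dips at laser onset and recovers
as the membrane reseals. The **resealing time** — the time after the pulse
at which ΔF/F climbs back to 90% of the resting level — is the pore's
lifetime, and it controls how much extracellular cargo (e.g. FITC-dextran
of 5–100 kDa) enters the cell before the pore closes.

`optopore` implements the full measurement-and-model chain for this
experiment, for researchers analyzing photoporation delivery data or
exploring its design space in silico:

- **`optopore.traces`** — per-cell trace processing: linear photobleaching
  correction fitted on the pre-laser background frames (100 frames at
  1 frame/s, then 380 post-laser frames), perforation calls against a
  noise-adaptive threshold, and the 90%-recovery resealing time with
  sub-frame interpolation.
- **`optopore.mc`** — a Brownian-motion Monte Carlo model of loading: the
  cell is a sphere with absorbing spherical-cap pores inside a reflecting
  outer boundary; point tracers random-walk with a per-step scale
  s(M) = s_ref·(M_ref/M)^(1/3), following the Stokes–Einstein chain
  D = k_BT/(6πηR), R ∝ M^(1/3). The fraction of walkers absorbed while the
  pores are open is the loading efficiency.
- **`optopore.fitting`** — the exponential calibration forms
  y = a·e^(x/b) + c (growth) and y = a·e^(−x/b) + c (decay) fitted by
  deterministic profiled nonlinear least squares, plus R² and
  simulated-vs-measured concordance (OLS).
- **`optopore.synthetic`** — synthetic traces, image stacks and whole
  experiments with exact ground truth, for testing every stage without
  real data.
- **`optopore.pipeline`** — the seeded end-to-end run:
  generate → extract → calibrate → simulate → fit → compare, with every
  intermediate written to CSV/JSON and a checksum manifest.

## Worked example

From `examples/01_resealing_from_trace.py` — one synthetic dye trace with
a known 75 s resealing time, analyzed end to end:

```text
perforated call:        True
dip depth (1 - min dF/F): 0.451
estimated resealing time: 75.46 s
true resealing time:      75.00 s
fitted bleach slope:      -0.0289 AU/frame
```

The trace dips to ~55% of resting at laser onset and recovers
exponentially; the analysis divides out the fitted bleaching line,
detects the dip against the background noise band, and interpolates the
first confirmed crossing of 0.90 — landing within half a frame of the
ground truth.

From `examples/03_loading_simulation.py` — the Monte Carlo dose
responses (1,000 particles, 5 replicates):

```text
loading vs pore-open time (10 kDa):
  t =   20.0 s   loading =  6.20 +- 0.24 %
  t =   40.0 s   loading = 11.86 +- 0.32 %
  t =   80.0 s   loading = 20.94 +- 0.20 %
  t =  160.0 s   loading = 36.28 +- 0.88 %
loading vs molecular weight (open 60 s):
  M =     5 kDa  loading = 24.46 +- 0.47 %
  M =    10 kDa  loading = 16.04 +- 0.42 %
  M =    40 kDa  loading =  7.54 +- 0.21 %
  M =   100 kDa  loading =  4.36 +- 0.23 %
```

Loading grows with pore-open time and falls with molecular weight — the
two dose responses the exponential calibrations summarize. The other
examples cover stack→trace extraction, the calibration fits, and the
full pipeline; each prints what its numbers mean.

## Command line

The same stages are available as a thin CLI:

```sh
optopore simulate-data --seed 2 --outdir data/
optopore extract --traces data/traces.csv -o results.csv
optopore fit results.csv --form growth --x-col fluence --y-col t -o fit.json
optopore mc --config sim.yaml -o loading.csv
optopore run --seed 0 --outdir run/
```

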