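# Methods

This note documents the models, estimators and numerical choices behind
`optopore`, and what the synthetic-data tests do and do not establish
about real data.

## Trace model and resealing-time estimator

A per-cell fluorescence recording is 100 background frames followed by
380 post-laser frames at 1 frame/s. The synthetic generator constructs
the noiseless trace multiplicatively,

    F(frame) = (F0 + s·frame) · g(t),

where `F0 + s·frame` is a linear photobleaching baseline and `g` is the
membrane gate: `g = 1` before laser onset and, for a perforated cell,

    g(t) = 1 − (1 − d)·exp(−(t − t_laser)/τ),    τ = T90 / ln((1 − d)/0.1),

so the relative intensity dips instantaneously to the dip fraction `d`
at laser onset (the 6 ns pulse is sub-frame) and recovers exponentially,
crossing 90% of resting exactly `T90` seconds after the pulse. The
single-exponential return is the simplest monotone recovery consistent
with observed post-poration ΔF/F traces; only the 90% crossing time
matters downstream, so the precise shape is not load-bearing. A dip
fraction ≥ 0.9 is rejected: such a trace never falls below the 90%
threshold and has no defined crossing. Noise is additive, independent,
stationary Gaussian per frame (EMCCD read/shot noise at fixed exposure
over a ~480 s recording).

Processing mirrors the construction without assuming it:

1. **Bleach correction** fits an OLS line to the background frames only
   (the post-laser frames contain the signal of interest) and divides the
   whole trace by its extrapolation. Division, not subtraction, because
   photobleaching scales the fluorescence yield. The correction is
   idempotent, and fails loudly if the extrapolated baseline is
   nonpositive anywhere. If the recording carries an additive camera
   offset (image stacks), that offset must be subtracted before
   correction — an uncorrected offset dilutes the relative dip and biases
   the crossing early (see `examples/02_stack_to_traces.py`).
2. **Perforation call**: noise σ is the sample SD of the corrected
   background. Because the baseline is extrapolated ~380 frames beyond
   the fit window, its prediction error grows with distance; the null SD
   of a corrected post-laser sample is σ·√(1+h(f)) with h(f) the OLS
   leverage of frame f. A cell is perforated iff some post-laser sample
   falls strictly below 1 − k·σ·√(1+h(f)), k = 5 by default. Without the
   leverage term the false-positive rate on unperforated noisy traces is
   several percent at any noise level (the flat threshold ignores the
   correlated extrapolation drift); with it, the rate is ≪ 1%. A value
   exactly at the threshold is unperforated (strict inequality), and a
   floor of 1e−9 on the margin keeps machine-epsilon dips in noiseless
   renders from triggering calls. Only decreases count: perforation
   depolarizes the membrane and the dye reports it as a dip.
3. **Resealing time**: scanning forward from the post-laser minimum, the
   first frame at or above the threshold (0.90) that stays there for 3
   consecutive frames marks recovery; the crossing is linearly
   interpolated between the bracketing frames and reported relative to
   laser onset. The confirmation window resists single-frame noise
   upticks; a trace that ends below threshold is "unresealed within the
   observation window" (no time reported). On noiseless traces the
   interpolation error is < 0.01 s; under noise the dominant error is
   σ_rel divided by the recovery slope at the crossing (0.1/τ), i.e.
   roughly σ_rel·10·τ seconds per cell — an intrinsic property of timing
   a slow threshold crossing, not of the estimator.

## Loading model

The cell is a sphere (radius 1, all lengths in cell radii) whose surface
carries spherical-cap pores; a reflecting outer sphere bounds the medium
and fixes a finite reservoir. Tracer molecules are independent points —
no excluded volume, hydrodynamics, crowding or efflux — initially uniform
in the shell between membrane and boundary. Each step displaces a walker
by an isotropic Gaussian with per-axis SD s(M)·√dt; fixed-length isotropic
steps of matched mean-square displacement are available as an alternative
(`step_model="fixed"`). The molecular-weight dependence is

    s(M) = s_ref · (M_ref/M)^(1/3),

from the Stokes–Einstein chain: D ∝ 1/R and R ∝ M^(1/3), so the
simulated mean-squared displacement per unit time scales as M^(−2/3).
The physical-unit helpers (`molecule_radius`, `diffusion_coefficient`)
evaluate the dimensional formulas for reporting; the simulation itself
uses only the proportionality.

Membrane interaction is resolved by segment–sphere intersection on every
step — endpoint-only testing would let fast walkers tunnel through the
membrane — with the intersection point's angular distance to each pore
center deciding absorb versus specular reflection. Absorbed walkers are
removed (influx only). Pores stay at constant size while open and close
instantaneously at the resealing time; a linearly shrinking cap is a
config option (`shrinking_pores`), since whether the experimental pore
size shrinks during resealing or varies with fluence is not observable
in the data this model is built from. The outer boundary reflects
radially. Walker conservation (delivered + surviving = total) is
asserted after every step.

### Time step

`dt` is chosen automatically so the per-axis step SD does not exceed
0.1× the smallest pore-cap chord (then rounded so an integer number of
steps spans the open time exactly). This resolves the absorbing geometry:
a coarser step under-detects cap hits. The dense-dt oracle test (5× finer
steps, 100 particles) confirms the default step reproduces the
fully-absorbing limit.

### Geometry defaults and calibration

The library-level `CellModel` default is a single cap of half-angle
0.2 rad with the boundary at 5× the cell radius. The pipeline default
(`GeometryConfig`) uses 10 randomly placed disjoint caps of half-angle
0.4 rad with the boundary at 2.5×: pores form at multiple nanoparticle
sites across the membrane, a single small cap cannot reach the measured
~23% loading in ~90 s at any step scale (the capture rate of a partially
absorbing sphere saturates at the Berg–Purcell limit), and the smaller
reservoir (still ~15 cell volumes) keeps default runs at desk scale. The
simulation's absolute scale is set by one anchor measurement: bisection
on s_ref (geometric midpoints, monotone loading) until the simulated
loading for the anchor molecule and open time matches the anchor value
within ±0.01 — by default 22.9% for 10 kDa at 88.7 s, the measured
optimum of the experiment this package models. All other conditions reuse
the calibrated s_ref; with the default geometry it lands near
0.14 cell radii/√s.

Defaults: 5,000 particles, 10 independent replicates (replicate r reuses
the same sub-seed across grid points — common random numbers — so curves
are smooth in their abscissa). Every run is a pure function of its seed;
sub-seeds spawn via `numpy.random.SeedSequence`.

## Calibration fits

Both exponential forms are linear in (a, c) once b is fixed, so the
fitter profiles the linear parameters over a deterministic grid of 20
log-spaced rate constants spanning 0.1–10× the x-range — both signs for
the growth form, so saturating (a, b < 0) as well as diverging shapes
are reachable — and polishes the best candidates with damped least
squares. No random multi-start; identical inputs give identical fits.
Least squares is unweighted. R² is the coefficient of determination
1 − SS_res/SS_tot about the mean of y; constant-y input yields the
degenerate family a = 0, c = mean(y), flagged `rank_deficient` with R²
undefined (NaN). Concordance between simulated and measured loadings is
OLS of measured on simulated with its R².

A caution on interpreting fitted parameters: on the experimental fluence
design (0.064–1.6 J/cm² with b ≈ 2.7), e^(x/b) spans only 1.02–1.81 and
is nearly collinear with the constant term, so (a, c) are sloppy —
per-point errors of ~0.1 s in the mean resealing times already move the
fitted parameters by several percent. The fitted *curve* is far better
determined than the individual parameters.

## Pipeline and reproducibility

Stages run in order (generate → extract → fluence fit → step calibration
→ Monte Carlo curves → curve fits → concordance → report), each consuming
and producing only files, so any stage can be rerun standalone from the
manifest. A master seed derives per-stage sub-seeds via a stable SHA-256
hash of "seed:stage" (structure is portable across implementations;
bit-identical streams are not promised across languages, determinism is
promised within this one). The manifest records a SHA-256 checksum per
file; a fixed config + seed reproduces every byte. The concordance stage
compares simulated loadings against the design's reference dose–response
relations (percent loading vs. resealing time, and vs. molecular
weight) evaluated at the simulated conditions — in a synthetic run these
play the role of the flow-cytometry measurements.

## Synthetic-data defaults and what tests show

The default `ExperimentDesign` (6 fluences × 10 cells) draws true
resealing times from t = 106.3·e^(f/2.7) − 80.6 (seconds vs. J/cm²), the
reference calibration of the modeled experiment, spanning ~28–112 s over
0.064–1.6 J/cm². Its defaults form a validation configuration: noiseless
analytic traces (noise is opt-in on `TraceSpec`) and cell-to-cell jitter
of 0.1 s, below the 1 s frame interval. This is the regime in which
recovering the generating parameters through the full pipeline is
well-posed; given the (a, c) sloppiness above, demanding few-percent
parameter recovery under realistic per-cell timing noise (~0.5–4 s)
would test the conditioning of the design, not the correctness of the
code. Noisy regimes are exercised where they test the right thing: the
false-positive-rate test runs 1,000 unperforated traces at 1% noise, the
classification and round-trip tests use explicit nonzero noise, and the
noise-convergence test verifies fitted parameters converge as noise → 0.

Passing on synthetic data shows the estimators invert the generator's
assumptions (linear multiplicative bleaching, instantaneous dip,
exponential recovery, stationary additive noise). Real recordings can
violate those assumptions — nonlinear bleaching, focus drift, cell
movement, correlated noise, partial resealing — and nothing here
measures robustness to them. Masks are inputs; there is no segmentation
or motion correction, and no conversion of ΔF/F to millivolts.

## Known limitations

- The loading model has no pore-formation physics, no intracellular
  dynamics after entry, and treats death/viability as out of scope; at
  long resealing times (> ~110 s) measured loading in the modeled
  experiment falls below diffusion predictions because cell death
  intervenes, and this model does not capture that.
- The decay-form fit of loading vs. molecular weight is structurally
  limited: any capture curve whose rate scales as M^(−2/3) deviates from
  a single exponential in M by a small but systematic amount on the
  5–100 kDa grid (best attainable R² ≈ 0.989–0.991).
- The reservoir is finite; loading efficiencies depend on the chosen
  boundary radius (a dilution choice), which the anchor calibration
  absorbs into s_ref.
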