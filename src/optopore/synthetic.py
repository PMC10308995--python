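"""Synthetic voltage-sensitive-dye data with known ground truth.

Generates per-cell fluorescence traces, rendered image stacks and whole
experiment designs that emulate membrane-potential imaging around a
photoporation event: a resting baseline with linear photobleaching drift,
an instantaneous dip at laser onset for perforated cells followed by an
exponential return toward baseline, and flat traces for unperforated
cells.  Every generator is a pure function of its spec (including the
seed), so downstream stages can be tested against exact ground truth.

The noiseless perforated trace is constructed as::

    F(frame) = (resting + bleach_slope * frame) * g(t)
    g(t) = 1                                          before laser onset
    g(t) = 1 - (1 - dip) * exp(-(t - t_laser) / tau)  after laser onset

with ``tau = true_resealing_time / log((1 - dip) / 0.1)`` so that the
relative intensity crosses 90% of resting exactly ``true_resealing_time``
seconds after the laser pulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .traces import FluorescenceTrace

__all__ = [
    "TraceSpec",
    "StackSpec",
    "ExperimentDesign",
    "TraceTruth",
    "make_trace",
    "make_stack",
    "make_experiment",
    "save_stack",
]

#: Default calibration of resealing time (s) against fluence (J/cm^2),
#: the growth-form parameters (a, b, c) of t = a*exp(f/b) + c.
DEFAULT_TRUTH_CURVE = (106.3, 2.7, -80.6)

#: Default calibration of loading efficiency (%) against resealing time (s).
DEFAULT_LOADING_VS_TIME = (46.89, 251.87, -48.68)

#: Default calibration of loading efficiency (%) against tracer MW (kDa).
DEFAULT_LOADING_VS_MW = (23.5, 20.3, 4.5)

DEFAULT_FLUENCES = (0.064, 0.32, 0.64, 0.96, 1.28, 1.6)
DEFAULT_MOL_WEIGHTS = (5.0, 10.0, 40.0, 70.0, 100.0)


@dataclass(frozen=True)
class TraceSpec:
    """Recipe for one synthetic per-cell fluorescence trace.

    Intensities are in arbitrary fluorescence units (AU); the frame grid is
    ``n_background_frames`` resting frames followed by ``n_post_frames``
    frames after the laser pulse, sampled every ``frame_interval`` seconds.
    """

    resting_intensity: float = 100.0
    bleach_slope: float = -0.02
    n_background_frames: int = 100
    n_post_frames: int = 380
    frame_interval: float = 1.0
    perforated: bool = False
    dip_fraction: Optional[float] = None
    true_resealing_time: Optional[float] = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_frames < 2:
            raise ValueError("need at least 2 background frames")
        if self.n_post_frames < 1:
            raise ValueError("need at least 1 post-laser frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.perforated:
            if self.dip_fraction is None or self.true_resealing_time is None:
                raise ValueError(
                    "perforated traces need dip_fraction and true_resealing_time")
            if not 0.0 < self.dip_fraction < 1.0:
                raise ValueError("dip_fraction must lie in (0, 1)")
            if self.dip_fraction >= 0.9:
                raise ValueError(
                    "dip_fraction >= 0.9 never falls below the 90% threshold; "
                    "the resealing crossing is undefined")
            if self.true_resealing_time <= 0:
                raise ValueError("true_resealing_time must be positive")
        else:
            if self.true_resealing_time is not None:
                raise ValueError(
                    "unperforated traces must not set true_resealing_time")

    @property
    def n_frames(self) -> int:
        return self.n_background_frames + self.n_post_frames

    @property
    def recovery_tau(self) -> Optional[float]:
        """Time constant of the exponential return toward baseline."""
        if not self.perforated:
            return None
        return self.true_resealing_time / math.log(
            (1.0 - self.dip_fraction) / 0.1)


@dataclass(frozen=True)
class TraceTruth:
    """Ground-truth record emitted alongside each generated trace."""

    cell_id: str
    perforated: bool
    true_resealing_time: Optional[float]
    dip_fraction: Optional[float]
    seed: int


def _noiseless_trace(spec: TraceSpec) -> np.ndarray:
    frames = np.arange(spec.n_frames, dtype=float)
    baseline = spec.resting_intensity + spec.bleach_slope * frames
    gate = np.ones(spec.n_frames)
    if spec.perforated:
        t_post = (frames[spec.n_background_frames:]
                  - spec.n_background_frames) * spec.frame_interval
        gate[spec.n_background_frames:] = 1.0 - (
            1.0 - spec.dip_fraction) * np.exp(-t_post / spec.recovery_tau)
    return baseline * gate


def make_trace(spec: TraceSpec,
               cell_id: str = "cell_0") -> Tuple[FluorescenceTrace, TraceTruth]:
    """Generate one fluorescence trace plus its ground-truth record."""
    values = _noiseless_trace(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.size)
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_interval
    trace = FluorescenceTrace(times=times, intensities=values,
                              laser_index=spec.n_background_frames,
                              cell_id=cell_id)
    truth = TraceTruth(cell_id=cell_id, perforated=spec.perforated,
                       true_resealing_time=spec.true_resealing_time,
                       dip_fraction=spec.dip_fraction, seed=spec.seed)
    return trace, truth


@dataclass(frozen=True)
class StackSpec:
    """Recipe for a rendered multi-frame image stack.

    ``cells`` is a sequence of ``(center, radius, TraceSpec)`` with centers
    in (row, col) pixel coordinates.  Each cell is drawn as a disk whose
    pixel value follows its trace; ``psf_sigma`` applies a Gaussian optical
    blur per frame.
    """

    frame_shape: Tuple[int, int] = (64, 64)
    cells: Sequence[Tuple[Tuple[float, float], float, TraceSpec]] = ()
    psf_sigma: float = 0.0
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_shape
        for (cy, cx), r, _spec in self.cells:
            if r <= 0:
                raise ValueError("cell radii must be positive")
            if not (r <= cy <= h - 1 - r and r <= cx <= w - 1 - r):
                raise ValueError("cell disks must lie within frame bounds")
        for i in range(len(self.cells)):
            for j in range(i + 1, len(self.cells)):
                (ci, ri), (cj, rj) = self.cells[i][:2], self.cells[j][:2]
                d = math.hypot(ci[0] - cj[0], ci[1] - cj[1])
                if d <= ri + rj:
                    raise ValueError(
                        f"cell disks {i} and {j} overlap; ROI truth would be "
                        "ambiguous")


def make_stack(spec: StackSpec
               ) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a (frames, h, w) float stack, a label mask and a truth table.

    The mean intensity inside each label, minus the background level,
    reproduces that cell's trace (exactly when ``psf_sigma`` is 0).
    """
    h, w = spec.frame_shape
    rows, cols = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int32)
    traces, truths = [], []
    for idx, ((cy, cx), r, tspec) in enumerate(spec.cells, start=1):
        disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= r ** 2
        mask[disk] = idx
        # Distinct per-cell seed derived from the stack seed unless the
        # trace spec carries its own nonzero seed.
        sub = tspec if tspec.seed != 0 else replace(
            tspec, seed=spec.seed * 100003 + idx)
        trace, truth = make_trace(sub, cell_id=f"cell_{idx}")
        traces.append((disk, trace))
        truths.append(truth)

    n_frames = traces[0][1].intensities.size if traces else 0
    stack = np.full((n_frames, h, w), spec.background_level, dtype=float)
    for disk, trace in traces:
        stack[:, disk] = spec.background_level + trace.intensities[:, None]
    if spec.psf_sigma > 0:
        for k in range(n_frames):
            stack[k] = gaussian_filter(stack[k], spec.psf_sigma)

    table = pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in truths],
            "label": np.arange(1, len(truths) + 1),
            "perforated": [t.perforated for t in truths],
            "true_resealing_time_s": [t.true_resealing_time for t in truths],
            "dip_fraction": [t.dip_fraction for t in truths],
            "seed": [t.seed for t in truths],
        }
    )
    return stack, mask, table


def save_stack(path, stack: np.ndarray) -> None:
    """Write a float stack to a 16-bit unsigned multi-frame grayscale TIFF."""
    import tifffile

    arr = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, arr)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a full synthetic photoporation experiment.

    For each laser fluence, ``cells_per_condition`` perforated cells are
    generated whose true resealing times follow
    ``truth_curve = (a, b, c)`` of ``t = a*exp(fluence/b) + c`` plus
    Gaussian jitter of ``jitter_sd`` seconds (cell-to-cell variability).
    ``mol_weights`` lists the tracer sizes used downstream by the diffusion
    model; ``tracer_mw`` is the MW recorded for the fluence series.
    """

    fluences: Tuple[float, ...] = DEFAULT_FLUENCES
    mol_weights: Tuple[float, ...] = DEFAULT_MOL_WEIGHTS
    cells_per_condition: int = 10
    truth_curve: Tuple[float, float, float] = DEFAULT_TRUTH_CURVE
    jitter_sd: float = 0.1
    tracer_mw: float = 10.0
    trace_template: TraceSpec = field(default_factory=TraceSpec)
    dip_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fluences, dtype=float)
        if f.size == 0 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("fluences must be strictly positive and "
                             "strictly increasing")
        if self.cells_per_condition < 1:
            raise ValueError("cells_per_condition must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")

    def truth_resealing_time(self, fluence: float) -> float:
        a, b, c = self.truth_curve
        t = a * math.exp(fluence / b) + c
        if t <= 0:
            raise ValueError(
                f"truth curve gives nonpositive resealing time ({t:.3g} s) "
                f"at fluence {fluence} J/cm^2; adjust the design")
        return t


def make_experiment(design: ExperimentDesign
                    ) -> Tuple[list, pd.DataFrame]:
    """Generate all traces of an experiment plus the per-cell truth table.

    Returns ``(traces, truth_table)`` where ``traces`` is a list of
    :class:`~optopore.traces.FluorescenceTrace` and the table carries
    columns ``cell_id, fluence_J_cm2, mw_kDa, perforated,
    true_resealing_time_s, seed``.
    """
    # Validate every fluence up front so a bad design fails atomically.
    nominal = {f: design.truth_resealing_time(f) for f in design.fluences}

    rng = np.random.default_rng(design.seed)
    traces, records = [], []
    cell_no = 0
    for fluence in design.fluences:
        for _ in range(design.cells_per_condition):
            t_true = nominal[fluence]
            if design.jitter_sd > 0:
                # Redraw rather than clip so jitter stays Gaussian.
                for _attempt in range(1000):
                    cand = t_true + rng.normal(0.0, design.jitter_sd)
                    if cand > 0:
                        break
                else:  # pragma: no cover - jitter_sd << t_true in practice
                    raise ValueError("could not draw a positive resealing time")
                t_cell = cand
            else:
                t_cell = t_true
            cell_no += 1
            cell_id = f"cell_{cell_no:04d}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(design.trace_template, perforated=True,
                           dip_fraction=design.dip_fraction,
                           true_resealing_time=t_cell, seed=sub_seed)
            trace, _truth = make_trace(spec, cell_id=cell_id)
            traces.append(trace)
            records.append({"cell_id": cell_id, "fluence_J_cm2": fluence,
                            "mw_kDa": design.tracer_mw, "perforated": True,
                            "true_resealing_time_s": t_cell,
                            "seed": sub_seed})
    return traces, pd.DataFrame.from_records(records)
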