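"""Per-cell trace processing: photobleaching correction, perforation
calls and membrane resealing times.

A voltage-sensitive dye reports transmembrane potential: photoporation
transiently depolarizes the membrane, producing a dip in relative
fluorescence (dF/F) that recovers as the pore reseals.  The resealing time
is defined as the time after laser onset at which the relative intensity
first climbs back to 90% of the resting level and stays there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "CorrectedTrace",
    "ResealingResult",
    "extract_traces",
    "bleach_correct",
    "classification_threshold",
    "classify_perforated",
    "resealing_time",
    "analyze_trace",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw per-cell intensity vs. time on a uniform frame grid.

    ``laser_index`` is the index of the first post-laser frame (default
    protocol: 100 background frames at 1 s, so laser onset is index 100).
    """

    times: np.ndarray
    intensities: np.ndarray
    laser_index: int = 100
    cell_id: str = "cell_0"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        vals = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", vals)
        if times.ndim != 1 or times.size != vals.size:
            raise ValueError("times and intensities must be 1-D, same length")
        if times.size < 3:
            raise ValueError("trace too short")
        dt = np.diff(times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be strictly increasing and uniform")
        if not 0 <= self.laser_index < times.size:
            raise ValueError("laser_index out of range")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class CorrectedTrace:
    """Bleach-corrected dF/F-normalized trace; resting level is 1."""

    times: np.ndarray
    rel_intensity: np.ndarray
    resting_intensity: float
    bleach_slope: float
    laser_index: int
    cell_id: str = "cell_0"

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class ResealingResult:
    """Perforation call and resealing time for one cell."""

    cell_id: str
    perforated: bool
    dip_depth: float
    resealing_time: Optional[float]
    threshold: float = 0.90
    resting_intensity: float = float("nan")
    bleach_slope: float = float("nan")
    unresealed: bool = False


def extract_traces(stack: np.ndarray, label_mask: np.ndarray,
                   laser_index: int = 100, frame_interval: float = 1.0,
                   labels: Optional[Sequence[int]] = None
                   ) -> List[FluorescenceTrace]:
    """Per-cell ROI mean traces from an image stack and a label mask.

    One trace per label (ascending label id): the mean pixel intensity
    inside that label at each frame.  ``labels`` defaults to every nonzero
    label present in the mask; requesting a label with no pixels is an
    error.
    """
    stack = np.asarray(stack, dtype=float)
    label_mask = np.asarray(label_mask)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, height, width)")
    if label_mask.shape != stack.shape[1:]:
        raise ValueError("mask shape must match frame shape")
    if labels is None:
        labels = np.unique(label_mask)
        labels = labels[labels > 0]
    else:
        labels = np.sort(np.asarray(labels, dtype=label_mask.dtype))
    if len(labels) == 0:
        raise ValueError("label mask contains no labeled region")

    flat = stack.reshape(stack.shape[0], -1)
    mflat = label_mask.ravel()
    times = np.arange(stack.shape[0], dtype=float) * frame_interval
    traces = []
    for lab in labels:
        idx = np.flatnonzero(mflat == lab)
        if idx.size == 0:
            raise ValueError(f"label {int(lab)} has no pixels")
        traces.append(FluorescenceTrace(
            times=times, intensities=flat[:, idx].mean(axis=1),
            laser_index=laser_index, cell_id=f"cell_{int(lab)}"))
    return traces


def bleach_correct(trace: FluorescenceTrace) -> CorrectedTrace:
    """Remove linear photobleaching and normalize to the resting level.

    An ordinary-least-squares line ``F = F0 + s*frame`` is fitted to the
    background frames only (the post-laser frames contain the signal of
    interest) and extrapolated over the whole recording; the corrected
    series is the raw trace divided by that line, so the resting level
    is 1 by construction.
    """
    if trace.laser_index < 2:
        raise ValueError("need at least 2 background frames")
    frames = np.arange(trace.intensities.size, dtype=float)
    bg = slice(0, trace.laser_index)
    slope, intercept = np.polyfit(frames[bg], trace.intensities[bg], 1)
    baseline = intercept + slope * frames
    if np.any(baseline <= 0):
        raise ValueError(
            f"fitted bleach baseline is nonpositive within the recording for "
            f"{trace.cell_id}; linear correction is invalid")
    return CorrectedTrace(times=trace.times,
                          rel_intensity=trace.intensities / baseline,
                          resting_intensity=float(intercept),
                          bleach_slope=float(slope),
                          laser_index=trace.laser_index,
                          cell_id=trace.cell_id)


def classification_threshold(ct: CorrectedTrace, k_sigma: float = 5.0,
                             min_dip: float = 1e-9) -> np.ndarray:
    """Per-frame perforation threshold for the post-laser frames.

    The noise level sigma is the sample SD of the corrected background
    frames.  Because the bleach baseline is fitted on the background and
    extrapolated forward, its prediction error grows with distance from
    the background window; the null SD of a corrected post-laser sample is
    therefore ``sigma * sqrt(1 + h(f))`` with ``h(f)`` the OLS leverage of
    frame ``f`` relative to the background design.  The threshold is
    ``1 - max(k_sigma * sigma * sqrt(1 + h(f)), min_dip)``; ``min_dip``
    guards the noiseless limit against machine-epsilon dips.
    """
    n_bg = ct.laser_index
    bg = ct.rel_intensity[:n_bg]
    sigma = float(np.std(bg, ddof=1)) if n_bg > 1 else 0.0
    frames = np.arange(ct.rel_intensity.size, dtype=float)
    f_bar = frames[:n_bg].mean()
    sxx = float(np.sum((frames[:n_bg] - f_bar) ** 2))
    leverage = 1.0 / n_bg + (frames[n_bg:] - f_bar) ** 2 / sxx
    margin = np.maximum(k_sigma * sigma * np.sqrt(1.0 + leverage), min_dip)
    return 1.0 - margin


def classify_perforated(ct: CorrectedTrace, k_sigma: float = 5.0,
                        min_dip: float = 1e-9) -> tuple[bool, float]:
    """Call a cell perforated from its post-laser dip.

    The cell is perforated iff any post-laser corrected sample falls
    strictly below the per-frame threshold of
    :func:`classification_threshold`; a dip exactly at the boundary is
    classed unperforated.  In the noiseless degenerate case (sigma = 0)
    any genuine dip below resting triggers the call.  Returns
    ``(perforated, dip_depth)`` with
    ``dip_depth = 1 - min(post-laser rel_intensity)``.
    """
    post = ct.rel_intensity[ct.laser_index:]
    if post.size == 0:
        raise ValueError("no post-laser frames")
    thresh = classification_threshold(ct, k_sigma=k_sigma, min_dip=min_dip)
    return bool(np.any(post < thresh)), 1.0 - float(post.min())


def resealing_time(ct: CorrectedTrace, threshold: float = 0.90,
                   confirm_frames: int = 3) -> Optional[float]:
    """Time (s, from laser onset) at which recovery crosses ``threshold``.

    Scans forward from the post-laser minimum for the first frame at or
    above the threshold that stays there for ``confirm_frames`` consecutive
    frames (noise robustness), then linearly interpolates the crossing
    between the bracketing frames.  Returns ``None`` if no confirmed
    crossing occurs before the recording ends (unresealed within the
    observation window).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    post = ct.rel_intensity[ct.laser_index:]
    if post.size == 0:
        raise ValueError("no post-laser frames")
    dip_idx = int(np.argmin(post))
    above = post >= threshold
    for i in range(dip_idx, post.size):
        window = above[i:i + confirm_frames]
        if window.size < confirm_frames:
            # End of recording: accept only a full confirmation window.
            break
        if window.all():
            if i == 0:
                return 0.0
            lo, hi = post[i - 1], post[i]
            frac = 0.0 if hi == lo else (threshold - lo) / (hi - lo)
            frac = min(max(frac, 0.0), 1.0)
            return (i - 1 + frac) * ct.frame_interval
    return None


def analyze_trace(trace: FluorescenceTrace, threshold: float = 0.90,
                  k_sigma: float = 5.0, confirm_frames: int = 3
                  ) -> ResealingResult:
    """Full per-cell analysis: correct, classify, time the resealing."""
    ct = bleach_correct(trace)
    perforated, dip_depth = classify_perforated(ct, k_sigma=k_sigma)
    t_reseal = None
    unresealed = False
    if perforated:
        t_reseal = resealing_time(ct, threshold=threshold,
                                  confirm_frames=confirm_frames)
        unresealed = t_reseal is None
    return ResealingResult(cell_id=trace.cell_id, perforated=perforated,
                           dip_depth=dip_depth, resealing_time=t_reseal,
                           threshold=threshold,
                           resting_intensity=ct.resting_intensity,
                           bleach_slope=ct.bleach_slope,
                           unresealed=unresealed)
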