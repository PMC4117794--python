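"""Recovering the folded/unfolded state path from noisy extension traces.

Force-clamp traces show two extension levels separated by the unfolding
step size (~5-9 nm in the working force range) on top of ~2 nm Gaussian
camera noise.  The detector is a penalized change-point search (binary
segmentation, L2 cost) on the smoothed trace, followed by a minimum-step
filter, two-level classification of segment means, and run-length
extraction of dwell times with censoring flags.  Ramp segments are
handled separately: the rupture event is the largest step-like change
and its force is read off the protocol at the event time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import theilslopes
from sklearn.cluster import KMeans

from .trace_synthesis import ExtensionTrace

__all__ = [
    "TransitionEvent",
    "DwellSet",
    "DetectorConfig",
    "StepDetectionResult",
    "smooth_trace",
    "detect_steps",
    "extract_dwells",
    "detect_rupture",
]


@dataclass(frozen=True)
class TransitionEvent:
    """A detected folding or unfolding step."""

    time: float
    direction: str  # "fold" | "unfold"
    step: float  # nm, signed: >0 unfold (extension gain), <0 fold
    force_at_event: float

    def __post_init__(self) -> None:
        if self.direction not in ("fold", "unfold"):
            raise ValueError("direction must be 'fold' or 'unfold'")
        if self.direction == "unfold" and self.step <= 0:
            raise ValueError("unfold events must have positive step")
        if self.direction == "fold" and self.step >= 0:
            raise ValueError("fold events must have negative step")


@dataclass
class DwellSet:
    """Dwell durations per observable state class, with censoring flags.

    ``records`` columns: state_class ('folded'/'unfolded'), duration (s),
    force (pN), censored ('none'/'left'/'right'/'both').  Censored dwells
    are kept and flagged, never dropped silently.
    """

    records: pd.DataFrame

    _COLUMNS = ("state_class", "duration", "force", "censored")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"DwellSet missing columns {sorted(missing)}")
        if len(self.records) and (self.records["duration"] <= 0).any():
            raise ValueError("dwell durations must be positive")

    @classmethod
    def from_arrays(cls, state_class, duration, force, censored) -> "DwellSet":
        return cls(
            pd.DataFrame(
                {
                    "state_class": state_class,
                    "duration": duration,
                    "force": force,
                    "censored": censored,
                }
            )
        )

    @classmethod
    def concat(cls, sets: List["DwellSet"]) -> "DwellSet":
        return cls(
            pd.concat([s.records for s in sets], ignore_index=True)
            if sets
            else pd.DataFrame(columns=list(cls._COLUMNS))
        )

    def durations(
        self, state_class: str, include_censored: bool = True
    ) -> Tuple[np.ndarray, np.ndarray]:
        """(durations, right_censored flags) for one state class.

        Left-censored dwells (truncated at recording start) carry no
        usable duration information for an exponential fit and are
        returned as right-censored as well when doubly censored.
        """
        sub = self.records[self.records["state_class"] == state_class]
        if not include_censored:
            sub = sub[sub["censored"] == "none"]
        dur = sub["duration"].to_numpy(dtype=float)
        cens = sub["censored"].isin(("left", "right", "both")).to_numpy()
        return dur, cens

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DetectorConfig:
    """Tuning of the change-point detector.

    window_s: smoothing window (adjacent average), also the time
        resolution; the effective dead time is ``min_dwell_s``.
    min_step: smallest level change (nm) accepted as a transition.
    min_dwell_s: dwells shorter than this are merged into their
        neighbours (missed-event convention); default 2*window_s.
    penalty_scale: multiplies the sigma^2*ln(n) split penalty.
    """

    window_s: float = 0.5
    min_step: float = 3.0
    min_dwell_s: Optional[float] = None
    penalty_scale: float = 3.0
    min_size: int = 3
    detrend: bool = True
    min_samples: int = 20

    @property
    def dead_time(self) -> float:
        return self.min_dwell_s if self.min_dwell_s is not None else 2.0 * self.window_s


@dataclass
class StepDetectionResult:
    """Change points, segment levels, two-level classification and events."""

    change_points: np.ndarray  # sample index of each segment start (excl. 0)
    levels: np.ndarray  # per-segment mean extension
    folded: np.ndarray  # per-segment bool classification
    state_path: np.ndarray  # per-sample bool (True = folded)
    events: List[TransitionEvent] = field(default_factory=list)
    sigma: float = float("nan")


def smooth_trace(trace: ExtensionTrace, window: float) -> ExtensionTrace:
    """Centered moving average with a ``window``-second sliding window.

    Edges use shrinking windows, so the length (and a clean plateau
    level) is preserved.
    """
    w = int(round(window * trace.sampling_rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > len(trace):
        raise ValueError("window longer than trace")
    sm = _moving_average(trace.extension, w)
    return replace(trace, extension=sm)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average, shrinking at the edges (O(n) via cumsum)."""
    n = len(x)
    half_lo = (w - 1) // 2
    half_hi = w // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _robust_sigma(x: np.ndarray) -> float:
    """Noise SD from the median absolute successive difference."""
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / (0.6745 * np.sqrt(2.0))) if mad > 0 else float(np.std(d) / np.sqrt(2) + 1e-12)


def _change_point_candidates(
    x: np.ndarray, h: int, amplitude: float
) -> np.ndarray:
    """Candidate change points from a matched boxcar-difference filter.

    d[i] = mean(x[i:i+h]) - mean(x[i-h:i]) reaches the full level change
    for dwells of at least ``h`` samples; peaks of |d| above
    ``amplitude`` are candidate transitions.
    """
    from scipy.signal import find_peaks

    n = len(x)
    if n < 2 * h + 1:
        return np.array([], dtype=int)
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(h, n - h + 1)
    d = (c[i + h] - c[i]) / h - (c[i] - c[i - h]) / h
    peaks, _ = find_peaks(np.abs(d), height=amplitude, distance=max(h // 2, 1))
    return i[peaks]


def _refine_splits(
    x: np.ndarray, candidates: np.ndarray, h: int, penalty: float, min_size: int
) -> np.ndarray:
    """Exact local L2 split refinement with penalized acceptance.

    Each candidate is replaced by the argmin-cost split inside its
    +-h window and kept only when the local cost reduction exceeds
    ``penalty`` (the sigma^2-scaled change-point penalty).
    """
    n = len(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    refined: List[int] = []
    for cpt in candidates:
        a = max(int(cpt) - h, 0)
        b = min(int(cpt) + h, n)
        if b - a < 2 * min_size:
            continue
        cand = np.arange(a + min_size, b - min_size + 1)
        s_left = c1[cand] - c1[a]
        s_right = c1[b] - c1[cand]
        cost_split = (
            -(s_left * s_left / (cand - a))
            - s_right * s_right / (b - cand)
        )
        best = int(np.argmin(cost_split))
        s_all = c1[b] - c1[a]
        gain = (cost_split[best] * -1.0) - s_all * s_all / (b - a)
        if gain > penalty:
            refined.append(int(cand[best]))
    refined = sorted(set(refined))
    # enforce minimal spacing: keep the earlier of two conflicting splits
    out: List[int] = []
    for s in refined:
        if not out or s - out[-1] >= min_size:
            out.append(s)
    return np.array(out, dtype=int)


def _merge_small_levels(
    bounds: np.ndarray, x: np.ndarray, min_step: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Merge adjacent segments whose level difference is below min_step.

    ``bounds`` includes 0 and n.  Returns (bounds, levels) after
    iteratively merging the closest-level adjacent pair.
    """
    bounds = list(bounds)
    c1 = np.concatenate([[0.0], np.cumsum(x)])

    def level(i):
        a, b = bounds[i], bounds[i + 1]
        return (c1[b] - c1[a]) / (b - a)

    levels = [level(i) for i in range(len(bounds) - 1)]
    while len(levels) > 1:
        diffs = np.abs(np.diff(levels))
        i = int(np.argmin(diffs))
        if diffs[i] >= min_step:
            break
        # merge segments i and i+1
        del bounds[i + 1]
        levels[i : i + 2] = [level(i)]
    return np.asarray(bounds, dtype=int), np.asarray(levels, dtype=float)


def detect_steps(
    trace: ExtensionTrace, cfg: DetectorConfig = DetectorConfig()
) -> StepDetectionResult:
    """Detect stepwise transitions in a force-clamp trace.

    Pipeline: optional robust detrend -> matched boxcar-difference scan
    for candidate change points (window = detector dead time) -> exact
    local L2 split refinement with a sigma^2-scaled penalty -> merge of
    sub-``min_step`` level changes -> two-level classification (1-d
    2-means on segment levels, lower level = folded) -> transition
    events at class changes.
    """
    n = len(trace)
    if n < cfg.min_samples:
        raise ValueError(f"trace has {n} samples; need >= {cfg.min_samples}")
    x = trace.extension.astype(float)
    if cfg.detrend:
        sub = np.linspace(0, n - 1, min(n, 2001)).astype(int)
        slope = theilslopes(x[sub], trace.time[sub])[0]
        x = x - slope * trace.time
    sigma_raw = _robust_sigma(x)
    h = max(int(round(cfg.dead_time * trace.sampling_rate)), 2)
    amplitude = max(0.5 * cfg.min_step, 4.0 * sigma_raw / np.sqrt(h))
    penalty = cfg.penalty_scale * sigma_raw**2 * np.log(max(n, 2))
    candidates = _change_point_candidates(x, h, amplitude)
    splits = _refine_splits(x, candidates, h, penalty, max(cfg.min_size, 1))
    xs = x
    bounds = np.concatenate([[0], splits, [n]])
    bounds, levels = _merge_small_levels(bounds, xs, cfg.min_step)

    if len(levels) == 1:
        folded_seg = np.array([False])  # single level: class unknown -> unfolded
        path = np.zeros(n, dtype=bool)
        return StepDetectionResult(
            change_points=np.array([], dtype=int),
            levels=levels,
            folded=folded_seg,
            state_path=path,
            events=[],
            sigma=sigma_raw,
        )

    weights = np.diff(bounds).astype(float)
    km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(
        levels.reshape(-1, 1), sample_weight=weights
    )
    centers = km.cluster_centers_.ravel()
    folded_label = int(np.argmin(centers))  # lower extension = folded
    folded_seg = km.labels_ == folded_label

    # collapse adjacent same-class segments
    keep = np.flatnonzero(np.diff(folded_seg.astype(int)) != 0) + 1
    seg_starts = np.concatenate([[0], bounds[1:-1][keep - 1]])
    # recompute class-run boundaries and levels
    run_bounds = np.concatenate([[0], bounds[1:-1][keep - 1], [n]])
    run_folded = folded_seg[np.concatenate([[0], keep])]
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    run_levels = (c1[run_bounds[1:]] - c1[run_bounds[:-1]]) / np.diff(run_bounds)

    path = np.zeros(n, dtype=bool)
    for a, b, fl in zip(run_bounds[:-1], run_bounds[1:], run_folded):
        path[a:b] = fl

    events: List[TransitionEvent] = []
    for i, s in enumerate(run_bounds[1:-1]):
        t_ev = trace.time[s]
        step = float(run_levels[i + 1] - run_levels[i])
        direction = "fold" if run_folded[i + 1] else "unfold"
        # enforce sign consistency with the classification
        if direction == "unfold":
            step = abs(step)
        else:
            step = -abs(step)
        events.append(
            TransitionEvent(
                time=float(t_ev),
                direction=direction,
                step=step,
                force_at_event=float(trace.force[s]),
            )
        )
    return StepDetectionResult(
        change_points=run_bounds[1:-1].copy(),
        levels=run_levels,
        folded=run_folded,
        state_path=path,
        events=events,
        sigma=sigma_raw,
    )


def extract_dwells(
    state_path: np.ndarray,
    sampling_rate: float,
    min_dwell: float = 0.0,
    force: float = float("nan"),
) -> DwellSet:
    """Run-length encode a binary state path into a DwellSet.

    Dwells shorter than ``min_dwell`` are merged into their neighbours
    (shortest first), the missed-event convention whose dead time the
    downstream MLE corrects for.  First and last dwells are flagged as
    left-/right-censored (a single uninterrupted dwell is 'both').
    """
    path = np.asarray(state_path, dtype=bool)
    if path.ndim != 1 or len(path) == 0:
        raise ValueError("state_path must be a non-empty 1-d boolean array")
    change = np.flatnonzero(np.diff(path.astype(int)) != 0) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(path)]]))
    classes = path[starts]

    min_len = int(round(min_dwell * sampling_rate))
    lengths = lengths.astype(int).tolist()
    classes = classes.tolist()
    while len(lengths) > 1:
        i = int(np.argmin(lengths))
        if lengths[i] >= min_len:
            break
        if i == 0:
            lengths[1] += lengths[0]
            del lengths[0], classes[0]
        elif i == len(lengths) - 1:
            lengths[-2] += lengths[-1]
            del lengths[-1], classes[-1]
        else:
            lengths[i - 1] += lengths[i] + lengths[i + 1]
            del lengths[i : i + 2], classes[i : i + 2]

    n_dwell = len(lengths)
    censored = ["none"] * n_dwell
    censored[0] = "both" if n_dwell == 1 else "left"
    if n_dwell > 1:
        censored[-1] = "right"
    durations = np.asarray(lengths, dtype=float) / sampling_rate
    return DwellSet.from_arrays(
        state_class=["folded" if c else "unfolded" for c in classes],
        duration=durations,
        force=np.full(n_dwell, force),
        censored=censored,
    )


def detect_rupture(
    trace: ExtensionTrace,
    cfg: DetectorConfig = DetectorConfig(window_s=0.25),
    local_window_s: float = 1.0,
) -> Optional[Tuple[float, float]]:
    """Find the unfolding rupture in a force-ramp trace.

    Returns (rupture force pN, step size nm) of the largest step-like
    extension increase exceeding ``cfg.min_step``, or None when no such
    event exists (the tether was already unfolded).  The force is read
    from the protocol force channel at the event time; the step is the
    difference of local means just after vs just before the event.
    """
    n = len(trace)
    if n < cfg.min_samples:
        raise ValueError(f"trace has {n} samples; need >= {cfg.min_samples}")
    w = max(int(round(cfg.window_s * trace.sampling_rate)), 2)
    xs = _moving_average(trace.extension.astype(float), w)
    lw = max(int(round(local_window_s * trace.sampling_rate)), 2)
    # forward-backward local mean difference (matched step filter)
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    idx = np.arange(lw, n - lw)
    if len(idx) == 0:
        return None
    fwd = (c1[idx + lw] - c1[idx]) / lw
    bwd = (c1[idx] - c1[idx - lw]) / lw
    d = fwd - bwd
    best = int(np.argmax(d))
    if d[best] < cfg.min_step:
        return None
    s = int(idx[best])
    step = float(d[best])
    return float(trace.force[s]), step
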