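"""Motif segmentation, body/leg coupling, and long-time grooming progression.

Anterior motifs are maximal runs of head cleaning (h) and front-leg rubbing
(f); posterior motifs are maximal runs of abdomen (a), wing (w) cleaning and
back-leg rubbing (b). Walking, standing, and the opposite motif's actions
terminate a run. Body/leg accounting: anterior body = {h}, leg = {f};
posterior body = {a, w}, leg = {b}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .ethogram import BoutEthogram, FrameEthogram

ANTERIOR = frozenset({"f", "h"})
POSTERIOR = frozenset({"a", "b", "w"})
_BODY = {"anterior": frozenset({"h"}), "posterior": frozenset({"a", "w"})}
_LEG = {"anterior": frozenset({"f"}), "posterior": frozenset({"b"})}

DEFAULT_WINDOW_FRAMES = 500


def _classify(action: str) -> Optional[str]:
    if action in ANTERIOR:
        return "anterior"
    if action in POSTERIOR:
        return "posterior"
    return None


@dataclass(frozen=True)
class Motif:
    """Maximal run of same-leg-set bouts with body/leg time totals."""

    motif_class: str
    actions: tuple[str, ...]
    durations: tuple[float, ...]
    start_index: int  # index of the first bout within its source ethogram

    @property
    def n_bouts(self) -> int:
        return len(self.actions)

    @property
    def body_time(self) -> float:
        body = _BODY[self.motif_class]
        return sum(d for a, d in zip(self.actions, self.durations) if a in body)

    @property
    def leg_time(self) -> float:
        leg = _LEG[self.motif_class]
        return sum(d for a, d in zip(self.actions, self.durations) if a in leg)

    @property
    def total_time(self) -> float:
        return sum(self.durations)


def segment_motifs(etho: BoutEthogram, min_bouts: int = 1) -> list[Motif]:
    """Split an ethogram into maximal anterior/posterior runs.

    Runs with fewer than ``min_bouts`` bouts are discarded; non-motif bouts
    (walking, standing) never join a run.
    """
    motifs: list[Motif] = []
    run_class: Optional[str] = None
    run_start = 0
    run_actions: list[str] = []
    run_durations: list[float] = []

    def flush() -> None:
        if run_class is not None and len(run_actions) >= min_bouts:
            motifs.append(
                Motif(
                    motif_class=run_class,
                    actions=tuple(run_actions),
                    durations=tuple(run_durations),
                    start_index=run_start,
                )
            )

    for i, bout in enumerate(etho):
        cls = _classify(bout.action)
        if cls != run_class:
            flush()
            run_class = cls
            run_start = i
            run_actions, run_durations = [], []
        if cls is not None:
            run_actions.append(bout.action)
            run_durations.append(bout.duration)
    flush()
    return motifs


# ---------------------------------------------------------------------------
# Linear relationships
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float
    n: int

    @property
    def r_squared(self) -> float:
        return self.r * self.r


def _fit_line(x: np.ndarray, y: np.ndarray) -> LinearFit:
    n = x.size
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        # degenerate: correlation undefined
        slope = math.nan if n < 2 or np.ptp(x) == 0 else 0.0
        return LinearFit(slope=slope, intercept=math.nan, r=math.nan, n=n)
    res = sstats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept), r=float(res.rvalue), n=n
    )


@dataclass(frozen=True)
class MotifCoupling:
    motif_class: str
    body_time: np.ndarray
    leg_time: np.ndarray
    fit: LinearFit


def motif_body_leg_relation(
    motifs: Sequence[Motif], min_bouts: int = 4
) -> dict[str, MotifCoupling]:
    """Per-class (body_time, leg_time) scatter with least-squares fit and
    Pearson correlation, over motifs with at least ``min_bouts`` bouts."""
    out: dict[str, MotifCoupling] = {}
    for cls in ("anterior", "posterior"):
        sel = [m for m in motifs if m.motif_class == cls and m.n_bouts >= min_bouts]
        body = np.asarray([m.body_time for m in sel])
        leg = np.asarray([m.leg_time for m in sel])
        out[cls] = MotifCoupling(
            motif_class=cls, body_time=body, leg_time=leg, fit=_fit_line(body, leg)
        )
    return out


def intra_motif_transition_fractions(
    cohort: Sequence[BoutEthogram],
) -> tuple[float, float]:
    """Fraction of transitions out of anterior (resp. posterior) bouts that
    land on the same motif class; NaN when a class has no source bouts."""
    if not cohort:
        raise ValueError("empty cohort")
    counts = {"anterior": [0, 0], "posterior": [0, 0]}  # [total, within]
    for etho in cohort:
        acts = etho.actions
        for cls, members in (("anterior", ANTERIOR), ("posterior", POSTERIOR)):
            src = np.isin(acts[:-1], list(members))
            counts[cls][0] += int(src.sum())
            counts[cls][1] += int(np.isin(acts[1:][src], list(members)).sum())
    def frac(cls: str) -> float:
        total, within = counts[cls][0], counts[cls][1]
        return within / total if total else math.nan
    return frac("anterior"), frac("posterior")


@dataclass(frozen=True)
class ConsecutivePairs:
    motif_class: str
    first: np.ndarray
    second: np.ndarray
    fit: LinearFit


def consecutive_bout_scatter(
    cohort: Sequence[BoutEthogram], motif_class: str = "anterior"
) -> ConsecutivePairs:
    """(duration_t, duration_{t+1}) pairs for consecutive within-class bouts,
    with regression diagnostics."""
    members = ANTERIOR if motif_class == "anterior" else POSTERIOR
    first: list[float] = []
    second: list[float] = []
    for etho in cohort:
        inside = np.isin(etho.actions, list(members))
        pair = inside[:-1] & inside[1:]
        first.extend(etho.durations[:-1][pair])
        second.extend(etho.durations[1:][pair])
    x, y = np.asarray(first), np.asarray(second)
    return ConsecutivePairs(motif_class=motif_class, first=x, second=y, fit=_fit_line(x, y))


# ---------------------------------------------------------------------------
# Sliding-window progression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProgressionCurve:
    """Per-action occupancy fraction in a sliding frame window."""

    times_s: np.ndarray
    proportions: np.ndarray  # (n_actions, n_times)
    actions: tuple[str, ...]
    window: int
    frame_rate: float

    def proportion(self, action: str) -> np.ndarray:
        return self.proportions[self.actions.index(action)]


def sliding_window_proportions(
    frames: FrameEthogram,
    window: int = DEFAULT_WINDOW_FRAMES,
    stride: int = 1,
    actions: Optional[Sequence[str]] = None,
) -> ProgressionCurve:
    """Occupancy fraction of each action in a centered sliding window.

    Windows are truncated at the record edges, so proportions always sum to 1
    over the actions present in the record.
    """
    n = frames.n_frames
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if actions is None:
        actions = tuple(sorted(set(frames.labels.tolist())))
    else:
        actions = tuple(actions)
    centers = np.arange(0, n, stride)
    half = window // 2
    lo = np.maximum(centers - half, 0)
    hi = np.minimum(centers - half + window, n)
    sizes = (hi - lo).astype(float)
    props = np.empty((len(actions), centers.size))
    for k, action in enumerate(actions):
        csum = np.concatenate(([0], np.cumsum(frames.labels == action)))
        props[k] = (csum[hi] - csum[lo]) / sizes
    return ProgressionCurve(
        times_s=centers / frames.frame_rate,
        proportions=props,
        actions=actions,
        window=window,
        frame_rate=frames.frame_rate,
    )


def cohort_progression(
    cohort: Sequence[FrameEthogram],
    window: int = DEFAULT_WINDOW_FRAMES,
    stride: int = 1,
    actions: Optional[Sequence[str]] = None,
) -> ProgressionCurve:
    """Pointwise average of per-fly progression curves (records truncated to
    the shortest fly)."""
    if not cohort:
        raise ValueError("empty cohort")
    n_min = min(f.n_frames for f in cohort)
    if actions is None:
        labels = set()
        for f in cohort:
            labels.update(f.labels.tolist())
        actions = tuple(sorted(labels))
    curves = [
        sliding_window_proportions(
            FrameEthogram(f.labels[:n_min], f.frame_rate, f.fly_id),
            window=window,
            stride=stride,
            actions=actions,
        )
        for f in cohort
    ]
    props = np.mean([c.proportions for c in curves], axis=0)
    return ProgressionCurve(
        times_s=curves[0].times_s,
        proportions=props,
        actions=tuple(actions),
        window=window,
        frame_rate=cohort[0].frame_rate,
    )
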