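"""Frame- and bout-level ethogram containers, de-noising, and duration binning.

A *frame ethogram* is a dense per-video-frame label stream; a *bout ethogram*
is its run-length encoding into (action, duration) bouts. Downstream Markov
analysis operates on bout ethograms whose durations may additionally be
collapsed into per-action equal-occupancy categories (short/medium/long).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, NamedTuple, Optional, Sequence

import numpy as np

#: Full label alphabet: five grooming actions, walking, standing.
ALPHABET = ("f", "h", "a", "b", "w", "wk", "s")

#: Canonical non-standing action order used for state spaces.
GROOMING_ACTIONS = ("f", "h", "a", "b", "w", "wk")

STANDING = "s"

#: Bouts shorter than this (seconds) are treated as classifier artifacts.
DEFAULT_MIN_BOUT_DURATION = 0.167


class EthogramError(ValueError):
    """Base class for ethogram validation failures."""


class UnknownLabelError(EthogramError):
    def __init__(self, label: str, index: int):
        self.label = label
        self.index = index
        super().__init__(f"unknown behavior label {label!r} at frame {index}")


class EmptyEthogramError(EthogramError):
    """Raised when an operation would leave an ethogram with no bouts."""


class BinningError(EthogramError):
    """Raised for invalid binning schemes or unbinnable bouts."""


@dataclass(frozen=True)
class FrameEthogram:
    """One behavior label per video frame, recorded at ``frame_rate`` Hz."""

    labels: np.ndarray
    frame_rate: float
    fly_id: Optional[str] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype="<U2")
        if labels.ndim != 1 or labels.size < 1:
            raise EthogramError("frame ethogram must be a non-empty 1-D label vector")
        if self.frame_rate <= 0:
            raise EthogramError(f"frame_rate must be positive, got {self.frame_rate}")
        bad = ~np.isin(labels, ALPHABET)
        if bad.any():
            idx = int(np.argmax(bad))
            raise UnknownLabelError(str(labels[idx]), idx)
        object.__setattr__(self, "labels", labels)

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def __len__(self) -> int:
        return self.n_frames


class Bout(NamedTuple):
    """A maximal run of one action; ``category`` is the duration bin, if assigned."""

    action: str
    duration: float
    category: Optional[int] = None


@dataclass(frozen=True)
class BoutEthogram:
    """Ordered (action, duration[, category]) bouts for a single fly.

    Invariant: no two consecutive bouts share an action, so self-transitions
    never occur in downstream transition counting.
    """

    actions: np.ndarray
    durations: np.ndarray
    categories: Optional[np.ndarray] = None
    frame_rate: Optional[float] = None
    fly_id: Optional[str] = None

    def __post_init__(self) -> None:
        actions = np.asarray(self.actions, dtype="<U2")
        durations = np.asarray(self.durations, dtype=float)
        if actions.ndim != 1 or actions.size < 1:
            raise EmptyEthogramError("bout ethogram must contain at least one bout")
        if durations.shape != actions.shape:
            raise EthogramError("actions and durations must have equal length")
        if (durations <= 0).any():
            raise EthogramError("all bout durations must be positive")
        if actions.size > 1 and (actions[1:] == actions[:-1]).any():
            i = int(np.argmax(actions[1:] == actions[:-1]))
            raise EthogramError(
                f"consecutive bouts {i} and {i + 1} share action {actions[i]!r}"
            )
        object.__setattr__(self, "actions", actions)
        object.__setattr__(self, "durations", durations)
        if self.categories is not None:
            cats = np.asarray(self.categories, dtype=int)
            if cats.shape != actions.shape:
                raise EthogramError("categories must have one entry per bout")
            if (cats < 0).any():
                raise EthogramError("categories must be non-negative")
            object.__setattr__(self, "categories", cats)

    # -- container protocol -------------------------------------------------

    @property
    def n_bouts(self) -> int:
        return int(self.actions.size)

    @property
    def total_time(self) -> float:
        """Total recorded time in seconds (sum of bout durations)."""
        return float(self.durations.sum())

    @property
    def is_binned(self) -> bool:
        return self.categories is not None

    @property
    def start_times(self) -> np.ndarray:
        """Start time of each bout in seconds."""
        out = np.empty(self.n_bouts)
        out[0] = 0.0
        np.cumsum(self.durations[:-1], out=out[1:])
        return out

    def __len__(self) -> int:
        return self.n_bouts

    def __iter__(self) -> Iterator[Bout]:
        cats = self.categories
        for i in range(self.n_bouts):
            yield Bout(
                str(self.actions[i]),
                float(self.durations[i]),
                None if cats is None else int(cats[i]),
            )

    def __getitem__(self, key):
        if isinstance(key, slice):
            return BoutEthogram(
                actions=self.actions[key],
                durations=self.durations[key],
                categories=None if self.categories is None else self.categories[key],
                frame_rate=self.frame_rate,
                fly_id=self.fly_id,
            )
        i = int(key)
        return Bout(
            str(self.actions[i]),
            float(self.durations[i]),
            None if self.categories is None else int(self.categories[i]),
        )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def discretize(frames: FrameEthogram) -> BoutEthogram:
    """Run-length encode a frame ethogram into a bout ethogram.

    Consecutive identical labels collapse into a single bout whose duration is
    the run length divided by the frame rate; :func:`expand` inverts this
    exactly.
    """
    labels = frames.labels
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return BoutEthogram(
        actions=labels[starts],
        durations=(ends - starts) / frames.frame_rate,
        frame_rate=frames.frame_rate,
        fly_id=frames.fly_id,
    )


def expand(etho: BoutEthogram, frame_rate: Optional[float] = None) -> FrameEthogram:
    """Inverse of :func:`discretize`: rebuild the per-frame label vector.

    Durations are converted to frame counts by rounding to the nearest frame
    (bouts derived from frames have exactly integral counts).
    """
    fr = frame_rate if frame_rate is not None else etho.frame_rate
    if fr is None:
        raise EthogramError("frame_rate required to expand a bout ethogram")
    counts = np.rint(etho.durations * fr).astype(int)
    counts = np.maximum(counts, 1)
    return FrameEthogram(
        labels=np.repeat(etho.actions, counts), frame_rate=fr, fly_id=etho.fly_id
    )


# ---------------------------------------------------------------------------
# De-noising
# ---------------------------------------------------------------------------


class DenoiseResult(NamedTuple):
    ethogram: BoutEthogram
    deleted_time: float
    deleted_fraction: float


def _merge_consecutive(
    actions: np.ndarray, durations: np.ndarray, categories: Optional[np.ndarray]
):
    """Merge adjacent same-action bouts (durations summed, categories dropped)."""
    if actions.size == 0:
        return actions, durations, categories
    same = np.concatenate(([False], actions[1:] == actions[:-1]))
    if not same.any():
        return actions, durations, categories
    group = np.cumsum(~same) - 1
    n_groups = int(group[-1]) + 1
    merged_dur = np.zeros(n_groups)
    np.add.at(merged_dur, group, durations)
    keep = np.flatnonzero(~same)
    # merged bouts lose any duration category (the summed duration was never binned)
    return actions[keep], merged_dur, None


def remove_short_bouts(
    etho: BoutEthogram, min_duration: float = DEFAULT_MIN_BOUT_DURATION
) -> DenoiseResult:
    """Delete artifact bouts shorter than ``min_duration`` seconds.

    Deleted time is dropped from the record (total_time shrinks). Surviving
    same-action neighbors left adjacent by a deletion are merged in a single
    pass; merged bouts are not re-filtered. Returns the filtered ethogram
    together with the absolute and fractional deleted time.
    """
    if min_duration < 0:
        raise EthogramError("min_duration must be non-negative")
    keep = etho.durations >= min_duration
    if keep.all():
        return DenoiseResult(etho, 0.0, 0.0)
    total = etho.total_time
    deleted = float(etho.durations[~keep].sum())
    if not keep.any():
        raise EmptyEthogramError(
            f"all {etho.n_bouts} bouts fall below the {min_duration} s threshold"
        )
    actions = etho.actions[keep]
    durations = etho.durations[keep]
    categories = None if etho.categories is None else etho.categories[keep]
    actions, durations, categories = _merge_consecutive(actions, durations, categories)
    out = BoutEthogram(
        actions=actions,
        durations=durations,
        categories=categories,
        frame_rate=etho.frame_rate,
        fly_id=etho.fly_id,
    )
    return DenoiseResult(out, deleted, deleted / total)


def drop_action(etho: BoutEthogram, action: str = STANDING) -> BoutEthogram:
    """Remove every bout of ``action`` (standing by default), merging the
    same-action neighbors the removal exposes. Absent action -> identity."""
    if action not in ALPHABET:
        raise UnknownLabelError(action, -1)
    keep = etho.actions != action
    if keep.all():
        return etho
    if not keep.any():
        raise EmptyEthogramError(f"dropping {action!r} empties the ethogram")
    actions, durations, categories = _merge_consecutive(
        etho.actions[keep],
        etho.durations[keep],
        None if etho.categories is None else etho.categories[keep],
    )
    return BoutEthogram(
        actions=actions,
        durations=durations,
        categories=categories,
        frame_rate=etho.frame_rate,
        fly_id=etho.fly_id,
    )


# ---------------------------------------------------------------------------
# Duration binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinningScheme:
    """Per-action equal-occupancy duration bin edges.

    ``edges[action]`` holds ``n_bins - 1`` strictly increasing thresholds in
    seconds. Categories are half-open on the left: a duration equal to a
    threshold falls in the upper bin.
    """

    n_bins: int
    edges: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise BinningError("n_bins must be >= 1")
        norm = {}
        for action, thr in self.edges.items():
            thr = tuple(float(x) for x in thr)
            if len(thr) != self.n_bins - 1:
                raise BinningError(
                    f"action {action!r}: expected {self.n_bins - 1} thresholds, got {len(thr)}"
                )
            if any(x <= 0 for x in thr):
                raise BinningError(f"action {action!r}: thresholds must be positive")
            if any(b <= a for a, b in zip(thr, thr[1:])):
                raise BinningError(
                    f"action {action!r}: thresholds must be strictly increasing"
                )
            norm[action] = thr
        object.__setattr__(self, "edges", norm)

    def category_of(self, action: str, duration: float) -> int:
        if self.n_bins == 1:
            return 0
        if action not in self.edges:
            raise BinningError(f"no bin edges for action {action!r}")
        return int(np.searchsorted(self.edges[action], duration, side="right"))


def fit_binning_scheme(
    cohort: Sequence[BoutEthogram], n_bins: int
) -> BinningScheme:
    """Fit per-action equal-count duration bin edges on a cohort.

    Thresholds sit at midpoints between the bracketing order statistics of
    each action's pooled duration sample, so bin occupancies on the fitting
    corpus differ by at most one (exactly, up to duration ties).
    """
    if n_bins < 1:
        raise BinningError("n_bins must be >= 1")
    if not cohort:
        raise BinningError("empty cohort")
    pools: dict[str, list[np.ndarray]] = {}
    for etho in cohort:
        for action in np.unique(etho.actions):
            pools.setdefault(str(action), []).append(
                etho.durations[etho.actions == action]
            )
    edges: dict[str, tuple[float, ...]] = {}
    for action, chunks in pools.items():
        d = np.sort(np.concatenate(chunks))
        n = d.size
        if n < n_bins:
            raise BinningError(
                f"action {action!r} has only {n} bouts; need at least {n_bins}"
            )
        thr: list[float] = []
        for k in range(1, n_bins):
            cut = int(round(k * n / n_bins))
            cut = min(max(cut, 1), n - 1)
            t = 0.5 * (d[cut - 1] + d[cut])
            if thr and t <= thr[-1]:  # duration ties: keep edges strictly increasing
                t = np.nextafter(thr[-1], np.inf)
            thr.append(float(t))
        edges[action] = tuple(thr)
    return BinningScheme(n_bins=n_bins, edges=edges)


def apply_binning(etho: BoutEthogram, scheme: BinningScheme) -> BoutEthogram:
    """Annotate each bout with its duration category under ``scheme``."""
    if scheme.n_bins == 1:
        cats = np.zeros(etho.n_bouts, dtype=int)
    else:
        missing = sorted(set(map(str, etho.actions)) - set(scheme.edges))
        if missing:
            raise BinningError(f"scheme lacks edges for actions: {missing}")
        cats = np.empty(etho.n_bouts, dtype=int)
        for action, thr in scheme.edges.items():
            mask = etho.actions == action
            if mask.any():
                cats[mask] = np.searchsorted(
                    np.asarray(thr), etho.durations[mask], side="right"
                )
    return replace(etho, categories=cats)
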