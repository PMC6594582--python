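"""First-order Markov transition models over action x duration-category states.

State spaces are the ordered product of a canonical action list with duration
categories; transition matrices are maximum-likelihood row-normalized count
matrices with same-action blocks identically zero (run-length-encoded bout
streams never self-transition). Model comparison uses BIC = ln(n)*k - 2*lnL.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .ethogram import BoutEthogram, GROOMING_ACTIONS

#: Duration-category letters used in state labels, per number of bins.
_CATEGORY_LETTERS = {2: ("s", "l"), 3: ("s", "m", "l")}


class StateSpaceError(ValueError):
    pass


class ModelError(ValueError):
    pass


def category_letter(n_bins: int, category: int) -> str:
    letters = _CATEGORY_LETTERS.get(n_bins)
    return letters[category] if letters else str(category)


@dataclass(frozen=True)
class StateSpace:
    """Ordered (action, category) product space.

    Actions keep the order given at construction; categories ascend within
    each action, so state index = action_index * n_bins + category.
    """

    actions: tuple[str, ...]
    n_bins: int

    def __post_init__(self) -> None:
        actions = tuple(self.actions)
        if not actions:
            raise StateSpaceError("need at least one action")
        if len(set(actions)) != len(actions):
            raise StateSpaceError(f"duplicate actions in {actions}")
        if self.n_bins < 1:
            raise StateSpaceError("n_bins must be >= 1")
        object.__setattr__(self, "actions", actions)

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def v(self) -> int:
        """Total state count."""
        return self.n_actions * self.n_bins

    @property
    def states(self) -> tuple[tuple[str, int], ...]:
        return tuple((a, c) for a in self.actions for c in range(self.n_bins))

    def index(self, action: str, category: int = 0) -> int:
        try:
            ai = self.actions.index(action)
        except ValueError:
            raise StateSpaceError(f"action {action!r} not in state space") from None
        if not 0 <= category < self.n_bins:
            raise StateSpaceError(f"category {category} out of range for n_bins={self.n_bins}")
        return ai * self.n_bins + category

    def labels(self) -> list[str]:
        """State labels like ``h.s`` / ``h.m`` / ``h.l`` (plain action at 1 bin)."""
        if self.n_bins == 1:
            return list(self.actions)
        return [
            f"{a}.{category_letter(self.n_bins, c)}"
            for a in self.actions
            for c in range(self.n_bins)
        ]

    def action_of_state(self, state: int) -> str:
        return self.actions[state // self.n_bins]

    def same_action_mask(self) -> np.ndarray:
        """v x v boolean mask of (row, col) pairs sharing an action."""
        ai = np.repeat(np.arange(self.n_actions), self.n_bins)
        return ai[:, None] == ai[None, :]

    def state_indices(self, etho: BoutEthogram) -> np.ndarray:
        """Vectorized state index of each bout in ``etho``."""
        lookup = {a: i for i, a in enumerate(self.actions)}
        ai = np.empty(etho.n_bouts, dtype=np.int64)
        for a in np.unique(etho.actions):
            if str(a) not in lookup:
                raise StateSpaceError(f"action {str(a)!r} not in state space")
            ai[etho.actions == a] = lookup[str(a)]
        if self.n_bins == 1:
            return ai
        if etho.categories is None:
            raise ModelError("ethogram must be duration-binned for n_bins > 1")
        if (etho.categories >= self.n_bins).any():
            raise ModelError("bout category exceeds state-space n_bins")
        return ai * self.n_bins + etho.categories


def build_state_space(
    actions: Sequence[str] = GROOMING_ACTIONS, n_bins: int = 1
) -> StateSpace:
    """Build the deterministic product state space (v = |actions| * n_bins)."""
    return StateSpace(actions=tuple(actions), n_bins=n_bins)


# ---------------------------------------------------------------------------
# Counting and MLE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionCounts:
    counts: np.ndarray
    state_space: StateSpace

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        v = self.state_space.v
        if counts.shape != (v, v):
            raise ModelError(f"counts must be {v}x{v}")
        if (counts < 0).any():
            raise ModelError("counts must be non-negative")
        if counts[self.state_space.same_action_mask()].any():
            raise ModelError("same-action transition counts must be zero")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def count_transitions(
    cohort: Iterable[BoutEthogram], space: StateSpace
) -> TransitionCounts:
    """Pool bout-to-bout transition counts across flies.

    Transitions never cross fly boundaries; the consecutive-distinct bout
    invariant guarantees an empty same-action block.
    """
    v = space.v
    counts = np.zeros((v, v), dtype=np.int64)
    for etho in cohort:
        idx = space.state_indices(etho)
        if idx.size >= 2:
            np.add.at(counts, (idx[:-1], idx[1:]), 1)
    return TransitionCounts(counts=counts, state_space=space)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probabilities over a :class:`StateSpace`.

    Rows without any observed transition are "unsupported": all-zero, flagged
    in ``row_support``, and excluded from likelihoods and parameter counts.
    ``free_parameters`` carries a model-specific parameter count for
    constrained models (e.g. permutation nulls); ``None`` means "derive from
    matrix structure".
    """

    probs: np.ndarray
    state_space: StateSpace
    row_support: np.ndarray
    free_parameters: Optional[int] = None
    #: sub-stochastic rows allowed (e.g. the unrenormalized order-permuted
    #: null, whose rows lose the forbidden same-action mass)
    substochastic: bool = False

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        support = np.asarray(self.row_support, dtype=bool)
        v = self.state_space.v
        if probs.shape != (v, v):
            raise ModelError(f"probs must be {v}x{v}")
        if support.shape != (v,):
            raise ModelError("row_support must have one flag per state")
        if (probs < -1e-15).any() or (probs > 1 + 1e-12).any():
            raise ModelError("probabilities must lie in [0, 1]")
        if probs[self.state_space.same_action_mask()].any():
            raise ModelError("same-action block must be identically zero")
        sums = probs.sum(axis=1)
        if self.substochastic:
            if (sums[support] > 1 + 1e-12).any():
                raise ModelError("sub-stochastic rows must sum to at most 1")
        elif not np.allclose(sums[support], 1.0, atol=1e-12):
            raise ModelError("supported rows must sum to 1 within 1e-12")
        if (np.abs(sums[~support]) > 1e-15).any():
            raise ModelError("unsupported rows must be all-zero")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "row_support", support)


def mle_transition_matrix(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalize transition counts: entry ij = n_ij / sum_u n_iu."""
    row_sums = counts.counts.sum(axis=1)
    support = row_sums > 0
    probs = np.zeros_like(counts.counts, dtype=float)
    probs[support] = counts.counts[support] / row_sums[support, None]
    return TransitionMatrix(
        probs=probs, state_space=counts.state_space, row_support=support
    )


# ---------------------------------------------------------------------------
# Likelihood, parameter counting, BIC
# ---------------------------------------------------------------------------


def log_likelihood(
    cohort: Iterable[BoutEthogram],
    matrix: TransitionMatrix,
    return_offending: bool = False,
):
    """Sum of log transition probabilities over all per-fly bout pairs (nats).

    An observed transition with zero model probability yields ``-inf``;
    with ``return_offending`` the zero-probability transitions are listed as
    (fly_index, position, state_i, state_j).
    """
    space = matrix.state_space
    total = 0.0
    offending: list[tuple[int, int, int, int]] = []
    for f, etho in enumerate(cohort):
        idx = space.state_indices(etho)
        if idx.size < 2:
            continue
        p = matrix.probs[idx[:-1], idx[1:]]
        zero = p <= 0.0
        if zero.any():
            for t in np.flatnonzero(zero):
                offending.append((f, int(t), int(idx[t]), int(idx[t + 1])))
            total = -math.inf
        if np.isfinite(total):
            total += float(np.log(p).sum())
    if return_offending:
        return total, offending
    return total


def count_free_parameters(
    matrix: TransitionMatrix, convention: str = "structural"
) -> int:
    """Free-parameter count of an unconstrained transition matrix.

    structural: per supported row, all structurally allowed entries
    (v minus the row's same-action block width) minus one normalization.
    observed: strictly positive entries minus one per supported row.
    """
    space = matrix.state_space
    support = matrix.row_support
    if convention == "structural":
        allowed_per_row = space.v - space.n_bins
        return int(support.sum()) * (allowed_per_row - 1)
    if convention == "observed":
        return int((matrix.probs > 0).sum()) - int(support.sum())
    raise ModelError(f"unknown parameter convention {convention!r}")


@dataclass(frozen=True)
class ModelScore:
    log_likelihood: float
    k: int
    n: int
    bic: float
    convention: str

    def __post_init__(self) -> None:
        expected = math.log(self.n) * self.k - 2.0 * self.log_likelihood
        if math.isfinite(self.bic) or math.isfinite(expected):
            if self.bic != expected:
                raise ModelError("bic must equal ln(n)*k - 2*logL exactly")


def bic_score(
    cohort: Sequence[BoutEthogram],
    matrix: TransitionMatrix,
    convention: str = "structural",
) -> ModelScore:
    """Score ``matrix`` on ``cohort``: BIC = ln(n)*k - 2*lnL (lower is better).

    ``k`` is the matrix's intrinsic ``free_parameters`` when set (constrained
    null models), otherwise derived from matrix structure per ``convention``.
    A -inf likelihood propagates to +inf BIC.
    """
    counts = count_transitions(cohort, matrix.state_space)
    n = counts.n_total
    if n < 1:
        raise ModelError("need at least one observed transition")
    ll = log_likelihood(cohort, matrix)
    if matrix.free_parameters is not None:
        k = matrix.free_parameters
    else:
        k = count_free_parameters(matrix, convention)
    bic = math.log(n) * k - 2.0 * ll
    return ModelScore(log_likelihood=ll, k=k, n=n, bic=bic, convention=convention)


def rank_models(scores: dict[str, ModelScore]) -> list[str]:
    """Model names ordered by ascending BIC (best first)."""
    return sorted(scores, key=lambda name: scores[name].bic)


# ---------------------------------------------------------------------------
# Phase splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhasePartition:
    rule: str
    boundary_min: Optional[float]
    early: tuple[BoutEthogram, ...]
    late: tuple[BoutEthogram, ...]


def _split_at_time(etho: BoutEthogram, boundary_s: float):
    """Split by bout start time; a bout straddling the boundary goes to the
    phase containing its start."""
    n_early = int((etho.start_times < boundary_s).sum())
    return etho[:n_early] if n_early else None, etho[n_early:] if n_early < len(etho) else None


def half_bout_boundary(cohort: Sequence[BoutEthogram]) -> float:
    """Cohort-average time (minutes) at which each fly has performed half of
    its bouts."""
    times = []
    for etho in cohort:
        half = math.ceil(etho.n_bouts / 2)
        times.append(float(etho.durations[:half].sum()))
    return float(np.mean(times)) / 60.0


def split_phases(
    cohort: Sequence[BoutEthogram],
    rule: str = "half-bouts",
    boundary_min: Optional[float] = None,
    n_edge_bouts: int = 200,
) -> PhasePartition:
    """Partition each fly's record into early and late phases.

    rules:
      fixed-time   -- split at ``boundary_min`` minutes (bout start time).
      half-bouts   -- fixed-time split at the cohort-average half-bout time.
      edge-bouts   -- early = first ``n_edge_bouts`` bouts, late = last.
      thirds       -- early = first third of bouts, late = last third.
    """
    if not cohort:
        raise ModelError("empty cohort")
    early: list[BoutEthogram] = []
    late: list[BoutEthogram] = []
    boundary: Optional[float] = None
    if rule in ("fixed-time", "half-bouts"):
        if rule == "half-bouts":
            boundary = half_bout_boundary(cohort)
        else:
            if boundary_min is None:
                raise ModelError("fixed-time rule requires boundary_min")
            boundary = float(boundary_min)
        for etho in cohort:
            e, l = _split_at_time(etho, boundary * 60.0)
            if e is not None:
                early.append(e)
            if l is not None:
                late.append(l)
    elif rule == "edge-bouts":
        for etho in cohort:
            n = etho.n_bouts
            if n < 2 * n_edge_bouts:
                warnings.warn(
                    f"fly {etho.fly_id!r}: {n} bouts < 2*{n_edge_bouts}; "
                    "early/late windows truncated and may overlap",
                    stacklevel=2,
                )
            m = min(n_edge_bouts, n)
            early.append(etho[:m])
            late.append(etho[-m:])
    elif rule == "thirds":
        for etho in cohort:
            third = etho.n_bouts // 3
            if third < 1:
                warnings.warn(f"fly {etho.fly_id!r}: too few bouts for thirds", stacklevel=2)
                continue
            early.append(etho[:third])
            late.append(etho[-third:])
    else:
        raise ModelError(f"unknown phase rule {rule!r}")
    return PhasePartition(
        rule=rule, boundary_min=boundary, early=tuple(early), late=tuple(late)
    )


# ---------------------------------------------------------------------------
# Matrix comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatrixComparison:
    residual: np.ndarray
    n_joint_nonzero: int
    below_threshold: dict[float, tuple[int, float]]  # threshold -> (count, fraction)


def compare_matrices(
    m1: TransitionMatrix,
    m2: TransitionMatrix,
    thresholds: Sequence[float] = (0.05, 0.01),
) -> MatrixComparison:
    """Elementwise residual m1 - m2 with the fraction of jointly non-zero
    entries whose |residual| falls below each threshold."""
    if m1.state_space != m2.state_space:
        raise ModelError("matrices live on different state spaces")
    residual = m1.probs - m2.probs
    joint = (m1.probs > 0) & (m2.probs > 0)
    n_joint = int(joint.sum())
    below: dict[float, tuple[int, float]] = {}
    for thr in thresholds:
        cnt = int((np.abs(residual[joint]) < thr).sum())
        below[float(thr)] = (cnt, cnt / n_joint if n_joint else math.nan)
    return MatrixComparison(
        residual=residual, n_joint_nonzero=n_joint, below_threshold=below
    )
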