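"""Permutation null transition models, analytic and Monte-Carlo.

Two nulls factor the observed bout statistics:

* duration-permuted -- keeps the action-order transition structure but makes
  duration categories independent of history: entry ((a_i, c) -> (a_j, d)) =
  P(a_j | a_i) * P(d | a_j).
* order-permuted -- keeps only state marginals: every admissible entry of a
  row is proportional to the destination state's marginal probability.

Both are the infinite-permutation limits of shuffling, respectively, duration
category labels within each action (per fly) and bout order (per fly); the
Monte-Carlo constructor performs those shuffles explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ethogram import BoutEthogram
from .markov import (
    ModelError,
    StateSpace,
    TransitionCounts,
    TransitionMatrix,
    mle_transition_matrix,
)


@dataclass(frozen=True)
class MarginalStatistics:
    """Joint marginal summaries of a binned cohort used by both nulls."""

    state_space: StateSpace
    action_transition: np.ndarray  # n_actions x n_actions, row-stochastic, zero diagonal
    duration_given_action: np.ndarray  # n_actions x n_bins rows P(cat | action)
    state_marginal: np.ndarray  # length-v bout state frequencies
    duration_marginal: np.ndarray  # length-n_bins global category frequencies
    action_row_support: np.ndarray  # which action rows had >= 1 outgoing transition


def marginal_statistics(
    cohort: Sequence[BoutEthogram], space: StateSpace
) -> MarginalStatistics:
    """Extract action-level transition probabilities, per-action duration
    category frequencies, and state/category marginals from a cohort."""
    if not cohort:
        raise ModelError("empty cohort")
    na, nb, v = space.n_actions, space.n_bins, space.v
    state_counts = np.zeros(v)
    action_counts = np.zeros((na, na))
    for etho in cohort:
        idx = space.state_indices(etho)
        np.add.at(state_counts, idx, 1)
        ai = idx // nb
        if ai.size >= 2:
            np.add.at(action_counts, (ai[:-1], ai[1:]), 1)
    if state_counts.sum() == 0:
        raise ModelError("cohort contains no bouts")
    row_sums = action_counts.sum(axis=1)
    support = row_sums > 0
    action_transition = np.zeros_like(action_counts)
    action_transition[support] = action_counts[support] / row_sums[support, None]
    per_action = state_counts.reshape(na, nb)
    action_totals = per_action.sum(axis=1)
    duration_given_action = np.zeros((na, nb))
    seen = action_totals > 0
    duration_given_action[seen] = per_action[seen] / action_totals[seen, None]
    absent = [space.actions[i] for i in np.flatnonzero(~seen)]
    if absent:
        import warnings

        warnings.warn(f"actions with zero bouts excluded: {absent}", stacklevel=2)
    return MarginalStatistics(
        state_space=space,
        action_transition=action_transition,
        duration_given_action=duration_given_action,
        state_marginal=state_counts / state_counts.sum(),
        duration_marginal=per_action.sum(axis=0) / state_counts.sum(),
        action_row_support=support,
    )


def _null_free_parameters_duration(stats: MarginalStatistics, duration: str) -> int:
    """Structural parameter count of the duration-permuted null: the action
    matrix's free entries plus the duration-category distributions."""
    na, nb = stats.state_space.n_actions, stats.state_space.n_bins
    k_action = int(stats.action_row_support.sum()) * (na - 2) if na > 1 else 0
    if duration == "conditional":
        return k_action + na * (nb - 1)
    return k_action + (nb - 1)


def duration_permuted_null(
    stats: MarginalStatistics,
    space: Optional[StateSpace] = None,
    duration: str = "conditional",
) -> TransitionMatrix:
    """Analytic duration-permuted null.

    Entry ((a_i, c), (a_j, d)) = P(a_j | a_i) * P(d | a_j); with
    ``duration="global"`` the category factor is the global category marginal
    P(d) instead of the destination-action-conditional one.
    """
    space = space or stats.state_space
    if space != stats.state_space:
        raise ModelError("state space does not match the marginal statistics")
    na, nb = space.n_actions, space.n_bins
    if duration == "conditional":
        dur = stats.duration_given_action  # (na, nb), indexed by destination action
    elif duration == "global":
        dur = np.broadcast_to(stats.duration_marginal, (na, nb))
    else:
        raise ModelError(f"unknown duration factor {duration!r}")
    # probs[(ai, c), (aj, d)] = A[ai, aj] * dur[aj, d]
    probs = np.einsum("ij,jd->ijd", stats.action_transition, dur)
    probs = np.repeat(probs.reshape(na, na * nb), nb, axis=0)
    support = np.repeat(stats.action_row_support, nb)
    return TransitionMatrix(
        probs=probs,
        state_space=space,
        row_support=support,
        free_parameters=_null_free_parameters_duration(stats, duration),
    )


def order_permuted_null(
    stats: MarginalStatistics,
    space: Optional[StateSpace] = None,
    renormalize_self: bool = True,
) -> TransitionMatrix:
    """Analytic order-permuted null: every admissible entry of row (a_i, c)
    is proportional to the destination state's marginal probability.

    Same-action columns are structurally forbidden (discretized bout streams
    never self-transition) and are zeroed; with ``renormalize_self`` (default)
    each row is renormalized over its admissible mass, otherwise rows are left
    sub-stochastic at the raw marginal values.
    """
    space = space or stats.state_space
    if space != stats.state_space:
        raise ModelError("state space does not match the marginal statistics")
    v, nb = space.v, space.n_bins
    probs = np.tile(stats.state_marginal, (v, 1))
    probs[space.same_action_mask()] = 0.0
    row_mass = probs.sum(axis=1)
    support = row_mass > 0
    if renormalize_self:
        probs[support] /= row_mass[support, None]
    probs[~support] = 0.0
    return TransitionMatrix(
        probs=probs,
        state_space=space,
        row_support=support,
        free_parameters=v - 1,
        substochastic=not renormalize_self,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo permutation nulls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonteCarloNull:
    """Permutation-null estimate with per-entry uncertainty.

    ``mean``/``se`` average the per-permutation MLE matrices (standard error
    of the mean); ``pooled`` row-normalizes counts summed over permutations,
    which is the consistent estimator of the infinite-permutation analytic
    limit. ``kind``, ``n_perm`` and ``seed`` record provenance.
    """

    kind: str
    n_perm: int
    seed: Optional[int]
    state_space: StateSpace
    mean: np.ndarray
    se: np.ndarray
    pooled: TransitionMatrix


def _permuted_indices(
    idx: np.ndarray, space: StateSpace, kind: str, rng: np.random.Generator
) -> np.ndarray:
    nb = space.n_bins
    if kind == "duration":
        # shuffle category labels among each action's bouts; order unchanged
        out = idx.copy()
        ai = idx // nb
        for a in np.unique(ai):
            pos = np.flatnonzero(ai == a)
            if pos.size > 1:
                cats = idx[pos] % nb
                out[pos] = a * nb + rng.permutation(cats)
        return out
    if kind == "order":
        return idx[rng.permutation(idx.size)]
    raise ModelError(f"unknown permutation kind {kind!r}")


def monte_carlo_null(
    cohort: Sequence[BoutEthogram],
    space: StateSpace,
    kind: str,
    n_perm: int,
    seed: Optional[int] = None,
) -> MonteCarloNull:
    """Estimate a null transition matrix by explicit within-fly permutation.

    duration kind: per fly, category labels are permuted within each action's
    bouts (bout order preserved). order kind: per fly, bout order is permuted;
    same-action adjacencies created by the shuffle are skipped when counting
    (run-length convention: a discretized stream cannot self-transition).
    """
    if n_perm < 1:
        raise ModelError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    fly_indices = [space.state_indices(etho) for etho in cohort]
    v = space.v
    total_counts = np.zeros((v, v), dtype=np.int64)
    mean_acc = np.zeros((v, v))
    sq_acc = np.zeros((v, v))
    nb = space.n_bins
    for _ in range(n_perm):
        counts = np.zeros((v, v), dtype=np.int64)
        for idx in fly_indices:
            perm = _permuted_indices(idx, space, kind, rng)
            if perm.size < 2:
                continue
            src, dst = perm[:-1], perm[1:]
            if kind == "order":
                ok = (src // nb) != (dst // nb)
                src, dst = src[ok], dst[ok]
            np.add.at(counts, (src, dst), 1)
        total_counts += counts
        row = counts.sum(axis=1)
        probs = np.zeros((v, v))
        sup = row > 0
        probs[sup] = counts[sup] / row[sup, None]
        mean_acc += probs
        sq_acc += probs * probs
    mean = mean_acc / n_perm
    var = np.maximum(sq_acc / n_perm - mean * mean, 0.0)
    if n_perm > 1:
        var *= n_perm / (n_perm - 1)
    se = np.sqrt(var / n_perm)
    pooled = mle_transition_matrix(
        TransitionCounts(counts=total_counts, state_space=space)
    )
    return MonteCarloNull(
        kind=kind,
        n_perm=n_perm,
        seed=seed,
        state_space=space,
        mean=mean,
        se=se,
        pooled=pooled,
    )
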