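"""Nonstationary Markov renewal process (MRP) simulation.

State transitions follow a time-varying transition matrix M(t): a convex
combination of an early and a late matrix for t <= t_switch (minutes), and
the late matrix afterwards. Bout durations are drawn per state from
state-specific samplers (empirical pools by default), which do not change
over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import ndtri

from .ethogram import BoutEthogram
from .markov import (
    ModelError,
    StateSpace,
    TransitionMatrix,
    count_transitions,
    mle_transition_matrix,
)

DEFAULT_SWITCH_MIN = 13.0
DEFAULT_EDGE_BOUTS = 200
DEFAULT_TOTAL_MIN = 27.8


class SimulationError(RuntimeError):
    pass


class EmpiricalDurationSampler:
    """Draw durations uniformly from an observed pool."""

    kind = "empirical"

    def __init__(self, pool: Sequence[float]):
        pool = np.asarray(pool, dtype=float)
        if pool.size == 0:
            raise ModelError("empty duration pool")
        if (pool <= 0).any():
            raise ModelError("durations must be positive")
        self.pool = pool

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.pool[rng.integers(self.pool.size)])


class TruncatedLogNormalSampler:
    """Log-normal durations restricted to a quantile band [q_lo, q_hi).

    Used by the synthetic ground truth so that a state's duration always
    falls inside its own duration category.
    """

    kind = "trunc_lognorm"

    def __init__(self, mu: float, sigma: float, q_lo: float = 0.0, q_hi: float = 1.0):
        if not 0.0 <= q_lo < q_hi <= 1.0:
            raise ModelError("need 0 <= q_lo < q_hi <= 1")
        if sigma <= 0:
            raise ModelError("sigma must be positive")
        self.mu, self.sigma, self.q_lo, self.q_hi = mu, sigma, q_lo, q_hi

    def sample(self, rng: np.random.Generator) -> float:
        u = rng.uniform(self.q_lo, self.q_hi)
        u = min(max(u, 1e-12), 1 - 1e-12)
        return float(np.exp(self.mu + self.sigma * ndtri(u)))


@dataclass(frozen=True)
class MRPModel:
    """Early/late transition matrices, switch time, per-state duration
    samplers, and the initial state distribution."""

    state_space: StateSpace
    m_early: TransitionMatrix
    m_late: TransitionMatrix
    duration_samplers: Mapping[int, object]
    initial_distribution: np.ndarray
    t_switch_min: float = DEFAULT_SWITCH_MIN

    def __post_init__(self) -> None:
        if self.m_early.state_space != self.state_space or (
            self.m_late.state_space != self.state_space
        ):
            raise ModelError("early/late matrices must share the model state space")
        if self.t_switch_min <= 0:
            raise ModelError("t_switch must be positive")
        p = np.asarray(self.initial_distribution, dtype=float)
        if p.shape != (self.state_space.v,) or (p < 0).any():
            raise ModelError("initial_distribution must be a length-v probability vector")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ModelError("initial_distribution must sum to 1 within 1e-12")
        object.__setattr__(self, "initial_distribution", p)
        for s in np.flatnonzero(p > 0):
            if int(s) not in self.duration_samplers:
                raise ModelError(f"no duration sampler for reachable state {int(s)}")


def interpolate_transition_matrix(model: MRPModel, t_min: float) -> TransitionMatrix:
    """M(t): convex combination of early/late for t <= t_switch, late after."""
    if t_min < 0:
        raise ModelError("time must be non-negative")
    ts = model.t_switch_min
    if t_min > ts:
        return model.m_late
    if t_min == 0:
        return model.m_early
    w = (ts - t_min) / ts
    probs = w * model.m_early.probs + (1.0 - w) * model.m_late.probs
    support = probs.sum(axis=1) > 0
    probs[support] /= probs[support].sum(axis=1, keepdims=True)
    return TransitionMatrix(
        probs=probs, state_space=model.state_space, row_support=support
    )


def build_mrp_from_cohort(
    cohort: Sequence[BoutEthogram],
    space: StateSpace,
    n_edge_bouts: int = DEFAULT_EDGE_BOUTS,
    t_switch_min: float = DEFAULT_SWITCH_MIN,
) -> MRPModel:
    """Fit an MRP to a cohort: M_early from each fly's first ``n_edge_bouts``
    bouts, M_late from the last; duration pools per state from the whole
    recordings; initial distribution from first-bout state frequencies."""
    if not cohort:
        raise ModelError("empty cohort")
    early, late = [], []
    for etho in cohort:
        n = etho.n_bouts
        if n < 2 * n_edge_bouts:
            warnings.warn(
                f"fly {etho.fly_id!r}: {n} bouts < 2*{n_edge_bouts}; edge windows overlap",
                stacklevel=2,
            )
        m = min(n_edge_bouts, n)
        early.append(etho[:m])
        late.append(etho[-m:])
    m_early = mle_transition_matrix(count_transitions(early, space))
    m_late = mle_transition_matrix(count_transitions(late, space))
    pools: dict[int, list[np.ndarray]] = {}
    init = np.zeros(space.v)
    for etho in cohort:
        idx = space.state_indices(etho)
        init[idx[0]] += 1
        for s in np.unique(idx):
            pools.setdefault(int(s), []).append(etho.durations[idx == s])
    samplers = {
        s: EmpiricalDurationSampler(np.concatenate(chunks))
        for s, chunks in pools.items()
    }
    return MRPModel(
        state_space=space,
        m_early=m_early,
        m_late=m_late,
        duration_samplers=samplers,
        initial_distribution=init / init.sum(),
        t_switch_min=t_switch_min,
    )


@dataclass(frozen=True)
class SimulatedEthogram:
    ethogram: BoutEthogram
    state_sequence: np.ndarray
    start_times_min: np.ndarray  # start time of each bout, minutes
    seed: Optional[int] = None


def simulate_ethogram(
    model: MRPModel,
    total_time_min: float = DEFAULT_TOTAL_MIN,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    fly_id: Optional[str] = None,
) -> SimulatedEthogram:
    """Generate one synthetic bout ethogram of exactly ``total_time_min``.

    The initial state is drawn from the model's initial distribution; each
    step draws the current state's duration, advances the clock, and draws
    the next state from the row of M(t) at the new elapsed time. The final
    bout is truncated so the total time is exact.
    """
    if total_time_min <= 0:
        raise ModelError("total_time must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    space = model.state_space
    nb = space.n_bins
    early, late = model.m_early.probs, model.m_late.probs
    ts = model.t_switch_min
    total_s = total_time_min * 60.0
    state = int(rng.choice(space.v, p=model.initial_distribution))
    states: list[int] = []
    durations: list[float] = []
    starts_min: list[float] = []
    clock = 0.0  # seconds
    while clock < total_s - 1e-12:
        sampler = model.duration_samplers.get(state)
        if sampler is None:
            raise SimulationError(
                f"no duration sampler for state {state} at t={clock / 60:.3f} min"
            )
        d = min(sampler.sample(rng), total_s - clock)
        states.append(state)
        durations.append(d)
        starts_min.append(clock / 60.0)
        clock += d
        if clock >= total_s - 1e-12:
            break
        t_min = clock / 60.0
        if t_min > ts:
            row = late[state]
        else:
            w = (ts - t_min) / ts
            row = w * early[state] + (1.0 - w) * late[state]
        mass = row.sum()
        if mass <= 0:
            raise SimulationError(
                f"absorbing/unsupported state {state} at t={t_min:.3f} min"
            )
        state = int(rng.choice(space.v, p=row / mass))
    idx = np.asarray(states, dtype=np.int64)
    etho = BoutEthogram(
        actions=np.asarray(space.actions, dtype="<U2")[idx // nb],
        durations=np.asarray(durations),
        categories=(idx % nb) if nb > 1 else None,
        fly_id=fly_id,
    )
    return SimulatedEthogram(
        ethogram=etho,
        state_sequence=idx,
        start_times_min=np.asarray(starts_min),
        seed=seed,
    )
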