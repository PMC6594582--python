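"""Ground-truth synthetic cohorts for end-to-end pipeline validation.

Builds a nonstationary Markov renewal generator with known block-structured
transition matrices (high within-motif mass, duration-category coupling, a
slow anterior-to-posterior drift), simulates frame-level label streams from
it, and optionally injects sub-threshold classifier-artifact noise — so every
analysis stage can be checked against known parameters without any recorded
data.

Duration families are log-normal stand-ins whose modes mimic the qualitative
shapes of observed bout-duration distributions (anterior actions near 1 s,
abdomen/wing near 0.25 s); they are emulation defaults, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import ndtri

from .ethogram import (
    ALPHABET,
    BinningScheme,
    BoutEthogram,
    FrameEthogram,
    GROOMING_ACTIONS,
)
from .markov import StateSpace, TransitionMatrix, build_state_space
from .mrp import (
    DEFAULT_SWITCH_MIN,
    DEFAULT_TOTAL_MIN,
    MRPModel,
    TruncatedLogNormalSampler,
    simulate_ethogram,
)

ANTERIOR_ACTIONS = ("f", "h")
POSTERIOR_ACTIONS = ("a", "b", "w")


@dataclass(frozen=True)
class DurationSpec:
    """Log-normal duration family: mode = exp(mu - sigma^2)."""

    mu: float
    sigma: float

    @classmethod
    def from_mode(cls, mode: float, sigma: float = 0.7) -> "DurationSpec":
        return cls(mu=math.log(mode) + sigma * sigma, sigma=sigma)


def default_duration_specs() -> dict[str, DurationSpec]:
    return {
        "f": DurationSpec.from_mode(1.0),
        "h": DurationSpec.from_mode(1.0),
        "a": DurationSpec.from_mode(0.25),
        "w": DurationSpec.from_mode(0.25),
        "b": DurationSpec.from_mode(0.5),
        "wk": DurationSpec.from_mode(0.5, sigma=0.8),
    }


@dataclass(frozen=True)
class Drift:
    """Early-to-late tilts of the generator's block structure."""

    t_switch_min: float = DEFAULT_SWITCH_MIN
    anterior_mass_late: float = 0.55
    posterior_mass_late: float = 0.80
    wk_to_anterior_early: float = 0.75
    wk_to_anterior_late: float = 0.15


@dataclass(frozen=True)
class GroundTruthSpec:
    n_flies: int = 92
    total_time_min: float = DEFAULT_TOTAL_MIN
    actions: tuple[str, ...] = GROOMING_ACTIONS
    n_bins: int = 3
    anterior_block_mass: float = 0.88
    posterior_block_mass: float = 0.70
    duration_specs: Mapping[str, DurationSpec] = field(
        default_factory=default_duration_specs
    )
    drift: Optional[Drift] = field(default_factory=Drift)
    duration_coupling: float = 0.6
    noise_rate: float = 0.0
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1 or self.total_time_min <= 0:
            raise ValueError("need n_flies >= 1 and positive total_time")
        for mass in (self.anterior_block_mass, self.posterior_block_mass):
            if not 0.0 <= mass <= 1.0:
                raise ValueError("block masses must lie in [0, 1]")
        if not 0.0 <= self.duration_coupling < 1.0:
            raise ValueError("duration_coupling must lie in [0, 1)")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")
        missing = set(self.actions) - set(self.duration_specs)
        if missing:
            raise ValueError(f"missing duration specs for {sorted(missing)}")


# ---------------------------------------------------------------------------
# Generator construction
# ---------------------------------------------------------------------------


def _action_matrix(
    actions: Sequence[str],
    anterior_mass: float,
    posterior_mass: float,
    wk_to_anterior: float,
) -> np.ndarray:
    """Block-structured action-level transition matrix (zero diagonal)."""
    na = len(actions)
    idx = {a: i for i, a in enumerate(actions)}
    ant = [a for a in actions if a in ANTERIOR_ACTIONS]
    post = [a for a in actions if a in POSTERIOR_ACTIONS]
    other = [a for a in actions if a not in ANTERIOR_ACTIONS and a not in POSTERIOR_ACTIONS]
    A = np.zeros((na, na))
    for a in actions:
        i = idx[a]
        if a in ANTERIOR_ACTIONS:
            within = [x for x in ant if x != a]
            rest = post + other
            block, rem = anterior_mass, 1.0 - anterior_mass
        elif a in POSTERIOR_ACTIONS:
            within = [x for x in post if x != a]
            rest = ant + other
            block, rem = posterior_mass, 1.0 - posterior_mass
        else:  # walking
            within, rest = [], []
            for x in ant:
                A[i, idx[x]] = wk_to_anterior / len(ant)
            for x in post:
                A[i, idx[x]] = (1.0 - wk_to_anterior) / len(post)
            continue
        if not within and block > 0:
            raise ValueError(f"row {a!r}: no within-block destination for mass {block}")
        for x in within:
            A[i, idx[x]] = block / len(within)
        if rest:
            for x in rest:
                A[i, idx[x]] = rem / len(rest)
        elif rem > 1e-12:
            raise ValueError(f"row {a!r}: leftover mass {rem} has no destination")
    return A


def _category_kernel(space: StateSpace, coupling: float) -> np.ndarray:
    """K[src_cat, dst_action, dst_cat] = P(dst category | src category, dst action).

    Symmetric same-category coupling into anterior destinations, asymmetric
    (shifted toward longer categories) into posterior ones, uniform into
    walking; coupling = 0 gives duration-independent transitions.
    """
    nb, na = space.n_bins, space.n_actions
    K = np.full((nb, na, nb), 1.0 / nb)
    if coupling == 0 or nb == 1:
        return K
    for j, action in enumerate(space.actions):
        for c in range(nb):
            if action in ANTERIOR_ACTIONS:
                target = c  # symmetric: stay in the same duration category
            elif action in POSTERIOR_ACTIONS:
                # asymmetric cyclic shift: couples categories directionally
                # without starving any category's marginal occupancy
                target = (c + 1) % nb
            else:
                continue
            K[c, j] = (1.0 - coupling) / nb
            K[c, j, target] += coupling
    return K


def _expand_action_matrix(
    A: np.ndarray, space: StateSpace, coupling: float
) -> TransitionMatrix:
    na, nb, v = space.n_actions, space.n_bins, space.v
    K = _category_kernel(space, coupling)
    # probs[(ai, c), (aj, d)] = A[ai, aj] * K[c, aj, d]
    probs = np.einsum("ij,cjd->icjd", A, K).reshape(v, v)
    return TransitionMatrix(
        probs=probs, state_space=space, row_support=np.ones(v, dtype=bool)
    )


def true_binning_scheme(spec: GroundTruthSpec) -> BinningScheme:
    """Analytic equal-mass quantile edges of each action's duration family."""
    if spec.n_bins == 1:
        return BinningScheme(n_bins=1, edges={})
    edges = {}
    for action in spec.actions:
        ds = spec.duration_specs[action]
        edges[action] = tuple(
            float(np.exp(ds.mu + ds.sigma * ndtri(k / spec.n_bins)))
            for k in range(1, spec.n_bins)
        )
    return BinningScheme(n_bins=spec.n_bins, edges=edges)


def make_ground_truth_mrp(spec: GroundTruthSpec) -> MRPModel:
    """Compose the ground-truth MRP: early/late block matrices, truncated
    log-normal per-state duration samplers, anterior-weighted initial states."""
    space = build_state_space(spec.actions, spec.n_bins)
    drift = spec.drift or Drift()
    a_early = _action_matrix(
        spec.actions,
        spec.anterior_block_mass,
        spec.posterior_block_mass,
        drift.wk_to_anterior_early,
    )
    if spec.drift is None:
        a_late = a_early
    else:
        a_late = _action_matrix(
            spec.actions,
            drift.anterior_mass_late,
            drift.posterior_mass_late,
            drift.wk_to_anterior_late,
        )
    m_early = _expand_action_matrix(a_early, space, spec.duration_coupling)
    m_late = _expand_action_matrix(a_late, space, spec.duration_coupling)
    samplers = {}
    for s, (action, cat) in enumerate(space.states):
        ds = spec.duration_specs[action]
        samplers[s] = TruncatedLogNormalSampler(
            ds.mu, ds.sigma, cat / spec.n_bins, (cat + 1) / spec.n_bins
        )
    init = np.zeros(space.v)
    for action in ANTERIOR_ACTIONS:
        if action in spec.actions:
            for c in range(spec.n_bins):
                init[space.index(action, c)] = 1.0
    if init.sum() == 0:
        init[:] = 1.0
    return MRPModel(
        state_space=space,
        m_early=m_early,
        m_late=m_late,
        duration_samplers=samplers,
        initial_distribution=init / init.sum(),
        t_switch_min=drift.t_switch_min,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def rasterize(
    etho: BoutEthogram, frame_rate: float, n_frames: Optional[int] = None
) -> FrameEthogram:
    """Render a bout ethogram to frame labels: durations round to whole
    frames (minimum 1); the stream is clipped/padded to ``n_frames``."""
    counts = np.maximum(np.rint(etho.durations * frame_rate).astype(int), 1)
    labels = np.repeat(etho.actions, counts)
    if n_frames is not None:
        if labels.size > n_frames:
            labels = labels[:n_frames]
        elif labels.size < n_frames:
            labels = np.concatenate(
                [labels, np.full(n_frames - labels.size, labels[-1], dtype=labels.dtype)]
            )
    return FrameEthogram(labels=labels, frame_rate=frame_rate, fly_id=etho.fly_id)


@dataclass(frozen=True)
class NoiseInjection:
    frames: FrameEthogram
    mask: np.ndarray  # True where a frame was overwritten

    @property
    def corrupted_fraction(self) -> float:
        return float(self.mask.mean())


def inject_label_noise(
    frames: FrameEthogram,
    noise_rate: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> NoiseInjection:
    """Overwrite random 1-4-frame spans with alien labels until roughly
    ``noise_rate`` of frames are corrupted (reproducible under seed)."""
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise_rate must lie in [0, 1)")
    n = frames.n_frames
    mask = np.zeros(n, dtype=bool)
    if noise_rate == 0.0:
        return NoiseInjection(frames=frames, mask=mask)
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = frames.labels.copy()
    target = int(round(noise_rate * n))
    candidates = [a for a in ALPHABET]
    attempts = 0
    while mask.sum() < target and attempts < 100 * target:
        attempts += 1
        pos = int(rng.integers(n))
        span = slice(pos, min(pos + int(rng.integers(1, 5)), n))
        current = labels[pos]
        alien = candidates[int(rng.integers(len(candidates)))]
        if alien == current:
            continue
        labels[span] = alien
        mask[span] = True
    return NoiseInjection(
        frames=FrameEthogram(labels=labels, frame_rate=frames.frame_rate, fly_id=frames.fly_id),
        mask=mask,
    )


@dataclass(frozen=True)
class CohortTruth:
    """A synthetic cohort together with its generating ground truth."""

    spec: GroundTruthSpec
    model: MRPModel
    binning: BinningScheme
    bout_ethograms: tuple[BoutEthogram, ...]  # clean, duration-categorized
    frame_ethograms: tuple[FrameEthogram, ...]  # rasterized (noisy if requested)
    noise_masks: tuple[np.ndarray, ...]


def generate_cohort(spec: GroundTruthSpec, rasterize_frames: bool = True) -> CohortTruth:
    """Simulate ``spec.n_flies`` independent ethograms and rasterize them to
    frame labels; per-fly seeds derive deterministically from ``spec.seed``.

    ``rasterize_frames=False`` skips the frame-level rendering (and noise
    injection) when only bout ethograms are needed.
    """
    model = make_ground_truth_mrp(spec)
    scheme = true_binning_scheme(spec)
    n_frames = int(round(spec.total_time_min * 60.0 * spec.frame_rate))
    bouts: list[BoutEthogram] = []
    frames: list[FrameEthogram] = []
    masks: list[np.ndarray] = []
    for i in range(spec.n_flies):
        sim = simulate_ethogram(
            model,
            total_time_min=spec.total_time_min,
            seed=spec.seed + i,
            fly_id=f"synth-{i:03d}",
        )
        etho = replace(sim.ethogram, frame_rate=spec.frame_rate)
        bouts.append(etho)
        if not rasterize_frames:
            continue
        raster = rasterize(etho, spec.frame_rate, n_frames=n_frames)
        noise = inject_label_noise(
            raster, spec.noise_rate, seed=spec.seed + 1_000_000 + i
        )
        frames.append(noise.frames)
        masks.append(noise.mask)
    return CohortTruth(
        spec=spec,
        model=model,
        binning=scheme,
        bout_ethograms=tuple(bouts),
        frame_ethograms=tuple(frames),
        noise_masks=tuple(masks),
    )
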