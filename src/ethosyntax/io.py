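"""Plain-text serialization for ethograms, schemes, matrices, and models.

Frame ethograms: one label per line with ``# key=value`` headers.
Bout ethograms: CSV ``action,duration_s,category`` with the same headers.
Matrices: CSV with ``action.category`` row/column labels (e.g. ``h.s``), or a
JSON dialect carrying the explicit state-space block. Everything round-trips
losslessly (floats via repr).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .ethogram import BinningScheme, BoutEthogram, FrameEthogram
from .markov import ModelScore, StateSpace, TransitionMatrix, build_state_space
from .mrp import EmpiricalDurationSampler, MRPModel, TruncatedLogNormalSampler

PathLike = Union[str, Path]


class ParseError(ValueError):
    def __init__(self, path: PathLike, line: int, message: str):
        self.path, self.line = str(path), line
        super().__init__(f"{path}:{line}: {message}")


def _read_lines(path: PathLike) -> list[str]:
    text = Path(path).read_text()
    # tolerate CRLF and trailing newline
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


def _parse_headers(lines: list[str]) -> tuple[dict[str, str], int]:
    headers: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        item = line.lstrip("#").strip()
        if "=" in item:
            key, _, value = item.partition("=")
            headers[key.strip()] = value.strip()
        body_start = i + 1
    return headers, body_start


def _format_headers(
    frame_rate: Optional[float], fly_id: Optional[str], extra: Optional[dict] = None
) -> list[str]:
    out = []
    if frame_rate is not None:
        out.append(f"# frame_rate={frame_rate!r}")
    if fly_id is not None:
        out.append(f"# fly_id={fly_id}")
    for key, value in (extra or {}).items():
        out.append(f"# {key}={value}")
    return out


# ---------------------------------------------------------------------------
# Frame ethograms
# ---------------------------------------------------------------------------


def write_frame_ethogram(etho: FrameEthogram, path: PathLike) -> None:
    lines = _format_headers(etho.frame_rate, etho.fly_id)
    lines.extend(etho.labels.tolist())
    Path(path).write_text("\n".join(lines) + "\n")


def read_frame_ethogram(path: PathLike) -> FrameEthogram:
    lines = _read_lines(path)
    headers, start = _parse_headers(lines)
    if "frame_rate" not in headers:
        raise ParseError(path, 1, "missing required '# frame_rate=<Hz>' header")
    labels = []
    from .ethogram import ALPHABET

    for i, line in enumerate(lines[start:], start=start + 1):
        label = line.strip()
        if not label:
            continue
        if label not in ALPHABET:
            raise ParseError(path, i, f"unknown behavior label {label!r}")
        labels.append(label)
    if not labels:
        raise ParseError(path, len(lines), "no frame labels found")
    return FrameEthogram(
        labels=np.asarray(labels),
        frame_rate=float(headers["frame_rate"]),
        fly_id=headers.get("fly_id"),
    )


# ---------------------------------------------------------------------------
# Bout ethograms
# ---------------------------------------------------------------------------


def write_bout_ethogram(
    etho: BoutEthogram, path: PathLike, extra_headers: Optional[dict] = None
) -> None:
    lines = _format_headers(etho.frame_rate, etho.fly_id, extra_headers)
    lines.append("action,duration_s,category")
    cats = etho.categories
    for i in range(etho.n_bouts):
        cat = "" if cats is None else str(int(cats[i]))
        lines.append(f"{etho.actions[i]},{float(etho.durations[i])!r},{cat}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bout_ethogram(path: PathLike) -> BoutEthogram:
    lines = _read_lines(path)
    headers, start = _parse_headers(lines)
    if start >= len(lines) or lines[start].strip() != "action,duration_s,category":
        raise ParseError(path, start + 1, "expected header 'action,duration_s,category'")
    actions, durations, categories = [], [], []
    for i, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(path, i, f"expected 3 comma-separated fields, got {len(parts)}")
        action, dur, cat = (p.strip() for p in parts)
        try:
            durations.append(float(dur))
        except ValueError:
            raise ParseError(path, i, f"bad duration {dur!r}") from None
        actions.append(action)
        categories.append(int(cat) if cat else None)
    if not actions:
        raise ParseError(path, len(lines), "no bouts found")
    has_cats = all(c is not None for c in categories)
    if not has_cats and any(c is not None for c in categories):
        raise ParseError(path, start + 1, "mixed binned/unbinned bouts")
    return BoutEthogram(
        actions=np.asarray(actions),
        durations=np.asarray(durations),
        categories=np.asarray(categories, dtype=int) if has_cats else None,
        frame_rate=float(headers["frame_rate"]) if "frame_rate" in headers else None,
        fly_id=headers.get("fly_id"),
    )


# ---------------------------------------------------------------------------
# Binning schemes
# ---------------------------------------------------------------------------


def write_binning_scheme(scheme: BinningScheme, path: PathLike) -> None:
    payload = {"n_bins": scheme.n_bins, "edges": {a: list(t) for a, t in scheme.edges.items()}}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_binning_scheme(path: PathLike) -> BinningScheme:
    payload = json.loads(Path(path).read_text())
    return BinningScheme(
        n_bins=int(payload["n_bins"]),
        edges={a: tuple(t) for a, t in payload["edges"].items()},
    )


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------


def write_transition_matrix_csv(matrix: TransitionMatrix, path: PathLike) -> None:
    labels = matrix.state_space.labels()
    lines = ["state," + ",".join(labels)]
    for label, row in zip(labels, matrix.probs):
        lines.append(label + "," + ",".join(repr(float(p)) for p in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _space_from_labels(labels: list[str]) -> StateSpace:
    actions: list[str] = []
    for lab in labels:
        action = lab.split(".")[0]
        if action not in actions:
            actions.append(action)
    n_bins = len(labels) // len(actions)
    return build_state_space(actions, n_bins)


def read_transition_matrix_csv(path: PathLike) -> TransitionMatrix:
    lines = [l for l in _read_lines(path) if l.strip()]
    header = lines[0].split(",")
    if header[0] != "state":
        raise ParseError(path, 1, "expected 'state' header cell")
    labels = header[1:]
    space = _space_from_labels(labels)
    if space.labels() != labels:
        raise ParseError(path, 1, "column labels are not a canonical state ordering")
    probs = np.zeros((space.v, space.v))
    for i, line in enumerate(lines[1 : space.v + 1]):
        parts = line.split(",")
        probs[i] = [float(p) for p in parts[1:]]
    support = probs.sum(axis=1) > 0
    return TransitionMatrix(probs=probs, state_space=space, row_support=support)


def write_transition_matrix_json(matrix: TransitionMatrix, path: PathLike) -> None:
    payload = {
        "state_space": {
            "actions": list(matrix.state_space.actions),
            "n_bins": matrix.state_space.n_bins,
            "labels": matrix.state_space.labels(),
        },
        "probs": matrix.probs.tolist(),
        "row_support": matrix.row_support.tolist(),
        "free_parameters": matrix.free_parameters,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_transition_matrix_json(path: PathLike) -> TransitionMatrix:
    payload = json.loads(Path(path).read_text())
    space = build_state_space(
        payload["state_space"]["actions"], payload["state_space"]["n_bins"]
    )
    return TransitionMatrix(
        probs=np.asarray(payload["probs"]),
        state_space=space,
        row_support=np.asarray(payload["row_support"], dtype=bool),
        free_parameters=payload.get("free_parameters"),
    )


def write_model_score(score: ModelScore, path: PathLike) -> None:
    payload = {
        "loglik": score.log_likelihood,
        "k": score.k,
        "n": score.n,
        "bic": score.bic,
        "convention": score.convention,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def model_score_dict(score: ModelScore) -> dict:
    return {
        "loglik": score.log_likelihood,
        "k": score.k,
        "n": score.n,
        "bic": score.bic,
        "convention": score.convention,
    }


# ---------------------------------------------------------------------------
# MRP models
# ---------------------------------------------------------------------------


def _sampler_payload(sampler) -> dict:
    if isinstance(sampler, EmpiricalDurationSampler):
        return {"kind": "empirical", "pool": sampler.pool.tolist()}
    if isinstance(sampler, TruncatedLogNormalSampler):
        return {
            "kind": "trunc_lognorm",
            "mu": sampler.mu,
            "sigma": sampler.sigma,
            "q_lo": sampler.q_lo,
            "q_hi": sampler.q_hi,
        }
    raise TypeError(f"cannot serialize sampler of type {type(sampler).__name__}")


def _sampler_from_payload(payload: dict):
    if payload["kind"] == "empirical":
        return EmpiricalDurationSampler(payload["pool"])
    if payload["kind"] == "trunc_lognorm":
        return TruncatedLogNormalSampler(
            payload["mu"], payload["sigma"], payload["q_lo"], payload["q_hi"]
        )
    raise ValueError(f"unknown sampler kind {payload['kind']!r}")


def write_mrp_model(model: MRPModel, path: PathLike) -> None:
    payload = {
        "state_space": {
            "actions": list(model.state_space.actions),
            "n_bins": model.state_space.n_bins,
        },
        "t_switch_min": model.t_switch_min,
        "m_early": model.m_early.probs.tolist(),
        "m_late": model.m_late.probs.tolist(),
        "initial_distribution": model.initial_distribution.tolist(),
        "duration_samplers": {
            str(s): _sampler_payload(smp) for s, smp in model.duration_samplers.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_mrp_model(path: PathLike) -> MRPModel:
    payload = json.loads(Path(path).read_text())
    space = build_state_space(
        payload["state_space"]["actions"], payload["state_space"]["n_bins"]
    )

    def matrix(key: str) -> TransitionMatrix:
        probs = np.asarray(payload[key])
        return TransitionMatrix(
            probs=probs, state_space=space, row_support=probs.sum(axis=1) > 0
        )

    return MRPModel(
        state_space=space,
        m_early=matrix("m_early"),
        m_late=matrix("m_late"),
        duration_samplers={
            int(s): _sampler_from_payload(p)
            for s, p in payload["duration_samplers"].items()
        },
        initial_distribution=np.asarray(payload["initial_distribution"]),
        t_switch_min=float(payload["t_switch_min"]),
    )
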