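"""Greedy Granger-style inference of higher-order neighbor sets.

A candidate complex c is declared *non-causal* for node u when removing it
from the candidate set does not worsen the held-out one-step prediction
error of u's reservoir by more than a threshold eps_e.  The search starts
from a coarse candidate set (by default the single complex of all
variables), and alternates two moves until a fixed point:

* deletion — drop any candidate whose removal does not hurt prediction;
* refinement — replace a d-dimensional complex by its (d-1)-dimensional
  facets when the finer wiring predicts at least as well, i.e. the joint
  term was actually separable.

Each candidate set is scored by training a block-structured reservoir on
the first part of the data and measuring the mean absolute one-step error
on a held-out tail; the score is the median over a few reservoir
realisations to damp the randomness of the fixed matrices (median).  Variables are
standardised (zero mean, unit variance over the scored window) before they
reach the reservoir, so the tanh units operate in their sensitive range
regardless of the system's amplitude; errors are therefore reported in
units of the target variable's standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reservoir import ReservoirConfig, build_node_reservoir, drive, fit_readout
from .structures import (
    Complex,
    HigherOrderStructure,
    canonical_order,
    canonicalize,
)
from .systems import Trajectory

__all__ = [
    "InferenceConfig",
    "InferenceTrace",
    "TraceRecord",
    "candidate_error",
    "is_noncausal",
    "infer_higher_order_neighbors",
    "infer_full_structure",
    "subsystem_coupling_scan",
    "estimate_epsilon",
]


def _default_inference_reservoir() -> ReservoirConfig:
    # scoring-oriented operating point: memoryless-leaning dynamics (full
    # leak, modest spectral radius) so hidden states track the current
    # input and the non-causality test reflects direct dependence rather
    # than history-based reconstruction of excluded variables
    return ReservoirConfig(
        n=900,
        leak=1.0,
        spectral_radius=0.4,
        input_scale=1.0,
        bias_scale=0.5,
        ridge=1e-6,
        washout=100,
    )


@dataclass
class InferenceConfig:
    """Knobs of the greedy search.

    ``epsilon`` is the error slack of the non-causality test (None selects
    it automatically as 5x the standard error of the initial candidate
    error across ``epsilon_replicates`` reservoir realisations — useful for
    noisy data); ``holdout_fraction`` is the tail of the training window
    reserved for the one-step error; ``n_realizations`` averages the error
    over independently drawn reservoirs.
    """

    epsilon: float | None = 1e-7
    holdout_fraction: float = 0.2
    n_realizations: int = 5
    epsilon_replicates: int = 5
    max_iterations: int = 20
    block_size: int | None = None
    shared_blocks: bool = True
    reservoir: ReservoirConfig = field(default_factory=_default_inference_reservoir)

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")


@dataclass
class TraceRecord:
    action: str  # init | delete | split
    candidates: tuple[Complex, ...]
    error: float
    accepted: bool
    detail: str = ""


@dataclass
class InferenceTrace:
    node: str
    records: list[TraceRecord] = field(default_factory=list)
    epsilon: float = 0.0
    converged: bool = True

    def append(self, *a, **kw) -> None:
        self.records.append(TraceRecord(*a, **kw))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "action": [r.action for r in self.records],
                "candidates": [repr(list(r.candidates)) for r in self.records],
                "error": [r.error for r in self.records],
                "accepted": [r.accepted for r in self.records],
                "detail": [r.detail for r in self.records],
            }
        )


def _split_index(T: int, holdout_fraction: float) -> int:
    return int(round(T * (1.0 - holdout_fraction)))


def _standardize(arr: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance columns (degenerate columns pass unscaled)."""
    std = arr.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (arr - arr.mean(axis=0)) / std


def candidate_error(
    u: str,
    complexes: Sequence[Complex],
    data: Trajectory,
    cfg: InferenceConfig,
    columns_of: Mapping[str, Sequence[int]] | None = None,
    inputs: np.ndarray | None = None,
) -> float:
    """Held-out mean absolute one-step error of the candidate set.

    The reservoir is trained (readout only) on the first
    1 - holdout_fraction of ``data`` and scored on the remaining tail;
    an empty candidate set is scored as the persistence forecast
    u_hat(t+dt) = u(t).  Deterministic given the configuration seeds.

    ``inputs`` optionally overrides the driving matrix (e.g. a sin/cos
    encoding of ``data``) while targets still come from ``data``'s column u.
    """
    X = data.states if inputs is None else np.asarray(inputs)
    X = _standardize(X)
    useries = _standardize(data.column(u))
    T = len(useries)
    s = _split_index(T, cfg.holdout_fraction)
    targets = useries[1:] - useries[:-1]  # row t: u(t+dt) - u(t)
    if not complexes:
        return float(np.mean(np.abs(targets[s:])))
    rcfg = cfg.reservoir
    errs = []
    for k in range(cfg.n_realizations):
        res = build_node_reservoir(
            complexes,
            data.names,
            rcfg,
            node=u,
            columns_of=columns_of,
            realization=k,
            block_size=cfg.block_size,
            shared_blocks=True,
        )
        R = drive(res, X)
        ro = fit_readout(
            R[:s], useries[: s + 1], ridge=rcfg.ridge, washout=rcfg.washout, node=u
        )
        pred = R[s : T - 1] @ ro.w.ravel()
        errs.append(np.mean(np.abs(pred - targets[s:])))
    # median across reservoir realisations: robust to a single bad draw
    return float(np.median(errs))


def estimate_epsilon(
    u: str,
    complexes: Sequence[Complex],
    data: Trajectory,
    cfg: InferenceConfig,
    columns_of=None,
) -> float:
    """Noise-adaptive threshold: 5x the standard error of e over replicates."""
    single = InferenceConfig(
        epsilon=cfg.epsilon,
        holdout_fraction=cfg.holdout_fraction,
        n_realizations=1,
        max_iterations=cfg.max_iterations,
        reservoir=cfg.reservoir,
    )
    errs = []
    for k in range(cfg.epsilon_replicates):
        single.reservoir = cfg.reservoir.replace(seed=cfg.reservoir.seed + 7919 * (k + 1))
        errs.append(candidate_error(u, complexes, data, single, columns_of))
    # 5x the standard error of the replicate scores: wide enough to absorb
    # reservoir-draw variability of a candidate's score, narrow enough to
    # stay below the systematic error jump caused by deleting a complex
    # that carries real dynamical information
    return float(5.0 * np.std(errs) / np.sqrt(len(errs)))


class _ErrorCache:
    def __init__(self, u, data, cfg, columns_of=None, inputs=None):
        self.u, self.data, self.cfg = u, data, cfg
        self.columns_of, self.inputs = columns_of, inputs
        self._cache: dict[tuple, float] = {}

    def __call__(self, complexes: Sequence[Complex]) -> float:
        key = tuple(sorted(c.members for c in complexes))
        if key not in self._cache:
            self._cache[key] = candidate_error(
                self.u, complexes, self.data, self.cfg, self.columns_of, self.inputs
            )
        return self._cache[key]


def is_noncausal(
    C: Sequence[Complex],
    c_k: Complex,
    u: str,
    data: Trajectory,
    cfg: InferenceConfig,
    base_error: float | None = None,
    epsilon: float | None = None,
) -> bool:
    """Granger-style test: does deleting c_k leave prediction as good?

    True iff  e(C) + eps >= e(C \\ {c_k}); then c_k is not a causal
    higher-order neighbor of u.  c_k must be a member of C and must not be
    a subcomplex of any other member (otherwise its variables still reach
    the reservoir and the test is vacuous).
    """
    if c_k not in list(C):
        raise ValueError(f"{c_k} is not in the candidate set")
    others = [c for c in C if c != c_k]
    if any(c_k.is_subcomplex(o) for o in others):
        raise ValueError(f"{c_k} is a subcomplex of another candidate")
    eps = cfg.epsilon if epsilon is None else epsilon
    if eps is None:
        eps = estimate_epsilon(u, list(C), data, cfg)
    e_with = candidate_error(u, list(C), data, cfg) if base_error is None else base_error
    e_without = candidate_error(u, others, data, cfg)
    return e_with + eps >= e_without


def infer_higher_order_neighbors(
    u: str,
    C0: Sequence[Complex],
    data: Trajectory,
    cfg: InferenceConfig | None = None,
    columns_of=None,
    inputs=None,
) -> tuple[list[Complex], InferenceTrace]:
    """Greedy refinement of C0 into the higher-order neighbor set S_u.

    Alternates non-causal deletions (in canonical order, rescoring after
    every accepted deletion) and facet splits until the candidate set stops
    changing; returns the final set and the full decision trace.
    """
    cfg = cfg or InferenceConfig()
    C = canonicalize(C0)
    if not C:
        raise ValueError("initial candidate set must be non-empty")
    err = _ErrorCache(u, data, cfg, columns_of, inputs)
    eps = cfg.epsilon
    if eps is None:
        eps = estimate_epsilon(u, C, data, cfg, columns_of)
    trace = InferenceTrace(node=u, epsilon=eps)
    e_base = err(C)
    trace.append("init", tuple(C), e_base, True)

    converged = False
    for _ in range(cfg.max_iterations):
        changed = False
        # deletions: traverse the canonical order, greedily accepting
        for c in list(C):
            if c not in C:
                continue
            trial = [x for x in C if x != c]
            e_trial = err(trial)
            accept = e_base + eps >= e_trial
            trace.append("delete", tuple(trial), e_trial, accept, detail=repr(c))
            if accept:
                C, e_base = canonical_order(trial), e_trial
                changed = True
                if not C:
                    break
        # splits: replace a complex by its facets when it predicts as well
        for c in [x for x in C if x.dimension >= 1]:
            if c not in C:
                continue
            trial = canonicalize([x for x in C if x != c] + c.split())
            if set(trial) == set(C):
                continue
            e_trial = err(trial)
            accept = e_base + eps >= e_trial
            trace.append("split", tuple(trial), e_trial, accept, detail=repr(c))
            if accept:
                C, e_base = trial, e_trial
                changed = True
        if not changed:
            converged = True
            break
    trace.converged = converged
    return canonical_order(C), trace


def infer_full_structure(
    data: Trajectory,
    node_list: Sequence[str] | None = None,
    C0_builder: Callable[[str], Sequence[Complex]] | None = None,
    cfg: InferenceConfig | None = None,
) -> tuple[HigherOrderStructure, dict[str, InferenceTrace], dict[str, Exception]]:
    """Run the per-node search independently for every node.

    Nodes are independent, so the result cannot depend on execution order.
    Per-node failures are collected (not fatal) and reported in the third
    return value; failed nodes are absent from the structure.
    """
    cfg = cfg or InferenceConfig()
    nodes = list(node_list) if node_list is not None else list(data.names)
    if C0_builder is None:
        C0_builder = lambda u: [Complex(data.names)]  # noqa: E731
    neighbors: dict[str, list[Complex]] = {}
    traces: dict[str, InferenceTrace] = {}
    failures: dict[str, Exception] = {}
    for u in nodes:
        try:
            S_u, trace = infer_higher_order_neighbors(u, C0_builder(u), data, cfg)
            neighbors[u] = S_u
            traces[u] = trace
        except Exception as exc:  # pragma: no cover - defensive
            failures[u] = exc
    structure = HigherOrderStructure(nodes=list(data.names), neighbors=neighbors)
    return structure, traces, failures


def subsystem_coupling_scan(
    target: str,
    self_complexes: Sequence[Complex],
    probes: Mapping[str, Sequence[Complex]],
    data: Trajectory,
    cfg: InferenceConfig | None = None,
) -> pd.DataFrame:
    """Leave-one-subsystem-out scan of coupling neighbors.

    ``target`` is the node receiving the coupling, ``self_complexes`` its
    within-subsystem neighbor complexes, and ``probes`` maps each candidate
    neighboring subsystem label to the complexes it would contribute.  The
    scan scores the full candidate set and each set with one probe removed;
    a probe is flagged as a true neighbor when removing it worsens the
    error beyond epsilon.
    """
    cfg = cfg or InferenceConfig()
    err = _ErrorCache(target, data, cfg)
    all_complexes = canonicalize(
        list(self_complexes) + [c for cs in probes.values() for c in cs]
    )
    e_all = err(all_complexes)
    eps = cfg.epsilon if cfg.epsilon is not None else estimate_epsilon(
        target, all_complexes, data, cfg
    )
    rows = []
    for label, cs in probes.items():
        drop = set(cs)
        reduced = canonicalize(
            [c for c in list(self_complexes) + [c for cc in probes.values() for c in cc]
             if c not in drop]
        )
        e_without = err(reduced)
        rows.append(
            {
                "probe": label,
                "e_all": e_all,
                "e_without": e_without,
                "error_jump": e_without - e_all,
                "is_neighbor": e_all + eps < e_without,
            }
        )
    return pd.DataFrame(rows)
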