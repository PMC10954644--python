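"""Forecast quality metrics and the RC / PRC / HoGRC comparison harness.

The headline metric is the number of *valid prediction steps* (VPS): the
first closed-loop forecast step at which the per-variable-normalised RMSE

    RMSE(t) = sqrt( (1/N) sum_i [ (xhat_i(t) - x_i(t)) / sigma_i ]^2 )

exceeds a threshold eps_r (0.01 by default; 0.03 for noisy data).  The
normalisation scales sigma_i are the standard deviations of the true test
trajectory, so VPS is comparable across systems of different amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeding import rng
from .structures import HigherOrderStructure
from .systems import Trajectory

__all__ = [
    "rmse_at",
    "rmse_series",
    "valid_prediction_steps",
    "PredictionReport",
    "pairwise_neighbors",
    "run_comparison",
    "run_sweep",
]


def rmse_at(pred, truth, sigma) -> float:
    """Normalised RMSE of one state (or the series mean if 2-D arrays)."""
    pred, truth = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("every normalisation scale sigma_i must be positive")
    return float(np.sqrt(np.mean(((pred - truth) / sigma) ** 2)))


def rmse_series(pred: np.ndarray, truth: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Per-step normalised RMSE of a forecast against the truth."""
    pred, truth = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("every normalisation scale sigma_i must be positive")
    return np.sqrt(np.mean(((pred - truth) / sigma) ** 2, axis=1))


def valid_prediction_steps(
    pred: Trajectory | np.ndarray,
    truth: Trajectory | np.ndarray,
    eps_r: float = 0.01,
    sigma: np.ndarray | None = None,
) -> int:
    """Index of the first step whose RMSE exceeds eps_r (series length if none).

    A forecast shorter than the truth (truncated on divergence) counts as
    exceeding at its end.
    """
    P = pred.states if isinstance(pred, Trajectory) else np.asarray(pred)
    Q = truth.states if isinstance(truth, Trajectory) else np.asarray(truth)
    if sigma is None:
        sigma = Q.std(axis=0)
    horizon = Q.shape[0]
    steps = min(P.shape[0], horizon)
    if steps == 0:
        return 0
    series = rmse_series(P[:steps], Q[:steps], sigma)
    above = np.nonzero(series > eps_r)[0]
    if above.size:
        return int(above[0])
    return steps if steps == horizon else steps  # truncated forecast ends here


@dataclass
class PredictionReport:
    method: str
    start: int
    vps: int
    eps_r: float
    rmse_series: np.ndarray

    def __post_init__(self) -> None:
        if self.vps < 0 or np.any(self.rmse_series < 0):
            raise ValueError("vps and RMSE values must be non-negative")


def pairwise_neighbors(structure: HigherOrderStructure) -> dict[str, set[str]]:
    """Project a higher-order structure to pairwise links: v -> u iff v
    appears in some complex of S_u.  This is the wiring the PRC baseline
    uses (self-links included)."""
    out: dict[str, set[str]] = {}
    for u in structure.nodes:
        members = {v for c in structure.neighbors.get(u, []) for v in c.members}
        out[u] = members | {u}
    return out


def run_comparison(
    trajectory: Trajectory,
    structure: HigherOrderStructure,
    methods: Iterable[str] = ("rc", "prc", "hogrc"),
    config=None,
    n_starts: int = 50,
    horizon: int = 1000,
    train_fraction: float = 0.6,
    warmup: int = 200,
    eps_r: float = 0.01,
    seed: int = 0,
    neighbors: Mapping[str, set] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train each method once and forecast from random test anchors.

    The first ``train_fraction`` of the data is the training set; anchors
    are drawn uniformly without replacement from the test segment, leaving
    ``horizon`` true steps after each.  Returns (per-run long table,
    per-method summary with median and quartiles of VPS).
    """
    from .model import ClassicRC, HoGRC, ParallelRC  # local: avoid cycle

    methods = list(methods)
    T = len(trajectory)
    split = int(round(T * train_fraction))
    if neighbors is None:
        neighbors = pairwise_neighbors(structure)

    fitted = {}
    for m in methods:
        if m == "rc":
            fitted[m] = ClassicRC(trajectory, config=config, train_fraction=train_fraction).fit()
        elif m == "prc":
            fitted[m] = ParallelRC(
                trajectory, neighbors, config=config, train_fraction=train_fraction
            ).fit()
        elif m == "hogrc":
            fitted[m] = HoGRC(
                trajectory, structure=structure, config=config, train_fraction=train_fraction
            ).fit()
        else:
            raise ValueError(f"unknown method {m!r}")

    lo = max(split, warmup)
    hi = T - horizon - 1
    if hi <= lo:
        raise ValueError("test segment too short for the requested horizon")
    k = min(n_starts, hi - lo)
    anchors = np.sort(rng(seed, "anchors").choice(np.arange(lo, hi), size=k, replace=False))

    sigma = trajectory.states[split:].std(axis=0)
    rows = []
    for m in methods:
        res = fitted[m]
        for a in anchors:
            fc = res.forecast(int(a), horizon, warmup=warmup)
            truth = trajectory.states[a + 1 : a + 1 + horizon]
            vps = valid_prediction_steps(fc.states, truth, eps_r=eps_r, sigma=sigma)
            rows.append({"method": m, "start": int(a), "vps": vps})
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("method")["vps"]
        .agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75), mean="mean")
        .reset_index()
    )
    return table, summary


def run_sweep(
    axis: str,
    grid: Sequence,
    make_instance,
    methods: Iterable[str] = ("rc", "prc", "hogrc"),
    seed: int = 0,
    **comparison_kw,
) -> pd.DataFrame:
    """One comparison per grid point, with shared seeds across points.

    ``make_instance(value, seed)`` must return ``(trajectory, structure)``
    for the grid value (e.g. a noise level, a training length, a subsystem
    count, or a topology name).  Per-point failures are recorded with NaN
    VPS and the sweep continues.  The result is a tidy long-format table.
    """
    if not len(grid):
        raise ValueError("grid must be non-empty")
    frames = []
    for value in grid:
        try:
            traj, structure = make_instance(value, seed)
            table, _ = run_comparison(
                traj, structure, methods=methods, seed=seed, **comparison_kw
            )
            table[axis] = value
            frames.append(table)
        except Exception as exc:
            frames.append(
                pd.DataFrame(
                    [{"method": m, "start": -1, "vps": np.nan, axis: value, "error": str(exc)}
                     for m in methods]
                )
            )
    return pd.concat(frames, ignore_index=True)
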