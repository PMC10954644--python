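"""Model / Results classes tying the reservoir machinery together.

The entry points mirror the fitted-model idiom of statistical packages:
construct a model from data (a :class:`~hogrc.systems.Trajectory` or a
DataFrame), call :meth:`fit` to train the readouts, and use the returned
Results object for forecasting, diagnostics and summaries.

    >>> model = HoGRC(trajectory, structure=S)
    >>> res = model.fit()
    >>> res.summary()
    >>> forecast = res.forecast(anchor, steps=500)

:class:`HoGRC` can also *infer* the structure from the data first
(:meth:`HoGRC.infer_structure`), which is the Granger-reservoir search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import InferenceConfig, InferenceTrace, infer_full_structure
from .reservoir import (
    Readout,
    ReservoirConfig,
    ReservoirEnsemble,
    build_classic_rc,
    build_node_reservoir,
    build_prc,
    drive,
    fit_readout,
)
from .structures import Complex, HigherOrderStructure
from .systems import Trajectory

__all__ = ["ClassicRC", "ParallelRC", "HoGRC", "RCResults", "StructureInferenceResults"]


@dataclass
class _Scaler:
    """Per-variable standardisation fitted on the training window.

    Reservoir tanh units need inputs of order one; all models therefore
    work in z-scored coordinates internally and map forecasts back.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, states: np.ndarray) -> "_Scaler":
        std = states.std(axis=0)
        return cls(states.mean(axis=0), np.where(std > 0, std, 1.0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.std + self.mean


class _BaseRCModel:
    """Shared construction / training plumbing of the three model families."""

    method = "base"

    def __init__(
        self,
        trajectory: Trajectory,
        config: ReservoirConfig | None = None,
        train_fraction: float = 0.6,
    ):
        if not 0 < train_fraction <= 1:
            raise ValueError("train_fraction must lie in (0, 1]")
        self.data = trajectory
        self.config = config or ReservoirConfig()
        self.train_fraction = train_fraction
        self.split = int(round(len(trajectory) * train_fraction))
        self.train = trajectory.window(0, self.split)
        self.scaler = _Scaler.fit(self.train.states)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float, **kwargs):
        traj = Trajectory(df.to_numpy(dtype=float), dt, [str(c) for c in df.columns])
        return cls(traj, **kwargs)

    # subclasses provide _build_members() -> (members, out_index)

    def fit(self) -> "RCResults":
        members, out_index = self._build_members()
        fitted = []
        diagnostics = []
        X = self.scaler.transform(self.train.states)
        for res, targets in members:
            R = drive(res, X)
            cols = X[:, targets]
            ro = fit_readout(
                R,
                cols,
                ridge=self.config.ridge,
                washout=self.config.washout,
                node=res.node,
            )
            fitted.append((res, ro))
            resid = R[self.config.washout : len(X) - 1] @ ro.w.T - (
                cols[1 + self.config.washout :] - cols[self.config.washout : -1]
            )
            diagnostics.append(
                {
                    "node": res.node,
                    "D_u": len(res.complexes),
                    "n_eff": res.n,
                    "train_mae": float(np.mean(np.abs(resid))),
                }
            )
        ensemble = ReservoirEnsemble(fitted, self.data.names, out_index=out_index)
        return RCResults(
            model=self,
            ensemble=ensemble,
            readouts={res.node: ro for res, ro in fitted},
            diagnostics=pd.DataFrame(diagnostics),
        )


class ClassicRC(_BaseRCModel):
    """Single-reservoir baseline: one random W_in / A, an N x n readout.

    The shared reservoir uses the same size ``config.n`` as a single node
    reservoir — the same-hyperparameters convention under which the
    structured models are a subset of the classic model class — and is
    overridable via ``total_size``.
    """

    method = "rc"

    def __init__(self, trajectory, config=None, train_fraction: float = 0.6,
                 total_size: int | None = None):
        super().__init__(trajectory, config, train_fraction)
        self.total_size = total_size or self.config.n

    def _build_members(self):
        cfg = self.config.replace(n=self.total_size)
        res = build_classic_rc(self.data.names, cfg)
        members = [(res, list(range(self.data.n_vars)))]
        return members, [list(range(self.data.n_vars))]


class ParallelRC(_BaseRCModel):
    """Node-level reservoirs wired by pairwise neighbor sets only."""

    method = "prc"

    def __init__(
        self,
        trajectory,
        neighbors: Mapping[str, Sequence[str]],
        config=None,
        train_fraction: float = 0.6,
    ):
        super().__init__(trajectory, config, train_fraction)
        for u in trajectory.names:
            if u not in neighbors:
                raise ValueError(f"no neighbor set for node {u!r}")
            if u not in set(neighbors[u]) | {u}:  # pragma: no cover
                raise ValueError(f"neighbor set of {u!r} must include the node")
        self.neighbors = {u: set(neighbors[u]) | {u} for u in trajectory.names}

    def _build_members(self):
        members = []
        for i, u in enumerate(self.data.names):
            res = build_prc(u, sorted(self.neighbors[u]), self.data.names, self.config)
            members.append((res, [i]))
        return members, [[i] for i in range(self.data.n_vars)]


class HoGRC(_BaseRCModel):
    """Higher-order Granger reservoir computing.

    Built from a trajectory and (optionally) a declared higher-order
    structure.  If no structure is given, :meth:`infer_structure` runs the
    greedy Granger search on the training window and stores the result;
    :meth:`fit` then trains one block-structured reservoir per node.
    """

    method = "hogrc"

    def __init__(
        self,
        trajectory,
        structure: HigherOrderStructure | None = None,
        config=None,
        train_fraction: float = 0.6,
    ):
        super().__init__(trajectory, config, train_fraction)
        self.structure = structure

    def infer_structure(
        self,
        inference_config: InferenceConfig | None = None,
        initial: Mapping[str, Sequence[Complex]] | None = None,
        nodes: Sequence[str] | None = None,
    ) -> "StructureInferenceResults":
        """Infer S_u for every node from the training window (Task I)."""
        cfg = inference_config or InferenceConfig(
            reservoir=InferenceConfig().reservoir.replace(seed=self.config.seed)
        )
        builder = None
        if initial is not None:
            builder = lambda u: list(initial[u])  # noqa: E731
        structure, traces, failures = infer_full_structure(
            self.train, node_list=nodes, C0_builder=builder, cfg=cfg
        )
        if not failures and nodes is None:
            self.structure = structure
        return StructureInferenceResults(
            structure=structure, traces=traces, failures=failures
        )

    def _build_members(self):
        if self.structure is None:
            raise ValueError(
                "no structure: pass one to the constructor or call infer_structure()"
            )
        members = []
        for i, u in enumerate(self.data.names):
            S_u = self.structure[u]
            res = build_node_reservoir(S_u, self.data.names, self.config, node=u)
            members.append((res, [i]))
        return members, [[i] for i in range(self.data.n_vars)]


@dataclass
class StructureInferenceResults:
    """Outcome of the per-node greedy search (Task I)."""

    structure: HigherOrderStructure
    traces: dict[str, InferenceTrace]
    failures: dict[str, Exception] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for u, trace in self.traces.items():
            rows.append(
                {
                    "node": u,
                    "S_u": repr(self.structure.neighbors.get(u, [])),
                    "D_u": len(self.structure.neighbors.get(u, [])),
                    "evaluations": len(trace.records),
                    "final_error": trace.records[-1].error if trace.records else np.nan,
                    "converged": trace.converged,
                }
            )
        return pd.DataFrame(rows)


def load_bundle(directory):
    """Load a serialised fit: returns (ReservoirEnsemble, metadata dict).

    The metadata carries the variable names, dt, scaler mean/std and the
    per-member structure, enough to warm the ensemble on scaled data and
    forecast.
    """
    import yaml

    import scipy.sparse as sp
    from pathlib import Path

    from .reservoir import NodeReservoir

    directory = Path(directory)
    meta = yaml.safe_load((directory / "model.yaml").read_text())
    arrays = np.load(directory / "matrices.npz")
    members = []
    for idx, m in enumerate(meta["members"]):
        res = NodeReservoir(
            node=m["node"],
            complexes=tuple(Complex(c) for c in m["complexes"]),
            names=list(meta["names"]),
            W_in=arrays[f"W_in_{idx}"],
            A=sp.csr_matrix(arrays[f"A_{idx}"]),
            b=arrays[f"b_{idx}"],
            leak=m["leak"],
            block_size=m["block_size"],
        )
        ro = Readout(w=arrays[f"W_out_{idx}"], ridge=meta["config"].get("ridge", 0.0),
                     node=m["node"])
        members.append((res, ro))
    ensemble = ReservoirEnsemble(
        members, meta["names"], out_index=[m["outputs"] for m in meta["members"]]
    )
    return ensemble, meta


class RCResults:
    """Fitted readouts plus the closed-loop forecasting ensemble."""

    def __init__(
        self,
        model: _BaseRCModel,
        ensemble: ReservoirEnsemble,
        readouts: dict[str, Readout],
        diagnostics: pd.DataFrame,
    ):
        self.model = model
        self.ensemble = ensemble
        self.readouts = readouts
        self.diagnostics = diagnostics

    @property
    def train_mae(self) -> float:
        """Mean absolute one-step training error over all nodes."""
        return float(self.diagnostics["train_mae"].mean())

    def forecast(self, anchor: int, steps: int, warmup: int = 200) -> Trajectory:
        """Closed-loop forecast of ``steps`` states following index ``anchor``.

        The reservoirs are synchronised on the ``warmup`` true samples
        ending at the anchor, then run autonomously; forecast row s
        predicts the true state at index anchor + 1 + s.
        """
        if steps == 0:
            return Trajectory(
                np.empty((0, self.model.data.n_vars)),
                self.model.data.dt,
                list(self.model.data.names),
            )
        data = self.model.data
        if not 0 <= anchor < len(data):
            raise ValueError("anchor outside the data")
        scaler = self.model.scaler
        self.ensemble.reset()
        w0 = max(0, anchor - warmup)
        if anchor > w0:
            self.ensemble.warm(scaler.transform(data.states[w0:anchor]))
        fc, self.diverged = self.ensemble.forecast(
            scaler.transform(data.states[anchor]),
            steps,
            data.dt,
            t0=data.t0 + data.dt * (anchor + 1),
        )
        fc.states = scaler.inverse(fc.states)
        return fc

    def predict_one_step(self, X: np.ndarray | None = None) -> np.ndarray:
        """Teacher-forced one-step predictions over a state matrix."""
        data = self.model.data
        scaler = self.model.scaler
        X = scaler.transform(data.states if X is None else np.asarray(X))
        self.ensemble.reset()
        preds = np.empty((X.shape[0], len(data.names)))
        for t in range(X.shape[0]):
            r = self.ensemble._advance(X[t])
            preds[t] = X[t] + self.ensemble._W_out @ r
        return scaler.inverse(preds)  # row t predicts the state at t+1

    def save(self, directory) -> None:
        """Serialise the fitted bundle: matrices as .npz, config as YAML."""
        import yaml

        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        meta = {
            "model": type(self.model).__name__,
            "names": self.model.data.names,
            "dt": float(self.model.data.dt),
            "train_fraction": self.model.train_fraction,
            "config": {
                k: (float(v) if isinstance(v, (int, float)) else v)
                for k, v in vars(self.model.config).items()
            },
            "scaler_mean": [float(v) for v in self.model.scaler.mean],
            "scaler_std": [float(v) for v in self.model.scaler.std],
            "members": [],
        }
        for idx, ((res, ro), outs) in enumerate(
            zip(self.ensemble.members, self.ensemble.out_index)
        ):
            arrays[f"W_in_{idx}"] = res.W_in
            arrays[f"A_{idx}"] = res.A.toarray()
            arrays[f"b_{idx}"] = res.b
            arrays[f"W_out_{idx}"] = ro.w
            meta["members"].append(
                {
                    "node": res.node,
                    "complexes": [list(c.members) for c in res.complexes],
                    "leak": res.leak,
                    "block_size": res.block_size,
                    "outputs": list(outs),
                }
            )
        np.savez_compressed(directory / "matrices.npz", **arrays)
        (directory / "model.yaml").write_text(yaml.safe_dump(meta))
        if isinstance(self.model, HoGRC) and self.model.structure is not None:
            self.model.structure.to_file(directory / "structure.tsv")

    def summary(self) -> str:
        head = (
            f"{type(self.model).__name__} fit: {self.model.data.n_vars} variables, "
            f"{self.model.split} training samples (dt={self.model.data.dt}), "
            f"ridge={self.model.config.ridge:g}\n"
        )
        return head + self.diagnostics.to_string(index=False)

    def __repr__(self) -> str:
        return (
            f"<RCResults {type(self.model).__name__} "
            f"train_mae={self.train_mae:.3e} nodes={self.model.data.n_vars}>"
        )
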