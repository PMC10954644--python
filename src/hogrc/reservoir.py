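"""Echo-state reservoirs with higher-order structure embedded in their wiring.

Three model families share one leaky-tanh update

    r(t+dt) = (1-l) r(t) + l tanh(W_in x(t) + A r(t) + b)

and one trained component, a ridge-regression readout predicting the
one-step residual u(t+dt) - u(t):

* classic RC — a single reservoir; W_in fully random, A sparse random, one
  N x n readout shared by all variables.
* parallel RC (PRC) — one reservoir per node whose W_in sees only the node
  and its pairwise neighbors, as a single undivided block.
* higher-order reservoir — one reservoir per node whose W_in is partitioned
  into D_u row blocks, block i reading only the variables of the i-th
  higher-order neighbor complex, and whose A is block-diagonal so the D_u
  hidden sub-populations do not mix.  The PRC is the degenerate single-block
  case, and the classic RC the single-block case over all variables, so both
  are built through the same constructor (structural containment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._seeding import rng
from .structures import Complex, canonical_order
from .systems import DivergenceError, Trajectory

__all__ = [
    "ReservoirConfig",
    "NodeReservoir",
    "Readout",
    "build_node_reservoir",
    "build_classic_rc",
    "build_prc",
    "drive",
    "fit_readout",
    "one_step",
    "ReservoirEnsemble",
    "encode_angles",
    "decode_delta",
    "angle_columns",
]


@dataclass(frozen=True)
class ReservoirConfig:
    """Hyperparameters of one node-level reservoir.

    ``n`` is the nominal hidden size before the floor rule (the effective
    size is D_u * floor(n / D_u)); ``washout`` is the number of initial
    states excluded from the readout regression.
    """

    n: int = 600
    leak: float = 0.6
    spectral_radius: float = 0.9
    input_scale: float = 0.5
    density: float = 0.05
    bias_scale: float = 0.1
    ridge: float = 1e-6
    washout: int = 200
    state_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("reservoir size n must be >= 1")
        if not 0 < self.leak <= 1:
            raise ValueError("leak rate must lie in (0, 1]")
        if self.spectral_radius <= 0:
            raise ValueError("spectral radius must be positive")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.ridge < 0 or self.washout < 0 or self.state_noise < 0:
            raise ValueError("ridge, washout and state_noise must be non-negative")

    def replace(self, **kw) -> "ReservoirConfig":
        return replace(self, **kw)


@dataclass
class NodeReservoir:
    """One node's fixed hidden system (matrices are never trained)."""

    node: str
    complexes: tuple[Complex, ...]
    names: list[str]
    W_in: np.ndarray  # n' x N_cols dense
    A: sp.csr_matrix  # n' x n' block-diagonal sparse
    b: np.ndarray  # n'
    leak: float
    block_size: int
    # training-time state-noise regularisation (Jaeger-style): std of the
    # Gaussian perturbation added inside the tanh at every update, and the
    # substream key making it reproducible and candidate-independent
    state_noise: float = 0.0
    noise_key: tuple = ()

    @property
    def n(self) -> int:
        return self.W_in.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[1]

    def block_rows(self, i: int) -> slice:
        return slice(i * self.block_size, (i + 1) * self.block_size)


@dataclass
class Readout:
    """Trained 1 x n (or N x n) linear output map for the one-step residual."""

    w: np.ndarray
    ridge: float
    node: str = ""

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))


def _spectral_radius(A: sp.spmatrix) -> float:
    n = A.shape[0]
    if n <= 400:
        return float(np.abs(np.linalg.eigvals(A.toarray())).max())
    try:
        vals = spla.eigs(
            A.astype(float), k=1, which="LM", return_eigenvectors=False, maxiter=2000
        )
        return float(np.abs(vals).max())
    except (spla.ArpackNoConvergence, spla.ArpackError):
        # power-iteration estimate of the dominant magnitude
        gen = np.random.default_rng(0)
        v = gen.standard_normal(n)
        v /= np.linalg.norm(v)
        est = 0.0
        for _ in range(200):
            w = A @ v
            est = np.linalg.norm(w)
            if est == 0:
                return 0.0
            v = w / est
        return float(est)


def _random_sparse_block(size: int, density: float, gen: np.random.Generator):
    """Uniform(-1, 1) sparse block rescaled to unit spectral radius."""
    mat = sp.random(
        size,
        size,
        density=density,
        format="csr",
        random_state=np.random.RandomState(int(gen.integers(2**31))),
        data_rvs=lambda k: gen.uniform(-1.0, 1.0, size=k),
    )
    radius = _spectral_radius(mat) if mat.nnz else 0.0
    if radius > 0:
        mat = mat.multiply(1.0 / radius).tocsr()
    return mat


def build_node_reservoir(
    S_u: Sequence[Complex],
    names: Sequence[str],
    cfg: ReservoirConfig,
    node: str = "",
    columns_of: Mapping[str, Sequence[int]] | None = None,
    realization: int = 0,
    block_size: int | None = None,
    shared_blocks: bool = False,
) -> NodeReservoir:
    """Build the block-structured reservoir encoding the neighbor set S_u.

    Row block i of W_in (of height floor(n / D_u)) has random entries only
    in the columns of the variables of complex s_{u,i}; A is block-diagonal
    with each sparse block rescaled to the target spectral radius.  The
    matrices are deterministic given (seed, node, canonical S_u,
    realization), so repeated candidate evaluations are reproducible.

    ``columns_of`` maps a variable name to its input column indices; it
    defaults to the identity (one column per name) and supports encodings
    where one variable occupies several columns (e.g. sin/cos phase pairs).

    Two scoring-oriented variants are available for the structure search:
    ``block_size`` fixes the per-complex block height instead of dividing
    ``cfg.n`` among the complexes, and ``shared_blocks`` keys each block's
    random draw by its complex (not by the whole candidate set), so the
    same complex receives identical wiring in every candidate set that
    contains it.  Together they make candidate comparisons nested: deleting
    a complex removes exactly its features and leaves the others bit-for-
    bit unchanged.
    """
    complexes = tuple(canonical_order(S_u))
    if not complexes:
        raise ValueError("S_u must contain at least one complex")
    D = len(complexes)
    if block_size is not None:
        if block_size < 1:
            raise ValueError("block_size must be positive")
        block = block_size
    else:
        if cfg.n < D:
            raise ValueError(f"reservoir size {cfg.n} smaller than D_u={D}")
        block = cfg.n // D
    n_eff = D * block
    if columns_of is None:
        columns_of = {v: [i] for i, v in enumerate(names)}
    n_cols = max(c for cols in columns_of.values() for c in cols) + 1

    key = tuple(c.members for c in complexes)
    gen = rng(cfg.seed, "reservoir", node, key, realization)

    W_in = np.zeros((n_eff, n_cols))
    blocks = []
    bias = []
    for i, c in enumerate(complexes):
        g = rng(cfg.seed, "block", node, c.members, realization) if shared_blocks else gen
        cols = sorted({j for v in c.members for j in columns_of[v]})
        W_in[i * block : (i + 1) * block, cols] = g.uniform(
            -cfg.input_scale, cfg.input_scale, size=(block, len(cols))
        )
        blocks.append(_random_sparse_block(block, cfg.density, g) * cfg.spectral_radius)
        bias.append(g.uniform(-cfg.bias_scale, cfg.bias_scale, size=block))
    A = sp.block_diag(blocks, format="csr")
    b = np.concatenate(bias)
    return NodeReservoir(
        node=node,
        complexes=complexes,
        names=list(names),
        W_in=W_in,
        A=A,
        b=b,
        leak=cfg.leak,
        block_size=block,
        state_noise=cfg.state_noise,
        noise_key=(cfg.seed, "state-noise", node, realization),
    )


def build_classic_rc(
    names: Sequence[str],
    cfg: ReservoirConfig,
    columns_of: Mapping[str, Sequence[int]] | None = None,
) -> NodeReservoir:
    """Single shared reservoir: fully random W_in, one sparse random A."""
    return build_node_reservoir(
        [Complex(names)], names, cfg, node="__all__", columns_of=columns_of
    )


def build_prc(
    node: str,
    neighbors: Sequence[str],
    names: Sequence[str],
    cfg: ReservoirConfig,
    columns_of: Mapping[str, Sequence[int]] | None = None,
) -> NodeReservoir:
    """Pairwise-structure reservoir: one undivided block over {u} ∪ N(u)."""
    members = sorted(set(neighbors) | {node})
    return build_node_reservoir(
        [Complex(members)], names, cfg, node=node, columns_of=columns_of
    )


def drive(
    res: NodeReservoir, x_series: Trajectory | np.ndarray, r0: np.ndarray | None = None
) -> np.ndarray:
    """Run the leaky-tanh recursion over an input series.

    Returns R of shape (T, n) where R[t] = r(t+dt), the state produced by
    consuming input x(t); row t therefore pairs with the regression target
    u(t+dt) - u(t).
    """
    X = x_series.states if isinstance(x_series, Trajectory) else np.asarray(x_series)
    if X.shape[1] != res.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns, reservoir expects {res.n_inputs}"
        )
    T = X.shape[0]
    r = np.zeros(res.n) if r0 is None else np.asarray(r0, dtype=float).copy()
    out = np.empty((T, res.n))
    one_minus_l, leak, A, b = 1.0 - res.leak, res.leak, res.A, res.b
    U = X @ res.W_in.T
    if res.state_noise > 0:
        gen = rng(res.noise_key[0] if res.noise_key else 0, *res.noise_key[1:])
        U = U + res.state_noise * gen.standard_normal(U.shape)
    for t in range(T):
        r = one_minus_l * r + leak * np.tanh(U[t] + A @ r + b)
        out[t] = r
    if not np.all(np.isfinite(out)):
        raise DivergenceError("reservoir state became non-finite")
    return out


def _ridge_solve(R: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form Tikhonov solution W = Y^T R (R^T R + lam I)^-1."""
    if lam > 0:
        G = R.T @ R + lam * np.eye(R.shape[1])
        W = np.linalg.solve(G, R.T @ Y).T
    else:
        # unregularised: minimum-norm least squares handles rank deficiency
        W, _, rank, _ = np.linalg.lstsq(R, Y, rcond=None)
        if rank < R.shape[1]:
            warnings.warn(
                "rank-deficient regression with ridge=0; using the pseudoinverse solution"
            )
        W = W.T
    return np.atleast_2d(W)


def fit_readout(
    states: np.ndarray,
    u_series: np.ndarray,
    ridge: float = 1e-6,
    washout: int = 200,
    node: str = "",
) -> Readout:
    """Ridge-regress the one-step residuals of ``u_series`` on the states.

    ``states[t]`` must be r(t+dt) (the alignment :func:`drive` produces);
    the target for row t is u(t+dt) - u(t).  Rows before ``washout`` are
    excluded to remove the initial-condition transient.
    """
    u = np.asarray(u_series, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    T = u.shape[0]
    if states.shape[0] < T - 1:
        raise ValueError("need one state per transition")
    targets = u[1:] - u[:-1]  # row t: u(t+dt) - u(t)
    R = states[washout : T - 1]
    Y = targets[washout:]
    w = _ridge_solve(R, Y, ridge)
    return Readout(w=w, ridge=ridge, node=node)


def one_step(u_now, r_next: np.ndarray, readout: Readout):
    """One-step prediction u_hat(t+dt) = u(t) + W_out r(t+dt)."""
    return np.asarray(u_now) + (readout.w @ np.asarray(r_next)).squeeze()


# --------------------------------------------------------------------------
# closed-loop multi-step forecasting


class ReservoirEnsemble:
    """Per-node reservoirs + readouts advanced synchronously in closed loop.

    All node reservoirs are stacked into one block-diagonal sparse update so
    a forecast step is a single sparse matvec; the predicted full state at
    t+dt is fed back as the input at the next step.  A classic RC is the
    special case of a single member whose readout has one row per variable.
    """

    def __init__(
        self,
        members: Sequence[tuple[NodeReservoir, Readout]],
        names: Sequence[str],
        out_index: Sequence[Sequence[int]] | None = None,
    ):
        self.members = list(members)
        self.names = list(names)
        n_out = len(names)
        # rows of the stacked readout matrix -> which output variables
        if out_index is None:
            if len(self.members) == n_out:
                out_index = [[i] for i in range(n_out)]
            elif len(self.members) == 1:
                out_index = [list(range(n_out))]
            else:
                raise ValueError("out_index required for mixed ensembles")
        self.out_index = [list(ix) for ix in out_index]

        self._A = sp.block_diag([r.A for r, _ in self.members], format="csr")
        self._W_in = np.vstack([r.W_in for r, _ in self.members])
        self._b = np.concatenate([r.b for r, _ in self.members])
        self._leak = self.members[0][0].leak
        if any(abs(r.leak - self._leak) > 0 for r, _ in self.members):
            raise ValueError("all ensemble members must share one leak rate")
        # stacked readout: W_big[v, hidden-slice of the member predicting v]
        n_tot = self._A.shape[0]
        self._W_out = np.zeros((n_out, n_tot))
        offset = 0
        for (res, ro), outs in zip(self.members, self.out_index):
            if ro.w.shape != (len(outs), res.n):
                raise ValueError(
                    f"readout shape {ro.w.shape} does not match member ({len(outs)}, {res.n})"
                )
            self._W_out[np.asarray(outs), offset : offset + res.n] = ro.w
            offset += res.n
        self._r = np.zeros(n_tot)

    @property
    def n_total(self) -> int:
        return self._A.shape[0]

    def reset(self) -> None:
        self._r = np.zeros(self.n_total)

    def _advance(self, x: np.ndarray) -> np.ndarray:
        self._r = (1.0 - self._leak) * self._r + self._leak * np.tanh(
            self._W_in @ x + self._A @ self._r + self._b
        )
        return self._r

    def warm(self, warm_series: Trajectory | np.ndarray) -> None:
        """Drive the ensemble over true samples to synchronise hidden states."""
        X = (
            warm_series.states
            if isinstance(warm_series, Trajectory)
            else np.asarray(warm_series)
        )
        for t in range(X.shape[0]):
            self._advance(X[t])

    def forecast(
        self, x_start: np.ndarray, steps: int, dt: float, t0: float = 0.0
    ) -> tuple[Trajectory, bool]:
        """Closed-loop forecast of ``steps`` states after ``x_start``.

        Returns the forecast trajectory and a divergence flag; on
        divergence the trajectory is truncated at the last finite state.
        """
        x = np.asarray(x_start, dtype=float).copy()
        out = np.empty((steps, len(self.names)))
        for s in range(steps):
            r = self._advance(x)
            x = x + self._W_out @ r
            if not np.all(np.isfinite(x)):
                return Trajectory(out[:s].copy(), dt, list(self.names), t0=t0), True
            out[s] = x
        return Trajectory(out, dt, list(self.names), t0=t0), False


# --------------------------------------------------------------------------
# phase-variable codec (sin/cos input, phase-increment output)


def encode_angles(theta: Trajectory | np.ndarray, names: Sequence[str] | None = None):
    """Encode phases as interleaved (sin, cos) input columns.

    Phase variables wrap on the circle, so reservoirs read the continuous
    embedding (sin th_i, cos th_i) instead of th_i itself.  Returns the
    encoded trajectory/array; use :func:`angle_columns` for the variable ->
    column mapping the reservoir builders need.
    """
    if isinstance(theta, Trajectory):
        arr, names, dt, t0 = theta.states, theta.names, theta.dt, theta.t0
    else:
        arr = np.asarray(theta, dtype=float)
        dt = t0 = None
    T, N = arr.shape
    enc = np.empty((T, 2 * N))
    enc[:, 0::2] = np.sin(arr)
    enc[:, 1::2] = np.cos(arr)
    if dt is None:
        return enc
    enc_names = [f"{fn}_{v}" for v in names for fn in ("sin", "cos")]
    return Trajectory(enc, dt, enc_names, t0=t0)


def angle_columns(names: Sequence[str]) -> dict[str, list[int]]:
    """Variable -> encoded-column indices for the sin/cos interleaving."""
    return {v: [2 * i, 2 * i + 1] for i, v in enumerate(names)}


def decode_delta(delta_pred, theta_now, dt: float):
    """Next phase from a predicted rate: th(t+dt) = th(t) + delta * dt."""
    return np.asarray(theta_now) + np.asarray(delta_pred) * dt
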