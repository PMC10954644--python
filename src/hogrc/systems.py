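"""Dynamical-system simulators and ground-truth higher-order structures.

Every test system is integrated with a shared fixed-step RK4 integrator:

* Lorenz63 — the 3-variable chaotic benchmark.
* CL63 — m diffusively coupled Lorenz63 subsystems, with a linear,
  sinusoidal or absolute-value coupling function acting on the y variables.
* Network dynamical systems dX_i/dt = F(X_i) + γ Σ_j w_ij G(X_i, X_j) with
  FitzHugh–Nagumo, Rössler or simplified Hodgkin–Huxley self-dynamics.
* A Kuramoto model with triangle (2-simplex) interactions on top of the
  pairwise graph.

For each system the hand-derived higher-order neighbor sets implied by the
separability of its right-hand side are available via :func:`true_structure`;
these are the ground truths the inference module is benchmarked against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from ._seeding import rng
from .structures import Complex, HigherOrderStructure, canonicalize

__all__ = [
    "Trajectory",
    "CouplingNetwork",
    "SystemParams",
    "DEFAULT_PARAMS",
    "DEFAULT_DT",
    "rk4_integrate",
    "lorenz63_field",
    "cl63_field",
    "nds_field",
    "kuramoto_ho_field",
    "generate_network",
    "add_observation_noise",
    "true_structure",
    "simulate",
    "variable_names",
]


class DivergenceError(RuntimeError):
    """Raised when the integrator or a forecast produces non-finite state."""


# --------------------------------------------------------------------------
# containers


@dataclass
class Trajectory:
    """Regularly sampled multivariate time series (T x N)."""

    states: np.ndarray
    dt: float
    names: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2:
            raise ValueError("states must be a T x N matrix")
        if self.states.shape[1] != len(self.names):
            raise ValueError("column count does not match variable names")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def n_vars(self) -> int:
        return self.states.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    def window(self, start: int, stop: int | None = None) -> "Trajectory":
        sl = slice(start, stop)
        return Trajectory(
            self.states[sl],
            self.dt,
            list(self.names),
            t0=self.t0 + self.dt * (start if start >= 0 else len(self) + start),
        )

    def to_csv(self, path, metadata: dict | None = None) -> None:
        """Write a headered CSV plus a JSON sidecar with dt / t0 / metadata."""
        path = Path(path)
        header = ",".join(self.names)
        np.savetxt(path, self.states, delimiter=",", header=header, comments="")
        side = {"dt": self.dt, "t0": self.t0, "names": self.names}
        side.update(metadata or {})
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def from_csv(cls, path, dt: float | None = None) -> "Trajectory":
        path = Path(path)
        with open(path) as fh:
            names = fh.readline().strip().split(",")
        states = np.loadtxt(path, delimiter=",", skiprows=1)
        t0 = 0.0
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            dt = meta.get("dt", dt)
            t0 = meta.get("t0", 0.0)
        if dt is None:
            raise ValueError("dt not given and no sidecar found")
        return cls(np.atleast_2d(states), dt, names, t0=t0)


@dataclass
class CouplingNetwork:
    """Weighted interaction network among m subsystems.

    ``weights[i, j]`` is the weight of the influence of subsystem j on
    subsystem i (zero means no edge); ``triangles`` lists 2-simplex
    interactions (i, j, k, weight), used by the higher-order Kuramoto model.
    """

    weights: np.ndarray
    triangles: list[tuple[int, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        m = self.m
        if self.weights.shape != (m, m):
            raise ValueError("weight matrix must be square")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-coupling (nonzero diagonal) is not allowed")
        for i, j, k, _ in self.triangles:
            if len({i, j, k}) != 3 or not all(0 <= v < m for v in (i, j, k)):
                raise ValueError(f"invalid triangle ({i},{j},{k})")

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    @property
    def in_degree(self) -> np.ndarray:
        return (self.weights != 0).sum(axis=1)

    def incoming(self, i: int) -> list[int]:
        return [j for j in range(self.m) if self.weights[i, j] != 0]

    def triangles_of(self, i: int) -> list[tuple[int, int, float]]:
        out = []
        for a, b, c, w in self.triangles:
            if a == i:
                out.append((b, c, w))
        return out

    # -- edge-list round trip ----------------------------------------------

    def to_files(self, edge_path, triangle_path=None) -> None:
        with open(edge_path, "w") as fh:
            for i in range(self.m):
                for j in range(self.m):
                    if self.weights[i, j] != 0:
                        fh.write(f"{i}\t{j}\t{self.weights[i, j]:.12g}\n")
        if triangle_path is not None:
            with open(triangle_path, "w") as fh:
                for i, j, k, w in self.triangles:
                    fh.write(f"{i}\t{j}\t{k}\t{w:.12g}\n")

    @classmethod
    def from_files(cls, edge_path, triangle_path=None, m: int | None = None):
        rows = np.atleast_2d(np.loadtxt(edge_path))
        if m is None:
            m = int(rows[:, :2].max()) + 1 if rows.size else 0
        weights = np.zeros((m, m))
        for i, j, w in rows:
            weights[int(i), int(j)] = w
        triangles = []
        if triangle_path is not None and Path(triangle_path).exists():
            trows = np.atleast_2d(np.loadtxt(triangle_path))
            triangles = [(int(i), int(j), int(k), float(w)) for i, j, k, w in trows]
        return cls(weights, triangles)


@dataclass
class SystemParams:
    """A named system together with its scalar parameters."""

    name: str
    params: dict[str, float] = field(default_factory=dict)
    m: int = 1
    coupling: str = "linear"  # CL63 coupling function: linear | sine | abs

    def __post_init__(self) -> None:
        if self.name not in DEFAULT_PARAMS:
            raise ValueError(f"unknown system {self.name!r}")
        if self.m < 1:
            raise ValueError("subsystem count m must be >= 1")
        merged = dict(DEFAULT_PARAMS[self.name])
        merged.update(self.params)
        self.params = merged


# --------------------------------------------------------------------------
# parameter defaults (the values the study systems are generated with)

DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "lorenz63": {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0},
    "cl63": {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0, "gamma": 0.5},
    "fhn": {"a": 0.28, "b": 0.5, "c": -0.04, "gamma": 0.5},
    "cros": {"a": 0.2, "b": 0.2, "c": -6.0, "gamma": 1.0},
    "cshhs": {
        "a": 1.0,
        "b": 3.0,
        "c": 1.0,
        "u": 5.0,
        "s": 4.0,
        "r": 0.005,
        "x0": -1.6,
        "gamma": 0.1,
        "V_syn": 2.0,
        "lam": 10.0,
        "Omega_syn": 1.0,
        "I_ext": 3.24,
    },
    "kuramoto_ho": {"gamma1": 0.4, "gamma2": 0.4},
}

DEFAULT_DT: dict[str, float] = {
    "lorenz63": 0.02,
    "cl63": 0.02,
    "fhn": 0.25,
    "cros": 0.1,
    "cshhs": 0.04,
    "kuramoto_ho": 0.08,
}

_NDS_COMPONENTS = {"fhn": 2, "cros": 3, "cshhs": 3}


def variable_names(system: str, m: int = 1) -> list[str]:
    """Canonical variable labels for a system with m subsystems."""
    if system == "lorenz63":
        return ["x", "y", "z"]
    if system == "cl63":
        return [f"{v}{i + 1}" for i in range(m) for v in "xyz"]
    if system in _NDS_COMPONENTS:
        k = _NDS_COMPONENTS[system]
        return [f"x{i + 1}_{c + 1}" for i in range(m) for c in range(k)]
    if system == "kuramoto_ho":
        return [f"th{i + 1}" for i in range(m)]
    raise ValueError(f"unknown system {system!r}")


# --------------------------------------------------------------------------
# vector fields


def lorenz63_field(params: dict | None = None) -> Callable[[np.ndarray], np.ndarray]:
    p = dict(DEFAULT_PARAMS["lorenz63"], **(params or {}))
    sigma, rho, beta = p["sigma"], p["rho"], p["beta"]

    def field(x: np.ndarray) -> np.ndarray:
        x1, y1, z1 = x
        return np.array(
            [sigma * (y1 - x1), rho * x1 - y1 - x1 * z1, -beta * z1 + x1 * y1]
        )

    return field


_COUPLING_FUNCS = {
    "linear": lambda yi, yj: yj - yi,
    "sine": lambda yi, yj: np.sin(yj - yi),
    "abs": lambda yi, yj: np.abs(yj - yi),
}


def cl63_field(
    net: CouplingNetwork,
    h: np.ndarray,
    coupling: str = "linear",
    params: dict | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Coupled Lorenz63 field on states ordered (x1, y1, z1, x2, y2, z2, ...).

    Subsystem i follows

        dx_i/dt = -sigma [x_i - y_i + gamma sum_j w_ij g(y_i, y_j)]
        dy_i/dt = rho (1 + h_i) x_i - y_i - x_i z_i
        dz_i/dt = x_i y_i - beta z_i
    """
    if coupling not in _COUPLING_FUNCS:
        raise ValueError(f"unknown coupling kind {coupling!r}")
    p = dict(DEFAULT_PARAMS["cl63"], **(params or {}))
    sigma, rho, beta, gamma = p["sigma"], p["rho"], p["beta"], p["gamma"]
    g = _COUPLING_FUNCS[coupling]
    m = net.m
    h = np.asarray(h, dtype=float)
    W = net.weights

    def field(state: np.ndarray) -> np.ndarray:
        if state.size != 3 * m:
            raise ValueError(f"state must have length {3 * m}")
        s = state.reshape(m, 3)
        x, y, z = s[:, 0], s[:, 1], s[:, 2]
        # coupling sum over j of w_ij * g(y_i, y_j)
        gy = g(y[:, None], y[None, :])  # gy[i, j] = g(y_i, y_j)
        csum = (W * gy).sum(axis=1)
        dx = -sigma * (x - y + gamma * csum)
        dy = rho * (1.0 + h) * x - y - x * z
        dz = x * y - beta * z
        return np.column_stack([dx, dy, dz]).ravel()

    return field


def _mu(x: np.ndarray, lam: float, omega: float) -> np.ndarray:
    """Synaptic activation sigmoid of the simplified Hodgkin–Huxley model."""
    return 1.0 / (1.0 + np.exp(-lam * (x - omega)))


def nds_field(
    self_kind: str,
    net: CouplingNetwork,
    h: np.ndarray | None = None,
    params: dict | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Network dynamical system dX_i/dt = F(X_i) + gamma sum_j w_ij G(X_i, X_j)."""
    if self_kind not in _NDS_COMPONENTS:
        raise ValueError(f"unknown self-dynamics kind {self_kind!r}")
    p = dict(DEFAULT_PARAMS[self_kind], **(params or {}))
    gamma = p["gamma"]
    m = net.m
    k = _NDS_COMPONENTS[self_kind]
    W = net.weights
    kin = net.in_degree.astype(float)
    if self_kind == "fhn" and np.any((kin == 0) & (np.abs(W).sum(axis=1) > 0)):
        raise ValueError("FHN: node with incoming weight but zero in-degree")
    if h is None:
        h = np.ones(m)
    h = np.asarray(h, dtype=float)

    def field(state: np.ndarray) -> np.ndarray:
        if state.size != k * m:
            raise ValueError(f"state must have length {k * m}")
        s = state.reshape(m, k)
        if self_kind == "fhn":
            x1, x2 = s[:, 0], s[:, 1]
            f1 = x1 - x1**3 - x2
            f2 = p["a"] + p["b"] * x1 + p["c"] * x2
            # G = (x_i - x_j)/k_i^in on the first component
            diff = x1[:, None] - x1[None, :]
            safe_kin = np.where(kin > 0, kin, 1.0)
            csum = (W * diff).sum(axis=1) / safe_kin
            return np.column_stack([f1 + gamma * csum, f2]).ravel()
        if self_kind == "cros":
            x1, x2, x3 = s[:, 0], s[:, 1], s[:, 2]
            f1 = -h * x2 - x3
            f2 = h * x1 + p["a"] * x2
            f3 = p["b"] + x3 * (x1 + p["c"])
            diff = x1[None, :] - x1[:, None]  # x_j - x_i
            csum = (W * diff).sum(axis=1)
            return np.column_stack([f1 + gamma * csum, f2, f3]).ravel()
        # cshhs
        x1, x2, x3 = s[:, 0], s[:, 1], s[:, 2]
        f1 = x2 - p["a"] * x1**3 + p["b"] * x1**2 - x3 + p["I_ext"]
        f2 = p["c"] - p["u"] * x1**2 - x2
        f3 = p["r"] * (p["s"] * (x1 - p["x0"]) - x3)
        act = _mu(x1, p["lam"], p["Omega_syn"])  # mu(x_j^1)
        csum = (p["V_syn"] - x1) * (W * act[None, :]).sum(axis=1)
        return np.column_stack([f1 + gamma * csum, f2, f3]).ravel()

    return field


def kuramoto_ho_field(
    omega: np.ndarray,
    net: CouplingNetwork,
    gamma1: float = 0.4,
    gamma2: float = 0.4,
) -> Callable[[np.ndarray], np.ndarray]:
    """Kuramoto phases with pairwise and triangle interactions.

    dtheta_i/dt = omega_i + gamma1 sum_j A_ij sin(theta_j - theta_i)
                + gamma2 sum_{(j,k)} B_ijk sin(theta_j + theta_k - 2 theta_i)

    The triangle list of ``net`` populates B symmetrically in (j, k): each
    listed triangle (i, j, k, w) contributes once per ordered pair, matching
    the double sum with B_ijk = B_ikj = w.
    """
    omega = np.asarray(omega, dtype=float)
    A = net.weights
    tri_by_node: list[list[tuple[int, int, float]]] = [
        net.triangles_of(i) for i in range(net.m)
    ]

    def field(theta: np.ndarray) -> np.ndarray:
        pair = gamma1 * (A * np.sin(theta[None, :] - theta[:, None])).sum(axis=1)
        out = omega + pair
        for i, tris in enumerate(tri_by_node):
            acc = 0.0
            for j, k, w in tris:
                acc += 2.0 * w * np.sin(theta[j] + theta[k] - 2.0 * theta[i])
            out[i] += gamma2 * acc
        return out

    return field


# --------------------------------------------------------------------------
# integrator


def rk4_integrate(
    field: Callable[[np.ndarray], np.ndarray],
    x0: Sequence[float],
    dt: float,
    steps: int,
    transient: int = 0,
    names: Sequence[str] | None = None,
) -> Trajectory:
    """Fixed-step 4th-order Runge–Kutta integration.

    Returns ``steps`` samples recorded *after* discarding ``transient``
    steps; the first recorded state is the state reached after the
    transient.  Raises :class:`DivergenceError` (naming the step) if the
    state becomes non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x0, dtype=float).copy()
    if not np.all(np.isfinite(field(x))):
        raise ValueError("vector field is not finite at the initial condition")
    n = x.size
    out = np.empty((steps, n))
    total = transient + steps
    rec = 0
    for step in range(total):
        if step >= transient:
            out[rec] = x
            rec += 1
            if rec == steps:
                break
        k1 = field(x)
        k2 = field(x + 0.5 * dt * k1)
        k3 = field(x + 0.5 * dt * k2)
        k4 = field(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise DivergenceError(f"state diverged at integration step {step}")
    if names is None:
        names = [f"v{i + 1}" for i in range(n)]
    return Trajectory(out, dt, list(names), t0=transient * dt)


# --------------------------------------------------------------------------
# network generation


def generate_network(
    kind: str,
    m: int,
    degree: int = 2,
    n_edges: int | None = None,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.5, 1.5),
    weights: np.ndarray | None = None,
) -> CouplingNetwork:
    """Seed-deterministic coupling network of the requested topology.

    regular — circulant ring where each node couples to its ``degree``
    nearest neighbors; er — uniform random graph with ``n_edges`` edges;
    ba — preferential attachment; explicit — wrap a supplied weight matrix.
    Edge weights are drawn uniformly from ``weight_range`` and are symmetric.
    """
    if kind == "explicit":
        if weights is None:
            raise ValueError("explicit networks need a weight matrix")
        return CouplingNetwork(np.asarray(weights, dtype=float))
    if m < 2:
        raise ValueError("need at least two subsystems")
    if kind == "regular":
        if degree < 1 or degree >= m or degree % 2:
            raise ValueError("regular topology needs an even degree < m")
        g = nx.circulant_graph(m, list(range(1, degree // 2 + 1)))
    elif kind == "er":
        if n_edges is None:
            n_edges = m
        if n_edges > m * (m - 1) // 2:
            raise ValueError("more edges requested than pairs available")
        g = nx.gnm_random_graph(m, n_edges, seed=int(rng(seed, "er").integers(2**31)))
    elif kind == "ba":
        g = nx.barabasi_albert_graph(
            m, 1, seed=int(rng(seed, "ba").integers(2**31))
        )
    else:
        raise ValueError(f"unknown network kind {kind!r}")
    gen = rng(seed, "weights", kind, m)
    W = np.zeros((m, m))
    for i, j in sorted(g.edges()):
        w = gen.uniform(*weight_range)
        W[i, j] = W[j, i] = w
    return CouplingNetwork(W)


def find_triangles(net: CouplingNetwork, weight: float = 1.0) -> CouplingNetwork:
    """Return a copy of ``net`` with every 3-clique listed as a triangle.

    Each clique {a, b, c} produces the three per-node entries (a,b,c),
    (b,a,c), (c,a,b) so every member feels the 2-simplex interaction.
    """
    g = nx.from_numpy_array((net.weights != 0).astype(int))
    triangles: list[tuple[int, int, int, float]] = []
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) == 3:
            a, b, c = sorted(clique)
            triangles += [(a, b, c, weight), (b, a, c, weight), (c, a, b, weight)]
        elif len(clique) > 3:
            break
    return CouplingNetwork(net.weights.copy(), triangles)


# --------------------------------------------------------------------------
# observational noise


def add_observation_noise(
    traj: Trajectory, sigma_n: float, mode: str = "per-variable-std", seed: int = 0
) -> Trajectory:
    """Add i.i.d. zero-mean Gaussian measurement noise to every sample.

    In ``per-variable-std`` mode the noise on variable i has standard
    deviation ``sigma_n * std(x_i)`` so the intensity is relative to each
    variable's scale (matching the normalised RMSE metric); ``absolute``
    uses ``sigma_n`` directly.
    """
    if sigma_n < 0:
        raise ValueError("sigma_n must be non-negative")
    if sigma_n == 0:
        return traj
    if mode == "per-variable-std":
        scale = traj.states.std(axis=0) * sigma_n
    elif mode == "absolute":
        scale = np.full(traj.n_vars, sigma_n)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    noise = rng(seed, "obs-noise").normal(size=traj.states.shape) * scale
    return Trajectory(traj.states + noise, traj.dt, list(traj.names), t0=traj.t0)


# --------------------------------------------------------------------------
# ground-truth higher-order structures


def true_structure(
    system: SystemParams | str,
    net: CouplingNetwork | None = None,
    coupling: str | None = None,
) -> HigherOrderStructure:
    """Hand-derived higher-order neighbor sets for a recognised system.

    Each node's set lists the variable groups of the inseparable terms of
    its governing equation; complexes subsumed by a larger complex are
    removed (e.g. {y_i} disappears once {y_i, y_j} is present).
    """
    if isinstance(system, SystemParams):
        name = system.name
        coupling = coupling or system.coupling
        m = system.m
    else:
        name = system
        m = net.m if net is not None else 1
    coupling = coupling or "linear"

    def C(*names: str) -> Complex:
        return Complex(names)

    if name == "lorenz63":
        return HigherOrderStructure(
            nodes=["x", "y", "z"],
            neighbors={
                "x": [C("x"), C("y")],
                "y": [C("y"), C("x", "z")],
                "z": [C("z"), C("x", "y")],
            },
        )

    if net is None:
        raise ValueError(f"{name} needs a coupling network")
    names = variable_names(name, net.m)
    nbrs: dict[str, list[Complex]] = {}

    if name == "cl63":
        for i in range(net.m):
            xi, yi, zi = f"x{i + 1}", f"y{i + 1}", f"z{i + 1}"
            sx = [C(xi), C(yi)]
            for j in net.incoming(i):
                yj = f"y{j + 1}"
                if coupling == "linear":
                    sx.append(C(yj))
                else:
                    sx.append(C(yi, yj))
            nbrs[xi] = canonicalize(sx)
            nbrs[yi] = [C(yi), C(xi, zi)]
            nbrs[zi] = [C(zi), C(xi, yi)]
        return HigherOrderStructure(nodes=names, neighbors=nbrs)

    if name == "fhn":
        for i in range(net.m):
            u, v = f"x{i + 1}_1", f"x{i + 1}_2"
            s1 = [C(u), C(v)] + [C(f"x{j + 1}_1") for j in net.incoming(i)]
            nbrs[u] = canonicalize(s1)
            nbrs[v] = [C(u), C(v)]
        return HigherOrderStructure(nodes=names, neighbors=nbrs)

    if name == "cros":
        for i in range(net.m):
            a, b, c = (f"x{i + 1}_{k}" for k in (1, 2, 3))
            s1 = [C(b), C(c)]
            inc = net.incoming(i)
            if inc:
                s1.append(C(a))  # the -x_i^1 part of the diffusive sum
                s1 += [C(f"x{j + 1}_1") for j in inc]
            nbrs[a] = canonicalize(s1)
            nbrs[b] = [C(a), C(b)]
            nbrs[c] = [C(a, c)]
        return HigherOrderStructure(nodes=names, neighbors=nbrs)

    if name == "cshhs":
        for i in range(net.m):
            a, b, c = (f"x{i + 1}_{k}" for k in (1, 2, 3))
            s1 = [C(a), C(b), C(c)]
            s1 += [C(a, f"x{j + 1}_1") for j in net.incoming(i)]
            nbrs[a] = canonicalize(s1)
            nbrs[b] = [C(a), C(b)]
            nbrs[c] = [C(a), C(c)]
        return HigherOrderStructure(nodes=names, neighbors=nbrs)

    if name == "kuramoto_ho":
        for i in range(net.m):
            ti = f"th{i + 1}"
            s = [C(ti)]
            s += [C(ti, f"th{j + 1}") for j in net.incoming(i)]
            s += [
                C(ti, f"th{j + 1}", f"th{k + 1}") for j, k, _ in net.triangles_of(i)
            ]
            nbrs[ti] = canonicalize(s)
        return HigherOrderStructure(nodes=names, neighbors=nbrs)

    raise ValueError(f"unknown system {name!r}")


# --------------------------------------------------------------------------
# one-call simulation of a named system

_IC_BOX = {
    "lorenz63": (-5.0, 5.0),
    "cl63": (-5.0, 5.0),
    "fhn": (-1.0, 1.0),
    "cros": (-5.0, 5.0),
    "cshhs": (-1.0, 1.0),
    "kuramoto_ho": (0.0, 2.0 * np.pi),
}


def simulate(
    system: SystemParams | str,
    net: CouplingNetwork | None = None,
    dt: float | None = None,
    steps: int = 5000,
    transient: int = 1000,
    seed: int = 0,
    coupling: str = "linear",
    params: dict | None = None,
) -> Trajectory:
    """Simulate a named system with seeded initial conditions and scales.

    Initial conditions are uniform in a system-specific box and a transient
    is discarded so recording starts on (or near) the attractor.  Subsystem
    scales h_i and Kuramoto natural frequencies, which vary per realisation,
    are drawn from named substreams of ``seed``.
    """
    if not isinstance(system, SystemParams):
        system = SystemParams(
            system, params or {}, m=net.m if net is not None else 1, coupling=coupling
        )
    name = system.name
    m = net.m if net is not None else system.m
    if dt is None:
        dt = DEFAULT_DT[name]
    names = variable_names(name, m)

    if name == "lorenz63":
        fld = lorenz63_field(system.params)
    elif name == "cl63":
        # h_i is a +-10% heterogeneity of the subsystem scale: the drive
        # term is rho*(1+h_i)*x_i, so each subsystem stays Lorenz-like
        h = rng(seed, "h-scales").uniform(-0.1, 0.1, size=m)
        fld = cl63_field(net, h, coupling=system.coupling, params=system.params)
    elif name in _NDS_COMPONENTS:
        h = rng(seed, "h-scales").uniform(0.9, 1.1, size=m)
        fld = nds_field(name, net, h=h, params=system.params)
    elif name == "kuramoto_ho":
        omega = rng(seed, "omega").uniform(-1.0, 1.0, size=m)
        fld = kuramoto_ho_field(
            omega, net, system.params["gamma1"], system.params["gamma2"]
        )
    else:  # pragma: no cover - guarded by SystemParams
        raise ValueError(name)

    lo, hi = _IC_BOX[name]
    x0 = rng(seed, "ic").uniform(lo, hi, size=len(names))
    return rk4_integrate(fld, x0, dt, steps, transient=transient, names=names)
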