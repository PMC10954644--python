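"""Higher-order neighbor sets as per-node collections of simplicial complexes.

A variable ``u`` of a dynamical system dx/dt = f(x) has *higher-order
neighbors*: the right-hand side f_u is written as a sum of inseparable terms,
and the variable set of each term is one neighbor — a (k-1)-dimensional
simplicial complex on k variables.  The collection ``S_u`` of those complexes,
over all nodes, is a hypergraph G = (V, S) that encodes which groups of
variables act *jointly* on each node.

Complexes in a valid ``S_u`` never subsume one another (no member set is a
subset of another member set); during the greedy inference this invariant is
relaxed for intermediate candidate sets and re-imposed by
:func:`canonicalize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence


@dataclass(frozen=True, order=True)
class Complex:
    """An inseparable group of variables (a (k-1)-D simplicial complex).

    Members are stored sorted, so two complexes with the same variables
    compare and hash equal regardless of construction order.
    """

    members: tuple[str, ...]

    def __init__(self, members: Iterable[str]):
        mem = tuple(sorted(set(members)))
        if not mem:
            raise ValueError("a complex must contain at least one variable")
        object.__setattr__(self, "members", mem)

    @property
    def dimension(self) -> int:
        return len(self.members) - 1

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, name: str) -> bool:
        return name in self.members

    def __repr__(self) -> str:
        return "{" + ",".join(self.members) + "}"

    def is_subcomplex(self, other: "Complex") -> bool:
        """True iff every member of self is a member of ``other``."""
        return set(self.members) <= set(other.members)

    def split(self) -> list["Complex"]:
        """All facets (subsets of one variable fewer), in canonical order.

        A d-dimensional complex yields d+1 facets of dimension d-1; the
        greedy refinement tries to replace a complex by this set.
        """
        if self.dimension < 1:
            raise ValueError(f"cannot split the 0-dimensional complex {self}")
        facets = [
            Complex(self.members[:i] + self.members[i + 1 :])
            for i in range(len(self.members))
        ]
        return canonical_order(facets)


def is_subcomplex(a: Complex, b: Complex) -> bool:
    return a.is_subcomplex(b)


def split_complex(c: Complex) -> list[Complex]:
    return c.split()


def canonical_order(complexes: Iterable[Complex]) -> list[Complex]:
    """Deduplicate and sort from high order to low order.

    Within a dimension the order is descending lexicographic on the member
    tuple, so for three variables the 1-D complexes traverse as
    {y,z}, {x,z}, {x,y}.  Any fixed order makes the greedy search
    deterministic; this one also makes its walk on small alphabetic systems
    follow the natural "last variables first" elimination sequence.
    """
    return sorted(set(complexes), key=lambda c: (c.dimension, c.members), reverse=True)


def canonicalize(candidates: Iterable[Complex]) -> list[Complex]:
    """Remove duplicates and subsumed complexes; return canonical order.

    A complex that is a subcomplex of another retained complex carries no
    extra structural information (its variables already act jointly in the
    larger complex) and is dropped.
    """
    unique = set(candidates)
    kept = [
        c
        for c in unique
        if not any(c is not other and c.is_subcomplex(other) for other in unique)
    ]
    return canonical_order(kept)


@dataclass
class HigherOrderStructure:
    """The hypergraph G = (V, S): every node's higher-order neighbor set."""

    nodes: list[str]
    neighbors: dict[str, list[Complex]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        cleaned: dict[str, list[Complex]] = {}
        for u, complexes in self.neighbors.items():
            if u not in known:
                raise ValueError(f"node {u!r} not in the variable list")
            complexes = canonical_order(complexes)
            for c in complexes:
                missing = set(c.members) - known
                if missing:
                    raise ValueError(f"complex {c} of node {u} uses unknown {missing}")
            for a in complexes:
                for b in complexes:
                    if a is not b and a.is_subcomplex(b):
                        raise ValueError(
                            f"S_{u} violates the subsumption rule: {a} ⊆ {b}"
                        )
            cleaned[u] = complexes
        self.neighbors = cleaned

    def __getitem__(self, node: str) -> list[Complex]:
        return self.neighbors[node]

    def __contains__(self, node: str) -> bool:
        return node in self.neighbors

    def degree(self, node: str) -> int:
        """D_u, the number of higher-order neighbors of ``node``."""
        return len(self.neighbors[node])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HigherOrderStructure):
            return NotImplemented
        return self.nodes == other.nodes and {
            u: set(cs) for u, cs in self.neighbors.items()
        } == {u: set(cs) for u, cs in other.neighbors.items()}

    # -- hyperedge-list round trip ------------------------------------------

    def to_file(self, path) -> None:
        """Write one line per complex: ``u <TAB> v1,v2,...,vk``."""
        with open(path, "w") as fh:
            for u in self.nodes:
                for c in self.neighbors.get(u, []):
                    fh.write(f"{u}\t{','.join(c.members)}\n")

    @classmethod
    def from_file(cls, path, nodes: Sequence[str] | None = None) -> "HigherOrderStructure":
        neighbors: dict[str, list[Complex]] = {}
        seen: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                u, members = line.split("\t")
                if u not in neighbors:
                    neighbors[u] = []
                    seen.append(u)
                neighbors[u].append(Complex(members.split(",")))
        if nodes is None:
            extra = sorted(
                {v for cs in neighbors.values() for c in cs for v in c.members}
                - set(seen)
            )
            nodes = seen + extra
        return cls(nodes=list(nodes), neighbors=neighbors)

    @classmethod
    def from_mapping(
        cls, nodes: Sequence[str], mapping: Mapping[str, Iterable[Iterable[str]]]
    ) -> "HigherOrderStructure":
        return cls(
            nodes=list(nodes),
            neighbors={u: [Complex(m) for m in cs] for u, cs in mapping.items()},
        )
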