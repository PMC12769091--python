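"""Self-avoiding-walk enumeration and pathway free-energy bounds.

Every reversible-edge network defines, for each species Z, a set of
self-avoiding walks (SAWs) from the null complex Ø to Z.  A SAW together
with its reverse is a *pathway*; its free-energy change is the sum of edge
free-energy changes along the walk (sign-flipped for edges traversed
against their stored orientation):

    delta_g_S = sum_{e in S} ±delta_g_e        [k_B T]

The extreme pathway free energies bound the steady-state concentration of
Z for any thermodynamically self-consistent choice of rates:

    e^{-delta_g_L} <= c_Z <= e^{-delta_g_U},
    delta_g_U = min_S delta_g_S,   delta_g_L = max_S delta_g_S.

The per-product spread ``delta_G = delta_g_L - delta_g_U`` is the quantity
that bounds the accuracy of the whole product ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .network import NetworkError, TemplatingNetwork

__all__ = [
    "Pathway",
    "SpeciesBounds",
    "PathwayBounds",
    "EnumerationCapError",
    "enumerate_pathways",
    "pathway_bounds",
    "pathway_table",
]


class EnumerationCapError(NetworkError):
    """SAW enumeration exceeded the configured cap."""

    def __init__(self, species: str, cap: int):
        self.species = species
        self.cap = cap
        super().__init__(
            f"more than {cap} self-avoiding walks to {species!r}; "
            "raise the cap to enumerate exhaustively"
        )


@dataclass(frozen=True)
class Pathway:
    """One self-avoiding walk from Ø to a species.

    ``edge_sequence`` holds ``(u, v, key)`` triples oriented along the
    walk; ``key`` indexes the network's edge list.  ``delta_g_S`` is the
    summed free-energy change in k_B T.
    """

    species: str
    edge_sequence: tuple[tuple[str, str, int], ...]
    delta_g_S: float

    @property
    def node_sequence(self) -> tuple[str, ...]:
        return (self.edge_sequence[0][0],) + tuple(v for _, v, _ in self.edge_sequence)


def enumerate_pathways(
    network: TemplatingNetwork, species: str, cap: int = 10**6
) -> list[Pathway]:
    """Exhaustively enumerate SAWs from Ø to ``species``.

    Walks may traverse any reversible edge in either direction; cycles are
    excluded by construction (a SAW never revisits a node), so proofreading
    loops contribute only by opening additional acyclic routes.

    Raises
    ------
    EnumerationCapError
        If more than ``cap`` walks exist.
    KeyError
        If ``species`` is not a node of the network.
    """
    if species not in network.nodes:
        raise KeyError(f"unknown species {species!r}")
    root = network.null_id
    g = network.to_multigraph()
    out: list[Pathway] = []
    for edge_path in nx.all_simple_edge_paths(g, root, species):
        if len(out) >= cap:
            raise EnumerationCapError(species, cap)
        total = 0.0
        oriented: list[tuple[str, str, int]] = []
        for (u, v, key) in edge_path:
            e = network.edges[key]
            # MultiGraph reports endpoints in traversal order; the sign of
            # delta_g depends on whether that matches the stored direction.
            total += e.delta_g if (u, v) == (e.from_node, e.to_node) else -e.delta_g
            oriented.append((u, v, key))
        out.append(Pathway(species, tuple(oriented), total))
    return out


@dataclass(frozen=True)
class SpeciesBounds:
    """Concentration bounds for one species from its pathway extremes."""

    species: str
    delta_g_U: float  # min_S delta_g_S
    delta_g_L: float  # max_S delta_g_S
    n_pathways: int

    @property
    def c_U(self) -> float:
        return math.exp(-self.delta_g_U)

    @property
    def c_L(self) -> float:
        return math.exp(-self.delta_g_L)

    @property
    def delta_G(self) -> float:
        return self.delta_g_L - self.delta_g_U


@dataclass
class PathwayBounds:
    """Per-species pathway bounds plus the network-level spread."""

    products: dict[str, SpeciesBounds]
    intermediates: dict[str, SpeciesBounds]
    #: shared per-product spread when all products have identical
    #: {delta_g_S} extremes (symmetric networks); None otherwise.
    shared_delta_G: float | None

    def __getitem__(self, species: str) -> SpeciesBounds:
        if species in self.products:
            return self.products[species]
        return self.intermediates[species]

    def pairwise_delta_G(self, x: str, y: str) -> float:
        """Spread governing the concentration ratio c_x/c_y: delta_g_L(y) - delta_g_U(x)."""
        return self.products[y].delta_g_L - self.products[x].delta_g_U


def _species_bounds(network: TemplatingNetwork, species: str, cap: int) -> SpeciesBounds:
    pws = enumerate_pathways(network, species, cap=cap)
    sums = [p.delta_g_S for p in pws]
    return SpeciesBounds(species, min(sums), max(sums), len(sums))


def pathway_bounds(
    network: TemplatingNetwork, cap: int = 10**6, tol: float = 1e-9
) -> PathwayBounds:
    """Compute pathway free-energy extremes and concentration bounds.

    Bounds are computed for every species (products and intermediates —
    the underlying theorem applies to any species of a linear connected
    CRN rooted at Ø).  ``shared_delta_G`` is set when all products agree
    on (delta_g_U, delta_g_L) within ``tol``.
    """
    products = {p: _species_bounds(network, p, cap) for p in network.product_ids}
    intermediates = {
        i: _species_bounds(network, i, cap) for i in network.intermediate_ids
    }
    shared: float | None = None
    vals = list(products.values())
    if vals and all(
        abs(b.delta_g_U - vals[0].delta_g_U) <= tol
        and abs(b.delta_g_L - vals[0].delta_g_L) <= tol
        for b in vals
    ):
        shared = vals[0].delta_G
    return PathwayBounds(products, intermediates, shared)


def pathway_table(network: TemplatingNetwork, cap: int = 10**6) -> str:
    """TSV of all product pathways: product, pathway_index, node_sequence, delta_g_S."""
    lines = ["product\tpathway_index\tnode_sequence\tdelta_g_S"]
    for p in network.product_ids:
        for i, pw in enumerate(enumerate_pathways(network, p, cap=cap)):
            seq = "->".join(pw.node_sequence)
            lines.append(f"{p}\t{i}\t{seq}\t{pw.delta_g_S:.12g}")
    return "\n".join(lines) + "\n"
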