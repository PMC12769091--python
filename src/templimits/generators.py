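"""Constructors for templating networks with known ground truth.

These families are first-class citizens of the package: they define the
study conditions for the property suite and the worked examples.

* ``make_two_product_network`` — the minimal Ø⇌X, Ø⇌Y system with equal
  pathway free energies (zero spread, unbiased steady state) but
  arbitrary kinetic bias, used for the transient-specificity example.
* ``make_symmetric_network`` — M products, each wired to Ø by
  topologically identical pathway sets with identical pathway free
  energies but randomized intermediate energetics.
* ``make_saturating_network`` — a kinetically tuned family approaching
  the concentration bounds (and hence the specificity bound) in
  pseudo-equilibrium as the off-pathway slowdown ε → 0.
* ``make_random_consistent_network`` — random connected, reversible,
  thermodynamically self-consistent networks for property tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import ComplexNode, ReactionEdge, TemplatingNetwork

__all__ = [
    "PathwaySpec",
    "make_two_product_network",
    "make_symmetric_network",
    "make_saturating_network",
    "make_random_consistent_network",
    "add_cycle_edge",
    "NULL",
]

NULL = "Ø"


@dataclass(frozen=True)
class PathwaySpec:
    """Topology and total free-energy change of one pathway family."""

    length: int  # number of edges Ø -> product
    delta_g_S: float  # k_BT

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("pathway length must be >= 1")


def _rev(k_fwd: float, delta_g: float) -> float:
    """k_rev implied by local detailed balance for a target edge delta_g."""
    return k_fwd * math.exp(delta_g)


def make_two_product_network(
    k_X: float, k_Y: float, delta_g: float = 0.0
) -> TemplatingNetwork:
    """Two products made directly from Ø with equal pathway free energies.

    Production rate constants ``k_X``/``k_Y`` are free (kinetic bias);
    degradation rates follow from local detailed balance so both single-edge
    pathways carry the same ``delta_g``, giving zero spread.
    """
    if k_X <= 0 or k_Y <= 0:
        raise ValueError("rate constants must be positive")
    nodes = {
        NULL: ComplexNode(NULL, "null"),
        "X": ComplexNode("X", "product", free_energy=delta_g),
        "Y": ComplexNode("Y", "product", free_energy=delta_g),
    }
    edges = [
        ReactionEdge(NULL, "X", k_X, _rev(k_X, delta_g), chem_work=0.0),
        ReactionEdge(NULL, "Y", k_Y, _rev(k_Y, delta_g), chem_work=0.0),
    ]
    return TemplatingNetwork(nodes, edges, G0=delta_g)


def _chain(
    nodes: dict[str, ComplexNode],
    edges: list[ReactionEdge],
    product: str,
    tag: str,
    spec: PathwaySpec,
    rng: np.random.Generator,
    g_product: float,
    k_scale: float = 1.0,
) -> list[int]:
    """Append a chain Ø ⇌ I1 ⇌ … ⇌ product with total delta_g = spec.delta_g_S.

    Intermediate free energies are randomized; edge chemical work makes
    every edge individually consistent.  Returns the indices of the new
    edges.
    """
    interior = [f"I_{product}_{tag}_{j}" for j in range(spec.length - 1)]
    g_interior = rng.uniform(-3.0, 3.0, size=len(interior))
    for name, g in zip(interior, g_interior):
        nodes[name] = ComplexNode(name, "intermediate", free_energy=float(g))
    # split the pathway free energy into per-edge increments
    if spec.length == 1:
        splits = np.array([spec.delta_g_S])
    else:
        splits = rng.uniform(-2.0, 2.0, size=spec.length)
        splits[-1] = spec.delta_g_S - splits[:-1].sum()
    path = [NULL, *interior, product]
    g_node = [0.0, *g_interior, g_product]
    new_indices = []
    for j in range(spec.length):
        dg = float(splits[j])
        k_fwd = float(k_scale * 10 ** rng.uniform(-1, 1))
        chem_work = dg - (g_node[j + 1] - g_node[j])
        edges.append(
            ReactionEdge(path[j], path[j + 1], k_fwd, _rev(k_fwd, dg),
                         chem_work=chem_work)
        )
        new_indices.append(len(edges) - 1)
    return new_indices


def make_symmetric_network(
    M: int,
    pathway_specs: list[PathwaySpec],
    seed: int,
    G0: float = 0.0,
) -> TemplatingNetwork:
    """M products, each with the same pathway topologies and free energies.

    Intermediate free energies — and therefore rate constants — are
    drawn independently per product, so kinetics differ while every
    product shares the same multiset of pathway free-energy changes.
    """
    if M < 1:
        raise ValueError("need M >= 1")
    if not pathway_specs:
        raise ValueError("need at least one pathway spec")
    rng = np.random.default_rng(seed)
    nodes = {NULL: ComplexNode(NULL, "null")}
    edges: list[ReactionEdge] = []
    for i in range(1, M + 1):
        z = f"Z{i}"
        nodes[z] = ComplexNode(z, "product", free_energy=G0)
        for j, spec in enumerate(pathway_specs):
            _chain(nodes, edges, z, f"p{j}", spec, rng, g_product=G0)
    return TemplatingNetwork(nodes, edges, G0=G0)


def make_saturating_network(
    M: int,
    g_U: float,
    g_L: float,
    epsilon: float,
    seed: int,
    length: int = 2,
) -> TemplatingNetwork:
    """Bound-saturating family: kinetic tuning toward pseudo-equilibrium.

    Every product has exactly two pathways with free-energy changes
    ``g_U <= g_L``.  For product Z1, every edge of the g_L pathway is
    slowed by ``epsilon`` in *both* directions (pure kinetic tuning: all
    edge free energies are preserved); for the other products the g_U
    pathway is slowed instead.  As ε → 0 each product equilibrates along
    its fast pathway, so c_{Z1} → e^{-g_U} and c_{Zi>1} → e^{-g_L},
    approaching the specificity bound at spread g_L - g_U.
    """
    if not (g_U <= g_L):
        raise ValueError("need g_U <= g_L")
    if not (0 < epsilon <= 1):
        raise ValueError("epsilon must be in (0, 1]")
    rng = np.random.default_rng(seed)

    # one rate/energy template per pathway family, shared by all products,
    # so at epsilon = 1 the products are exactly interchangeable
    def template(total_dg: float):
        g_interior = rng.uniform(-2.0, 2.0, size=length - 1)
        if length == 1:
            splits = np.array([total_dg])
        else:
            splits = rng.uniform(-1.5, 1.5, size=length)
            splits[-1] = total_dg - splits[:-1].sum()
        k_fwds = 10 ** rng.uniform(-0.5, 0.5, size=length)
        return g_interior, splits, k_fwds

    templates = {"U": template(g_U), "L": template(g_L)}
    nodes = {NULL: ComplexNode(NULL, "null")}
    edges: list[ReactionEdge] = []
    for i in range(1, M + 1):
        z = f"Z{i}"
        nodes[z] = ComplexNode(z, "product", free_energy=0.0)
        slow_upper = i > 1  # product 1 keeps the favorable pathway fast
        for tag, slow in (("U", slow_upper), ("L", not slow_upper)):
            g_interior, splits, k_fwds = templates[tag]
            interior = [f"I_{z}_{tag}_{j}" for j in range(length - 1)]
            for name, g in zip(interior, g_interior):
                nodes[name] = ComplexNode(name, "intermediate", free_energy=float(g))
            path = [NULL, *interior, z]
            g_node = [0.0, *g_interior, 0.0]
            scale = epsilon if slow else 1.0
            for j in range(length):
                dg = float(splits[j])
                k_fwd = float(scale * k_fwds[j])
                chem_work = dg - (g_node[j + 1] - g_node[j])
                edges.append(
                    ReactionEdge(path[j], path[j + 1], k_fwd, _rev(k_fwd, dg),
                                 chem_work=chem_work)
                )
    return TemplatingNetwork(nodes, edges, G0=0.0)


def make_random_consistent_network(
    n_intermediates: int,
    n_products: int,
    extra_edges: int,
    seed: int,
    energy_range: float = 5.0,
    chem_work_range: float = 3.0,
) -> TemplatingNetwork:
    """Random connected reversible network, consistent by construction.

    Node free energies are uniform in [-energy_range, energy_range] k_BT,
    edge chemical work uniform in [-chem_work_range, chem_work_range],
    k_fwd log-uniform in [1e-2, 1e2] with k_rev fixed by local detailed
    balance.  A spanning tree rooted at Ø guarantees connectivity; extra
    edges (never product-product) add alternative pathways and cycles.
    """
    if n_products < 1:
        raise ValueError("need at least one product")
    rng = np.random.default_rng(seed)
    nodes = {NULL: ComplexNode(NULL, "null")}
    inter = [f"I{j}" for j in range(1, n_intermediates + 1)]
    prods = [f"Z{j}" for j in range(1, n_products + 1)]
    for name in inter:
        nodes[name] = ComplexNode(name, "intermediate",
                                  free_energy=float(rng.uniform(-energy_range, energy_range)))
    for name in prods:
        nodes[name] = ComplexNode(name, "product",
                                  free_energy=float(rng.uniform(-energy_range, energy_range)))

    def g_of(name: str) -> float:
        fe = nodes[name].free_energy
        return 0.0 if fe is None else fe

    def make_edge(u: str, v: str) -> ReactionEdge:
        w = float(rng.uniform(-chem_work_range, chem_work_range))
        dg = g_of(v) - g_of(u) + w
        k_fwd = float(10 ** rng.uniform(-2, 2))
        return ReactionEdge(u, v, k_fwd, _rev(k_fwd, dg), chem_work=w)

    edges: list[ReactionEdge] = []
    # spanning tree: intermediates attach to Ø or earlier intermediates;
    # products attach to Ø or any intermediate (no product-product edges)
    attachable = [NULL]
    for name in inter:
        parent = attachable[rng.integers(len(attachable))]
        edges.append(make_edge(parent, name))
        attachable.append(name)
    for name in prods:
        parent = attachable[rng.integers(len(attachable))]
        edges.append(make_edge(parent, name))

    non_null = inter + prods
    added = 0
    attempts = 0
    while added < extra_edges and attempts < 50 * (extra_edges + 1):
        attempts += 1
        u = ([NULL] + non_null)[rng.integers(len(non_null) + 1)]
        v = non_null[rng.integers(len(non_null))]
        if u == v:
            continue
        if nodes[u].kind == "product" and nodes[v].kind == "product":
            continue
        edges.append(make_edge(u, v))
        added += 1
    return TemplatingNetwork(nodes, edges)


def add_cycle_edge(
    network: TemplatingNetwork,
    node_a: str,
    node_b: str,
    delta_g: float,
    k_fwd: float = 1.0,
) -> TemplatingNetwork:
    """Add one consistent reversible edge closing a cycle (in place).

    ``delta_g`` is a free choice because chemical work on the new edge is
    unconstrained; the chem_work annotation is derived from the node free
    energies when both are present so validation still passes.
    """
    ga = network.nodes[node_a].free_energy
    gb = network.nodes[node_b].free_energy
    if network.nodes[node_a].kind == "null":
        ga = 0.0 if ga is None else ga
    if network.nodes[node_b].kind == "null":
        gb = 0.0 if gb is None else gb
    chem_work = None if ga is None or gb is None else delta_g - (gb - ga)
    network.edges.append(
        ReactionEdge(node_a, node_b, k_fwd, _rev(k_fwd, delta_g), chem_work=chem_work)
    )
    return network
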