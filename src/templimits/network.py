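"""Thermodynamically self-consistent linear templating networks.

A templating network is a connected graph of *complexes*: a unique null
complex Ø (free chemostatted species only), intermediate complexes, and
product complexes.  Every edge is a reversible mass-action reaction whose
forward/backward rate constants already absorb the concentrations of
chemostatted species (monomers, fuels, catalysts, templates).  Local
detailed balance ties kinetics to thermodynamics on every edge:

    delta_g = -ln(k_fwd / k_rev)        [k_B T]

where ``delta_g`` is the normalized standard free-energy change of the
reaction.  Optional per-node free energies and per-edge chemical-work
annotations allow cross-validation of that relation but are never required
for the dynamics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ComplexNode",
    "ReactionEdge",
    "TemplatingNetwork",
    "NetworkError",
    "SchemaError",
    "ValidationError",
    "ConnectivityError",
    "ValidationReport",
    "NETWORK_SCHEMA",
    "edge_free_energy",
    "load_network",
    "loads_network",
    "write_network",
    "dumps_network",
    "validate_thermodynamics",
    "check_product_symmetry",
]

NULL_LABEL = "Ø"

NODE_KINDS = ("null", "intermediate", "product")


class NetworkError(Exception):
    """Base class for templating-network errors."""


class SchemaError(NetworkError):
    """The network document violates the file schema."""


class ValidationError(NetworkError):
    """The network violates a structural or thermodynamic requirement."""


class ConnectivityError(ValidationError):
    """Some complex is unreachable from the null complex."""


#: Informal schema of the network JSON dialect (documented constant; the
#: loader enforces it field by field).
NETWORK_SCHEMA: Mapping[str, object] = {
    "nodes": [{"id": "str", "kind": "null|intermediate|product",
               "free_energy": "float (optional, k_BT)"}],
    "edges": [{"from": "str", "to": "str", "k_fwd": "float > 0",
               "k_rev": "float > 0", "chem_work": "float (optional, k_BT)"}],
    "meta": {"M": "int (optional)", "L": "float (optional)",
             "G0": "float (optional)",
             "chemostats": {"species": "mu_tilde (k_BT)"}},
}


def edge_free_energy(k_fwd: float, k_rev: float) -> float:
    """Normalized reaction free-energy change from local detailed balance.

    Returns ``-ln(k_fwd / k_rev)`` in units of k_B T.  Antisymmetric under
    swapping the two rates.

    Raises
    ------
    ValueError
        If either rate constant is not strictly positive.
    """
    if not (k_fwd > 0 and k_rev > 0):
        raise ValueError(
            f"rate constants must be positive, got k_fwd={k_fwd}, k_rev={k_rev}"
        )
    return -math.log(k_fwd / k_rev)


@dataclass
class ComplexNode:
    """One complex in the network (null, intermediate, or product)."""

    id: str
    kind: str
    free_energy: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise SchemaError(
                f"node {self.id!r}: kind must be one of {NODE_KINDS}, got {self.kind!r}"
            )


@dataclass
class ReactionEdge:
    """A reversible reaction between two complexes.

    ``delta_g`` is always derived from the rates via local detailed balance;
    ``chem_work`` (sum of chemostat chemical-potential changes along the
    reaction, k_B T) is optional bookkeeping used only for validation.
    """

    from_node: str
    to_node: str
    k_fwd: float
    k_rev: float
    chem_work: float | None = None

    def __post_init__(self) -> None:
        if not (self.k_fwd > 0):
            raise ValidationError(
                f"edge {self.from_node}->{self.to_node}: k_fwd must be > 0"
            )
        if not (self.k_rev > 0):
            raise ValidationError(
                f"edge {self.from_node}->{self.to_node}: k_rev must be > 0 "
                "(every reaction is reversible)"
            )

    @property
    def delta_g(self) -> float:
        """Free-energy change (k_B T) in the stored from→to direction."""
        return edge_free_energy(self.k_fwd, self.k_rev)

    @property
    def label(self) -> str:
        return f"{self.from_node}->{self.to_node}"


@dataclass
class TemplatingNetwork:
    """A linear templating CRN as a rooted, reversible-edge graph."""

    nodes: dict[str, ComplexNode]
    edges: list[ReactionEdge]
    L: float | None = None
    G0: float | None = None
    chemostats: dict[str, float] = field(default_factory=dict)

    # -- structure ----------------------------------------------------------

    @property
    def null_id(self) -> str:
        for node in self.nodes.values():
            if node.kind == "null":
                return node.id
        raise ValidationError("network has no null complex")

    @property
    def product_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.kind == "product"]

    @property
    def intermediate_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.kind == "intermediate"]

    @property
    def M(self) -> int:
        """Number of product complexes."""
        return len(self.product_ids)

    def to_multigraph(self) -> nx.MultiGraph:
        """Undirected multigraph view; edge key = index into ``self.edges``.

        Undirected because every reaction is reversible: a pathway may
        traverse any edge in either direction (reverse traversal negates
        ``delta_g``).
        """
        g = nx.MultiGraph()
        for node in self.nodes.values():
            g.add_node(node.id, kind=node.kind)
        for i, e in enumerate(self.edges):
            g.add_edge(e.from_node, e.to_node, key=i)
        return g

    def validate_structure(self) -> None:
        """Raise on structural violations (kinds, endpoints, connectivity)."""
        nulls = [n for n in self.nodes.values() if n.kind == "null"]
        if len(nulls) != 1:
            raise ValidationError(
                f"expected exactly one null complex, found {len(nulls)}"
            )
        for e in self.edges:
            for end in (e.from_node, e.to_node):
                if end not in self.nodes:
                    raise SchemaError(f"edge {e.label}: unknown node {end!r}")
            if e.from_node == e.to_node:
                raise ValidationError(f"edge {e.label}: self-loops not allowed")
            ka, kb = self.nodes[e.from_node].kind, self.nodes[e.to_node].kind
            if ka == "product" and kb == "product":
                raise ValidationError(
                    f"edge {e.label}: direct product-product reactions are "
                    "excluded (at most one product/intermediate per reaction)"
                )
        g = self.to_multigraph()
        root = self.null_id
        reachable = nx.node_connected_component(g, root) if g.number_of_nodes() else set()
        missing = set(self.nodes) - reachable
        if missing:
            raise ConnectivityError(
                f"nodes unreachable from {root!r}: {sorted(missing)}"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {
            "nodes": [
                {"id": n.id, "kind": n.kind}
                | ({"free_energy": n.free_energy} if n.free_energy is not None else {})
                for n in self.nodes.values()
            ],
            "edges": [
                {"from": e.from_node, "to": e.to_node,
                 "k_fwd": e.k_fwd, "k_rev": e.k_rev}
                | ({"chem_work": e.chem_work} if e.chem_work is not None else {})
                for e in self.edges
            ],
            "meta": {"M": self.M},
        }
        if self.L is not None:
            doc["meta"]["L"] = self.L
        if self.G0 is not None:
            doc["meta"]["G0"] = self.G0
        if self.chemostats:
            doc["meta"]["chemostats"] = dict(self.chemostats)
        return doc


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise SchemaError(msg)


def _parse_document(doc: object) -> TemplatingNetwork:
    _require(isinstance(doc, dict), "document root must be a JSON object")
    assert isinstance(doc, dict)
    unknown = set(doc) - {"nodes", "edges", "meta"}
    _require(not unknown, f"unknown top-level keys: {sorted(unknown)}")
    _require("nodes" in doc, "missing required key 'nodes'")
    _require("edges" in doc, "missing required key 'edges'")
    _require(isinstance(doc["nodes"], list), "'nodes' must be a list")
    _require(isinstance(doc["edges"], list), "'edges' must be a list")

    nodes: dict[str, ComplexNode] = {}
    for raw in doc["nodes"]:
        _require(isinstance(raw, dict), "each node must be an object")
        _require("id" in raw, "node missing 'id'")
        _require("kind" in raw, f"node {raw.get('id')!r} missing 'kind'")
        nid = raw["id"]
        _require(isinstance(nid, str) and nid, "node 'id' must be a non-empty string")
        _require(nid not in nodes, f"duplicate node id {nid!r}")
        fe = raw.get("free_energy")
        if fe is not None:
            _require(isinstance(fe, (int, float)), f"node {nid!r}: 'free_energy' must be a number")
        nodes[nid] = ComplexNode(id=nid, kind=raw["kind"], free_energy=fe)

    edges: list[ReactionEdge] = []
    for raw in doc["edges"]:
        _require(isinstance(raw, dict), "each edge must be an object")
        for key in ("from", "to", "k_fwd", "k_rev"):
            _require(key in raw, f"edge {raw.get('from')}->{raw.get('to')}: missing '{key}'")
        for key in ("k_fwd", "k_rev", "chem_work"):
            val = raw.get(key)
            if key in raw:
                _require(isinstance(val, (int, float)),
                         f"edge {raw['from']}->{raw['to']}: '{key}' must be a number")
        edges.append(
            ReactionEdge(
                from_node=raw["from"], to_node=raw["to"],
                k_fwd=float(raw["k_fwd"]), k_rev=float(raw["k_rev"]),
                chem_work=(float(raw["chem_work"]) if "chem_work" in raw else None),
            )
        )

    meta = doc.get("meta", {})
    _require(isinstance(meta, dict), "'meta' must be an object")
    chemostats = meta.get("chemostats", {})
    _require(isinstance(chemostats, dict), "'meta.chemostats' must be an object")

    net = TemplatingNetwork(
        nodes=nodes,
        edges=edges,
        L=meta.get("L"),
        G0=meta.get("G0"),
        chemostats={str(k): float(v) for k, v in chemostats.items()},
    )
    net.validate_structure()
    declared_m = meta.get("M")
    if declared_m is not None and declared_m != net.M:
        raise SchemaError(
            f"meta.M = {declared_m} disagrees with product count {net.M}"
        )
    return net


def loads_network(text: str) -> TemplatingNetwork:
    """Parse and validate a network from a JSON string."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON: {exc}") from exc
    return _parse_document(doc)


def load_network(path) -> TemplatingNetwork:
    """Load and validate a network from a JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_network(fh.read())


def dumps_network(network: TemplatingNetwork) -> str:
    return json.dumps(network.to_dict(), indent=2, ensure_ascii=False)


def write_network(network: TemplatingNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_network(network) + "\n")


# -- thermodynamic validation -------------------------------------------------


@dataclass
class ValidationCheck:
    subject: str
    check: str
    residual: float
    passed: bool


@dataclass
class ValidationReport:
    checks: list[ValidationCheck]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_tsv(self) -> str:
        lines = ["subject\tcheck\tresidual\tpass"]
        for c in self.checks:
            lines.append(f"{c.subject}\t{c.check}\t{c.residual:.12g}\t{c.passed}")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        status = "PASS" if self.ok else "FAIL"
        body = "\n".join(
            f"  [{'ok' if c.passed else 'FAIL'}] {c.subject}: {c.check} "
            f"(residual {c.residual:.3g})"
            for c in self.checks
        )
        return f"thermodynamic validation: {status}\n{body}"


def validate_thermodynamics(
    network: TemplatingNetwork, tol: float = 1e-8
) -> ValidationReport:
    """Check local detailed balance consistency of a loaded network.

    Per edge: rates strictly positive (reversibility) and, when both node
    free energies and ``chem_work`` are annotated, agreement of
    ``-ln(k_fwd/k_rev)`` with ``G_to - G_from + chem_work`` to ``tol``.
    Also records connectivity.  Failures are carried in the report, not
    raised.
    """
    checks: list[ValidationCheck] = []
    for e in network.edges:
        ok = e.k_fwd > 0 and e.k_rev > 0
        checks.append(ValidationCheck(e.label, "reversibility", 0.0 if ok else math.inf, ok))
        g_from = network.nodes[e.from_node].free_energy
        g_to = network.nodes[e.to_node].free_energy
        if network.nodes[e.from_node].kind == "null":
            g_from = 0.0 if g_from is None else g_from
        if network.nodes[e.to_node].kind == "null":
            g_to = 0.0 if g_to is None else g_to
        if g_from is not None and g_to is not None and e.chem_work is not None:
            residual = e.delta_g - (g_to - g_from + e.chem_work)
            checks.append(
                ValidationCheck(e.label, "local_detailed_balance",
                                residual, abs(residual) <= tol)
            )
    try:
        network.validate_structure()
        checks.append(ValidationCheck("network", "connectivity", 0.0, True))
    except NetworkError:
        checks.append(ValidationCheck("network", "connectivity", math.inf, False))
    return ValidationReport(checks)


# -- product symmetry ---------------------------------------------------------


@dataclass
class SymmetryPair:
    product_a: str
    product_b: str
    isomorphic: bool
    delta_g_match: bool

    @property
    def equivalent(self) -> bool:
        return self.isomorphic and self.delta_g_match


@dataclass
class SymmetryReport:
    pairs: list[SymmetryPair]

    @property
    def symmetric(self) -> bool:
        return all(p.equivalent for p in self.pairs)


def _saw_subgraph(network: TemplatingNetwork, product: str, cap: int) -> nx.MultiGraph:
    """Union of all self-avoiding walks Ø→product, as a rooted multigraph.

    Node attribute ``role`` marks the root and the target product so the
    isomorphism test respects the rooting.
    """
    from .pathways import enumerate_pathways  # local import: avoid cycle

    g = network.to_multigraph()
    sub = nx.MultiGraph()
    for pw in enumerate_pathways(network, product, cap=cap):
        for (u, v, key) in pw.edge_sequence:
            sub.add_edge(u, v, key=key)
    root = network.null_id
    for n in sub.nodes:
        if n == root:
            role = "root"
        elif n == product:
            role = "target"
        else:
            role = "other"
        sub.nodes[n]["role"] = role
    _ = g
    return sub


def check_product_symmetry(
    network: TemplatingNetwork,
    tol: float = 1e-9,
    cap: int = 10**6,
) -> SymmetryReport:
    """Test pairwise topological equivalence of products.

    Two products are equivalent when (a) the subgraphs spanned by their
    self-avoiding walks from Ø are isomorphic as rooted graphs and (b) the
    multisets of pathway free-energy changes coincide within ``tol``.
    Symmetry is reported, never required: asymmetric networks are analyzed
    per product downstream.
    """
    from .pathways import enumerate_pathways

    products = network.product_ids
    sums: dict[str, list[float]] = {}
    subs: dict[str, nx.MultiGraph] = {}
    for p in products:
        sums[p] = sorted(pw.delta_g_S for pw in enumerate_pathways(network, p, cap=cap))
        subs[p] = _saw_subgraph(network, p, cap=cap)

    pairs: list[SymmetryPair] = []
    for i, a in enumerate(products):
        for b in products[i + 1:]:
            iso = nx.is_isomorphic(
                subs[a], subs[b],
                node_match=lambda x, y: x["role"] == y["role"],
            )
            ga, gb = sums[a], sums[b]
            match = len(ga) == len(gb) and all(
                abs(x - y) <= tol for x, y in zip(ga, gb)
            )
            pairs.append(SymmetryPair(a, b, iso, match))
    return SymmetryReport(pairs)
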