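"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import pytest

from templimits.network import ComplexNode, ReactionEdge, TemplatingNetwork

NULL = "Ø"


def build_network(node_specs, edge_specs, **meta) -> TemplatingNetwork:
    """Compact literal constructor: node_specs = {id: kind}, edge_specs =
    [(u, v, k_fwd, k_rev), ...]."""
    nodes = {nid: ComplexNode(nid, kind) for nid, kind in node_specs.items()}
    edges = [ReactionEdge(u, v, kf, kr) for u, v, kf, kr in edge_specs]
    return TemplatingNetwork(nodes, edges, **meta)


@pytest.fixture
def single_edge_network() -> TemplatingNetwork:
    """Ø ⇌ Z with k_fwd=2, k_rev=1: equilibrium c_Z = 2."""
    return build_network({NULL: "null", "Z": "product"}, [(NULL, "Z", 2.0, 1.0)])


@pytest.fixture
def chain_network() -> TemplatingNetwork:
    """Ø ⇌ I ⇌ Z with edge free energies (-1, +0.5): one pathway, sum -0.5."""
    return build_network(
        {NULL: "null", "I": "intermediate", "Z": "product"},
        [(NULL, "I", math.e, 1.0), ("I", "Z", 1.0, math.exp(0.5))],
    )


@pytest.fixture
def diamond_network() -> TemplatingNetwork:
    """Two 2-edge pathways to Z with sums -2 and +1 (spread 3)."""
    return build_network(
        {NULL: "null", "I1": "intermediate", "I2": "intermediate", "Z": "product"},
        [
            (NULL, "I1", math.e, 1.0),  # dg = -1
            ("I1", "Z", math.e, 1.0),   # dg = -1   -> pathway sum -2
            (NULL, "I2", 1.0, math.e),  # dg = +1
            ("I2", "Z", 1.0, 1.0),      # dg = 0    -> pathway sum +1
        ],
    )


def brute_force_saws(network: TemplatingNetwork, target: str):
    """Independent recursive enumerator of simple paths Ø → target.

    Works directly on the edge list (both traversal directions), with no
    networkx involvement; returns a sorted list of (node_tuple, delta_g_S).
    """
    adj: dict[str, list[tuple[str, float]]] = {}
    for e in network.edges:
        adj.setdefault(e.from_node, []).append((e.to_node, e.delta_g))
        adj.setdefault(e.to_node, []).append((e.from_node, -e.delta_g))
    root = network.null_id
    results: list[tuple[tuple[str, ...], float]] = []

    def recurse(node: str, visited: tuple[str, ...], total: float) -> None:
        if node == target:
            results.append((visited, total))
            return
        for nxt, dg in adj.get(node, ()):
            if nxt not in visited:
                recurse(nxt, visited + (nxt,), total + dg)

    recurse(root, (root,), 0.0)
    return sorted(results)
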