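"""Exact stochastic simulation (SSA) of linear templating networks.

Chemostatted species are implicit, so every reaction is either a
zeroth-order birth from the null complex Ø (propensity ``k_fwd * V``), a
unimolecular hop between tracked complexes (propensity ``k * count``), or
a death into Ø.  Copy numbers relate to deterministic activities through
the volume ``V`` (counts = concentration × V).

Because the network is linear, molecules evolve independently; the event
stream can therefore be decomposed into single-molecule trajectories.
Each molecule's life splits into excursions:

* Ø → first arrival at a product: a *production* event,
* product → first return to Ø: a *degradation* event,

and each excursion is assigned to a self-avoiding walk of the network by
loop-erasure of its node sequence.  The per-pathway ratio of production
to degradation counts is the empirical Γ̂, whose steady-state expectation
is ``e^{-delta_g_S} / c``; Γ̂ = 1 on every pathway is the fingerprint of
pseudo-equilibrium operation.

Entropy production is accumulated per event as
``ln(a_forward / a_reverse_after)`` (k_B), the log-ratio of the executed
transition's propensity to that of its reverse in the post-jump state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import TemplatingNetwork

__all__ = [
    "EventLog",
    "PathwayCounts",
    "TrajectoryStats",
    "simulate",
    "classify_trajectories",
    "entropy_per_event",
]

_REPLAY_SALT = 0x5EED


@dataclass
class EventLog:
    """Ordered record of one SSA realization."""

    seed: int
    volume: float
    horizon: float
    #: (time, edge_index, direction) with direction +1 = stored from→to
    events: list[tuple[float, int, int]]
    final_counts: dict[str, int]

    def to_tsv(self) -> str:
        lines = ["time\tedge_index\tdirection"]
        for t, e, d in self.events:
            lines.append(f"{t:.12g}\t{e}\t{d:+d}")
        return "\n".join(lines) + "\n"


def _directed_reactions(network: TemplatingNetwork):
    """Flatten reversible edges into directed reactions (edge, dir, src, dst, k)."""
    out = []
    for i, e in enumerate(network.edges):
        out.append((i, +1, e.from_node, e.to_node, e.k_fwd))
        out.append((i, -1, e.to_node, e.from_node, e.k_rev))
    return out


def simulate(
    network: TemplatingNetwork,
    volume: float,
    horizon: float,
    seed: int,
    initial_counts: dict[str, int] | None = None,
    max_events: int = 10**7,
) -> EventLog:
    """Run the exact SSA until ``horizon`` and return the event log.

    Identical arguments (including ``seed``) give a bit-identical log.
    Raises ``RuntimeError`` if ``max_events`` is exceeded (guard against
    runaway propensities).
    """
    if volume <= 0 or horizon <= 0:
        raise ValueError("volume and horizon must be positive")
    rng = np.random.default_rng(seed)
    null = network.null_id
    reactions = _directed_reactions(network)
    counts: dict[str, int] = {n: 0 for n in network.nodes if n != null}
    if initial_counts:
        for k, v in initial_counts.items():
            if v < 0:
                raise ValueError("negative initial count")
            counts[k] = int(v)

    by_source: dict[str, list[int]] = {}
    for j, (_e, _d, src, _dst, _k) in enumerate(reactions):
        by_source.setdefault(src, []).append(j)

    def propensity(j: int) -> float:
        _e, _d, src, _dst, k = reactions[j]
        return k * volume if src == null else k * counts[src]

    props = [propensity(j) for j in range(len(reactions))]
    total = sum(props)
    events: list[tuple[float, int, int]] = []
    t = 0.0
    n_events = 0
    while True:
        if total <= 0:
            break  # absorbing (impossible with any Ø-outgoing edge)
        t += rng.exponential(1.0 / total)
        if t > horizon:
            break
        u = rng.random() * total
        acc = 0.0
        j = len(reactions) - 1
        for jj, a in enumerate(props):
            acc += a
            if u < acc:
                j = jj
                break
        e_idx, direction, src, dst, _k = reactions[j]
        if src != null:
            counts[src] -= 1
        if dst != null:
            counts[dst] += 1
        for node in (src, dst):
            if node != null:
                for jj in by_source.get(node, ()):
                    total -= props[jj]
                    props[jj] = propensity(jj)
                    total += props[jj]
        events.append((t, e_idx, direction))
        n_events += 1
        if n_events > max_events:
            raise RuntimeError(f"exceeded max_events={max_events} before horizon")
        if n_events % 4096 == 0:
            total = sum(props)  # refresh running sum against float drift
    return EventLog(seed, volume, horizon, events, dict(counts))


@dataclass
class PathwayCounts:
    production: int = 0
    degradation: int = 0
    batch_production: list[int] = field(default_factory=list)
    batch_degradation: list[int] = field(default_factory=list)

    @property
    def gamma_hat(self) -> float:
        if self.degradation == 0:
            return math.inf
        return self.production / self.degradation


@dataclass
class TrajectoryStats:
    """Trajectory-level summary of an event log."""

    #: keyed by (product, node-sequence of the loop-erased SAW from Ø)
    pathways: dict[tuple[str, tuple[str, ...]], PathwayCounts]
    total_entropy: float  # k_B, summed over all events
    batch_entropy: list[float]
    batch_events: list[int]
    mean_counts: dict[str, float]  # time-averaged copy numbers
    volume: float
    horizon: float

    @property
    def production_total(self) -> int:
        return sum(p.production for p in self.pathways.values())

    @property
    def degradation_total(self) -> int:
        return sum(p.degradation for p in self.pathways.values())

    @property
    def entropy_per_production_event(self) -> float:
        if self.production_total == 0:
            raise ValueError("no production events recorded")
        return self.total_entropy / self.production_total

    def entropy_per_event_se(self) -> float:
        """Batch-means standard error of the entropy per production event."""
        vals = []
        for s, prod in zip(self.batch_entropy, self._batch_production()):
            if prod > 0:
                vals.append(s / prod)
        if len(vals) < 2:
            return math.inf
        return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))

    def _batch_production(self) -> list[int]:
        n_batches = len(self.batch_entropy)
        out = [0] * n_batches
        for pc in self.pathways.values():
            for b, v in enumerate(pc.batch_production):
                out[b] += v
        return out

    def gamma_hat(self, product: str, node_seq: tuple[str, ...]) -> float:
        return self.pathways[(product, node_seq)].gamma_hat

    def gamma_hat_se(self, product: str, node_seq: tuple[str, ...]) -> float:
        pc = self.pathways[(product, node_seq)]
        vals = [
            p / d
            for p, d in zip(pc.batch_production, pc.batch_degradation)
            if d > 0
        ]
        if len(vals) < 2:
            return math.inf
        return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))

    def to_tsv(self) -> str:
        lines = ["product\tpathway\tproduction\tdegradation\tgamma_hat"]
        for (prod, seq), pc in sorted(self.pathways.items()):
            g = pc.gamma_hat
            lines.append(
                f"{prod}\t{'->'.join(seq)}\t{pc.production}\t{pc.degradation}"
                f"\t{g if math.isfinite(g) else 'inf'}"
            )
        lines.append(f"# total_entropy_kB\t{self.total_entropy:.12g}")
        return "\n".join(lines) + "\n"


class _Token:
    """One tracked molecule: current loop-erased path and excursion mode."""

    __slots__ = ("path", "pos", "mode", "anchor")

    def __init__(self, start: str):
        self.path: list[str] = [start]
        self.pos: dict[str, int] = {start: 0}
        self.mode = "production"  # or "degradation"
        self.anchor = start  # Ø in production mode, the product in degradation

    def step(self, node: str) -> None:
        """Move to ``node``, erasing any loop this closes."""
        if node in self.pos:
            cut = self.pos[node] + 1
            for n in self.path[cut:]:
                del self.pos[n]
            del self.path[cut:]
        else:
            self.path.append(node)
            self.pos[node] = len(self.path) - 1


def classify_trajectories(
    log: EventLog, network: TemplatingNetwork, n_batches: int = 20
) -> TrajectoryStats:
    """Replay an event log into per-molecule excursions and entropy.

    Events at a node are attributed to a uniformly random molecule at
    that node (molecules of a linear CRN are exchangeable, so this
    recovers unbiased single-molecule statistics); the attribution RNG is
    derived from the log's seed, making classification deterministic.
    Molecules present before the first event (initial counts) are treated
    as freshly created at their node.
    """
    null = network.null_id
    products = set(network.product_ids)
    rng = np.random.default_rng((log.seed ^ _REPLAY_SALT) & 0x7FFFFFFF)
    reactions = _directed_reactions(network)

    # reconstruct initial counts by undoing the event stream from the final state
    counts = dict(log.final_counts)
    for _t, e_idx, direction in reversed(log.events):
        _e, _d, src, dst, _k = reactions[2 * e_idx + (0 if direction == +1 else 1)]
        if dst != null:
            counts[dst] -= 1
        if src != null:
            counts[src] += 1

    tokens: dict[str, list[_Token]] = {n: [] for n in counts}
    for node, n0 in counts.items():
        tokens[node].extend(_Token(node) for _ in range(n0))

    pathways: dict[tuple[str, tuple[str, ...]], PathwayCounts] = {}
    batch_width = log.horizon / n_batches
    total_entropy = 0.0
    batch_entropy = [0.0] * n_batches
    batch_events = [0] * n_batches
    time_weighted = {n: 0.0 for n in counts}
    t_prev = 0.0

    def counts_key(product: str, seq: tuple[str, ...]) -> PathwayCounts:
        key = (product, seq)
        if key not in pathways:
            pathways[key] = PathwayCounts(
                batch_production=[0] * n_batches, batch_degradation=[0] * n_batches
            )
        return pathways[key]

    for t, e_idx, direction in log.events:
        b = min(int(t / batch_width), n_batches - 1)
        fwd = reactions[2 * e_idx + (0 if direction == +1 else 1)]
        rev = reactions[2 * e_idx + (1 if direction == +1 else 0)]
        _e, _d, src, dst, k = fwd
        a_fwd = k * log.volume if src == null else k * counts[src]
        for node in counts:
            time_weighted[node] += counts[node] * (t - t_prev)
        t_prev = t

        # move one molecule
        if src == null:
            tok = _Token(null)
            tok.step(dst)
        else:
            pool = tokens[src]
            i = int(rng.integers(len(pool)))
            pool[i], pool[-1] = pool[-1], pool[i]
            tok = pool.pop()
            counts[src] -= 1
            tok.step(dst)
        if dst != null:
            tokens[dst].append(tok)
            counts[dst] += 1

        a_rev = rev[4] * log.volume if dst == null else rev[4] * counts[dst]
        ds = math.log(a_fwd / a_rev)
        total_entropy += ds
        batch_entropy[b] += ds
        batch_events[b] += 1

        # excursion bookkeeping
        if tok.mode == "production" and dst in products:
            seq = tuple(tok.path)
            if seq[0] == null:  # molecules present at t=0 are not counted
                pc = counts_key(dst, seq)
                pc.production += 1
                pc.batch_production[b] += 1
            tok.mode = "degradation"
            tok.anchor = dst
            tok.path = [dst]
            tok.pos = {dst: 0}
        elif tok.mode == "degradation" and dst == null:
            seq = tuple(reversed(tok.path))  # SAW Ø -> anchor product
            if seq[-1] in products and seq[0] == null:
                pc = counts_key(seq[-1], seq)
                pc.degradation += 1
                pc.batch_degradation[b] += 1
        elif tok.mode == "production" and dst == null:
            pass  # unproductive excursion; molecule died before any product

    for node in counts:
        time_weighted[node] += counts[node] * (log.horizon - t_prev)
    mean_counts = {n: v / log.horizon for n, v in time_weighted.items()}
    return TrajectoryStats(
        pathways=pathways,
        total_entropy=total_entropy,
        batch_entropy=batch_entropy,
        batch_events=batch_events,
        mean_counts=mean_counts,
        volume=log.volume,
        horizon=log.horizon,
    )


def entropy_per_event(stats: TrajectoryStats) -> float:
    """Entropy produced per completed production event (k_B)."""
    return stats.entropy_per_production_event
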