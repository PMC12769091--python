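"""Deterministic mass-action dynamics of linear templating networks.

Because every complex holds at most one tracked species and chemostatted
species are absorbed into rate constants, the concentration dynamics are
linear with the null complex Ø acting as a constant source (activity
c_Ø ≡ 1).  Steady states are therefore obtained by a direct linear solve;
ODE integration is provided both for transients and as an independent
cross-check of the solver.

The module also computes per-edge fluxes, the total entropy production
rate

    sigma = sum_edges (J+ - J-) ln(J+/J-)       [k_B / time],

the pathway production/degradation ratios Gamma = e^{-delta_g_S}/c, and
the steady-state identity linking concentration ratios of two products to
the pathway spread and their Gamma ratios:

    ln(c_X/c_Y) = delta_G + ln(Gamma_Y(delta_g_L) / Gamma_X(delta_g_U)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkError, TemplatingNetwork
from .pathways import Pathway, PathwayBounds, pathway_bounds

__all__ = [
    "ConcentrationProfile",
    "EdgeFlux",
    "FluxReport",
    "SolverError",
    "solve_steady_state",
    "integrate_transient",
    "edge_fluxes",
    "gamma_ratio",
    "eq_balance_residual",
]


class SolverError(NetworkError):
    """Linear solve or ODE integration failed."""


@dataclass
class ConcentrationProfile:
    """Concentrations (dimensionless activities) of all non-null species."""

    concentrations: dict[str, float]
    time: float | None = None  # None marks a steady state

    @property
    def steady(self) -> bool:
        return self.time is None

    def total_product_concentration(self, network: TemplatingNetwork) -> float:
        return sum(self.concentrations[p] for p in network.product_ids)

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]


def _species_order(network: TemplatingNetwork) -> list[str]:
    return [n for n in network.nodes if network.nodes[n].kind != "null"]


def _rate_operator(network: TemplatingNetwork) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Linear generator (W, s) with dc/dt = W c + s, c ordered as returned."""
    order = _species_order(network)
    idx = {n: i for i, n in enumerate(order)}
    null = network.null_id
    n = len(order)
    w = np.zeros((n, n))
    s = np.zeros(n)
    for e in network.edges:
        u, v = e.from_node, e.to_node
        # forward direction u -> v at k_fwd, reverse v -> u at k_rev
        for src, dst, k in ((u, v, e.k_fwd), (v, u, e.k_rev)):
            if src == null:
                s[idx[dst]] += k  # zeroth-order source, c_null == 1
            else:
                i = idx[src]
                w[i, i] -= k
                if dst != null:
                    w[idx[dst], i] += k
    return order, w, s


def solve_steady_state(
    network: TemplatingNetwork,
    residual_tol: float = 1e-9,
    cond_warn: float = 1e12,
) -> ConcentrationProfile:
    """Solve the stationary balance equations W c = -s exactly.

    Raises
    ------
    SolverError
        If the system is singular, the relative residual exceeds
        ``residual_tol``, or any concentration comes out negative beyond
        round-off.
    """
    order, w, s = _rate_operator(network)
    if not order:
        return ConcentrationProfile({}, time=None)
    try:
        c = np.linalg.solve(w, -s)
    except np.linalg.LinAlgError as exc:
        raise SolverError(f"singular balance system: {exc}") from exc
    residual = np.linalg.norm(w @ c + s)
    scale = max(np.linalg.norm(s), 1.0)
    if residual > residual_tol * scale:
        cond = np.linalg.cond(w)
        raise SolverError(
            f"steady-state residual {residual:.3e} exceeds tolerance "
            f"(condition number ~{cond:.3e})"
        )
    if np.any(c < -1e-12 * scale):
        raise SolverError("negative steady-state concentration")
    cond = np.linalg.cond(w)
    if cond > cond_warn:
        import warnings

        warnings.warn(
            f"ill-conditioned balance system (cond ~ {cond:.3e})", RuntimeWarning
        )
    return ConcentrationProfile(dict(zip(order, np.maximum(c, 0.0))), time=None)


def integrate_transient(
    network: TemplatingNetwork,
    initial: dict[str, float] | None,
    times: "np.ndarray | list[float]",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> list[ConcentrationProfile]:
    """Integrate the mass-action ODEs on a strictly increasing time grid.

    ``initial`` maps species to starting concentrations (missing species
    start at zero; ``None`` means all zero).  Converges to the
    ``solve_steady_state`` fixed point as t → ∞.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be one-dimensional and strictly increasing")
    order, w, s = _rate_operator(network)
    c0 = np.zeros(len(order))
    if initial:
        for name, val in initial.items():
            if val < 0:
                raise ValueError(f"negative initial concentration for {name!r}")
            c0[order.index(name)] = val
    sol = solve_ivp(
        lambda _t, c: w @ c + s,
        (0.0, float(t[-1])),
        c0,
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
        jac=lambda _t, _c: w,
    )
    if not sol.success:
        raise SolverError(f"transient integration failed: {sol.message}")
    return [
        ConcentrationProfile(dict(zip(order, sol.y[:, j])), time=float(t[j]))
        for j in range(t.size)
    ]


@dataclass(frozen=True)
class EdgeFlux:
    edge_index: int
    label: str
    j_plus: float
    j_minus: float

    @property
    def net(self) -> float:
        return self.j_plus - self.j_minus

    @property
    def entropy_rate(self) -> float:
        """(J+ - J-) ln(J+/J-); zero when balanced, +inf on one-way flux."""
        if self.j_plus == self.j_minus:
            return 0.0
        if self.j_plus <= 0 or self.j_minus <= 0:
            return math.inf
        return (self.j_plus - self.j_minus) * math.log(self.j_plus / self.j_minus)


@dataclass
class FluxReport:
    fluxes: list[EdgeFlux]

    @property
    def sigma(self) -> float:
        """Total entropy production rate, k_B per unit time."""
        return sum(f.entropy_rate for f in self.fluxes)

    def to_tsv(self) -> str:
        lines = ["edge\tj_plus\tj_minus\tnet\tentropy_rate"]
        for f in self.fluxes:
            lines.append(
                f"{f.label}\t{f.j_plus:.12g}\t{f.j_minus:.12g}"
                f"\t{f.net:.12g}\t{f.entropy_rate:.12g}"
            )
        lines.append(f"TOTAL\t\t\t\t{self.sigma:.12g}")
        return "\n".join(lines) + "\n"


def edge_fluxes(network: TemplatingNetwork, profile: ConcentrationProfile) -> FluxReport:
    """Per-edge forward/backward/net fluxes and entropy production rate."""
    null = network.null_id

    def conc(node: str) -> float:
        return 1.0 if node == null else profile.concentrations[node]

    fluxes = [
        EdgeFlux(i, e.label, e.k_fwd * conc(e.from_node), e.k_rev * conc(e.to_node))
        for i, e in enumerate(network.edges)
    ]
    return FluxReport(fluxes)


def gamma_ratio(
    network: TemplatingNetwork,
    profile: ConcentrationProfile,
    species: str,
    pathway: "Pathway | float",
) -> float:
    """Steady-state production/degradation trajectory ratio along a pathway.

    Gamma = e^{-delta_g_S} / c_species.  Gamma = 1 on every pathway is
    pseudo-equilibrium; Gamma > 1 signals net production along the
    pathway, Gamma < 1 net degradation.
    """
    c = profile.concentrations[species]
    if c <= 0:
        raise ValueError(f"species {species!r} has non-positive concentration")
    dg = pathway.delta_g_S if isinstance(pathway, Pathway) else float(pathway)
    return math.exp(-dg) / c


def eq_balance_residual(
    network: TemplatingNetwork,
    profile: ConcentrationProfile,
    x: str,
    y: str,
    bounds: PathwayBounds | None = None,
) -> float:
    """Residual of the steady-state accuracy identity for products x, y.

    Returns ln(c_x/c_y) - [delta_G + ln(Gamma_y(delta_g_L) * Gamma_x(delta_g_U))]
    with delta_G = delta_g_L(y) - delta_g_U(x); identically zero (to
    floating error) at any steady state, making it a strong solver check.
    """
    if bounds is None:
        bounds = pathway_bounds(network)
    gx = gamma_ratio(network, profile, x, bounds.products[x].delta_g_U)
    gy = gamma_ratio(network, profile, y, bounds.products[y].delta_g_L)
    dG = bounds.pairwise_delta_G(x, y)
    lhs = math.log(profile.concentrations[x] / profile.concentrations[y])
    return lhs - (dG + math.log(gy / gx))
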