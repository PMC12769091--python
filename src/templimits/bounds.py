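"""Closed-form accuracy bounds on the steady-state product ensemble.

For M products whose concentrations are confined to [c_L, c_U] =
[e^{-delta_g_L}, e^{-delta_g_U}] with spread delta_G = delta_g_L -
delta_g_U, two accuracy metrics of the product distribution
p_i = c_i / c_T are bounded in closed form:

* single-product specificity:
      p_max <= (1 + (M-1) e^{-delta_G})^{-1},   p_low = e^{-delta_G} p_max

* Shannon entropy (nats): H[p] >= min_m H(m) over integer m in {1..M},

      H(m) = (M-m) delta_G e^{-delta_G} / (m + (M-m) e^{-delta_G})
             + ln(m + (M-m) e^{-delta_G}),

  realized by m species at c_U and M-m at c_L.  The minimizing m can
  exceed 1: pushing several species to the upper bound inflates c_T and
  suppresses everyone else.  The specificity- and entropy-optimal
  ensembles coincide only above roughly delta_G = ln M + ln ln M.

All entropies are in nats unless converted explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import TemplatingNetwork
from .steady_state import ConcentrationProfile

__all__ = [
    "ProductDistribution",
    "BoundResult",
    "product_distribution",
    "specificity_bound",
    "required_delta_G",
    "entropy_bound",
    "continuous_m_argmin",
    "max_specificity_entropy",
    "overlap_threshold",
    "sweep_bounds",
]

#: switch from exhaustive integer scan to convexity-based search above this M
_SCAN_LIMIT = 10**7


@dataclass
class ProductDistribution:
    """Normalized steady-state product ensemble and its accuracy metrics."""

    labels: list[str]
    p: np.ndarray

    @property
    def M(self) -> int:
        return self.p.size

    @property
    def p_max(self) -> float:
        return float(self.p.max())

    @property
    def entropy(self) -> float:
        """Shannon entropy H = -sum p ln p in nats (0 ln 0 := 0)."""
        pos = self.p[self.p > 0]
        return float(-(pos * np.log(pos)).sum())

    @property
    def info(self) -> float:
        """ln M - H: capacity of the network viewed as a template→product channel."""
        return math.log(self.M) - self.entropy

    def entropy_bits(self) -> float:
        return self.entropy / math.log(2.0)


def product_distribution(
    profile: ConcentrationProfile, network: TemplatingNetwork
) -> ProductDistribution:
    """Normalize product concentrations into a probability distribution."""
    labels = network.product_ids
    c = np.array([profile.concentrations[z] for z in labels], dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("all product concentrations are zero")
    return ProductDistribution(labels, c / total)


def specificity_bound(M: int, delta_G: float) -> tuple[float, float]:
    """Upper bound on single-product specificity and the matching floor.

    Returns ``(p_max_bound, p_low)`` with p_max = (1+(M-1)e^{-delta_G})^{-1}
    and p_low = e^{-delta_G} p_max (the weight of each of the other M-1
    products in the saturating ensemble).  Computed in log space so it
    stays finite and monotone up to M ~ 2**63.
    """
    if M < 2:
        raise ValueError("specificity bound needs M >= 2 competing products")
    if delta_G < 0:
        raise ValueError("delta_G must be non-negative")
    # (M-1) e^{-dG} without forming M-1 e^{dG} style overflows
    t = math.exp(math.log(M - 1) - delta_G)
    p_max = 1.0 / (1.0 + t)
    return p_max, math.exp(-delta_G) * p_max


def required_delta_G(M: int, target_error: float) -> float:
    """Pathway spread needed so the total error 1 - p_max equals ``target_error``.

    Inverts the specificity bound: delta_G = ln((M-1)(1-e)/e).  Feasible
    targets lie in (0, 1 - 1/M]; the endpoint is the uniform ensemble,
    which needs no drive (delta_G = 0).
    """
    if M < 2:
        raise ValueError("need M >= 2")
    if not (0.0 < target_error <= 1.0 - 1.0 / M):
        raise ValueError(
            f"target error must lie in (0, 1 - 1/M] = (0, {1 - 1/M:.6g}]"
        )
    return math.log(M - 1) + math.log1p(-target_error) - math.log(target_error)


def _h_of_m(m, M: int, delta_G: float):
    """Entropy H(m) of m species at c_U and M-m at c_L (vectorized in m)."""
    m = np.asarray(m, dtype=float)
    a = math.exp(-delta_G)
    d = m + (float(M) - m) * a
    return (float(M) - m) * delta_G * a / d + np.log(d)


def _p_high(m: float, M: int, delta_G: float) -> float:
    a = math.exp(-delta_G)
    return m / (m + (M - m) * a)


def continuous_m_argmin(M: int, delta_G: float) -> float:
    """Stationary point of H(m) treated as continuous, clamped to [1, M].

    Closed form m* = M a (delta_G - 1 + a) / (1 - a)^2 with a = e^{-delta_G};
    a slightly weaker relaxation of the integer minimization, useful for
    very large M and as an analytic cross-check.
    """
    a = math.exp(-delta_G)
    if a >= 1.0:  # delta_G == 0: H is flat
        return 1.0
    m_star = M * a * (delta_G - 1.0 + a) / (1.0 - a) ** 2
    return min(max(m_star, 1.0), float(M))


@dataclass
class BoundResult:
    """Entropy-minimization result for a given (M, delta_G)."""

    M: int
    delta_G: float
    h_min: float          # nats
    m_min: float          # integer-valued unless method == "continuous"
    p_high: float         # total weight of the m_min high-concentration species
    method: str = "integer"

    def h_of_m(self, m):
        """Evaluate the entropy H(m) of the two-level ensemble at given m."""
        return _h_of_m(m, self.M, self.delta_G)

    @property
    def h_min_bits(self) -> float:
        return self.h_min / math.log(2.0)


def _integer_argmin(M: int, delta_G: float) -> int:
    """Smallest integer m in {1..M} minimizing H(m)."""
    if math.exp(-delta_G) >= 1.0:
        return 1  # flat objective; smallest-m tie-break
    if M <= _SCAN_LIMIT:
        m = np.arange(1, M + 1)
        return int(m[np.argmin(_h_of_m(m, M, delta_G))])
    # H(m) is unimodal in m (discretely convex); narrow by ternary search,
    # then scan a safety window so the smallest minimizer is reported.
    lo, hi = 1, M
    while hi - lo > 8:
        m1 = lo + (hi - lo) // 3
        m2 = hi - (hi - lo) // 3
        if _h_of_m(m1, M, delta_G) < _h_of_m(m2, M, delta_G):
            hi = m2 - 1
        else:
            lo = m1 + 1
    window = np.arange(max(1, lo - 4), min(M, hi + 4) + 1)
    return int(window[np.argmin(_h_of_m(window, M, delta_G))])


def entropy_bound(M: int, delta_G: float, method: str = "integer") -> BoundResult:
    """Lower bound on ensemble entropy by minimizing H(m) over m.

    ``method="integer"`` (default) minimizes exactly over m in {1..M};
    ``method="continuous"`` uses the analytic continuous-m stationary
    point, a slightly weaker bound retained for analysis at extreme M.
    """
    if M < 1:
        raise ValueError("need M >= 1")
    if delta_G < 0:
        raise ValueError("delta_G must be non-negative")
    if method == "integer":
        m_min: float = _integer_argmin(M, delta_G)
    elif method == "continuous":
        m_min = continuous_m_argmin(M, delta_G)
    else:
        raise ValueError(f"unknown method {method!r}")
    return BoundResult(
        M=M,
        delta_G=delta_G,
        h_min=float(_h_of_m(m_min, M, delta_G)),
        m_min=m_min,
        p_high=_p_high(m_min, M, delta_G),
        method=method,
    )


def max_specificity_entropy(M: int, delta_G: float) -> float:
    """Entropy (nats) of the maximum-specificity ensemble.

    One species at p_max, the other M-1 at p_low; computed via
    (M-1) p_low = 1 - p_max so it is stable for astronomically large M.
    """
    p_max, p_low = specificity_bound(M, delta_G)
    ln_p_low = math.log(p_max) - delta_G
    h = -p_max * math.log(p_max)
    if p_max < 1.0:
        h -= (1.0 - p_max) * ln_p_low
    return h


def overlap_threshold(M: float) -> float:
    """delta_G above which entropy minimization collapses to m_min = 1.

    Leading order ln M + ln ln M; the subleading O(ln ln M / ln M)
    correction is not included.
    """
    if M < 3:
        raise ValueError("threshold needs M >= 3 (ln ln M defined)")
    return math.log(M) + math.log(math.log(M))


def sweep_bounds(M_values, ratio_grid) -> pd.DataFrame:
    """Tabulate all bound metrics over a grid of delta_G / ln M ratios.

    Returns a long-format DataFrame with columns
    (M, ratio, p_max, Hmin_norm, Hspec_norm, m_frac, p_high): the
    specificity bound, the entropy bound and max-specificity entropy per
    unit ln M, the fraction of high-concentration species, and their
    total weight.
    """
    rows = []
    for M in M_values:
        ln_m = math.log(M)
        for ratio in ratio_grid:
            if ratio < 0:
                raise ValueError("grid ratios must be >= 0")
            dG = ratio * ln_m
            p_max, _ = specificity_bound(M, dG)
            ent = entropy_bound(M, dG)
            rows.append(
                {
                    "M": M,
                    "ratio": ratio,
                    "p_max": p_max,
                    "Hmin_norm": ent.h_min / ln_m,
                    "Hspec_norm": max_specificity_entropy(M, dG) / ln_m,
                    "m_frac": ent.m_min / M,
                    "p_high": ent.p_high,
                }
            )
    return pd.DataFrame(rows)
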