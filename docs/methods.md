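# Methods

This note documents the modeling assumptions, numerical choices, and
limitations behind `templimits`. Everything stated here is computed by
the package itself (the test suite and `scripts/acceptance.py` exercise
each claim); no empirical result is asserted beyond what the code
produces.

## Model and assumptions

**Linear CRN with an implicit environment.** A templating network is a
connected graph of complexes rooted at a unique null complex Ø. Monomers,
fuels, waste, catalysts, and templates are chemostatted: their chemical
potentials are fixed by the environment and absorbed into effective rate
constants, so they never appear as nodes. Each remaining complex holds at
most one tracked species (an intermediate or a product), which makes the
mass-action dynamics linear with Ø acting as a zeroth-order source of
activity 1. Reactions between two tracked species (e.g., product–product
conversions) are excluded structurally. Sequestration of catalysts is out
of scope; a network with fixed total catalyst concentrations has the same
steady state as one chemostatted at the corresponding free concentrations,
so the bounds computed here carry over.

**Units.** All energies are in k_BT (natural log / nats). Concentrations
are dimensionless activities relative to the standard concentration, so a
single reversible edge at equilibrium gives c = e^{−δG̃} with no unit
juggling. Entropy production is in k_B per unit time (deterministic rate)
or k_B per completed production event (stochastic accounting).

**Thermodynamic self-consistency.** Every edge is reversible and obeys
local detailed balance, δG̃ = −ln(k_fwd/k_rev). Edges always carry the
two rate constants as the primary parameterization; node free energies
and per-edge chemical work (Σ_i μ̃_i δN_i) are optional annotations used
only to cross-validate δG̃ = G̃_to − G̃_from + chem_work. This keeps the
dynamical data minimal while letting generated fixtures be audited edge
by edge.

**Pathways.** A pathway is a self-avoiding walk (SAW) from Ø to a
species, traversing reversible edges in either direction (reverse
traversal negates δG̃). SAWs exclude cycles by construction, so
proofreading loops influence the bounds only by opening additional
acyclic routes. Enumeration is exhaustive depth-first search (via
`networkx.all_simple_edge_paths` on an undirected multigraph view) with a
configurable cap, default 10⁶ walks per species; exceeding the cap is an
error, never a silent truncation, because the bounds are extremes over
the full SAW set. Bounds are computed for intermediates as well as
products — the underlying confinement theorem applies to any species of
a linear connected CRN.

**Product symmetry is verified, not assumed.** Two products are reported
equivalent when the subgraphs spanned by their SAWs are isomorphic as
rooted graphs (roles: root / target / other) *and* their multisets of
pathway free energies agree within tolerance (default 10⁻⁹ k_BT). This
operationalizes "topologically equivalent pathways with equal free-energy
changes" without requiring a full labeled-graph identity, and all
downstream quantities are computed per product so asymmetric networks are
analyzed unchanged; for a product pair (X, Y) the relevant spread is
δG̃_L(Y) − δG̃_U(X).

## Deterministic solvers

The steady state solves the node-balance system W c = −s directly
(`numpy.linalg.solve`), with s collecting the Ø-source terms. The
relative residual must be ≤ 10⁻⁹ or the solver raises with a condition
estimate; a condition number above 10¹² triggers a warning. Transients
use LSODA with the exact (constant) Jacobian, rtol 10⁻¹⁰ / atol 10⁻¹².
ODE integration to long times serves as an independent oracle for the
linear solve in the test suite, never as the primary solver.

Entropy production uses the convention σ = Σ_edges (J⁺−J⁻) ln(J⁺/J⁻)
with balanced edges contributing exactly 0; an edge with zero
concentration on one side but nonzero net flux reports an infinite
contribution rather than NaN.

The accuracy identity
ln(c_X/c_Y) = ΔG̃ + ln(Γ_Y(δG̃_L)/Γ_X(δG̃_U)) with
Γ = e^{−δG̃_S}/c is algebraically exact at any steady state; its residual
(≤ 10⁻⁹ in tests) is used as an end-to-end consistency check of the
bounds and solver working together.

## Closed-form bounds

`specificity_bound` and `required_delta_G` evaluate
p_max = (1+(M−1)e^{−ΔG̃})⁻¹ and its inverse
ΔG̃ = ln((M−1)(1−e)/e) in log space, so they remain finite and monotone
up to M ≈ 2⁶³. The error-target domain is (0, 1−1/M], the endpoint being
the uniform ensemble (zero drive).

`entropy_bound` minimizes the two-level ensemble entropy

    H(m) = (M−m) ΔG̃ e^{−ΔG̃} / (m + (M−m)e^{−ΔG̃}) + ln(m + (M−m)e^{−ΔG̃})

over integer m ∈ {1..M}: an exact vectorized scan for M ≤ 10⁷, and a
ternary search exploiting the unimodality of H(m) (its continuous
derivative has exactly one sign change) with a ±4 safety window above
that. Ties report the smallest minimizing m; the only flat case is
ΔG̃ = 0, where m_min = 1 by that rule. The continuous relaxation has the
closed-form stationary point

    m* = M e^{−ΔG̃} (ΔG̃ − 1 + e^{−ΔG̃}) / (1 − e^{−ΔG̃})²,

clamped to [1, M]; it is exposed as `method="continuous"` (a slightly
weaker bound, never the default) and is cross-checked against integer
scans in the tests. The overlap threshold above which entropy
minimization collapses to a single dominant product is implemented at
leading order, ln M + ln ln M; the subleading O(ln ln M/ln M) correction
is not included, so near-threshold comparisons in the tests use an
explicit margin.

## Stochastic simulation and trajectory accounting

The SSA is the exact Gillespie algorithm on copy numbers (counts =
concentration × V): Ø-outgoing reactions fire at k·V, all others at
k·count. The generator is `numpy.random.default_rng(seed)` with the seed
a required argument; identical inputs give bit-identical event logs.

Because the CRN is linear, molecules are independent and exchangeable,
so the aggregate event log can be decomposed into single-molecule
trajectories by attributing each firing to a uniformly random molecule at
the source node (attribution RNG derived from the log seed, so
classification is deterministic). Each molecule's life is split into
excursions: Ø → first arrival at a product is a *production* event, the
product → first return to Ø a *degradation* event. Each excursion is
assigned to a SAW by *loop-erasure* of its node sequence, maintained
online (revisiting a node truncates the path), which partitions every
excursion uniquely onto the same SAW set the bounds are built from. The
alternative — classifying only excursions whose raw edge sequence is
already self-avoiding — would leave most excursions unclassified;
loop-erasure was chosen as the canonical surjection. Molecules present at
t = 0 cannot be attributed a full Ø-rooted excursion and are excluded
from production counts.

Per-event entropy is ln(a_fwd/a_rev′): the propensity of the executed
transition over that of its reverse in the post-jump state, summed in
k_B. At stationarity this matches the deterministic σ·V·T up to boundary
terms, which is verified against the deterministic flux report in the
tests. Standard errors use batch means with 20 equal time batches, since
the event stream is autocorrelated.

Default study conditions in the tests: volume V = 1000 (relative
fluctuations of order 3% for activities near 1) with horizons of 10–50
time units, chosen so suites of SSA runs complete in seconds while
leaving thousands of production events per run; V = 300–500 is used for
auxiliary checks where only means are needed.

## Fixture families

* **Two-product** (Ø⇌X, Ø⇌Y): both single-edge pathways share one δG̃,
  so the spread is zero and the steady state is unbiased regardless of
  the kinetic bias k_X/k_Y; the t→0⁺ transient p_X = k_X/(k_X+k_Y)
  demonstrates unbounded *kinetic* specificity outside the steady state.
* **Symmetric family**: every product gets the same pathway topologies
  and pathway free energies, but intermediate free energies (hence
  rates) are redrawn per product — accuracy differences are purely
  kinetic, as the framework intends.
* **Saturating family**: every product has two pathways with free
  energies g_U ≤ g_L built from a *shared* rate template, and the
  off-pathway (g_L for product 1, g_U for the rest) is slowed by a
  factor ε in both directions. Scaling both directions equally is a pure
  kinetic tuning: every δG̃ is preserved, so the bounds are fixed while
  the steady state migrates toward them, reaching pseudo-equilibrium as
  ε → 0 (at ε = 1 the products are exactly interchangeable and
  p_max = 1/M). This family is this package's own construction of a
  bound-approaching network; it is not claimed to be the only or the
  most biologically plausible one.
* **Random consistent networks**: a spanning tree rooted at Ø plus extra
  edges (never product–product), node free energies uniform in ±5 k_BT,
  chemical work uniform in ±3 k_BT, k_fwd log-uniform in [10⁻², 10²],
  k_rev fixed by local detailed balance. The ranges span driven and
  near-equilibrium regimes while keeping the linear solves
  well-conditioned; the property suite checks the concentration-bound
  theorem across 100 such networks of up to 30 nodes.

## What the synthetic families do and do not show

The generators produce networks that are exactly thermodynamically
consistent, with perfectly chemostatted environments, no conservation
constraints among tracked species, and rate constants spanning four
decades. Real templating systems have sequence-correlated rate
structure, sequestration of templates and enzymes, and far larger state
spaces. Passing tests therefore demonstrate the mathematical claims —
confinement of steady states by pathway free energies, the closed-form
accuracy bounds, pseudo-equilibrium saturation — on the model class, not
that any particular biological network operates near its bounds; the
identity linking Γ ratios to concentration ratios is the tool the
package offers for asking that question of real parameter sets.

## Known limitations

* SAW enumeration is exhaustive; graphs whose simple-path count exceeds
  the cap (default 10⁶ per species) are rejected rather than sampled.
* Non-linear dynamics (explicit sequestration, bimolecular reactions
  between tracked species) are out of scope by design.
* The SSA is a plain exact algorithm — no tau-leaping — and is intended
  for desk-scale networks (≲10² reactions, ≲10⁶–10⁷ events).
* `check_product_symmetry` compares SAW-spanned rooted subgraphs; it can
  in principle report two products equivalent that differ only in
  features invisible to that comparison (e.g., identical pathway sets
  embedded differently in a larger shared context). The per-product
  bound computations do not rely on the symmetry verdict.
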