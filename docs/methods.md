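# Methods

This note records the model, the estimators, the numerical choices and the
known limitations of `kmclearn`, in the order of the pipeline.

## The stochastic model

The chemical system is a well-stirred collection of molecule counts
X(t) ∈ ℤ₊^m in a fixed volume, evolving under r elementary reactions.
Reaction j has a stoichiometric column R_j (products minus reactants), a
rate coefficient k_j with units count^(1−order)·time⁻¹, and a propensity
a_j(x) = k_j·h_j(x), where h_j counts the distinct reactant tuples available
at state x: h = Π_m C(X_m, ν_m) over reactant species with multiplicity ν_m
(so X for unimolecular, X·X′ for distinct bimolecular pairs, C(X,2) for
identical pairs, and the same product-of-binomials rule for trimolecular and
higher orders). The probability law over states follows the chemical master
equation; trajectories are sampled exactly with the Gillespie direct method.

Concentrations are dimensionless molecule counts — no volume or molarity
conversion is applied anywhere.

## Extraction: bond duration criterion and event detection

Raw bond states come either from a coordinate trajectory (bonded iff
distance ≤ per-element-pair cutoff, minimum-image when a periodic box is
given; the comparison is ≤, so a pair exactly at the cutoff is bonded) or
directly from per-frame bond lists.

The bond duration criterion τ (in frames) is a two-state hysteresis
automaton applied per atom pair: the bonding state flips only after the raw
signal has held the opposite value for τ consecutive frames, and the flip is
recorded **retroactively at the first frame of the persistent run** — the
physical event time — rather than at the confirmation frame. This keeps
detected events aligned with the concentration changes they cause. The
frame-0 raw state is accepted as the initial smoothed state, since no
history exists before the trajectory. τ = 1 is the identity.

Molecules are connected components of the smoothed bond graph
(scipy.sparse.csgraph). Species identity is the pair (element counts,
bond-type counts), rendered canonically as e.g. `C2 H6 1(C–C) 6(H–C)`
(elements C, H, then alphabetical; bond pairs (C–C), (H–C), (H–H), then
alphabetical). This dialect cannot distinguish structural isomers that share
both formula and bond-type totals; that is a deliberate, documented
limitation of the labelling scheme.

Between consecutive frames, a molecule is *unchanged* when both its atom set
and its species are identical; all other disappeared/appeared molecules are
linked through shared atoms, and each connected component of this bipartite
graph is one elementary reaction event (reactants = its frame-t molecules,
products = its frame-(t+1) molecules). Requiring the species to match — not
just the atom set — makes isomerizations (same atoms, different bonding)
detectable as A ⇒ B events. How overlapping multi-molecule rearrangements
split into elementary events is not uniquely defined by the data; the
connected-component rule is this package's explicit choice. By construction
Σ_j counts(t,j)·R_j = X(t+1) − X(t) holds exactly for every interval.

## Rate estimation

Under the tau-leaping approximation — propensities frozen within each frame
interval of length Δt — the firing counts n_j(t, t+Δt) are conditionally
independent Poisson variables with mean μ_j = k_j·h_j(X(t))·Δt. Maximizing
the Poisson log-likelihood ℓ = Σ_{t,j} [n log μ − μ − log n!] (log n! via
the log-gamma function) gives the closed form

    k̂_j = Σ_t n_j(t, t+Δt) / (Δt · Σ_t h_j(X(t))).

Each reaction also reports its number of *informative intervals*
(#{t : h_j > 0}) as a confidence proxy: rarely possible reactions have few
nontrivial observations and their rates are likely overestimated. No
shrinkage or Bernoulli saturation correction is applied — reduction handles
unreliable rates downstream. Δt equals the input frame spacing; no sub-frame
interpolation is attempted. A reaction observed in intervals where it was
never possible is an inconsistency error; one never possible and never
observed has an undefined (NaN) rate and is reported as absent.

## Gillespie simulation

The direct method: τ ~ Exponential(a₀), reaction j with probability a_j/a₀,
two uniform deviates per step, one seeded `numpy` Generator per simulation
(ensembles use seed + replicate index). No next-reaction or tau-leaping
acceleration is implemented — the intended networks are desk-scale. When
a₀ = 0 the system is frozen: the trajectory advances silently to t_end and
is flagged in metadata. Counts can never go negative because h_j = 0
whenever reactants are insufficient. Sampling is right-continuous
(an event exactly at a sample time is included); event binning uses
half-open intervals [t·dt, (t+1)·dt), so a boundary event belongs to the
later bin.

## Model reduction

**Count filter.** Remove reaction j iff Σ_t n_j < f. All reactions with
equal totals leave together — the method's granularity limit — and this is
*not* equivalent to dropping the lowest rates, since counts confound rate
and opportunity.

**Conditional-moments system.** For each sampled state X(t), the one-step
change y_{t+1} is a linear combination of independent Poisson firings, so
its conditional mean R·diag(w_t)·k and covariance R·Λ·Rᵀ (Λ_jj = w_tj·k_j,
with w_tj = k_est,j·h_j(X(t))·Δt after scaling by the MLE rates) are linear
in the dimensionless scaled rates k. Stacking m mean rows and m(m+1)/2
upper-triangular covariance rows per state over T states yields A k = b with
row count T·(m + m(m+1)/2); b is built with k = 1, so k = 1 is an exact
solution and ‖A·1 − b‖ = 0 to machine precision. Only AᵀA and Aᵀb are
accumulated (streaming, exact: A_t = B·diag(w_t) with the state-independent
basis B = [R ; triu(R_jR_jᵀ)], so AᵀA = (BᵀB) ∘ (WᵀW)); the explicit A is
kept only below 10⁵ rows. Negative eigenvalues from floating-point
accumulation are clipped to restore positive semidefiniteness. Sampling
states come from one full-model Gillespie run recorded at Δt by default;
pooling several replicates is supported. Covariance rows are not weighted
relative to mean rows (an acknowledged bias), and no row weighting matrix W
is implemented.

The right-hand side b may also be built from a *reference* network sharing
the species set (default: the candidate network itself). This is what makes
controlled support-recovery experiments well-posed: the candidate set can be
a superset of the data-generating model, with b carrying only the genuine
moments.

**IQP.** min ‖Ak − b‖², k ∈ {0,1}^r, Σk ≤ λ, solved exactly by depth-first
branch-and-bound: lexicographic branching by reaction index (include-first,
hence deterministic), bounds from the convex relaxation over the
box-capped simplex, pruning guarded by a 10⁻⁹·scale margin against solver
tolerance. Refused above r = 25 with a pointer to the LASSO path; verified
against exhaustive enumeration in the tests.

**Box-constrained LASSO.** The convex relaxation k ∈ [0,1]^r, Σk ≤ λ
(constrained form — λ is the L1 budget, never a penalty weight), solved by
FISTA with adaptive restart and exact Euclidean projection onto
{0 ≤ k ≤ 1, Σk ≤ λ} (box clip, then a bisection on the simplex-cap
threshold). Step size 1/L with L = 2·λ_max(AᵀA). Convergence: projected-
gradient (KKT) residual ≤ 10⁻⁸, or objective change ≤ 10⁻¹⁰ relative to
max(1, |objective|); non-convergence raises an error carrying iterate
diagnostics. Afterwards every entry below ε = 0.01 is set to 0 (a reaction
whose rate can be shrunk by more than 99% is removed) and final rates are
k_est ∘ k — kept rates may shrink below their estimates, deliberately,
because overestimation of rare rates is one-sided. Entries landing in
[ε, 0.5] violate the empirically expected phase separation and are flagged
in the result, not rejected. The reported sweep objective is the relaxed
optimum (provably non-increasing in λ); the thresholded k is reported
alongside.

## Error metrics and τ selection

Two per-species metrics in molecule-count units:

* RMSE of the ensemble mean: sqrt((1/T)·Σ_t (mean_S x_s(t) − x_ref(t))²),
  used against the source trajectory.
* Mean-over-replicates error: (1/S)·Σ_s sqrt((1/T)·Σ_t (x_s(t) − x̄_ref(t))²),
  used between stochastic models; its reference is the comparison model's
  mean trajectory, and by Jensen's inequality it is never smaller than the
  first metric on the same inputs. The exact reading of this
  model-comparison formula was a design decision and is recorded in the
  report metadata; it must not change silently.

A configurable `burn_in` (default 0) drops early samples before comparison.

τ selection extracts, estimates and simulates a model per grid value and
scores it (RMSE of the ensemble mean) against that τ's own smoothed
concentrations, returning the arg-min (ties to smaller τ). Degenerate limit:
a τ exceeding every bond lifetime freezes both the model and its reference,
scoring a trivial 0 — the grid must stay well below the data span. On real
reactive data, too-small τ admits vibrational flicker as spurious reactions
and too-large τ misses genuine elementary steps, producing the familiar
U-shaped curve.

## Synthetic ground truths: what they emulate and what not

The generators stand in for reactive atomistic trajectories:

* `generate_bond_signal` — a clean bonding step function plus Poisson-placed
  flicker runs strictly shorter than `flicker_max_len`, kept clear of true
  transitions, so the hysteresis filter at τ = flicker_max_len provably
  recovers the clean signal (and τ < flicker_max_len provably leaks).
* `generate_reacting_system` — an exact stochastic simulation of a known
  network with explicit atom bookkeeping: each firing consumes concrete
  reactant molecules and rewires their atoms into product templates, and
  per-frame bond graphs are emitted at the frame spacing. Emission is
  event-driven and exact; no coordinates, forces or energetics are involved.
* `generate_count_stream` — Poisson counts at the tau-leaping means.
* `inject_spurious_reactions` — element-balanced recombinations of existing
  species that never fired, carrying inflated rate estimates.

Default study conditions (chosen once): the methane-fragment set
{CH4, CH3, H, H2, C2H6} with the six reversible reactions
CH3 + H → CH4 (k = 0.05), CH4 → CH3 + H (0.2), H + H → H2 (0.05),
CH3 + CH3 → C2H6 (0.05), H2 → 2H (0.4), C2H6 → 2CH3 (0.3), starting from
20 CH4 molecules with frame spacing 0.01 time units. The rates and spacing
are set so that a given molecule rarely fires twice within one frame —
the regime in which the tau-leaping observation model is valid and
frame-to-frame differencing sees each firing as its own event.

What passing tests on these fixtures does **not** show about real data:
there is no force field, no atomic vibration (flicker is injected
synthetically with known bounds), no diffusion or spatial correlation (the
well-stirred assumption is built into the generator rather than tested), no
isomers beyond the bond-count dialect, and species/reaction counts are
desk-scale (m ≲ 10) rather than the hundreds-to-thousands of a real
high-temperature system.

## Numerical choices and degenerate inputs

* Combinatorial counts are exact integers in the scalar API and float64 in
  the vectorized path (exact far beyond any realistic molecule count).
* log(n!) via `scipy.special.gammaln`; μ = 0 with n = 0 contributes zero
  likelihood, μ = 0 with n > 0 yields −inf (flagged, not raised).
* The capped-simplex projection bisects 100 times (precision ~max(v)·2⁻¹⁰⁰).
* IQP ties between equal-objective supports resolve to the first found under
  include-first lexicographic branching.
* Empty networks simulate as frozen systems; empty bond frames partition
  into free atoms; a τ larger than the trajectory freezes the frame-0 state.
* Problem sizes in the test and acceptance runs (trajectory lengths,
  replicate counts, instance counts) are chosen as the smallest at which the
  statistical assertions have comfortable power margins.

## Known limitations

* Species identity by (formula, bond-type counts) conflates some isomers.
* Composite events: two firings touching the same molecule within one frame
  interval are extracted as a single merged event; keep rate·Δt per molecule
  small.
* The count filter cannot separate reactions with equal totals; the IQP is
  exact only up to r = 25; the LASSO's support is not guaranteed λ-sparse
  before thresholding.
* Rates of rarely possible reactions are systematically overestimated (no
  Bernoulli correction); reduction, not estimation, is the mitigation.
* No spatial, compartmental or hybrid simulation; no time-varying rates.
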