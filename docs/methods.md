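# Methods

## Model class and assumptions

`odezoom` operates on closed (or explicitly open) reaction networks in
state-space form `x' = S r(x, p)`, with amounts or concentrations as
states, positive rate parameters, and no external inputs or discrete
switches. The reduction assumes a user-declared split of the reaction
columns into fast and slow sets such that, over the time window of
interest, every species touched by a fast reaction is in quasi-steady
state: the fast net rates `S_f r_f` dominate the slow contributions
`S_s r_s` in those species' balances. The split is always explicit input;
a flux-balance heuristic (`suggest_fast_reactions`: a channel is a
candidate when its net rate stays below a configurable fraction, default
1e-3, of its gross rate along a pilot simulation) is provided for
orientation but never applied silently, because no consensus criterion for
automatic QSS detection exists.

Reversible reactions may be written either as one column with a signed
net rate (`k1*A*B - k_1*C`) or as two irreversible mass-action columns
(`k1, k_1` sugar); both produce identical right-hand sides, and the
quasi-steady-state machinery recognises two-column pairs whose
stoichiometries are exact negatives and merges them into a single
forward-minus-backward balance.

## The reduction pipeline

**Conservation analysis.** Left null spaces of `S` (exact moieties) and
`S_f` (apparent moieties) are computed over exact rationals and scaled to
coprime integers; floating-point rank is never used. A nonnegative basis
is sought by enumerating extreme rays of `{m ≥ 0 : m S = 0}` with the
classical tableau (double-description) pass, capped at 1024 intermediate
rows; if the cone does not contain a full basis (or the cap trips), a
signed integer basis is returned with a warning. Basis rows are named
L1, L2, ... deterministically; the shipped fixtures rename rows by
matching their supports to the canonical moiety names. An optional
transform (`maximize_vanishing_rows`) replaces the basis by `N·M_f` with
`N` nonsingular so that a provably maximal number of rows annihilate
`S_s` (the count equals the rank deficiency of `M_f S_s`); any maximizer
is accepted, as the choice of `N` is not unique.

**Lumping schemes.** `build_scheme` keeps named conservation rows as full
lumps, groups explicitly assigned leftovers, and makes every remaining
fast species its own singleton lump, in model order — mirroring how the
shipped case studies choose their reduced states. A lump is admissible
when its members lie inside the support of a single basis row or, failing
that, of some nonnegative combination of rows (decided by a linear
program over the basis coefficients); strict subsets of a row's support
are allowed whenever the resulting scheme is proper. Overlapping exact
conservations (e.g. the total-carrier and total-G6P moieties of the
transport model, which share two complexes) cannot both be kept; this is
detected and rejected with the shared species named. Each lump records a
parent conservation row (its own row for kept lumps; otherwise the first
unused row covering the members, then any covering row) — the parent
enters the corrected dynamics below, and with all identities exact, any
valid parent choice yields a QSS-consistent reduced model.

**Fraction parameters.** Candidate relations for a lump are its
definition, the fast-channel balances, the exact conservation sums, and
user constraints, filtered to those that involve at least one member and
are jointly of total degree ≤ 1 in the members with all other species
frozen as coefficients — the freezing is what makes bilinear mass-action
balances usable. Relation subsets of size `n_m` are tried in provenance
order (definition, QSS, conservation, extra); the first subset whose
denominator-cleared coefficient matrix has a nonvanishing polynomial
determinant is solved by Cramer's rule, which keeps all determinant work
polynomial and avoids the multivariate-GCD blow-up of a direct LU solve.
`Σ η = 1` and the per-relation residuals are verified by polynomial
expansion of cross-multiplied differences. For the constrained
transport variant (constant regional transporter concentrations), the
conservation rows are excluded from the candidate set so that the
constraint actually enters the solved system; with them included, an
alternative — equally valid but different — solution through the total
glucose moiety is found first. Lumps whose members appear in relations
only through foreign species are closed by iterated substitution of the
other lumps' `g` maps; a cyclic dependency raises an error. A lump with
no solvable system is marked non-back-translatable; reduction proceeds,
back-translation of that lump's members is refused explicitly.

**Corrected dynamics.** The reduced right-hand side per cluster block is
`(I + J)^(-1) M S_s r_s` with species replaced by `g`. Blocks follow the
connected components of the bipartite fast-species/fast-reaction graph;
lumps whose members span several clusters merge those clusters into one
block. Blocks of dimension ≤ 4 are inverted symbolically — again via
row-wise denominator clearing, a Berkowitz determinant and the adjugate —
with a final GCD cleanup only when the expression stays below ~4000
operations (larger quotients are left as numerator/determinant, which
integrates identically). Larger blocks switch to a numeric linear solve
at every right-hand-side evaluation, raising an explicit singularity
error if `det(I + J)` hits zero; the determinant is also checked to be
positive at the initial state at derivation time.

**Initial conditions and simulation.** Reduced initial states come from
(a) `equilibrate` (default): solving the fast balances together with the
apparent-conservation values at `x(0)` by damped least squares — the
numerical generalisation of the case study's closed-form equilibration,
reproducing `S(0) = √3 − 1` to 1e-10; (b) `burn_in`: integrating the
original model for `1e-3 ×` the comparison horizon (configurable) and
mapping the end state, with a warning when the worst relative channel
imbalance still exceeds 1e-6; or (c) `direct`: `M_m x(0)` unmodified.
Integration uses LSODA at `rtol = 1e-8`, `atol = 1e-10` by default so
that reduction error dominates integration error in every comparison;
`g` is evaluated as the cancelled product `η·l`, so lumps passing through
zero yield zero members rather than NaN.

**Validation.** `ε_i(t)` uses the original trajectory in the denominator;
samples with `|x°| ≤ atol` are skipped and counted. The robustness scan
scales one parameter at a time (plus a joint "All" row) in both models,
re-equilibrates the reduced initial condition at each scaled point, and
reports mean/inf pairs; failed cells become NaN without aborting the
scan. Scaling a parameter in both models means ratio parameters of the
reduced model (association constants) track the scaling — a scan cell
therefore measures the validity of the QSS premise at that parameter
point, not the mismatch of a reduced model frozen at nominal values.

## Case-study inputs and problem sizes

The enzyme model ships with its published rate constants
(`k1 = 1000, k_1 = 2000, k2 = 1, k3 = 3000, k_3 = 1000`, so
`M1 = 0.5, M3 = 3`) and initial condition `S(0) = E(0) = 1`. The third
channel is written with net rate `k_3*CP - k3*P*E`: this keeps the
published stoichiometric matrix exactly while giving the fast equilibrium
`CP = M3·P·E` that the published reduced model and its constants require
(the source's appendix rate list and its QSS equations disagree on the
roles of `k3`/`k_3`; the reduced-model formulas fix the convention).

The glucose-transport model ships with the published structure — nine
species, four fast binding channels, two slow translocation channels,
three exact moieties, five apparent moieties in two membrane clusters —
but its rate constants are synthetic placeholders (so documented in the
model file), chosen once so that binding is ≥ 1e3 × faster than
translocation and the total carrier is `LE = 0.01` with a realistic
glucose load (`Glc_e(0) = 0.5`, `G6P_i(0) = 0.05`, dissociation constants
between 0.1 and 1). Structural assertions are parameter-free; the error
comparisons at these placeholders show the qualitative ordering
(five-state ≈ four-state ≪ constrained three-state ≪ direct
substitution) on a horizon of 100 time units sampled at 1.

Comparisons use grids of 100 samples (enzyme: 0.1 to 10 step 0.1;
transport: 1 to 100 step 1); the enzyme scan in the test suite covers
three parameters × three decades, which keeps the full suite under two
minutes on one core while still exercising every code path, including the
two-cluster symbolic inversion.

## The random-network generator

`random_fast_cluster(seed, ...)` emulates the one structural motif the
method targets: fast reversible binding units `A + B ⇌ C` (rates of scale
`separation`, default 1e4) embedded in a slow closed recycling chain
`C → P₁ → ... → Pₙ → A + B` (rates of scale 1), one or more clusters,
log-uniform rate jitter, seeded and reproducible. By construction every
generated network is closed (≥ 1 exact moiety) and every cluster carries
two apparent moieties. It does not emulate other features of real
networks — shared species between clusters, higher-order kinetics,
open boundaries, or rate constants correlated with stoichiometry — so
passing property tests on it demonstrates exact-arithmetic correctness of
the conservation analysis and the expected separation-controlled error
scaling, not performance on arbitrary biochemical topologies.

## Known limitations

- Fast-set selection is manual by design; the heuristic is advisory.
- The symbolic right-hand sides of large blocks are left in
  numerator/determinant form; no expression-size post-processing is done.
- Linearisation around a steady state as a fallback source of linear
  relations (useful when QSS balances are too few) is not implemented.
- The validity window `[T0, T1)` of a fast/slow split is metadata only;
  the tool does not re-partition mid-simulation (models with switches
  would need that).
- The reduced model is exported as text/report only, not re-encoded as
  SBML (its rate laws are rational functions outside the mass-action
  subset the importer targets).
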