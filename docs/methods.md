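# Methods

## Model representation and preprocessing

A model is a list of species and irreversible-or-reversible reactions with
flux bounds; the stoichiometric matrix **N** (species × reactions) and the
box of bounds define the steady-state flux space
S = { v | **N**v = 0, v_min ≤ v ≤ v_max }, the single source of truth for
every linear program in the package.

Preprocessing follows the standard constraint-based recipe, in this order:

1. **Blocked-reaction removal.** Flux variability analysis on the original
   (possibly reversible) model with its original bounds; a reaction is
   blocked when both its minimum and maximum flux have magnitude below
   `zero_tol` (default 10⁻⁹ mmol gDW⁻¹ h⁻¹). Infinite bounds are capped at
   `bound_cap` (default 1000) first so all LPs are bounded.
2. **Reversible splitting.** Each reversible reaction becomes a forward
   and a sign-flipped backward irreversible copy; all lower bounds are set
   to zero and every upper bound is standardized to the maximum upper
   bound of the original model. After this step S is a bounded polytope,
   so every linear functional attains finite optima.

Reactions with a species on both sides are net-cancelled at construction
(equal coefficients drop the species entirely); this gives a deterministic
complex for each reaction side. The simple JSON/TSV dialects are
gcd-normalized on read (coefficients divided to smallest integers) because
complex identity is sensitive to stoichiometric scaling; SBML input is
taken as-is, since float coefficients carry the model's own convention.

## Complexes and decomposition

Distinct reaction sides become complexes; all empty sides map to a single
global zero complex regardless of compartment (an open choice — per-
compartment zero complexes would fragment exchange structure without any
downstream benefit here). Complex identity is exact coefficient equality;
float coefficients are compared at 10⁻⁹. Canonical labels sort
coefficients by species id ("1*AcCoa + 1*Oaa", "0"), making outputs
diff-able and complexes matchable across paired models.

## LP layer and the zero contract

All LPs are solved with scipy's HiGHS interface with primal/dual
feasibility tolerances set to `zero_tol/10`. A quantity is reported zero
iff its magnitude is ≤ `zero_tol` (default 10⁻⁹); the same threshold
serves for blocked reactions, balancedness, type-I blocking and lethality.
Unbounded LP statuses are raised as configuration errors: after
preprocessing they cannot occur mathematically.

## Balanced complexes, concordance, forced balancing

- **Balanced**: min and max of A^{i:}v over S both within `zero_tol` of
  zero. Sinks and sources need only one LP (their activity has constant
  sign under non-negative fluxes); that LP also yields the witness flux
  with nonzero activity that is cached for every non-balanced complex.
- **Concordance** uses the witness: if activities are coupled, the ratio
  is uniquely γ = (A^{j:}w)/(A^{i:}w), so two LPs certifying that
  (A^{j:} − γA^{i:})v has zero range over S decide the question. A
  candidate γ with |γ| ≤ `zero_tol` refutes immediately. Normalizing the
  activity to 1 instead would be unsound because S contains v = 0. The
  partition is built incrementally against module representatives only
  (valid by transitivity), with the representative being the lowest
  complex index, and iteration in index order, so results are
  byte-for-byte reproducible.
- **Forced balancing** of C_i adds the equality A^{i:}v = 0 and re-tests
  every other non-balanced complex; Q_i collects those that become
  balanced. Classification: trivial iff concordant with C_i (module
  lookup, no LP); otherwise FVA restricted to the reactions incident on
  the member — type I iff every incident reaction is blocked under the
  constraint, else type II. Potentials are computed once per concordance
  module through its representative (all members share the potential) and
  copied; lethality screens, by contrast, solve one FBA per complex
  because objective values are not proven constant within modules.

## Distribution of balancing potentials

Potentials are counts, so fitting is discrete. The focal model is
p(x) ∝ x^(−a) e^(−bx) on x ≥ x_min (default 1); zeros (balanced
complexes) are excluded and reported separately, since x^(−a) is undefined
at 0 and the model describes the non-zero tail. The normalizing constant
is summed directly with a geometric tail bound (truncation below 10⁻¹⁵
relative mass); b = 0 falls back to the Hurwitz zeta function. The MLE
uses bounded Nelder–Mead from three deterministic starts (tolerance 10⁻⁸
on the log-likelihood); standard errors come from the inverse
finite-difference observed information and are reported for interior
estimates. Alternatives (pure power law, exponential/geometric,
log-normal, stretched exponential) are discretized by unit binning of
their continuous forms, fitted by their own MLEs, and compared with the
normalized (Vuong) log-likelihood-ratio test; two empirical samples are
compared with the two-sample Kolmogorov–Smirnov test (conservative under
ties, which is the safe direction for count data).

## Differential screen

z_i* = max v_bio subject to Nv = 0, A^{i:}v = 0 and the bounds; forcing is
lethal iff z_i* < `lethal_tol` (10⁻⁹, strict). Candidates in a paired
model are shared complexes (matched by canonical label; the pair must
share a species namespace) that are lethal in the disease model while the
healthy model retains at least `healthy_fraction` (default 0.9) of its own
optimum. Reaction essentiality is single-knockout (v_r = 0, split pairs
knocked out jointly and counted once); module enrichment uses a 2×2 Fisher
exact test (reactions incident on the module × essential), computed
directly from the hypergeometric pmf by summing tables no more probable
than the observed one, so p-values are independent of the LP backend.
Exchange-based balancing adds an import/export pair for an internal
species and re-evaluates the target complex; for sink/source complexes
this can differ from direct forcing, since the added exchange does not
block the reactions around the complex.

## Synthetic generators and what they do (not) show

- **Toy network** (18 irreversible reactions, 11 species, 14 complexes):
  a TCA cycle with glyoxylate shunt, phosphoenolpyruvate entry and two
  exchanges, bounds (0, 1000). The four canonical reversible steps
  (aconitase, succinate dehydrogenase, fumarase, malate dehydrogenase)
  appear as explicit forward/backward pairs. Its full balancing structure
  is asserted jointly in the test suite as a validity certificate.
- **Random networks**: a backbone chain plus random one/two-species sides
  and a configurable fraction of exchanges, bounds (0, 1000). They
  exercise the algebraic invariants (Y·A = N, partition properties,
  oracle agreement) but are not biologically realistic: no mass
  conservation across reactions, no compartments, no realistic degree
  distribution. Passing tests on them certifies the algorithms, not any
  biological claim.
- **Planted pairs**: a shared biomass route S → B + E with an E drain
  through the complex 1*E; the healthy model adds a two-substrate bypass
  drain (E + X → W) not incident on 1*E, so forcing 1*E is lethal only in
  the disease model. A two-import merge gadget (M1 + M2 → K) gives the
  zero complex slack so it never becomes a spurious candidate; decoy
  import/export pairs vary network size, and the substrate uptake bound is
  drawn per seed. All invariants are verified by LP before a pair is
  returned. This emulates the *logic* of a tissue-pair screen, not the
  scale or content of genome-scale tissue models.

## Problem sizes and numerical choices

Property suites run on networks of 5–7 species and 8–12 reactions (50
networks for potential invariants, 20 for oracle equivalence), where
brute-force vertex enumeration of the flux polytope is exact and fast;
distribution tests use 10³–10⁴ simulated samples. These sizes fully
exercise every code path while keeping the default test run fast.

Known limitations: no gene–protein–reaction rules; no MILP/QP (nothing
here needs integrality); SBML is read-only; concordance tolerances are
absolute (`zero_tol`), appropriate for the default bound scale of 10³ but
worth revisiting for models with fluxes many orders larger.
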