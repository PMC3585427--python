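# Methods

## Model

The neuron is a binary two-stage unit. An input is a vector
`x ∈ {0,1}^n` (`n ≤ 7`). Each dendritic sub-unit `j` has a non-negative
integer weight vector `w_j` and an activation `D_j`; the soma fires when
the summed sub-unit outputs reach an integer threshold Θ:

    y(x) = 1   iff   Σ_j D_j(w_j · x) ≥ Θ.

Two nonlinear activation families are modeled, each with an integer
threshold θ ≥ 0 and height h ≥ 0:

* spiking:    `D(s) = 0` for `s < θ`, `h` for `s ≥ θ`;
* saturating: `D(s) = s` for `s < θ`, `h` for `s ≥ θ`;

plus the identity (linear) activation for the peri-somatic path. The
capacity searches use the one-nonlinear-sub-unit form: one linear sub-unit
plus one spiking or saturating sub-unit sharing the same inputs. The
synthesis results use the generic form with any number of nonlinear
sub-units.

Conventions that matter for reproducibility:

* **Firing rule is `sum ≥ Θ`**, with Θ ranging from 0 in all searches.
  Θ = 0 encodes the always-firing neuron; without it the constant-true
  class would be unreachable and every linear capacity count would be one
  lower. Any strict-inequality formulation maps onto this one by shifting
  Θ, since all quantities are integers.
* **Truth-table packing**: bit `k` (LSB first) of the packed table is the
  output for the input whose binary encoding is `k`, bit `j−1` of `k`
  being variable `x_j`. Hex serialization is the hex of this integer (the
  2-input AND is `"8"`).
* **Canonical representative** of a function is the lexicographically
  smallest packed table over all `n!` relabelings of the input variables,
  compared as an unsigned integer. Capacity is always counted in
  canonical classes.

## Sub- and supra-linearity, operational validation

`D` is supra-linear on `[0, m]` if some pair `x, y ∈ [0, m]` has
`D(x+y) > D(x) + D(y)`, sub-linear if some pair has `<`, and strictly
sub-linear if sub- but not supra-linear. Note the *couple* lies in the
interval; the sum may exceed it. Scanning pairs suffices even though the
definitions extend to k-tuples: if no pair violates super-additivity
(resp. sub-additivity), induction shows no tuple does.

Whether a `(θ, h)` pair really behaves as its nominal family is decided
operationally on the reachable domain `[0, Σ w]` of the sub-unit rather
than by closed-form constraints on `(θ, h)`: a spiking sub-unit must be
supra- and sub-linear and non-decreasing; a saturating one strictly
sub-linear and non-decreasing. This filters, for example, a "saturating"
unit with `h > θ ≥ 2`, whose jump is super-additive and which could
otherwise smuggle spiking behavior into a saturating search. A sub-unit
with all-zero weights is inert (constant on its reachable domain) and is
accepted in every search, so purely linear configurations remain inside
every model's capacity set. Searches can disable validation
(`validate_activations=False`) to mimic a raw unfiltered grid.

## Enumeration of positive functions

A positive function of `n` variables decomposes uniquely as
`f = f0 ∨ (x_n ∧ f1)` with `f0 ≤ f1` positive functions of `n−1`
variables. Enumerating ordered subset pairs of the level-`n−1` list is
therefore a bijection onto level `n`: each function is produced exactly
once and no deduplication pass is needed. Counts: 3, 6, 20, 168, 7 581,
7 828 354 for `n = 1..6`.

Class counts (3, 5, 10, 30, 210, 16 353) are obtained by canonicalizing
the stream; `representatives()` collects canonical tables in memory for
`n ≤ 5` and switches to sorted on-disk shards with a final merge for
larger `n`, so the non-canonical stream is never held at once. The `n = 7`
enumeration (490 013 148 classes) runs on the same streaming path but is
far beyond an interactive session and is not exercised by the test suite.

Two independent algorithms control the enumerator:

* the number of positive functions equals the number of order ideals of
  the Boolean lattice, counted by a memoized pivot recursion
  (`ideals(P) = ideals(P \ up(x)) + ideals(P \ down(x))`);
* the number of classes follows from Burnside's lemma: the average over
  variable permutations of the number of positive functions each fixes,
  one quotient-poset ideal count per cycle type.

Both agree with the enumeration wherever both are feasible (functions up
to `n = 6`, classes up to `n = 5`; the Burnside route alone also yields
16 353 at `n = 6` in under a second). The ideal-count memo exhausts memory
on the 128-point lattice, so neither counting route reaches `n = 7` here.

## Linear separability

`f` is linearly separable iff non-negative weights and a threshold exist
with `w · x ≥ Θ` exactly on the true inputs. With integer weights and 0/1
inputs, separation with margin 1 loses no generality, and for each
`n ≤ 6` there is a proven-sufficient maximal weight (1, 2, 2, 3, 5, 9 for
`n = 1..6`; the `n = 4..6` values are the published linear-model search
bounds). The decision therefore scans the finite weight grid; for a given
`w` the best threshold is the minimum weighted sum over true inputs, so no
threshold grid is needed. The result is exact — no floating-point ties.
For `n = 7` the decision falls back to LP feasibility with exact
verification of a rationalized witness; a negative answer at `n = 7` rests
on LP numerics and is flagged as such in the code. The test suite checks
the grid decision against an independent LP oracle for every positive
function of `n ≤ 4` and against an exhaustive small-grid oracle.

## Capacity searches

For a search space (maximal somatic weight, maximal dendritic weight,
θ, h and Θ bounds) the enumeration is memoized: all distinct dendritic
output vectors over the `2^n` inputs are precomputed — the neuron's output
depends on the dendritic parameters only through this vector — and crossed
with the somatic weight/threshold grid in vectorized sweeps. This is
mathematically identical to the naive product grid (asserted against an
unmemoized double loop at `n = 3` in the tests) and makes the `n = 5`
searches run in seconds and `n = 6` in hours instead of weeks.

Witness selection is deterministic: parameter sets are ranked soma-major —
somatic weight odometer, then somatic threshold ascending, then dendritic
pattern in (dendritic weight odometer, θ, h) first-appearance order — and
the first set reaching a class is stored as its witness. Every stored
witness is re-evaluated after the sweep; a mismatch would abort the
search. Results can be archived as HDF5 (tables + witness parameter
matrix), CSV or JSON-lines.

Problem sizes used by the default test suite and the acceptance script:
the `n = 4` and `n = 5` searches at their sufficient ranges (the largest,
spiking `n = 5`, is ≈ 3·10⁸ grid points, reduced to ≈ 3 200 dendritic
patterns × 1 024 somatic weight vectors × 13 thresholds; about a minute).
The `n = 6` searches are supported through the same interface but are
multi-hour runs and are left to explicit CLI invocation.

### Saturating ranges at n = 4

Under validated saturating activations the published sufficient ranges for
the saturating model at `n = 4` (weights ≤ 2, θ ≤ 2, h ≤ 2, Θ ≤ 4) reach
only two of the three non-separable classes — the FBP itself is not
computable there; the first saturating FBP witnesses appear at wider
ranges (weights ≤ 4, θ = h = 4, Θ up to 8, e.g. somatic weights
(0,2,1,1), dendritic weights (4,0,2,2), θ = h = 4, Θ = 6). The package
reports what each range actually yields and keeps the published presets
as published; `range_sufficiency_scan` makes such gaps visible.

## Synthesis and strategies

Every positive non-constant function has a complete positive DNF
(disjunction of prime implicants = supports of minimal true points) and a
complete positive CNF (conjunction of prime clauses = complements of
supports of maximal false points). Both reconstructions are verified
bit-exactly for all 30 classes at `n = 4` and all 210 at `n = 5`.

* DNF neuron: one spiking sub-unit per prime term `T` — indicator
  weights, θ = |T|, h = 1 — with Θ = 1. Normalizing h to 1 (rather than
  h = Θ) keeps witness integers minimal; the truth table is unchanged.
* CNF neuron: one sub-unit per prime clause — indicator weights, θ = 1,
  h = 1 — with Θ = number of clauses. Spiking and saturating activations
  coincide at θ ≤ 1, so either kind works.

A neuron's strategy is classified by its *local degree* `k`: the number of
nonlinear sub-units whose maximal achievable output (at the all-ones
input) alone reaches Θ. `k ≥ 1` is a local strategy, `k = 0` global. The
linear path is reported separately (`soma_alone`): the formal definitions
concern dendritic sub-units, but a somatic-path-triggered spike is worth
distinguishing rather than folding into either class. DNF neurons are
local with `k` = number of terms; CNF neurons with ≥ 2 clauses are global.

A single sub-unit *implements a term* when its output is exactly 0 on
term-false inputs and ≥ 1 on term-true inputs — the zero is essential,
since inside a DNF neuron an unsatisfied term's sub-unit must contribute
nothing to the shared soma. For a strictly sub-linear activation and a
term of ≥ 2 variables this is impossible (vanishing on the single-variable
inputs while firing on the full term would make the activation
super-additive on the weight tuple), hence saturating dendrites cannot
realize DNF/local implementations, regardless of their number.
`verify_no_local_sat_fbp` confirms the finite version exhaustively: over
all validated saturating parameter sets with weights ≤ 4, θ ≤ 4, h ≤ 4,
Θ ≤ 8 there are 0 local and 8 global FBP implementations, while the same
bounds with spiking sub-units contain local ones.

## Fixtures

`generate_fixtures` writes deterministic reference data: the truth tables
of AND, NAND, XOR and the FBP family, plus one spiking and one saturating
linear-plus-one-sub-unit witness per binding problem, each re-verified
against its table at generation time, with a sha256 manifest. There is no
randomness anywhere in the core; the only seeded component is the
hypothesis-based property tests (derandomized) and the acceptance script's
positivity self-check.

## Known limitations

* The `n = 7` class census and the `n = 6` capacity sweeps are supported
  but not desk-scale; no test asserts them.
* Negative separability decisions at `n = 7` rely on LP feasibility
  rather than an exact sufficient grid.
* Inhibition (negative weights), continuous activations and temporal
  dynamics are out of scope: the model is the binary, integer-weight
  abstraction, and conclusions about real neurons inherit its assumptions
  (binary inputs/outputs, independent sub-units, shared input set).
* Strategies intermediate between local and global (several sub-units
  jointly but not severally sufficient) are only partially captured by
  the local degree.
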