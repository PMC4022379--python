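# Methods

## Model class

A Boolean network on `n` nodes is a map `f = (f_1, ..., f_n) : {0,1}^n ->
{0,1}^n`. Over the two-element field GF(2), every Boolean function has a
unique *square-free* polynomial representative (`x^2 = x`), obtained from
logic via `x AND y = xy`, `x OR y = x + y + xy`, `NOT x = x + 1`, with `+`
itself being XOR. The package works exclusively in this representation: a
monomial is the set of variables in it (its *support*), a polynomial a set
of monomials (coefficients are 0/1 and equal monomials cancel in pairs),
and a model an ordered tuple of `n` coordinate polynomials. Dynamics are
simulated with a synchronous update; fixed points of the map are invariant
under any update schedule, which the test suite verifies empirically, so
steady-state statements do not depend on the synchronicity assumption
(periodic behaviour does, and is interpreted accordingly).

Knock-out or RNAi perturbations are modelled on the *model* side: a series
labelled as a knock-out of node `r` is explained by the knock-out model
`f* = (f_1, ..., 0, ..., f_n)` with the silenced coordinate replaced by the
zero function. Input data are taken as measured; the silenced column is not
clamped in the data itself.

## Search-space restriction

Each coordinate function is asked to interpolate the data at `m` points,
where `m = sum_mu (alpha_mu - 1)` is the number of observed transitions
(the *total length* of the series). Any monomial appearing in a minimal
interpolator of `m` points satisfies `prod_i (a_i + 1) <= m`; for square-free
monomials this is `2^|supp| <= m`, i.e. `|supp| <= Phi = floor(log2 m)`.
The search is therefore confined to the span of
`M = { x^a : |supp(x^a)| <= Phi }`, which has dimension
`sum_{i=0}^{Phi} C(n, i)` - e.g. 6,196 instead of 2^20 monomials for a
20-node network observed through ~16-31 transitions. The equivalence of the
two admissibility formulations is checked exhaustively in the tests, and the
existence of an exact interpolator inside `M` for consistent data is
verified against an independent GF(2) linear-algebra oracle. `m` is counted
once, globally, over all fragments (wildtype and perturbation) after
inconsistency breaking; a per-coordinate refinement `Phi_i <= Phi` can be
supplied when the maximum number of regulators of a gene is known.

## Data handling

A deterministic map cannot send one state to two successors, so inconsistent
data - a consequence of noise or discretization - are *broken*: every
transition out of an inconsistent state is removed (no successor is
preferred) and the affected series split into maximal consistent fragments;
length-1 fragments are kept but contribute no transitions. Wildtype series
are pooled for this check, since a single model must explain all of them;
each knock-out target is pooled separately under its own `f*`.

Noise injection flips exactly `round(xi * points * n)` distinct uniformly
chosen bits (round half-up; the protocol's bit count is stated without a
rounding rule, so one had to be fixed).

Continuous series are discretized column-wise. Quantile binning places
thresholds at the `j/s` quantiles of each variable's pooled values
(inclusive-median linear interpolation); values equal to a threshold take
the lower level, which makes the binary labels invariant under strictly
monotone per-column transforms. Interval binning uses equal-width bins on
the pooled range. Constant columns discretize to 0 with a logged warning.
Only `s = 2` feeds the inference engine; larger `s` exists to export data
to external tools in meta-inference workflows.

## Fitness

For a candidate model `f` on inconsistency-broken data:

* **Free-run model fit.** Each fragment is regenerated by iterating `f`
  (or `f*`) from its first time point; `D_mu` counts mismatched bits and
  `H_f = sum D_mu / (n * sum alpha_mu)`. Wildtype and knock-out
  contributions are combined by total-bit-count weighting (the combination
  rule is not specified by the theory; bit-count weighting makes `H_f` a
  single overall mismatch fraction). Contribution: `W_HM (1 - H_f)`.
* **Coordinate fit.** One coordinate cannot generate full states by
  itself, so the per-coordinate score is defined as one-step prediction
  from the *observed* predecessor state: `H_fi = mismatches / sum
  alpha_mu`, where fragments knocking out node `i` itself predict 0.
  Contribution: `W_HP * mean_i (1 - H_fi)`.
* **Complexity.** `c_i = total_degree(f_i) / Phi`, averaged over
  coordinates, entering as `W_C (1 - mean c)`. A degree above `Phi` cannot
  occur for candidates built from `M` and raises.
* **Priors.** A prior matrix `rho` gives the believed probability of each
  directed influence `j -> i`. With `V` the model's wiring diagram,
  `beta_ij = rho_ij` if `V_ij = 1` else `1 - rho_ij`; the score is the mean
  of `beta`, uniformly 0.5 for an uninformative prior. Biological and
  meta-inference ("reverse-engineering") priors enter with their own
  weights `W_B`, `W_RE`; a missing prior contributes nothing.

A model with `H_f <= xi` (the assumed noise fraction) is flagged
*data-consistent*; fitness itself stays graded, so the search is free to
trade residual mismatch against parsimony and priors within the tolerated
band.

Default weights are `(W_HM, W_HP, W_C, W_B, W_RE) = (1, 1, 0.5, 0.5, 0.5)`.
These are package choices, and for recovery-style experiments there is a
subtlety worth making explicit: at the coordinate level one degree of
complexity costs `W_C / Phi` while one repaired data bit earns only
`W_HP / sum alpha_mu`, so a large `W_C` can make parsimony outbid
exactness. `FitnessWeights.parsimony_safe` sets
`W_C = 0.5 * W_HP * Phi / total_points`, guaranteeing that parsimony only
discriminates among equally well-fitting candidates; the planted-model
experiments in the tests and the acceptance script use it.

## Evolutionary algorithm

Under synchronous update the fit of coordinate `i` depends only on observed
full states, so the problem splits into `n` sub-problems (divide and
conquer). The engine keeps a pool of candidate polynomials per coordinate
alongside a population of assembled models. Per generation:

1. pool candidates are scored on one-step fit + prior row + parsimony;
2. new models are assembled by n-point crossover (one tournament per
   coordinate, size 3 by default) or, with probability `1 -
   crossover_rate`, by cloning and mutating a tournament-selected parent;
3. assembled models are scored on the full fitness;
4. parents and offspring compete; the top `population_size` survive, the
   elite fraction verbatim (so the best total fitness is non-decreasing -
   verified in every seeded run);
5. pools are refreshed: elites and the survivors' coordinates persist,
   the rest are tournament-selected mutants (add / remove / replace one
   monomial from `M`) plus ~5% fresh random candidates;
6. a memetic polish step hill-climbs the incumbent best model
   coordinate-wise, accepting single-monomial toggles that improve the
   coordinate fitness (a full scan of `M` when it is small, a seeded
   random sample of moves otherwise). This reliably finishes the local
   refinement that blind mutation reaches only slowly, at negligible cost
   for the search-space sizes the bound produces.

Ties are broken by lower complexity, then lexicographic model text, so the
ranked output family is deterministic. All randomness flows from one root
seed; identical inputs and configuration reproduce the run exactly. Cached
scores are reused for cloned elites (the data are static). Stopping:
generation budget exhausted, or a data-consistent model exists and the best
total fitness improved by less than 1e-9 over 20 generations.

The output is a ranked family of models (default 10) with full fitness
reports, plus a consensus wiring diagram: the edge-frequency matrix over
the family, thresholded at 0.5 for a binary consensus network.

Population initialisation and fresh-blood injection sample each candidate
with a geometric number of monomials (regulatory rules are sparse, so
small candidates dominate while larger ones remain reachable), capped at
8 per coordinate by default; monomials are drawn uniformly from `M`, or -
when a prior is supplied - with variable weights
`max(rho_ij, 0.05)` (degree uniform on `1..Phi`, draws with replacement
collapsed to a set), which concentrates initial supports on believed
regulators while the 0.05 floor preserves exploration.

Latin hypercube sampling of EA parameters is provided for sensitivity
studies: each parameter's range is split into `k` equal strata with one
draw per stratum and independently permuted strata, so all one-dimensional
projections cover the range.

## Evaluation conventions

Directed-edge confusion counts: an inferred edge in the gold network is a
TP; any other inferred edge - including one pointing the wrong way along a
true interaction - is an FP, and the unrecovered true counterpart stays an
FN. The TN universe is all ordered pairs (self-loops excluded by default,
includable by flag) minus the gold edges; whether published FPR values use
the same universe is not always stated, hence the flag. PPV, recall and
FPR are reported raw and rounded half-up to two decimals (half-up is what
reproduces 7/8 -> 0.88 and 5/8 -> 0.63 simultaneously). PPV is defined as
0 and flagged when nothing was inferred. Steady-state retrieval checks
which reference states are fixed points of an inferred model.

## Synthetic study conditions

The fixture generator plants a random model (in-degree at most 2 by
default, 1-2 monomials per coordinate, 30% chance of a constant term giving
negation-like rules) and simulates 5 wildtype plus 2 knock-out series of 8
time points each from uniform initial states: 56 points and `m = 49`
transitions on 5 nodes, roughly the ~10 points-per-variable regime of
realistic perturbation time-course designs, and enough that `Phi >= 4`
admits every planted monomial. The generator refuses specs whose planted
degree exceeds the `Phi` of the data they generate (recovery would be
ill-posed) unless explicitly overridden.

What the fixtures do *not* emulate: continuous measurement with subsequent
discretization artefacts, unequal sampling intervals, biological
(non-bit-flip) noise, and the attractor structure of real regulatory
networks. Passing the recovery experiments therefore demonstrates the
correctness and internal consistency of the pipeline on data generated by
the model class itself, not performance on experimental microarray data.

The planted-recovery experiments (20 systems, exercised by both the test
suite and `scripts/acceptance.py`) use population 60 and at most 150
generations: at `n = 5`, `M` holds only 31 monomials, so a small population
suffices and most runs stop early on stagnation. Free-run `H_f` of the
*generating* model on 5%-noised data stays below `2 * xi` on average:
flips in later rows cost one bit each, and only flips in a fragment's
first row can cause compounding free-run divergence.

## Numerical and degenerate-input choices

* Noise bit counts round half-up; report rounding is half-up to 2 decimals.
* `Phi = 0` (a single transition) gives complexity 0 for constant
  coordinates; non-constant candidates cannot arise from `M`.
* Exhaustive fixed-point enumeration is capped at `n = 20` (2^20 states);
  beyond that a sampling mode must be requested explicitly and results are
  flagged non-exhaustive.
* Data sets whose transitions are entirely destroyed by inconsistency
  breaking (`m = 0`) are a hard error for inference.
* Length-1 fragments contribute no mismatches but keep their row in the
  fit denominators, exactly as the normalisations are written.

## Known limitations

* The EA is a heuristic: no guarantee of reaching the global optimum, and
  underdetermined data yield families of equally fitting models - that is
  by design, and the consensus matrix is the honest summary.
* Only binary models are inferred; multi-level discretization is
  export-only.
* Asynchronous dynamics are supported only as a fixed-point invariance
  check, not as a fitting target.
* No Groebner-basis machinery: the support bound is used combinatorially,
  which is all the inference loop needs.
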