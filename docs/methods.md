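# Methods

## Model

InterCriteria analysis treats each criterion as inducing a weak order on
the m objects and measures, for each pair of criteria, how often the two
orders agree. For one unordered object pair and one criterion, the
relation R = ">" either holds, or its dual "<" holds, or the two
evaluations tie. Over the m(m−1)/2 object pairs the counters are

- S^μ: both criteria give R, or both give the dual;
- S^ν: one gives R and the other the dual;
- ties (either criterion): routed by `tie_mode` (below).

Dividing by m(m−1)/2 yields the intuitionistic fuzzy pair ⟨μ, ν⟩ with
μ + ν ≤ 1; the deficit π = 1 − μ − ν is the uncertainty contributed by
ties. The n × n output matrix is symmetric with ⟨1, 0⟩ on the diagonal.
Because only orderings enter, μ and ν are invariant under strictly
increasing transforms of any single criterion column, and lower-is-better
criteria need no sign convention. On tie-free data μ − ν = Kendall τ_a.

## Classification and thresholds

A pair ⟨μ, ν⟩ is labelled against thresholds α > β.

- `quarters` scale (default α = 0.75, β = 0.25): positive consonance /
  negative consonance / dissonance — three classes.
- `thirds` scale (α = 0.67, β = 0.33): the dissonance region is split; a
  pair with μ + ν < α (i.e. π > 1 − α) that is in neither consonance is
  labelled *uncertainty*. At α = 2/3 this reproduces the symmetric
  thirds partition of the intuitionistic triangle; we generalise the 2/3
  cuts to α so the rule stays total for any thresholds.

`boundary` decides whether equality qualifies. The default is
`inclusive` (μ ≥ α and ν ≤ β for the positive class, mirrored for the
negative class): published agreement tables are printed to two decimals,
and only the inclusive convention on printed values regenerates their
summary counts (e.g. a pair printed μ = 0.60 counts at α = 0.60). The
`strict` convention (μ > α, ν < β) is available for un-rounded data.

Sweeps fix β = 1 − α and vary α over {0.75, 0.70, 0.67, 0.65, 0.60} by
default. With ν = 1 − μ (the fixture case) and α + β = 1, the two-sided
rule collapses to a single cut on μ, so per-block positive counts are
non-increasing in α — a property the tests assert.

## Tie handling

The counting rule for ties is not standardised across ICrA
implementations, so it is explicit here:

- `unbiased` (default): any tie in either criterion sends the comparison
  to the tie bucket, which only π sees. This preserves the
  interpretation of π as uncertainty and keeps μ = (1 + τ_a)/2 exact on
  tie-free data.
- `mu_biased`: a simultaneous tie in both criteria counts as agreement
  (both criteria "refuse to distinguish" the objects the same way);
  single-sided ties still go to the tie bucket.

`epsilon` (default 0) widens tie detection to |Δe| ≤ ε for noisy
floating-point inputs; exact equality is the default because the method
itself defines ties by equality.

## Fixture conventions

Only the degrees of agreement μ are published for the docking
comparison (15 criteria pairs × 4 docking outputs, two decimals). For
classification the fixture takes ν = 1 − μ, i.e. π = 0 — the worst case
consistent with μ + ν ≤ 1, and exact whenever α + β = 1 (every scheme in
the default sweep). Reports based on the fixture inherit this
assumption.

## Synthetic generator

The generator emulates the *numeric shape* of docking-output tables, not
docking: m objects (default 195, the size of the CASF-2013 benchmark),
five scoring-function columns plus one experimental −logK column. Rows
are drawn from a zero-mean Gaussian with correlation `target_rho`, then
each column passes through a strictly increasing marginal transform:
affine negative values (−15 + 3z) for score blocks, log-normal-like
non-negative values (2·e^{0.6z}, median 2 Å) for RMSD blocks, and
6 + 1.5z for the affinity column. The constants were chosen once to give
magnitudes typical of docking scores, pose RMSDs and −logK values; they
are irrelevant to ICrA, which sees only orderings.

Because the marginals are continuous (tie-free) and the transforms
monotone, the expected agreement follows the Gaussian-copula arcsine law
μ = ½ + arcsin(ρ)/π, giving an analytic oracle; `rho_for_target_mu`
inverts it. ρ = ±1 pairs are built by copying/negating latent columns so
co-/antimonotone pairs are exact, not approximate. Joint calibration of
a full 6×6 `target_rho` from 15 pairwise μ targets can be infeasible
(indefinite); it is then projected to the nearest correlation matrix
(alternating projections), and achieved agreements deviate slightly from
requested ones. The pairwise construction in `simulate_table1_mu`
side-steps this by drawing each pair independently.

What passing synthetic tests does *not* show: real docking outputs have
ties (identical scores), heavy tails, block-wise dependence beyond a
Gaussian copula, and structured missingness between outputs. Conclusions
about real scoring functions must come from real docking tables.

## Numerical choices

- Counters are exact integer counts (vectorised comparisons, no
  floating-point accumulation); μ, ν are single exact divisions, so the
  Kendall identity holds to 1e−12 against an independent τ
  implementation.
- Pearson r delegates to `scipy.stats.pearsonr`; constant columns raise
  instead of returning NaN.
- Eigenvalues below −1e−10 fail the PSD check for `target_rho`;
  eigenvalues are clipped at 0 when factorising.
- `IFPair` tolerates μ + ν exceeding 1 by at most 1e−12 (rounding in
  user-supplied values).
- Degenerate inputs are errors, never silently handled: fewer than 2
  objects or criteria, non-finite cells, duplicate labels, ragged CSV
  rows, comma decimal separators, missing values.

## Problem sizes

Default test and demonstration sizes are those of the study layout the
package emulates: m = 195 objects for fixture-scale runs, m = 400–1000
for stochastic recovery checks (sampling error of μ at m = 1000 is well
below the 0.02 tolerance asserted), 20 seeds for the profile-emulation
property. The full suite runs in a few seconds.

## Known limitations

- Only the `unbiased` and `mu_biased` tie rules are implemented; other
  ICrA variants (balanced, weighted) are out of scope.
- No missing-data support: the method defines no imputation rule, so
  missing cells are rejected.
- Threshold selection is manual; no algorithmic (α, β) search.
- The intuitionistic-triangle view is exported as coordinates only; no
  plotting front end.
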