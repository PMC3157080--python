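# Methods

## The prediction model

`nodalrisk` scores a query tumor's panel-restricted expression profile
against a labeled reference cohort. For each reference sample *i* with
nodal label *y<sub>i</sub>* ∈ {0 = node-negative, 1 = node-positive}, the
Spearman rank correlation ρ<sub>i</sub> between the query profile and the
reference profile is computed over the panel probes (average ranks for
ties, so ρ equals the Pearson correlation of the rank vectors). The
posterior risk is a prior-smoothed weighted vote:

    w_i = max(ρ_i, 0)^γ          (γ ≥ 0, default 1)
    p   = (s·π₀ + Σ w_i y_i) / (s + Σ w_i)

with baseline prevalence π₀ (default 0.23, the rate of nodal involvement
at radical cystectomy) acting as a Bayesian prior with pseudo-count mass
*s* (default 1). The description of the original classifier names the
family — Bayesian weighted nearest neighbor on Spearman similarity — but
not the exact weighting or prior, so this concrete instantiation was chosen
for its checkable limits and is fully parameterised: *s* = 0 gives a pure
weighted vote, *s* → ∞ collapses to the prior, γ sharpens or flattens the
weighting, and *k* restricts the vote to the *k* most-correlated references
(*k* = 0, the default, uses all; ties with the *k*-th correlation are all
retained so the cut is order-independent). Negative correlations contribute
zero weight rather than negative evidence, which keeps *p* a proper
probability — a convex combination of π₀ and the reference labels — without
renormalisation. If no reference receives positive weight and *s* = 0, *p*
falls back to π₀ and the result is flagged.

Assumptions: expression values are already preprocessed and log-scale
(normalisation is upstream and out of scope); the reference cohort is
drawn from the population the query belongs to; within-profile ranks carry
the class signal. Because only query ranks enter, the score is invariant
to any strictly increasing per-sample transform — the property that makes
rank-based matching attractive across platforms and preservation methods.

Risk tiers apply fixed cutpoints to *p*: high (> 0.247), intermediate
(closed interval [0.227, 0.247]), low (< 0.227). The cutpoints bracket the
23% baseline prevalence but are treated as independent constants, since no
derivation rule linking them to π₀ is published; both are exposed as
parameters.

## The probe-fidelity screen

A probe is *high fidelity* when two per-probe criteria hold jointly:

1. **Preservation concordance** — its values across matched FFPE–FF sample
   pairs (paired by sample ID) correlate positively: one-tailed p < 0.025
   for H₁: r > 0. The correlation is Pearson on the log-scale values with
   the p-value from the t-transform of r at n − 2 degrees of freedom;
   the original screen's correlation type is unstated, so Pearson (the
   conventional concordance measure on log intensities) is the default and
   Spearman is available via `method="spearman"`.
2. **Specimen-source stability** — its values do not differ significantly
   between independent TUR and cystectomy groups: two-tailed p ≥ 0.01 from
   a Welch two-sample t-test (unequal n and variance; the original test is
   unstated). This is a failure-to-reject rule exactly as described, not a
   formal equivalence (TOST) procedure.

No multiple-testing correction is applied across probes: the published
criteria are per-probe α thresholds. Zero-variance probes fail the screen
automatically with a reason code (a constant vector has no defined
correlation); identical constant groups yield p = 1 in the difference
test, constant-but-shifted groups p = 0.

## Evaluation conventions

* **Dichotomisation** — test-positive = high-risk tier; intermediate and
  low count as test-negative. This convention reproduces the published
  operating arithmetic (sens 0.44, spec 0.70 → PPV 0.30, NPV 0.81 at 23%
  prevalence); `positive_classes` lets intermediate count as positive
  instead.
* **PPV/NPV** — closed-form Bayes conversions from (sens, spec,
  prevalence). When a degenerate dichotomisation (all samples in one tier)
  zeroes a denominator, the affected value is reported as NaN, not an
  error.
* **Relative risk** — in-tier event rate over the rate in the tier's
  complement (the standard epidemiological comparator; `reference="cohort"`
  compares against the whole cohort instead, since the published comparator
  is unstated). 95% CIs use the Katz log-normal approximation,
  exp(ln RR ± 1.96·√(1/a − 1/n_in + 1/c − 1/n_out)); when an arm has zero
  events, 0.5 is added to every cell and the estimate is flagged. The Katz
  interval is cross-checked against a bootstrap in the tests.
* **AUC** — the Mann–Whitney probability P(score⁺ > score⁻) + ½·P(tie),
  computed via scikit-learn and verified in the tests against exhaustive
  pair counting.

## Synthetic data

The generators emulate the three study designs the method touches, under a
single master seed (per-generator streams are spawned deterministically, so
composite fixtures are bit-reproducible):

* **Cohorts** — labels Bernoulli(prevalence = 0.23); values are Gaussian
  on the log scale around a baseline intensity of 8.0 (a typical log2
  MAS5/RMA level) with per-probe SD `noise_sd` (default 1.0) and a single
  equicorrelation parameter across probes (default 0.2, a modest shared
  sample-level factor). Node-positive samples are shifted by `effect_size`
  on the first `n_informative` probes (defaults 1.0 SD on 10 of 21 probes —
  roughly half the panel informative, a realistic signature density; the
  signal strength is deliberately moderate so discrimination is good but
  imperfect).
* **Matched pairs** — FFPE and FF values share a latent signal with
  loading √|ρ_pair| plus independent preservation noise, giving population
  per-probe correlation `pair_concordance` (default 0.8, strong but
  imperfect concordance) across pairs; the 32-pair design is the screen's
  default in tests.
* **Specimen sets** — independent TUR and cystectomy groups (defaults 30
  vs 25) with `specimen_shift` added to the informative probes of the
  cystectomy group (default 0).

What the generator does **not** emulate: Affymetrix probe-level intensity
physics, heavy-tailed or batch-structured noise, probe-specific variances,
and realistic gene–gene correlation structure beyond equicorrelation.
Passing tests therefore demonstrate statistical correctness and calibration
of the implementation, not clinical performance on real cohorts — the
original training/validation data (MSKCC, Laval, AUO cohorts) are not
publicly deposited, so the published AUCs (0.72/0.67) and tier relative
risks cannot be recomputed here, and no attempt is made to imitate them.

## Numerical choices

* Spearman correlations for prediction are computed by rank-transforming
  profiles (average ranks), centering, L2-normalising and taking dot
  products; constant reference profiles get ρ = 0 (no vote) and a constant
  query profile is an error.
* Risk-tier boundaries are closed on the intermediate side: *p* equal to
  either cutpoint is intermediate.
* Matrix files are read with round-trip float parsing, so write→read
  reproduces values bit-identically; missing values are rejected rather
  than imputed (a 21-probe signature leaves no room for silent
  imputation).
* File dialect: tab-delimited default with comma auto-detected from the
  header; the first column is the row-ID column.

## Test and simulation sizes

The suite calibrates the fidelity screen with 2,000 null replicates at the
screen's own designs (binomial 3-SE bands around the nominal 0.025 pass
rate and 0.99 retention rate), and checks signal recovery with
leave-one-out prediction on 500-sample cohorts over effect sizes
{0, 0.5, 1, 2}·noise_sd — sizes at which the Monte-Carlo error bands are
tight enough to be informative while the whole suite runs in well under a
minute.

## Known limitations

* **Leave-one-out pessimism.** Under the null, leave-one-out AUC of a
  neighbor-vote classifier is slightly below 0.5 (empirically ≈ 0.46 at
  n = 500): excluding a node-positive query from its own reference pool
  depletes that pool of positives, a bias of order 1/n relative to the
  score spread. It shrinks with cohort size and is immaterial at the
  effect sizes of interest, but exact-0.5 null calibration should not be
  expected from LOO evaluation.
* The original classifier's exact weighting, prior, neighbor count and
  probe identities are in its development publication, not reproduced
  here; the parameters exposed (γ, s, k, π₀, thresholds, panel file) allow
  the original rule to be emulated once known.
* The fidelity screen mirrors the published per-probe decision rule; it is
  a screening heuristic, not a formal equivalence test, and carries no
  family-wise error control.
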