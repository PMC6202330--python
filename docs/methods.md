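# Methods

## Problem setting

A pooled shRNA dropout screen yields, after hairpin-to-gene
summarisation and Z-normalisation, a gene × cell-line matrix of
depletion scores in which strongly negative values mean the line
depends on the gene for viability. Given a binary biomarker annotation
of the lines (tumour-suppressor *defective* vs *not altered*), the
pipeline asks, gene by gene: is inhibition selectively lethal in the
defective group, is the lethality profound there and absent elsewhere,
and how penetrant is it across the defective lines?

## Sample classification

A sample is called defective if **any** evidence condition holds
(OR logic — "one or more defects"); the evidence fields and strict
thresholds are:

| evidence | condition | default |
|---|---|---|
| expression low | target mRNA cohort Z < `mrna_z_cut` | −1 |
| copy-number loss | CN log2 ratio < `cn_log2_cut` | −log2(3/2) ≈ −0.585 |
| deleterious mutation | truncating only (missense never counts) | — |
| protein low (cell lines) | caller-supplied boolean | — |

All comparisons are strict: a sample exactly at a boundary carries no
evidence. Copy-number ratios convert to gain/neutral/loss states
symmetrically at ±|`cn_log2_cut`|; a missing ratio yields a missing
state, never neutral. Tumour rule sets differ only in which fields they
consume: TCGA-style uses mRNA Z + CN log2 + mutation; Metabric-style
uses mRNA Z + a pre-made CN call. Cell lines additionally use the
protein-low flag, which stays a caller responsibility because no
numeric western/iBAQ cutoff is defensible in general. Conflicting
evidence (low mRNA, protein present) resolves to defective — the
any-evidence rule is deliberately sensitive; specificity is recovered
downstream by the penetrance gate.

## Hairpin aggregation and normalisation

A gene's depletion in one line is the mean of its **two most depleted**
hairpins (one hairpin: that score). This order statistic is robust to
inert hairpins while still requiring corroboration by a second reagent.
Gene-level scores are standardised to mean 0, sample SD 1 (ddof = 1)
per gene or per line; vectors with under two observations or zero
spread are errors naming the offender, since silently passing them
through would poison every downstream comparison.

## Median-permutation (MP) test

For gene *g* with defective scores **d** (n₁ ≥ 2) and not-altered
scores **u** (n₂ ≥ 2), the statistic is Δ = median(**d**) − median(**u**).
The null reference is Δ* under random reassignment of the n₁ + n₂
labels at the same group sizes. Two estimators:

* **Monte-Carlo** (`mp_test`): N draws (default 10⁶),
  p = (b + 1)/(N + 1) with b = #{Δ* ≤ Δ} (side `less`; ≥ for
  `greater`). The add-one form is never zero and is valid under the
  null; ties count toward b (conservative).
* **Exhaustive oracle** (`mp_test_exact`): all C(n, n₁) assignments
  (feasible for n ≤ 20), p = b/C(n, n₁) with the observed assignment
  included — exhaustive enumeration needs no continuity correction.
  The oracle exists to validate the Monte-Carlo path and is never used
  as the screen implementation.

The test depends only on score ranks within the pooled vector up to
median arithmetic, so p is invariant to adding a constant and to
positive rescaling — both properties are tested.

Screen-wide (`run_mp_screen`), genes sharing a **missingness pattern**
(the same set of scored lines) share one permutation stream whose seed
is derived by hashing (base seed, sorted present-line identifiers).
This makes results reproducible, fast, and invariant to the order in
which columns appear in the input file. Genes with fewer than two
scores in either group are reported as untested (p = NaN), never
silently dropped. Benjamini–Hochberg q-values are appended across
tested genes for reporting; hit-calling downstream uses raw p < 0.05,
matching the published workflow's choice (an optional q gate exists,
default off).

## Dropout-trend test

Where hairpin abundance was measured over multiple time points, the
dependency signal is the dropout *rate*. The hierarchical model is
approximated in two stages rather than re-implemented exactly, because
only the model's structure — shRNA abundance as a regression on time
with a group-difference term and hairpin-level random effects — is
specified at the level we build from:

1. OLS slope of log-abundance on time per (hairpin, line);
2. slopes modelled as `slope = μ + γ·defective + a_h + ε` with hairpin
   random intercept `a_h`, fitted by REML (statsmodels `MixedLM`);
   `γ̂` is the group difference in dropout rate, with a Wald p halved
   into the requested one-sided direction.

With a single hairpin the random intercept is unidentifiable and the
model reduces to OLS of slopes on group (equivalently an equal-variance
t test). A REML solution with zero hairpin variance is a legitimate
boundary fit; the fixed effects remain valid and the boundary warnings
are suppressed. Fully degenerate inputs (no residual variation) return
p = 1.

## Triage and penetrance

Significant genes (p < `p_cut`, default 0.05) pass two median-Z
filters, then penetrance scoring:

* removed if median(Z_def) > `median_def_max` (default −1): the effect
  is not profound in the group it is supposed to kill;
* removed if median(Z_not) < `median_not_min` (default −2): the gene is
  lethal regardless of biomarker — a poor therapeutic prospect;
* **SLP** = 100 · #{defective lines with Z < c}/#{defective lines
  scored}, c = `sens_z_cut` (default −1);
* **SLC** = 100 · #{defective sensitive}/#{all sensitive}; with no
  sensitive line SLC is *undefined* and serialised NA — an empty
  denominator means "nothing responded", which is information, not 0%
  or 100%;
* hit iff SLP > `slp_cut_pct` (default 80), strictly.

All comparisons are strict as printed; boundary behaviour (−1, −2,
80%) is unit-tested. SLC deliberately shares `sens_z_cut` with SLP — a
single definition of "sensitive" keeps the two percentages referring to
the same event. Every output row keeps all intermediate statistics and
per-filter flags so each removal is attributable.

## Cross-screen comparison and stratification

Hits from independently derived screens are intersected by upper-cased
gene symbol (no alias resolution — the public screens already publish
symbols; identifier mapping is an upstream concern). The intersection
can key on the full-pipeline hit flag (default) or on raw p < 0.05
alone. Fisher's combined p orders the output but never calls hits —
the screens use different libraries and score scales, so a pooled
statistic would be decorative at best. Stratified re-analysis reruns
the MP test and SLP/SLC within each stratum's lines; strata with a
single defective line are reported descriptively (scores and SLP
shown, p = NA) rather than tested.

## Synthetic screens

The generator produces scores directly on the post-normalisation Z
scale — the pipeline's actual substrate — rather than simulating read
counts:

* null gene: Z ~ N(0, σ²) i.i.d. per line (σ default 1, the scale of a
  Z score);
* planted SL gene with penetrance π and effect δ: each defective line
  is independently a *carrier* with probability π; carrier scores are
  shifted by −δ before noise. Independent per-line carrier status is
  the simplest model consistent with penetrance as a per-line event;
* pan-lethal gene: −δ in every line;
* missingness completely at random at a configured rate.

Default conditions mirror the triple-negative breast cancer panel the
method was designed around: 42 lines, 12 defective. Time courses
follow `y(t) = a_h + (μ + γ·carrier + u_h)·t + ε` with hairpin random
slope u_h; defaults (5 hairpins, 4 time points, μ = −0.1, hairpin SD
0.1, noise SD 0.1) give slope estimates precise enough that γ recovery
is limited by between-line variation, as in a real screen. The omics
simulator draws, for each defective sample, a random non-empty subset
of evidence fields pushed beyond threshold, and keeps all fields of
not-altered samples on the safe side, so classification round-trips
exactly.

Closed-form expected penetrance under this model,

E[SLP] = 100·[π·Φ((c + δ)/σ) + (1 − π)·Φ(c/σ)],

is the oracle against which realised SLP is checked (binomial
sampling envelopes at 12 defective lines are wide: at π = 0.5, δ = 3
about 5% of replicate screens exceed the 80% gate by chance, and the
tests bound rather than forbid this).

**What the simulation does not emulate** — and hence what passing tests
do not establish about real screens: off-target hairpin effects,
copy-number-driven essentiality artefacts, correlated missingness,
batch structure between screens, and real biomarker misclassification.
The generator validates the statistical machinery, not the biology.

## Problem sizes and numerical choices

Tests and the acceptance script use reduced permutation counts
(10³–10⁵ instead of the 10⁶ default) and modest gene counts
(10²–2·10³); these sizes give Monte-Carlo standard errors far below
every tolerance asserted, so larger runs would only re-confirm the
same digits. Monte-Carlo/oracle agreement is asserted within three
binomial standard errors; normalisation moments to 10⁻¹²; the
single-hairpin trend p to 10⁻⁶ of the closed-form t test. Permutation
sub-seeds are derived by hashing so that no two missingness patterns
ever share a stream by accident, and all generators are pure functions
of (config, seed).

## Known limitations

* The trend test is a two-stage approximation: it ignores stage-1
  slope uncertainty, which understates stage-2 standard errors when
  time courses are short or noisy. With ≥ 3 time points and the
  default noise levels the γ coverage is empirically adequate
  (parameter-recovery tests), but p-values from sparse time courses
  should be treated as rankings.
* MP-test p-values are bounded below by 1/(N + 1); genome-wide FDR
  control at stringent levels needs N well above the default when q
  values are the object of interest.
* The penetrance gate is a point estimate: with 12 defective lines the
  difference between SLP 80% and 92% is one line. Cohort sizes below
  ~10 defective lines make the gate noisy, which is intrinsic to the
  statistic, not to this implementation.
* Classification inherits whatever biases the input omics carry; the
  package does not normalise expression cohorts or call mutations.
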