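# Methods

## Rank aggregation

Each study contributes up to two ordered lists (up- and down-regulated
miRNAs, rank 1 most significant). Lists — not studies — are the aggregation
unit: a study profiled on several platforms contributes several lists, and
the two directions are aggregated independently (no signed combination).

An item at 1-based position *p* in a list over a universe of *N* candidates
gets normalized rank *r* = *p*/*N* ∈ (0, 1]. With *n* lists in a direction
and the item's observed ranks sorted ascending r₍₁₎ ≤ … ≤ r₍ₖ₎, the beta
order-statistic scores are P(Beta(j, n−j+1) ≤ r₍ⱼ₎) for j = 1…k; ρ is their
minimum. Missing entries (the item was not in a list) contribute no order
statistic, but *n* stays at the full list count — the same convention used
for aggregating partial top-k lists generally. An optional
`missing_as_worst` switch instead imputes r = 1.

Two Bonferroni factors are kept as separate fields because they answer
different questions:

- `score` = min(1, ρ·n) corrects for taking the minimum over n positions and
  is the item's p-value as a test statistic;
- `p_adjusted` = min(1, score·N) additionally corrects for screening N
  candidate items and is the item-level significance used for signature
  calling.

The universe defaults to the union of all standardized names across lists —
reproducible from the inputs alone — and can be fixed to a catalogue size
(e.g. 2588, a full registry release of mature human miRNAs) via
`universe_size`. Ties in `p_adjusted` are broken lexicographically by name
so output order is deterministic.

A Monte-Carlo oracle (`mc_null_oracle`) estimates the same tail
probabilities by direct simulation of uniform order statistics; it exists
purely as an independent check of the closed form and is held to it in the
test suite at 4 binomial standard errors.

## Stability resampling

`jackknife_stability` repeats the aggregation with one list of the direction
removed per round and averages each item's `p_adjusted` across rounds
(items absent from every remaining list contribute 1.0, the most
conservative value). Random mode draws the removed list uniformly **with
replacement** across rounds from a seeded generator; because only n distinct
leave-one-out configurations exist, the implementation computes each
configuration once and weights it by its draw count — numerically identical
to the naive loop, so the conventional 10,000-round setting runs in seconds.
Exhaustive mode removes each list exactly once and equals the expectation of
random mode; it is the seed-free quantity used in tests. Rounds keep the
full collection's universe size so per-round p-values remain comparable with
the full-collection ones.

## Signature calling

A miRNA enters the integrated signature iff

1. `p_adjusted` < α (default 0.05),
2. it was never reported in the opposite direction (direction consistency),
3. it was reported by ≥ ceil(f·n) lists of its direction, f = 0.5 by
   default. The fraction filter is a flag (`min_fraction_datasets=None`
   disables it) because consistent reporting by at least half the datasets
   is as much an empirical property of good signatures as a rule.

Items passing (1) but failing (2) are returned in an
`inconsistent_significant` side report rather than silently dropped.
Tissue-subset analysis re-runs the aggregation on the lists of one tissue
with the universe recomputed from the subset (or fixed, if configured).

## qPCR and expression validation

ΔΔCt per patient is (Ct_target − Ct_reference) in tumor minus the same in
paired normal tissue; the reference is a stable small RNA (RNU6B by
convention). The reported fold change is 2^−mean(ΔΔCt) — the geometric mean
of per-patient folds, not the arithmetic mean, which is the standard
convention and is noted in the output. Significance is a **paired** t-test
of the ΔΔCt values against zero, matching the paired tumor/normal design;
one pair yields a fold only, zero variance is flagged degenerate.

Sequencing matrices (reads per million) are filtered by missingness with a
strict inequality — a row is removed when its missing fraction *exceeds* the
threshold (default 10%), so exactly-10% rows survive — then
log2-transformed with a +1 offset (RPM data contain zeros; any positive
offset is allowed). Group comparisons (tumor stage I/II vs III/IV,
lymphovascular invasion, microscopic vascular invasion) use Welch's t-test
by default, with the pooled-variance Student variant selectable; groups are
ordered lexicographically by label and the mean difference is reported as
group2 − group1.

## Survival analysis

Kaplan–Meier, the two-group log-rank test (χ² = (O−E)²/V with
hypergeometric variance per distinct event time), maximally selected
cut-points and univariate Cox regression are implemented directly, with an
established survival library used only as an independent cross-check in the
tests.

Cut-point selection scans all midpoints between consecutive distinct marker
values whose low/high split keeps both groups at or above a minimum cohort
fraction (default 10%) and keeps the χ²-maximizing candidate (ties → smaller
cut-point). The raw minimum p is anticonservative because it is the best of
many correlated tests; the corrected p is the add-one permutation fraction
of marker shuffles whose own maximal χ² reaches the observed one. A
permutation correction was chosen over the Miller–Siegmund closed form for
exact finite-sample validity at the cohort sizes involved and one fewer
analytic approximation. The minimum group fraction and the number of
permutations are exposed because published cut-point optimizers do not agree
on either.

The Cox model maximizes the univariate partial likelihood by Newton
iteration from β = 0 (convergence when |score| or the step drops below
10⁻⁸, at most 50 iterations) with Breslow tie handling by default — the
simplest convention consistent with the log-rank variance — and Efron as an
option. The Wald SE comes from the observed information; a diverging β
(|β| > 50 standard deviations of the covariate) or non-positive information
flags monotone likelihood (perfect separation), and no finite estimate is
trusted in that case. Event/censoring ties at equal times resolve events
first throughout.

## Targets and enrichment

Consensus targets are genes predicted by at least 3 of the (default 5)
prediction algorithms, united with experimentally validated targets — union,
not intersection, so a validated gene with weak prediction support stays.
The 3′-UTR restriction of prediction tables is treated as a property of the
input data, not recomputed.

Enrichment uses the hypergeometric upper tail P(X ≥ overlap) against a
background defaulting to the union of all genes in the gene-set collection
(reproducible from inputs; configurable). FDR control is Benjamini–Hochberg
— the generic "FDR" of web enrichment tools is not further specified, so
the choice is fixed and recorded in output metadata. The enrichment ratio is
overlap/set_size (overlap/query_size via a flag), and the relatedness
classifier applies strict inequalities (ratio > 0.3 AND p < 10⁻⁵ by
default). Heatmap clustering of a miRNA × pathway matrix of −log10 q uses
1 − Pearson correlation distance with average linkage, rows and columns
independently; zero-variance rows are excluded with a warning.

## Synthetic data

Generators are pure functions of (config, seed) via `numpy`'s PCG64.

- **Ranked studies**: per study, a latent differential-expression score per
  assayed miRNA — planted items shifted by `signal_strength` (in noise-SD
  units, signed by direction), plus Normal noise whose SD is `noise_sd`
  scaled by a per-study factor drawn U(0.8, 1.2) to mimic between-platform
  heterogeneity. The top-L scores form the up list, the bottom-L the down
  list, with L drawn from `list_length` and the assayed subset a `coverage`
  fraction of the universe. Latent-score ranking (rather than sampling ranks
  directly) makes list length, coverage and signal interact the way partial
  platform-dependent lists do. Tissue labels rotate
  colon/rectum/colorectal for deterministic subset fixtures. Defaults — 20
  studies, universe 300, coverage 0.8, lists of 20–40, 10+10 planted at
  signal 3 — define the strong-signal recovery benchmark used in the
  acceptance checks.
- **Survival**: marker ~ N(0,1); event times exponential with hazard
  baseline·HR^marker (default HR 1.875, the magnitude of a typical
  single-miRNA prognostic effect); independent exponential censoring with
  its rate matched to the target censoring fraction at the population-centre
  hazard.
- **qPCR**: reference Cts near 20, target Cts offset so the expected ΔΔCt
  equals the configured shift, independent Normal noise on all four Cts;
  11 patients by default, the size of a typical in-house validation cohort.
- **Expression**: log-normal RPM with planted tumor/normal and
  clinical-group shifts; MCAR missingness rates cycle through values
  deliberately straddling the 10% filter.
- **Targets**: latent true-target indicators; algorithm sensitivity
  `agreement + (1 − agreement)·base_rate` (agreement 1 → unanimous,
  agreement 0 → true targets indistinguishable from the false-positive
  background), false positives at `base_rate`.

What the generators do **not** emulate: platform-specific rank biases beyond
coverage and length heterogeneity, correlated missingness, batch effects,
non-proportional hazards, or correlated prediction errors between
algorithms. Passing the planted-recovery benchmarks therefore demonstrates
correctness of the statistics under their own assumptions, not robustness to
every real-data pathology.

## Numerical and interface choices

- Ranks are 1-based ordinal positions; ties within a list are not
  representable (input lists are ordered).
- Name standardization is table-driven (raw → canonical, or a DROP sentinel
  for viral miRNAs and non-miRNA probes); merging two raw names onto one
  canonical keeps the better rank. Alias chains/cycles are rejected rather
  than resolved.
- All sorting uses stable mergesort with explicit lexicographic tie-breaks,
  so outputs are platform-independent.
- Problem sizes in the acceptance script (200 null collections, 10 recovery
  seeds, 50 Cox replicates, 500 enrichment replicates) were chosen so each
  Monte-Carlo margin (3 standard errors) is small relative to the quantity
  measured while the full run stays in the minutes range on a single core.

## Known limitations

- Only univariate Cox fits; no multivariable model selection.
- No genomic clustering or seed-family annotation of signature members
  (external annotation lookups).
- The aggregation p-values are Bonferroni-style upper bounds, hence
  conservative under the null (the measured null exceedance at 0.05 is about
  half the nominal level); this is inherited from the min-over-positions
  construction.
- The enrichment background must be supplied or derived from the gene-set
  collection; results depend on it, as with any over-representation test.
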