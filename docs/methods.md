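# Methods

This note documents the statistical methods implemented in `tilsig`, the
synthetic-cohort model used to exercise them, the default parameters and
the reasoning behind them, and the numerical choices that make results
reproducible.

## 1. Signature derivation

**Normalization.** Expression rows are z-normalized per gene,
`(x − mean)/sd`, with the sample (n−1) standard deviation. Constant rows
cannot be scaled and are dropped with a logged warning rather than
zero-filled, so NaNs never reach the correlation or clustering steps.
When a probe-level matrix is supplied, probes are collapsed to one row
per gene symbol by keeping the probe with the largest interquartile
range, computed on the raw scale (IQR on z-scores is meaningless — every
row then has the same spread by construction) with type-7
linear-interpolation quartiles.

**Anchor filter.** A candidate gene is retained when its Spearman
correlation with at least one anchor gene (*CD247*, *MS4A1* by default)
reaches the threshold (default 0.7). A candidate that is itself an
anchor is never scored against itself; it must pass against another
anchor. Spearman is computed as Pearson on average ranks, so ties are
handled.

**Refinement.** Retained genes are kept when the two-sided Mann-Whitney
p comparing pCR vs RD expression is below α (default 0.05). No
multiplicity adjustment is applied — this matches the original
derivation recipe and is a deliberate scientific caveat: the retained
set is optimistic under many candidates.

**Mann-Whitney p-values.** U is the rank-sum statistic with average
ranks. The two-sided p uses the doubling convention,
`min(1, 2·min(P(U ≤ u), P(U ≥ u)))`, evaluated three ways depending on
size:

* both groups ≤ 8: direct enumeration of all `C(n, n_a)` labelings;
* pooled n ≤ 60: the identical permutation distribution computed by
  subset-sum dynamic programming over doubled average ranks (doubling
  makes every rank an integer, so arbitrary tie patterns are exact; the
  unit tests show agreement with full enumeration at the overlap);
* larger: the normal approximation with tie-corrected variance and
  continuity correction. The approximation is kept only where the
  discrete distribution is smooth enough for it — with heavy ties at
  moderate n it can err by several hundredths, which is why the exact
  dynamic program covers that regime.

## 2. Case clustering and the binary TIL call

Cases are clustered on the signature-gene z-score columns with
agglomerative **centroid linkage** under euclidean distance, recomputing
centroids after every merge. Centroid linkage can invert (a merge lower
than an earlier one), so trees are cut by undoing merges in **merge
order**, not by height, which keeps k-cluster partitions well defined
and nested. Distance ties are broken by the smallest (first-node,
second-node) pair, making the tree deterministic for a given input
order.

Starting at k = 3, k is raised until the cut yields exactly three
clusters holding at least `min_fraction` (default 0.05) of cases each;
members of smaller clusters are flagged outliers and excluded from the
downstream contingency analyses. The three primary clusters are ordered
by mean signature score into high / intermediate / low. Intermediate and
low are merged into a single TIL-low group when their pCR rates are
statistically indistinguishable (two-sided Fisher p ≥ 0.05). When the
rates do differ the merge is withheld: only the high cluster receives a
binary label, the report flags the condition, and stages that need a
binary contrast (the logistic TIL term) record a skip instead of
fitting a degenerate model.

## 3. Response statistics

* **Fisher exact test** (two-sided): probability-mass ordering — the sum
  of hypergeometric probabilities of all tables with the same margins
  whose probability does not exceed the observed table's, within 1e-12
  relative tolerance to absorb floating-point ties. Computed in log
  space (`gammaln` + `logsumexp`) so large tables cannot overflow.
* **Odds ratio** `(a·d)/(b·c)` with the Haldane-Anscombe +0.5 applied to
  every cell when any cell is zero; **Woolf interval**
  `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))` with z = 1.959964.
* **Predictive values**: PPV `a/(a+b)`, NPV `d/(c+d)`, accuracy
  `(a+d)/n`, reported with their integer fractions.
* **Single-gene upper-quartile analysis**: high = strictly above the
  type-7 Q3 of the assessed samples; degenerate splits (Q3 equal to the
  maximum) raise an error rather than returning an empty group.
* **Logistic regression** by iteratively reweighted least squares:
  convergence when the largest absolute coefficient change is below
  1e-8 (max 50 iterations), Wald standard errors from the inverse
  observed information, and a separation guard — coefficients passing
  15 in absolute value mark the fit non-converged instead of reporting
  inflated estimates silently. The unit tests pin the fit against
  statsmodels to 1e-6.

## 4. Survival analysis

* **Kaplan-Meier** product-limit estimator; subjects censored exactly at
  an event time remain at risk for that event.
* **Two-group log-rank** with full hypergeometric variance bookkeeping;
  the reported hazard ratio is the Mantel-Haenszel form
  `exp((O−E)/V)` with CI `exp((O−E)/V ± 1.96/√V)` — the "log-rank HR"
  of classical clinical software, not a proportional-hazards fit.
* **Trend test** across ordered treatment arms with numeric scores
  (default none = 0, CMF = 1, anthracycline = 2), using the full
  multivariate hypergeometric covariance; with two groups it reduces
  exactly to the two-group log-rank (verified to 1e-9).
* **5-year DFS** as a binary proportion among evaluable patients (event
  before 60 months, or followed at least 60 months); patients censored
  earlier are excluded and counted, so the proportion can feed Fisher
  comparisons directly.
* **Dichotomization**: median rule puts ties at the cut in the low
  group; the upper-quartile rule is inclusive (≥ Q3).

## 5. IHC scoring

Density = raw intraepithelial count ÷ epithelial fraction of the scoring
grid; per-mm² values divide by the grid area 0.56 mm² (×20 objective).
One core represents each sample/marker: the scoring protocol's two
criteria are applied lexicographically — tumor/stroma ratio closest to
50:50, then highest density — with core id as a final deterministic
tie-break. Marker-marker association uses Spearman correlation with an
exact permutation p for ≤ 10 pairs (chunked enumeration of all rank
pairings) and the t-approximation otherwise.

## 6. Synthetic cohort model

Each case carries a latent infiltration class,
high / intermediate / low, drawn with probabilities (0.28, 0.49, 0.23).

**Expression.** Signature and anchor genes take the class mean
(0.75, 0, −0.5 on the z scale) plus noise
`noise_sd · (√ρ·(√½·w + √½·f_block) + √(1−ρ)·ε)` where `w` is a
case-wide infiltration factor shared by all lymphocyte genes, `f_block`
is a per-block (T/B) factor and ε is gene-specific, all standard normal.
The within-block noise correlation is exactly ρ (default 0.8) and
cross-block genes share half of it through the case factor — both
blocks are driven by the same underlying infiltration, which is what
lets each block's genes also pass the other block's anchor. Defaults
`noise_sd = 0.3` and the class means were chosen analytically so that a
Gaussian boundary argument puts binary class recovery near 95%; the
recovery actually achieved is measured by the acceptance script, not
assumed. Noise probes are independent N(0, 1).

**Outcomes.** pCR is Bernoulli with logit
`intercept + effect·1[class = high]`; the default intercept −0.8003 and
effect 1.8458 encode response probabilities 0.31 (non-high) and 0.74
(high).

**Survival.** Exponential event times with baseline hazard 0.0175 per
month, administratively censored at 120 months. Treatment multiplies
the hazard per (treatment, class): CMF 0.35 in every class;
anthracycline 0.28 in the high class and 1.0 elsewhere — the planted
treatment × TIL interaction. The 1.0 encodes the working hypothesis
that anthracycline benefit is confined to immune-rich tumors; it is
what makes "detected in the high stratum, absent in the low" a
well-posed recovery target.

**IHC.** Per-core Poisson counts with class-dependent mean intensity
(23.4, 9, 3 — a 7.8-fold high/low contrast), scaled by an epithelial
fraction drawn uniformly on (0.2, 0.8); two cores per case.

All streams (class, expression, outcome, survival, IHC, covariates) are
seeded independently via `np.random.default_rng([seed, stream_offset])`,
so regenerating one component never perturbs another.

**What the generator does *not* emulate:** microarray platform effects
(probe saturation, batch, background), correlation between expression
noise and IHC counts beyond the shared latent class, non-proportional
hazards, competing risks, informative censoring, and any real-cohort
covariate structure (covariates are drawn from fixed marginals,
independent of class). Cohort-level published effect sizes are therefore
reproduced only as parameter-recovery properties, not as data.

## 7. Numerical and reproducibility choices

* Quartiles are always type-7 (linear interpolation) so probe selection
  and cut-points are platform-stable.
* z = 1.959964 is used for all 95% Wald-type intervals.
* Log-space hypergeometric probabilities with a 1e-12 relative tolerance
  for mass ties in the two-sided Fisher ordering.
* Exact Mann-Whitney distributions via integer (doubled-rank) dynamic
  programming; float accumulation there stays far below the 1e-12
  comparison tolerance used in tests.
* Text-only I/O: TSV matrices (`%.17g`, round-trip exact), CSV clinical
  tables with empty-string NA, JSON reports with a 16-hex-digit SHA-256
  configuration hash.
* Every random quantity in the package and the acceptance script derives
  from an explicit integer seed; derived stream seeds stay below 2³¹.

## 8. Limitations

* The refinement step inherits the original recipe's lack of multiplicity
  control; with many candidates the retained set is anti-conservative.
* Centroid linkage is order-dependent under exact distance ties and can
  invert; determinism is guaranteed, global optimality is not, and with
  overlapping classes the three-cluster cut can misallocate boundary
  cases (the merge gate then withholds the binary call by design).
* The Mantel-Haenszel hazard ratio approximates the proportional-hazards
  estimate and degrades when hazards cross.
* 5-year DFS as a binary proportion discards information relative to the
  Kaplan-Meier estimate at 60 months; it is provided because the
  downstream Fisher comparisons need counts.
* Synthetic recovery rates quantify internal consistency of the
  implementation, not clinical performance of the signature.
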