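# Methods

This note documents the statistical procedures implemented in
`mirscreen`, the choices made where the underlying methods admit more than
one reading, and what the synthetic-data experiments do and do not
demonstrate.

## Reference-network assembly (`netbuild`)

The reference miRNA→mRNA network is the union of validated interactions
and agreed computational predictions.

* Validated records keep only the low-throughput evidence class by default
  (`require_low_throughput=True`); high-throughput-only records are
  excluded unless the flag is cleared. When the same pair carries
  conflicting evidence classes, the strongest class wins and a warning is
  emitted.
* Per-tool prediction filters: HOCTAR keeps the pairs whose score ranks in
  the top fraction (default 0.5) — rank ≤ ceil(fraction·n) on descending
  score, ties broken lexicographically by (miRNA, gene) id so the cut is
  deterministic; ExprTarget requires score strictly greater than 1;
  starBase requires readNUM ≥ 10 and BC ≥ 2 (both inclusive). A pair
  enters the network only if at least `min_tool_agreement` (default 2)
  distinct tools pass it. These thresholds are monotone: tightening any
  of them can only shrink the output.
* miRNA names are harmonized through a user-supplied alias table (e.g. a
  miRBase alias dump); unknown names pass through with only the
  `hsa-miR`/`hsa-let` prefix case-normalized, and arm suffixes are never
  stripped. No third-party database is bundled.

## Differential expression (`descreen`)

Missing values are filled by k-nearest-neighbour imputation in *feature*
space (default k = 10): the distance between two features is the
Euclidean distance over their co-observed samples, and a missing cell
(f, s) becomes the mean over the k nearest features observed at s.
Observed cells are never altered. (scikit-learn's imputer rescales by the
number of co-observed coordinates, which changes neighbour ranking; it is
used as a cross-check only.)

miRNA screening uses the two-sided t test with p < alpha strict
(alpha = 0.05 default). The Welch unequal-variance form is the default —
the classical description of the procedure does not fix the variant, and
Welch is the robust choice — with `equal_var=True` available.

mRNA screening computes one of six statistics per feature. Writing D and
C for the disease and control vectors, med/MAD for median and
normal-consistent median absolute deviation (scale 1.4826), and q_r for
the r-th percentile with linear interpolation:

* **t** — Welch two-sample t, disease minus control.
* **COPA** — q_r((D − med(D∪C)) / MAD(D∪C)), r = 90 by default
  (configurable; 75/90/95 are the usual choices).
* **OS** — Σ (d − med(D∪C))/MAD(D∪C) over disease values d exceeding
  q75(D∪C) + IQR(D∪C); 0 when no value exceeds the threshold.
* **ORT** — as OS but centred/scaled by med(C)/MAD(C) with the threshold
  q75(C) + IQR(C) from the control quartiles.
* **MOST** — with z the control-standardized disease values sorted
  descending, max over k of (Σ_{i≤k} z_i − E_k)/S_k, where E_k and S_k
  are the mean and SD of the sum of the k largest of n iid standard
  normals. These moments are estimated once per n by Monte Carlo
  (200 000 draws, fixed internal seed, cached), so the statistic is
  deterministic and independent of user-level seeds.
* **LSOSS** — sort the disease values, split at the change point
  minimizing the within-subset sum of squares, and score
  (mean(outlier subset) − mean(C)) / s, where
  s² = (SS_C + SS_within both disease subsets)/(n_C + n_D − 3). The
  pooled-variance form is the natural degrees-of-freedom-corrected
  pooling; it is frozen in both the implementation and the exhaustive
  test oracle.

The outlier statistics score up-outliers; down-regulation is captured by
a mirrored run on the negated data, and ranking uses the signed maximum
of the two runs. All six statistics are invariant under adding a constant
to every sample.

Per study, features are ranked by |statistic| descending (feature-id
tie-break) and the top fraction kept (default 0.4 of the cross-study
common feature universe; the universe is intersected *before* ranking,
with a flag to invert). The statistic whose top lists agree best across
studies — mean pairwise percentage overlap, 100·|A∩B|/list length — is
selected; a three-way-intersection mode is available, and ties fall back
to the fixed method order with a warning.

## Network indices and significance (`netstat`)

Condition-specific networks are induced from the reference network by
endpoint filtering: an edge survives iff its miRNA is in the miRNA seed
and its gene in the gene seed (either side may be "all"); isolated nodes
are dropped. Seeding the miRNA side with the DE miRNAs gives Net1 — this
reading follows from the observation that the gene-seeded network can
contain far more miRNAs than were differentially expressed, which is only
possible when all regulators of the seeded genes are kept — and seeding
the gene side with the DE genes gives Net2. Both seeds are explicit, so
other readings remain expressible.

NOD(i) counts targets of miRNA i with in-network in-degree exactly 1;
TFP(i) is the TF fraction of its targets (undefined, and excluded, at
out-degree 0 — impossible after isolated-node dropping). Σ_i NOD(i)
always equals the number of in-degree-1 genes.

Significance uses a degree-preserving permutation null by default: each
replicate applies 10·|E| attempted edge swaps — pick two edges (m1,g1),
(m2,g2) and exchange their targets when neither replacement edge exists —
which preserves every miRNA out-degree and every gene in-degree exactly.
One-sided upper add-one p-values, (1 + #{null ≥ obs})/(n_null + 1), are
computed per miRNA separately for NOD and TFP. The originally described
signed-rank construction is not reconstructible from a single observed
value per miRNA (there is no pairing), so the package provides this
rewiring null as the default together with a clearly labelled `rank` mode
that scores each miRNA against the cross-miRNA empirical distribution of
the observed network; both are reconstructions and the mode is always
explicit in the API. Candidates require p_nod < alpha and p_tfp < alpha
(strict, alpha = 0.05) in both networks, with expression direction
attached from the DE results.

## Classifier evaluation (`classeval`)

Panels of one or two miRNAs are evaluated by stratified k-fold (default
fivefold) cross-validation of an RBF SVM with the e1071-style defaults
(cost 1, kernel width 1/n_features), fixed-seed fold shuffling, and
pooled out-of-fold decision values for the AUC / pooled hard predictions
for the confusion metrics. Pooling (rather than per-fold averaging) is
the default because it gives a single well-defined ROC; per-fold
averaging is reachable through the underlying API. AUC is the mid-rank
Mann–Whitney form, ties contributing ½, identical to the trapezoidal area
under the empirical ROC. `panel_search` evaluates all singletons and all
C(n,2) pairs, attaching each pair's mean single-marker AUC. A `direct`
mode scores single markers by raw expression with the orientation chosen
so training AUC ≥ 0.5 (to be frozen before scoring validation data).
Sensitivity/specificity derive from the SVM's default decision threshold;
a Youden-optimal cut is not applied by default.

## Clinical stage (`clinassoc`)

The weighted tissue score is the percent-positive bin (cuts at
5/25/50/75, upper category winning at a boundary — the convention
anchored by the "≥ 75% ⇒ 4" endpoint; the interior boundaries are
otherwise ambiguous) plus the intensity grade 0–3; categories are
0–1 "–", 2–3 "+", 4–5 "++", 6–7 "+++", and score ≥ 4 defines high
expression. Associations use Pearson χ² on 2×2 tables *without* Yates
continuity correction — the convention validated by exact reproduction of
the published clinicopathological p-values (0.0289, 0.0410, 0.0199,
0.8436) from their printed counts. Mann–Whitney U uses the exact null for
combined n ≤ 20 without ties and the tie-corrected normal approximation
otherwise. Survival uses lifelines' Kaplan–Meier product-limit estimator
and log-rank test (χ²(1), two-sided); at tied times events precede
censorings, the standard convention.

## Synthetic-study conditions (`synthdata`)

The generator emulates the shapes of the real inputs at desk scale. The
default conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| miRNAs / planted | 300 / 20 | headline recovery conditions |
| exclusive targets per planted miRNA | 25 | headline recovery conditions |
| planted vs background TF rate | 0.4 vs 0.1 | headline recovery conditions |
| genes (exclusive + background pool) | 3000 (500 + 2500) | keeps the planted DE genes within the top-40% screening capacity |
| background TF genes | 250 | background TF rate 0.1 |
| background edge density | 0.01 | ≈ 25 background targets per miRNA, so induced-network genes are typically multiply regulated and exclusivity is informative |
| background DE miRNAs / DE genes | 100 / 600 | gives the condition networks a realistic non-planted component, so false positives are possible in principle |
| samples per group | 20 | two-group microarray scale |
| noise SD / miRNA shift / gene shift | 0.5 / 1.5 uniform / 1.5 in a 25% disease subgroup | log₂-scale array noise; a 3σ subgroup shift is the cancer-outlier regime the outlier statistics exist for |
| clinical cases / association odds / hazards | 90 / 3.0 / (0.1, 0.3) | tissue-microarray scale |

Geometry was designed analytically so that a planted miRNA's NOD and TFP
sit ≳ 3 null standard deviations above the rewiring-null mean in both
condition networks (the rewiring null preserves gene in-degrees, so the
planted exclusive modules themselves contribute to the null rate — the
background component must be dense enough to dilute that
self-contamination). Every true edge carries filter-surviving evidence
(validated low-throughput, or ≥ 2 tools with passing scores, with HOCTAR
decoys balancing the score ranking); decoy records — single-tool
predictions, sub-threshold scores, high-throughput-only validations —
exercise the rejection paths.

What the generator does *not* emulate: probe/batch effects, platform
differences, correlated noise between co-regulated genes, non-Gaussian
intensity distributions, and miRNA–target expression coupling. Passing
recovery therefore demonstrates that the pipeline's inference is correct
under its own model assumptions, not that real arrays of this size would
yield the same power.

## Numerical and degenerate-input conventions

Percentiles interpolate linearly between closest ranks (COPA and OS
depend on this). A zero MAD raises a degenerate-scale error naming the
feature rather than returning ±inf. Features with no variance in either
group and equal means are skipped from t screening with a warning.
Rewiring requires at least two miRNAs and two genes. All permutation and
CV stages are deterministic under a fixed seed; the Gaussian
order-statistic table uses its own fixed internal seed.

## Problem sizes used in the shipped experiments

The test suite runs the full pipeline twice: once at the default
conditions above (499 rewiring replicates per network) and once at a
scaled-down configuration (60 miRNAs, 5 planted, 12 exclusive targets,
199 replicates) used for fast structural checks; the scaled-down run is
asserted only for majority recovery since its per-index z-scores are
intentionally smaller. Type-I calibration uses 1000 null features at
9 + 9 samples; classifier-null calibration uses 200 permutation
replicates at n = 40.
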