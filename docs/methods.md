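# Methods

## The problem

Bulk tumor RNA profiles are mixtures. A resected pancreatic ductal
adenocarcinoma (PDAC) sample contains neoplastic cells at some purity
`p ∈ [0,1]` alongside acinar tissue, immune infiltrate and
cancer-associated fibroblasts (CAFs). A "subtype signature" scored on such
a sample may therefore be reading the tumor cells — or the contamination.
This package operationalizes that distinction: it scores signature gene
sets, relates scores to purity, contrasts tissue compartments, follows
signatures from primaries into derived model systems, and issues a
machine-readable verdict (`tumor_intrinsic` / `non_tumor` / `ambiguous`)
per signature. A synthetic mixture cohort with complete ground truth makes
every step testable as a parameter-recovery problem.

## Gene-set scoring

The score of set *S* in sample *i* is the arithmetic mean of the log2
expression of the genes of *S* present in the dataset — no weights, no rank
transform, no imputation. Scores are computed whenever at least one gene
matches; below 50% coverage a warning is logged (short intersections make
scores hard to interpret, and the decomposition analyses show that which
subset of a list survives matters). For cross-tissue panels, scores are
mean-centered and scaled (z-score, denominator `n−1`) across an explicit
cohort; standardized vectors carry a `cohort_id` because the same sample
gets a different z-score in a different cohort. All analyses require log2
data; `to_log2(x) = log2(x + pseudocount)` (default pseudocount 1.0,
recorded in provenance) is applied exactly once and refuses to run twice.

## The synthetic cohort

Linear-scale expression of sample *i* at gene *g*:

    x_ig = p_i · T(s_i)_g + Σ_c w_ci · C(c)_g ,     p_i + Σ_c w_ci = 1

Profiles `T` (tumor, by subtype `s`) and `C` (acinar, immune, CAF, flat
"normal-other") equal a shared housekeeping baseline `b = 100` everywhere
except on the gene block each elevates, where the value is `b·2^δ`
(default δ = 1.5 log2 units). Each tumor also carries a program intensity
`t ~ Beta(5, 2)` that scales its neoplastic elevation to `b·(1 + t(2^δ−1))`
and is shared between a primary and its derived cell line or metastasis —
so paired samples track each other's signature *levels*, not just their
subtype, which is what makes paired retention a continuous, correlatable
quantity. Observed values are `log2(x+1)` plus Gaussian noise
(sd 0.4 by default) on the log2 scale, i.e. multiplicative noise linearly.

Gene blocks (40 genes each, plus 220 background genes): `basal`,
`classical` (subtype-specific tumor genes), `tumor_shared` (elevated in
both subtypes; its bulk score *rises* with purity), `acinar`, `immune`,
`caf` (compartment markers whose bulk scores *fall* with purity), and
`background` (never elevated).

Cohort composition (defaults; every count configurable): 150 primary
tumors with purity `Beta(5,3)` (right-shifted, resection-grade
cellularity) and contamination split `(1−p)·Dirichlet(2,2,2)` over
acinar/immune/CAF; 30 cell lines (p = 1) and 24 metastases, 80% of each
paired to a primary (shared subtype, intensity and `pair_id`); 12 PDXs
(p = 0.95 with a small CAF weight); 10 pure CAF cultures; 12 normal
pancreata (80% acinar, 10% immune, 10% CAF); 6 acinar cell carcinomas —
high purity `Beta(8,2)` but an acinar-like neoplastic profile, the
known non-PDAC tumor that scores high on exocrine-type lists at high
purity. The paired panel was sized (≈24 cell-line pairs) so the paired
Spearman of a tumor-block signature is estimated stably; the asymptotic
value under the mixture is ≈ 0.82.

Emitted signatures: one per block, plus two deliberately impure lists
that mirror how published exocrine-like and immunogenic signatures mix
compartments: `sim_ADEX-like` = acinar block ∪ 15 background genes, and
`sim_immunogenic` = immune block ∪ ~13% tumor-classical genes.

Reproducibility: one master seed; sample *j* draws everything from the
substream `default_rng([seed, j])`, so extending a cohort never perturbs
existing samples.

What the generator does **not** emulate: read-level counts or
length/GC bias, UMI or single-cell structure, copy-number effects,
platform/batch differences, correlated gene-gene structure beyond the
block mixture, or purity *estimation* error (metadata purity is the true
mixing weight). Passing tests therefore demonstrate that the statistics
recover the mixture structure they target, not that any particular real
signature is or is not tumor-intrinsic.

`expected_score_slope` gives the analytic expectation of the regression
slope of a block score on purity across primaries: noise is mean-zero
additive on the log2 scale, so the conditional mean score given
`(p, t, d)` is closed-form and the slope `Cov(score,p)/Var(p)` is computed
by deterministic Beta-quantile-grid integration (4000 purity nodes,
≥256 nodes for the intensity/Dirichlet-marginal dimension). Contamination
blocks come out negative, `tumor_shared` positive, subtype blocks positive
scaled by the subtype mix, background exactly zero.

## Rank statistics

Self-contained implementations, cross-checked in tests against independent
enumeration and reference implementations:

* **Spearman rho** — average ranks for ties; `rho` = Pearson correlation of
  ranks; two-sided p from `t = rho·sqrt((n−2)/(1−rho²))` on `n−2` df.
  Pairs with a missing value are dropped (logged), never imputed; `|rho|=1`
  is flagged and reported with p = 0; constant input is an error, not a 0.
* **Wilcoxon rank-sum** — statistic = rank sum of the first group. When
  both groups have ≤ 10 observations the two-sided p comes from exact
  enumeration of all rank splits, a permutation test over the observed
  average ranks that is valid with or without ties. Above that, a normal
  approximation with tie correction and a continuity correction (deviation
  clamped at 0, so identical groups give exactly p = 1); just past the
  cutoff it agrees with full enumeration to within a few percent.

Two-sided p-values everywhere, no multiple-testing correction by default
(an optional Benjamini–Hochberg column is available for the contrast
table).

## Consensus clustering

From-scratch resampled k-means consensus: each of `R` resamples draws
`⌈f·n⌉` items without replacement (`f` = 0.8) and partitions them with
Euclidean k-means (k-means++ seeding, best of 10 restarts, 300 iterations,
tol 1e−6). The consensus matrix entry `M_ij` is the number of times *i*
and *j* co-clustered divided by the number of times they were co-sampled;
pairs never co-sampled (practically impossible at the defaults) get 0 with
a warning. The final partition cuts an average-linkage dendrogram of
`1 − M` into k groups; average linkage on the consensus distance is the
conventional final call for this procedure family, and the code is
factored so a medoid-based cut could be swapped in. Default `R` = 1000;
the analyses and tests use 100–250, which is where the matrices here stop
moving at the third decimal. Item resampling only (no feature resampling).
Seeding mirrors the generator: resample *r* uses `default_rng([seed, r])`.

Two modes: **samples** as items over the union of signature genes
(`assign_subtypes`, k = number of gene sets, matching the convention of
calling one cluster per candidate signature) and **genes** of one
signature as items over samples (`decompose_signature`), which splits a
list into compartment-specific and nonspecific subsets and reports each
cluster's mean expression by tissue type so callers can label them. In
both modes gene rows are centered/scaled first (flag to disable):
Euclidean distance is otherwise dominated by high-magnitude genes. Whether
the original procedure scaled genes is not something this package asserts;
the default is documented as its own choice. Cluster → signature naming is
a one-to-one greedy assignment on mean standardized scores (ties broken by
collection order), so relabeling k-means clusters never changes the
result.

## Specificity statistics and the verdict

* `purity_correlation` — Spearman of score vs purity over samples with a
  purity value (pairwise deletion, never imputation).
* `compartment_panel` — per signature and contrast (e.g. primary vs cell
  line, primary vs CAF): group means of scores standardized across *all*
  samples of the table (the recorded cohort) plus the rank-sum p.
* `paired_retention` — across `pair_id` groups with exactly one source and
  one derived sample: Spearman of (source, derived) scores, plus a loss
  summary = mean standardized derived − source score. The headline is
  deliberately two numbers (correlation and loss), because a paired plot
  supports both readings and neither alone distinguishes "retained" from
  "uniformly shifted".
* `gene_list_overlap` — `|A∩B|` and its fraction of `|A|` (asymmetric, the
  denominator is the first argument).
* `label_concordance` — agreement fraction under a supplied vocabulary
  mapping, or the agreement-maximizing (Hungarian) mapping when none is
  given.
* `signature_robustness_panel` — per set: size, coverage, and the spread
  of tissue-wise mean standardized scores; long lists that absorb
  off-compartment genes show wide spreads across normal tissues.

**Verdict rules** (explicit configuration, echoed in every report; the
thresholds are this package's operational choices — the underlying
findings are directional):

* `non_tumor` if (purity rho ≤ −0.1 AND p < 0.05) OR (cell lines score
  significantly below primaries AND paired loss < 0);
* `tumor_intrinsic` if there is no significant cell-line deficit AND
  purity rho > −0.1;
* otherwise `ambiguous`, including "insufficient evidence" when required
  inputs are missing.

Every verdict carries machine-readable rule ids (`purity_confounded`,
`cellline_loss`, `cellline_retention`, `insufficient_evidence`,
`conflicting_evidence`).

## Top-scoring-pairs classifier

A generic rank-based single-sample engine: ordered gene pairs `(up, down)`
each vote for the positive class when `expr(up) > expr(down)` *within the
sample*; the call is the majority (vote fraction vs threshold 0.5,
within-pair ties counting 0.5). Training scores every pair by
`|P(up>down | class₁) − P(up>down | class₂)|` (strict inequality) and
selects greedily with each gene used at most once, margin ties broken
lexicographically. Default 8 pairs: small fixed panels are the point of
TSP classifiers. There is deliberately no per-pair logistic weighting —
the engine stays self-contained and fully testable, and is not a clone of
any published fitted model. Because no cross-sample quantity enters,
predictions are identical in and out of a batch and invariant under any
strictly increasing transform of the sample's expression vector.

## Pipeline and determinism

`run_audit` chains simulate/load → filter → log2 → score → purity
correlation (over primary tumors) → compartment contrasts → paired
retention → optional clustering/decomposition → verdicts, and writes a
bundle: `report.json`, flat TSVs, a config echo and a `MANIFEST.json`
recording every stage's operation, parameters, outputs and status
(`complete: false` plus the failing stage on error). All seeds come from
the config, never the clock; reports contain no timestamps, so identical
configs produce byte-identical reports. Logs go to stderr only.

## Numerical and degenerate-input choices

Standardization uses `n−1`; zero variance is an error, never silent
zeros. Zero-variance gene rows are set to 0 (with a warning) before
clustering rather than dropped, preserving item indices. `k = 1` and
`k = n` consensus runs are handled as the degenerate limits they are.
Duplicate gene ids, extra metadata rows, linear-scale input to scoring,
double log2 transforms, empty contrast groups and duplicated pair roles
are all hard errors naming the offender. Expression I/O round-trips
bit-exactly (`float_precision="round_trip"` on read).

## Problem sizes used by tests and drivers

The default cohort is 460 genes × 244 samples; replicate loops use 100
seeds for the purity-confounding and verdict recovery rates, 20 seeds for
decomposition recovery, and consensus runs use 100–250 resamples. These
sizes were chosen so every recovery statistic is comfortably past its
decision boundary while the whole suite stays quick to iterate on.

## Known limitations

* Verdicts inherit the thresholds above; a signature near the boundary is
  honestly `ambiguous` rather than forced into a class.
* Gene identifiers match by exact string equality; no alias mapping,
  probe collapsing, cross-platform normalization or batch correction (the
  package assumes one row per gene, one platform per dataset).
* The generator's compartment weights are plausibility choices (labelled
  as such in the truth JSON); real tumors do not come with known weights.
* `assign_subtypes` assumes the candidate signatures are mutually
  exclusive cluster namesakes; overlapping signatures can produce naming
  collisions that the greedy assignment resolves but does not flag as
  biology.
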