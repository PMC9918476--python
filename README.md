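# sigspec

**Is a transcriptomic subtype signature reading the tumor — or the tissue
around it?**

Bulk tumor RNA profiles mix neoplastic cells (at purity *p*) with acinar
tissue, immune infiltrate and cancer-associated fibroblasts (CAFs). In
pancreatic ductal adenocarcinoma (PDAC), this matters acutely: the
basal-like/classical two-subtype model behaves as tumor-intrinsic, while
exocrine/"ADEX"-type and immunogenic signatures behave like contamination
readouts. `sigspec` packages the audit that makes this distinction
operational, for anyone evaluating signature gene sets on bulk expression
data:

* **gene-set scoring** — score of set *S* in sample *i* is the mean log2
  expression of S's genes, optionally z-scored across an explicit cohort;
* **purity confounding** — Spearman correlation of score with tumor purity
  across primaries (a contamination signature gives rho < 0: less tumor,
  higher score);
* **compartment contrasts** — rank-sum tests of standardized scores,
  primaries vs cell lines / PDXs / CAFs / normal tissue;
* **paired retention** — does the signature survive the transition from a
  primary into its derived cell line or metastasis? (Spearman across
  pairs + standardized loss);
* **consensus clustering** — from-scratch resampled k-means consensus, for
  subtype calling (k = number of gene sets) and for decomposing a single
  signature into compartment-specific vs nonspecific gene subsets;
* **verdicts** — explicit, configurable rules combine the above into
  `tumor_intrinsic` / `non_tumor` / `ambiguous`, with machine-readable
  justifications;
* **TSP classifier** — a generic top-scoring-pairs engine: rank-based,
  single-sample, cohort-free subtype calls;
* **synthetic cohorts** — a mixture-model generator
  (`x = p·T(s) + Σ w_c·C(c)`, log2, Gaussian noise) with full ground
  truth, so every statistic above is tested as a parameter-recovery
  problem. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from sigspec import SimulationConfig, generate_cohort, run_audit

result = run_audit({"seed": 0, "simulate": {}}, out_dir="results/audit")
for name, info in result.report["gene_sets"].items():
    print(name, info["verdict"], round(info["purity_rho"], 3), round(info["paired_loss"], 3))
```

prints (signature, verdict, purity rho, paired primary→cell-line loss):

```
sim_basal        tumor_intrinsic  0.171   0.278
sim_classical    tumor_intrinsic  0.207   0.499
sim_tumor_shared tumor_intrinsic  0.761   1.008
sim_ADEX-like    non_tumor       -0.522  -1.070
sim_immunogenic  non_tumor       -0.447  -0.958
sim_caf          non_tumor       -0.528  -1.191
sim_housekeeping tumor_intrinsic  0.036  -0.004
```

Reading this: the acinar-anchored `sim_ADEX-like` list anticorrelates with
purity (rho = −0.52 across 150 primaries) and collapses in cell lines
(standardized loss −1.07) — the generator built it from non-tumor
compartments, and the audit calls it `non_tumor` for exactly those two
reasons (`purity_confounded`, `cellline_loss`). The subtype blocks ride
with purity and are retained in cell lines (pairwise Spearman 0.87 for
basal, 0.83 for classical), so
they come back `tumor_intrinsic`. A flat housekeeping list is neither
purity-linked nor lost, and lands `tumor_intrinsic` under the rules (no
evidence of a non-tumor source).

The same pipeline runs from the shell on your own files
(`expression.tsv` genes × samples, `metadata.tsv` with `sample_id`,
`tissue_type`, `purity`, `pair_id`, and a `.gmt` of gene sets):

```bash
sigspec simulate --seed 0 --out-dir cohort/          # or bring your own trio
sigspec audit --config audit.yaml --out-dir audit/   # writes report.json + TSVs + MANIFEST
sigspec classify --model tsp_model.json --sample one_sample.tsv
```

## The analysis, step by step

Numbered drivers under `analysis/` tell the story on the default synthetic
cohort and write their tables under `results/`:

| script | what it shows |
|---|---|
| `01_simulate_cohort.py` | the mixture cohort (460 genes × 244 samples) and its ground truth |
| `02_score_signatures.py` | score table + cross-tissue robustness panel |
| `03_purity_confounding.py` | which signatures track purity (and the analytic slope check) |
| `04_retention_and_compartments.py` | compartment contrasts and paired retention/loss |
| `05_decompose_signature.py` | gene-based consensus decomposition of the mixed acinar-like list |
| `06_audit_verdicts.py` | the end-to-end audit bundle and verdicts |
| `07_tsp_classifier.py` | single-sample classifier + accuracy-vs-purity curves |

Run them in order from `analysis/` (each regenerates the cohort if
`results/cohort/` is absent).

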