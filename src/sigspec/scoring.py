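"""Gene-set scoring: per-sample mean log2 expression, with a cohort-wise
mean-centered/scaled variant for cross-tissue panels.

The unstandardized score of a set in a sample is the arithmetic mean of the
log2 expression of the set's genes present in the dataset — no weighting, no
rank transform, no imputation of missing genes.  Standardization (z-score
with the n-1 denominator) is an explicit, cohort-dependent second step, and
every standardized vector records the cohort it was standardized in.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSet, GeneSetCollection

log = logging.getLogger(__name__)

#: Below this fraction of a set's genes found in the dataset, a warning is
#: logged (the score is still computed as long as >= 1 gene matches).
LOW_COVERAGE_WARNING = 0.5


@dataclass(frozen=True)
class ScoreVector:
    gene_set_name: str
    scores: pd.Series  # indexed by sample_id
    coverage: float
    matched_genes: tuple[str, ...]
    standardized: bool = False
    cohort_id: str | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def _cohort_id(sample_ids: pd.Index) -> str:
    digest = hashlib.sha1("\n".join(map(str, sample_ids)).encode()).hexdigest()[:8]
    return f"n{len(sample_ids)}-{digest}"


def gene_set_score(ds: ExpressionDataset, gene_set: GeneSet) -> ScoreVector:
    """Mean log2 expression of the set's matched genes, per sample."""
    if ds.scale != "log2":
        raise ValueError(
            f"gene_set_score requires a log2-scaled dataset; got scale={ds.scale!r} "
            "(apply to_log2 first)"
        )
    matched = [g for g in gene_set.genes if g in ds.values.index]
    if not matched:
        raise ValueError(f"gene set {gene_set.name!r}: no genes found in dataset")
    missing = [g for g in gene_set.genes if g not in ds.values.index]
    if missing:
        log.info("gene set %r: %d gene(s) missing from dataset", gene_set.name, len(missing))
    coverage = len(matched) / len(gene_set.genes)
    if coverage < LOW_COVERAGE_WARNING:
        log.warning(
            "gene set %r: coverage %.0f%% (< %.0f%%); score interpretability degraded",
            gene_set.name, 100 * coverage, 100 * LOW_COVERAGE_WARNING,
        )
    scores = ds.values.loc[matched].mean(axis=0)
    scores.name = gene_set.name
    return ScoreVector(
        gene_set_name=gene_set.name,
        scores=scores,
        coverage=coverage,
        matched_genes=tuple(matched),
    )


def standardize_scores(sv: ScoreVector, cohort_id: str | None = None) -> ScoreVector:
    """Mean-center and scale (sd with denominator n-1) across the cohort.

    The result is cohort-dependent; ``cohort_id`` (default: derived from the
    sample ids) travels with the vector so reports can state the cohort used.
    """
    if len(sv.scores) < 2:
        raise ValueError("standardization requires >= 2 samples")
    sd = sv.scores.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(
            f"gene set {sv.gene_set_name!r}: zero variance, cannot standardize"
        )
    z = (sv.scores - sv.scores.mean()) / sd
    return replace(
        sv,
        scores=z,
        standardized=True,
        cohort_id=cohort_id if cohort_id is not None else _cohort_id(sv.scores.index),
    )


def score_panel(
    ds: ExpressionDataset,
    collection: GeneSetCollection,
    standardize: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score every set; returns (long-format table, per-set failure records).

    The table has columns (sample_id, gene_set, score, coverage,
    standardized).  A set that cannot be scored becomes a failure record
    (set name, reason) and the remaining sets are still scored.
    """
    frames = []
    failures: list[tuple[str, str]] = []
    for gs in collection:
        try:
            sv = gene_set_score(ds, gs)
            if standardize:
                sv = standardize_scores(sv)
        except ValueError as exc:
            failures.append((gs.name, str(exc)))
            continue
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sv.scores.index,
                    "gene_set": gs.name,
                    "score": sv.scores.to_numpy(),
                    "coverage": sv.coverage,
                    "standardized": sv.standardized,
                }
            )
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["sample_id", "gene_set", "score", "coverage", "standardized"])
    )
    return table, failures
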