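"""Signature-specificity statistics: purity correlation, compartment
contrasts, paired retention, list overlap/concordance, and the
tumor-intrinsic verdict.

Rank statistics are self-contained here (Spearman rho with a t-based
two-sided p; Wilcoxon rank-sum with exact small-sample enumeration), so the
whole audit depends on no black-box test implementation.  The scientific
logic: a signature that is tumor-intrinsic should (i) not track negatively
with neoplastic purity across bulk tumors, and (ii) be retained in pure
model systems (cell lines) derived from primaries.  A contamination-driven
signature shows the opposite pattern on both axes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist

from .datasets import ExpressionDataset, GeneSet, GeneSetCollection
from .scoring import ScoreVector, gene_set_score, standardize_scores

log = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 10


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n_used: int
    degenerate: bool = False  # |rho| == 1: p reported as 0


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value in either argument are dropped (count
    logged).  p is two-sided from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df;
    |rho| = 1 is flagged and reported with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        log.info("spearman: dropped %d pair(s) with missing values", dropped)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"spearman requires >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant argument")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        return SpearmanResult(rho=float(np.sign(rho)), p=0.0, n_used=n, degenerate=True)
    tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * t_dist.sf(abs(tstat), df=n - 2))
    return SpearmanResult(rho=rho, p=min(p, 1.0), n_used=n)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first group
    p: float
    method: str  # "exact" | "normal"


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test (average ranks for ties).

    Exact null enumeration of all rank splits (a permutation test over the
    observed average ranks, valid with or without ties) when both groups
    have <= 10 observations; otherwise a normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) + len(b) < 3:
        raise ValueError("combined n must be >= 3")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    na, nb = len(a), len(b)
    n = na + nb
    w = float(ranks[:na].sum())
    mean_w = na * (n + 1) / 2.0

    if na <= EXACT_RANKSUM_MAX_N and nb <= EXACT_RANKSUM_MAX_N:
        obs_dev = abs(w - mean_w)
        count = 0
        total = 0
        for pos in itertools.combinations(range(n), na):
            total += 1
            if abs(ranks[list(pos)].sum() - mean_w) >= obs_dev - 1e-9:
                count += 1
        return RankSumResult(statistic=w, p=count / total, method="exact")

    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return RankSumResult(statistic=w, p=1.0, method="normal")
    z = max(abs(w - mean_w) - 0.5, 0.0) / np.sqrt(var_w)
    p = float(min(1.0, 2.0 * norm.sf(z)))
    return RankSumResult(statistic=w, p=p, method="normal")


def purity_correlation(sv: ScoreVector, metadata: pd.DataFrame) -> SpearmanResult:
    """Spearman correlation of a gene-set score with tumor purity.

    Restricted to samples with a purity value; samples lacking purity are
    dropped pairwise, never imputed.
    """
    if "purity" not in metadata.columns:
        raise ValueError("metadata has no 'purity' column")
    purity = pd.to_numeric(metadata["purity"], errors="coerce").reindex(sv.scores.index)
    usable = purity.notna()
    if usable.sum() < 3:
        raise ValueError(
            f"purity_correlation needs >= 3 samples with purity, got {int(usable.sum())}"
        )
    return spearman(sv.scores[usable].to_numpy(), purity[usable].to_numpy())


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_i in range(m - 1, -1, -1):
        i = order[rank_i]
        running = min(running, p[i] * m / (rank_i + 1))
        adj[i] = running
    return adj


def compartment_panel(
    score_table: pd.DataFrame,
    metadata: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Tissue-compartment contrasts of standardized gene-set scores.

    ``score_table`` is the long-format output of
    :func:`sigspec.scoring.score_panel` (unstandardized); scores are
    standardized here across ALL samples of the table, which is the recorded
    standardization cohort.  Each contrast (tissue A vs tissue B) yields
    group means and a two-sided rank-sum p per gene set.
    """
    if "tissue_type" not in metadata.columns:
        raise ValueError("metadata has no 'tissue_type' column")
    tissue = metadata["tissue_type"]
    for ga, gb in contrasts:
        for g in (ga, gb):
            if g not in set(tissue.dropna()):
                raise ValueError(f"contrast group {g!r} absent from metadata tissue_type")
    rows = []
    for gene_set, sub in score_table.groupby("gene_set", sort=False):
        s = pd.Series(sub["score"].to_numpy(), index=sub["sample_id"].to_numpy())
        sd = s.std(ddof=1)
        if sd == 0:
            raise ValueError(f"gene set {gene_set!r}: zero score variance in panel")
        z = (s - s.mean()) / sd
        tt = tissue.reindex(z.index)
        for ga, gb in contrasts:
            za = z[(tt == ga).to_numpy()]
            zb = z[(tt == gb).to_numpy()]
            if len(za) == 0 or len(zb) == 0:
                raise ValueError(
                    f"contrast {ga!r} vs {gb!r}: empty group for set {gene_set!r}"
                )
            res = rank_sum_test(za.to_numpy(), zb.to_numpy())
            rows.append(
                {
                    "gene_set": gene_set,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(za),
                    "n_b": len(zb),
                    "mean_a": float(za.mean()),
                    "mean_b": float(zb.mean()),
                    "statistic": res.statistic,
                    "p": res.p,
                }
            )
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        out["q"] = _bh_adjust(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class RetentionResult:
    rho: float
    p: float
    n_pairs: int
    loss: float  # mean standardized derived score - mean standardized source score
    table: pd.DataFrame  # pair_id, source_sample, derived_sample, source_score, derived_score


def paired_retention(
    sv: ScoreVector,
    metadata: pd.DataFrame,
    source_type: str = "primary_tumor",
    derived_type: str = "cell_line",
) -> RetentionResult:
    """Does a signature survive the transition from bulk primary to a derived
    model system?

    Pairs are samples sharing a ``pair_id`` with exactly one sample of each
    requested tissue type.  Returns the Spearman correlation of (source,
    derived) scores across pairs and a loss summary: mean standardized
    derived minus source score (standardization over all samples of the
    score vector).  A retained signature shows high rho and loss >= 0; a
    contamination signature shows loss < 0 with little correlation.
    """
    for col in ("pair_id", "tissue_type"):
        if col not in metadata.columns:
            raise ValueError(f"metadata has no {col!r} column")
    meta = metadata.reindex(sv.scores.index)
    z = standardize_scores(sv).scores
    rows = []
    for pair_id, grp in meta.dropna(subset=["pair_id"]).groupby("pair_id"):
        src = grp.index[grp["tissue_type"] == source_type]
        der = grp.index[grp["tissue_type"] == derived_type]
        if len(src) > 1 or len(der) > 1:
            raise ValueError(f"pair {pair_id!r} has duplicated roles")
        if len(src) == 1 and len(der) == 1:
            rows.append(
                {
                    "pair_id": pair_id,
                    "source_sample": src[0],
                    "derived_sample": der[0],
                    "source_score": float(sv.scores[src[0]]),
                    "derived_score": float(sv.scores[der[0]]),
                    "source_z": float(z[src[0]]),
                    "derived_z": float(z[der[0]]),
                }
            )
    if len(rows) < 3:
        raise ValueError(
            f"paired_retention needs >= 3 usable {source_type}->{derived_type} pairs, "
            f"got {len(rows)}"
        )
    table = pd.DataFrame(rows)
    res = spearman(table["source_score"].to_numpy(), table["derived_score"].to_numpy())
    loss = float(table["derived_z"].mean() - table["source_z"].mean())
    return RetentionResult(rho=res.rho, p=res.p, n_pairs=len(table), loss=loss, table=table)


def gene_list_overlap(set_a: GeneSet, set_b: GeneSet) -> tuple[int, float]:
    """|A intersect B| and its fraction of |A| (asymmetric: denominator is
    the first argument)."""
    inter = set(set_a.genes) & set(set_b.genes)
    return len(inter), len(inter) / len(set_a.genes)


def label_concordance(
    labels_a: pd.Series,
    labels_b: pd.Series,
    mapping: Mapping[str, str] | None = None,
) -> tuple[float, dict[str, str]]:
    """Fraction of samples on which two labelings agree.

    When no vocabulary mapping a-label -> b-label is supplied, the mapping
    maximizing agreement is inferred (Hungarian assignment on the
    contingency table).  Both series must cover the same sample ids.
    """
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("label vectors cover different sample ids")
    b = labels_b.reindex(labels_a.index)
    if mapping is None:
        from scipy.optimize import linear_sum_assignment

        tab = pd.crosstab(labels_a, b)
        # pad to square so every a-label can map somewhere
        cols = list(tab.columns) + [f"__pad{i}" for i in range(max(0, len(tab) - len(tab.columns)))]
        tab = tab.reindex(columns=cols, fill_value=0)
        ri, ci = linear_sum_assignment(-tab.to_numpy())
        mapping = {
            str(tab.index[i]): str(tab.columns[j])
            for i, j in zip(ri, ci)
            if not str(tab.columns[j]).startswith("__pad")
        }
    mapped = labels_a.map(mapping)
    agree = float((mapped == b).mean())
    return agree, dict(mapping)


@dataclass(frozen=True)
class VerdictRules:
    """Operational thresholds for the tumor-intrinsic verdict (artifact
    configuration, echoed in every report; the underlying findings are
    directional)."""

    rho_threshold: float = -0.1
    p_threshold: float = 0.05


@dataclass(frozen=True)
class Verdict:
    verdict: str  # tumor_intrinsic | non_tumor | ambiguous
    rules_triggered: tuple[str, ...]
    rules: VerdictRules = field(default_factory=VerdictRules)


def signature_verdict(
    fragment: Mapping[str, float | None],
    rules: VerdictRules = VerdictRules(),
) -> Verdict:
    """Classify one signature as tumor_intrinsic / non_tumor / ambiguous.

    ``fragment`` carries: purity_rho, purity_p, primary_mean, cellline_mean,
    cellline_p (primary-vs-cell-line contrast), paired_loss (optional).

    non_tumor when the score tracks negatively with purity
    (rho <= rho_threshold, p < p_threshold) OR cell lines significantly
    underscore primaries with paired loss < 0.  tumor_intrinsic when
    cell-line retention holds (no significant cell-line deficit) and the
    purity correlation is not below the threshold.  Otherwise ambiguous.
    """
    def get(key: str) -> float | None:
        v = fragment.get(key)
        if v is None:
            return None
        v = float(v)
        return v if np.isfinite(v) else None

    rho, rho_p = get("purity_rho"), get("purity_p")
    pm, cm, cp = get("primary_mean"), get("cellline_mean"), get("cellline_p")
    loss = get("paired_loss")

    if rho is None or rho_p is None or pm is None or cm is None or cp is None:
        return Verdict("ambiguous", ("insufficient_evidence",), rules)

    triggered: list[str] = []
    purity_confounded = rho <= rules.rho_threshold and rho_p < rules.p_threshold
    cellline_deficit = cm < pm and cp < rules.p_threshold
    cellline_lost = cellline_deficit and loss is not None and loss < 0

    if purity_confounded:
        triggered.append("purity_confounded")
    if cellline_lost:
        triggered.append("cellline_loss")
    if purity_confounded or cellline_lost:
        return Verdict("non_tumor", tuple(triggered), rules)
    if not cellline_deficit and rho > rules.rho_threshold:
        return Verdict("tumor_intrinsic", ("cellline_retention",), rules)
    return Verdict("ambiguous", ("conflicting_evidence",), rules)


def signature_robustness_panel(
    collection: GeneSetCollection,
    ds: ExpressionDataset,
) -> pd.DataFrame:
    """Per-signature size, coverage and cross-tissue spread of mean
    standardized scores.

    A set whose standardized score swings widely across non-tumor tissue
    types is flagged by a large ``spread``; compact tumor-derived sets stay
    flat outside tumor compartments.  Longer lists tend to pick up more
    off-compartment genes, so spread is reported next to set size.
    """
    meta = ds.meta_aligned()
    if "tissue_type" not in meta.columns:
        raise ValueError("metadata has no 'tissue_type' column")
    tissue = meta["tissue_type"]
    rows = []
    for gs in collection:
        try:
            z = standardize_scores(gene_set_score(ds, gs)).scores
        except ValueError as exc:
            rows.append({"gene_set": gs.name, "size": len(gs), "error": str(exc)})
            continue
        by_tissue = z.groupby(tissue).mean()
        row = {
            "gene_set": gs.name,
            "size": len(gs),
            "coverage": len([g for g in gs.genes if g in ds.values.index]) / len(gs),
            "spread": float(by_tissue.max() - by_tissue.min()),
        }
        row.update({f"mean_{t}": float(v) for t, v in by_tissue.items()})
        rows.append(row)
    return pd.DataFrame(rows)
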