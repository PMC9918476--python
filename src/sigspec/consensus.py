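"""Resampled k-means consensus clustering, written from scratch.

The procedure: repeatedly subsample items without replacement, run Euclidean
k-means on each subsample, and tally how often each item pair lands in the
same cluster relative to how often it was co-sampled.  The consensus matrix
M (entries in [0,1]) summarizes partition stability; the final call cuts an
average-linkage dendrogram of the distance 1 - M into k groups.

Two modes are used by the analyses: samples as items with signature genes as
features (subtype calling, k = number of gene sets) and genes of one
signature as items with samples as features (signature decomposition into
compartment-specific vs nonspecific subsets).

Reproducibility: one master seed; resample r draws from the substream
``default_rng([seed, r])`` (subsample indices, then the k-means seed), so
runs are deterministic and resamples independent of each other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .datasets import ExpressionDataset, GeneSet, GeneSetCollection
from .scoring import gene_set_score, standardize_scores

log = logging.getLogger(__name__)

KMEANS_RESTARTS = 10
KMEANS_MAX_ITER = 300
KMEANS_TOL = 1e-6


@dataclass
class ConsensusResult:
    items: list[str]
    k: int
    consensus: np.ndarray       # M, symmetric, [0,1], diag 1
    cosample_counts: np.ndarray  # N_ij = times i and j drawn together
    assignments: pd.Series      # item -> cluster in 1..k
    resamples: int
    subsample_fraction: float
    seed: int

    def consensus_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.consensus, index=self.items, columns=self.items)


def _kmeans_labels(X: np.ndarray, k: int, random_state: int) -> np.ndarray:
    km = KMeans(
        n_clusters=k,
        n_init=KMEANS_RESTARTS,
        max_iter=KMEANS_MAX_ITER,
        tol=KMEANS_TOL,
        random_state=random_state,
    )
    return km.fit_predict(X)


def consensus_cluster(
    X: np.ndarray | pd.DataFrame,
    k: int,
    resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    item_ids: list[str] | None = None,
) -> ConsensusResult:
    """Consensus-cluster the rows of X (items x features) into k groups.

    Each resample draws ceil(f * n) items without replacement and k-means
    partitions them (Euclidean, k-means++ seeding, best of 10 restarts).
    M_ij = (# co-clustered) / (# co-sampled); pairs never co-sampled get
    M_ij = 0 with a warning (practically impossible at default settings).
    """
    if isinstance(X, pd.DataFrame):
        item_ids = item_ids or list(X.index.astype(str))
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if item_ids is None:
        item_ids = [str(i) for i in range(n)]
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n items; got k={k}, n={n}")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if resamples < 1:
        raise ValueError("resamples must be >= 1")

    m = math.ceil(subsample_fraction * n)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for r in range(resamples):
        rng = np.random.default_rng([seed, r])
        idx = np.sort(rng.choice(n, size=m, replace=False))
        km_seed = int(rng.integers(2**31))
        try:
            labels = _kmeans_labels(X[idx], k, km_seed)
        except Exception:  # degenerate subsample: re-seed once, then give up
            labels = _kmeans_labels(X[idx], k, km_seed + 1)
        block = np.ix_(idx, idx)
        co_sample[block] += 1.0
        co_cluster[block] += labels[:, None] == labels[None, :]

    never = co_sample == 0
    if never.any() and n > 1:
        off_diag_never = int(never.sum() - never.diagonal().sum())
        if off_diag_never:
            log.warning(
                "%d item pairs never co-sampled; their consensus set to 0 "
                "(increase resamples or subsample_fraction)",
                off_diag_never // 2,
            )
    with np.errstate(invalid="ignore"):
        M = np.where(never, 0.0, co_cluster / np.where(never, 1.0, co_sample))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)

    if k == 1 or n == 1:
        assign = np.ones(n, dtype=int)
    else:
        dist = 1.0 - M
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        assign = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(assign)) < k:
            log.warning(
                "average-linkage cut produced %d < k=%d groups", len(np.unique(assign)), k
            )
    return ConsensusResult(
        items=list(item_ids),
        k=k,
        consensus=M,
        cosample_counts=co_sample,
        assignments=pd.Series(assign, index=item_ids, name="cluster"),
        resamples=resamples,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def _center_scale_rows(X: pd.DataFrame) -> pd.DataFrame:
    """Center/scale each row (gene) across columns; zero-sd rows become 0."""
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        log.warning("%d zero-variance row(s) set to 0 before clustering", int(flat.sum()))
    sd = sd.replace(0, 1.0)
    return X.sub(mu, axis=0).div(sd, axis=0)


def assign_subtypes(
    ds: ExpressionDataset,
    collection: GeneSetCollection,
    resamples: int = 250,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    scale_genes: bool = True,
) -> tuple[pd.Series, ConsensusResult]:
    """Consensus-cluster samples on the union of signature genes, k = number
    of gene sets, then name each cluster after the gene set its members score
    highest on (one-to-one, greedy on score margins, ties by collection order).
    """
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    genes = [g for g in collection.gene_union() if g in ds.values.index]
    if not genes:
        raise ValueError("no signature genes present in dataset")
    if ds.n_samples < len(collection):
        raise ValueError(
            f"fewer samples ({ds.n_samples}) than gene sets ({len(collection)})"
        )
    X = ds.values.loc[genes]
    if scale_genes:
        X = _center_scale_rows(X)
    res = consensus_cluster(
        X.T, k=len(collection), resamples=resamples,
        subsample_fraction=subsample_fraction, seed=seed,
        item_ids=list(ds.values.columns),
    )

    # mean standardized score of each gene set within each cluster
    z = {}
    for gs in collection:
        z[gs.name] = standardize_scores(gene_set_score(ds, gs)).scores
    zdf = pd.DataFrame(z)  # samples x sets
    clusters = sorted(res.assignments.unique())
    mean_scores = zdf.groupby(res.assignments).mean()  # cluster x set

    set_order = {name: i for i, name in enumerate(collection.names)}
    cells = [
        (float(mean_scores.loc[c, s]), c, s)
        for c in clusters
        for s in collection.names
    ]
    # greedy: repeatedly take the best remaining (cluster, set) cell;
    # exact ties resolved by collection order, then cluster id
    cells.sort(key=lambda t: (-t[0], set_order[t[2]], t[1]))
    cluster_name: dict[int, str] = {}
    used_sets: set[str] = set()
    for _, c, s in cells:
        if c in cluster_name or s in used_sets:
            continue
        cluster_name[c] = s
        used_sets.add(s)
    labels = res.assignments.map(cluster_name)
    labels.name = "subtype"
    return labels, res


def decompose_signature(
    ds: ExpressionDataset,
    gene_set: GeneSet,
    k: int,
    resamples: int = 250,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    scale_genes: bool = True,
) -> tuple[pd.Series, pd.DataFrame, ConsensusResult]:
    """Gene-based consensus clustering of one signature.

    Items are the signature's genes (present in the dataset), features are
    samples.  Returns (gene -> cluster, per-cluster mean expression by
    tissue_type, full consensus result); the tissue profile lets callers
    label clusters (e.g. "ACC/pancreas-specific" vs "nonspecific").
    """
    genes = [g for g in gene_set.genes if g in ds.values.index]
    if len(genes) < k:
        raise ValueError(
            f"gene set {gene_set.name!r}: only {len(genes)} genes present, need >= k={k}"
        )
    X = ds.values.loc[genes]
    if scale_genes:
        X = _center_scale_rows(X)
    res = consensus_cluster(
        X, k=k, resamples=resamples, subsample_fraction=subsample_fraction,
        seed=seed, item_ids=genes,
    )
    labels = res.assignments.copy()
    labels.name = "gene_cluster"

    meta = ds.meta_aligned()
    if "tissue_type" in meta.columns and meta["tissue_type"].notna().any():
        groups = meta["tissue_type"]
        profile = (
            ds.values.loc[genes]
            .groupby(labels)
            .mean()
            .T.groupby(groups)
            .mean()
            .T
        )
    else:
        profile = ds.values.loc[genes].groupby(labels).mean().mean(axis=1).to_frame("all_samples")
    profile.index.name = "gene_cluster"
    return labels, profile, res
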