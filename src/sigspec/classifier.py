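"""Generic top-scoring-pairs (TSP) subtype classifier.

A TSP model is an ordered list of gene pairs; each pair votes for one class
when the first gene out-ranks the second WITHIN the sample.  Because every
comparison is internal to a sample, predictions need no cohort, no
normalization, and survive any strictly monotone transform of the
expression vector — the property that makes rank-based single-sample
classifiers attractive for clinical use on one patient at a time.

This is a self-contained majority-vote engine: pairs are selected greedily
by the between-class gap in P(expr_up > expr_down), each gene used at most
once, with no fitted per-pair weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset


@dataclass(frozen=True)
class TSPModel:
    """Pairs vote for ``classes[1]`` when expr(up) > expr(down); the sample
    is called ``classes[1]`` when the vote fraction exceeds ``threshold``."""

    pairs: tuple[tuple[str, str], ...]
    classes: tuple[str, str]  # (negative, positive)
    threshold: float = 0.5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        for up, down in self.pairs:
            if up == down:
                raise ValueError(f"pair uses the same gene twice: {up!r}")

    @property
    def genes(self) -> list[str]:
        out = []
        for up, down in self.pairs:
            out.extend([up, down])
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": [list(p) for p in self.pairs],
            "classes": list(self.classes),
            "threshold": self.threshold,
            "provenance": self.provenance,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TSPModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            pairs=tuple((up, down) for up, down in d["pairs"]),
            classes=tuple(d["classes"]),
            threshold=d["threshold"],
            provenance=d.get("provenance", {}),
        )


def train_tsp(ds: ExpressionDataset, labels: pd.Series, n_pairs: int = 8) -> TSPModel:
    """Select the top ``n_pairs`` gene pairs separating two classes.

    Each ordered pair (a, b) is scored by
    |P(expr_a > expr_b | class_pos) - P(expr_a > expr_b | class_neg)|
    (strict inequality; within-sample ties count as no event).  Pairs are
    taken greedily by descending margin with every gene used at most once;
    exact margin ties break lexicographically on (up, down) gene ids.
    Classes are ordered alphabetically: classes[1] (positive) is the
    later name.
    """
    if ds.scale != "log2":
        raise ValueError("train_tsp requires a log2-scaled dataset")
    labels = labels.reindex(ds.values.columns).dropna()
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    neg, pos = classes
    counts = labels.value_counts()
    if counts.min() < 5:
        raise ValueError(f"each class needs >= 5 samples, got {counts.to_dict()}")

    genes = np.array(ds.values.index)
    X = ds.values[labels.index].to_numpy()

    def greater_prob(cls: str) -> np.ndarray:
        cols = (labels == cls).to_numpy()
        acc = np.zeros((len(genes), len(genes)))
        for j in np.flatnonzero(cols):
            col = X[:, j]
            acc += col[:, None] > col[None, :]
        return acc / cols.sum()

    margin = greater_prob(pos) - greater_prob(neg)  # margin[a, b]
    np.fill_diagonal(margin, 0.0)

    # orient every unordered pair so that up > down votes for the positive
    # class, then rank by |margin|
    iu, ju = np.triu_indices(len(genes), k=1)
    m = margin[iu, ju]
    up_idx = np.where(m >= 0, iu, ju)
    down_idx = np.where(m >= 0, ju, iu)
    order = np.lexsort((genes[down_idx], genes[up_idx], -np.abs(m)))

    chosen: list[tuple[str, str]] = []
    used: set[str] = set()
    for t in order:
        a, b = genes[up_idx[t]], genes[down_idx[t]]
        if a in used or b in used:
            continue
        chosen.append((a, b))
        used.update((a, b))
        if len(chosen) == n_pairs:
            break
    if len(chosen) < n_pairs:
        raise ValueError(
            f"only {len(chosen)} admissible pairs available, requested {n_pairs}"
        )
    return TSPModel(
        pairs=tuple(chosen),
        classes=(neg, pos),
        provenance={
            "n_training_samples": int(len(labels)),
            "class_counts": {str(k): int(v) for k, v in counts.items()},
            "n_candidate_genes": int(len(genes)),
        },
    )


def predict_tsp(model: TSPModel, sample: pd.Series | dict) -> tuple[str, float]:
    """Classify one sample from its expression vector alone.

    vote_fraction = fraction of pairs with expr(up) > expr(down); exact
    within-pair ties count 0.5.  No cross-sample quantity enters, so the
    call is identical whether the sample arrives alone or inside a batch.
    """
    if isinstance(sample, dict):
        sample = pd.Series(sample)
    missing = [g for g in model.genes if g not in sample.index]
    if missing:
        raise ValueError(f"sample is missing model genes: {sorted(set(missing))}")
    votes = 0.0
    for up, down in model.pairs:
        a, b = float(sample[up]), float(sample[down])
        votes += 1.0 if a > b else (0.5 if a == b else 0.0)
    frac = votes / len(model.pairs)
    label = model.classes[1] if frac > model.threshold else model.classes[0]
    return label, frac


def predict_tsp_batch(model: TSPModel, ds: ExpressionDataset) -> pd.DataFrame:
    """Apply :func:`predict_tsp` independently to every column of a dataset."""
    rows = []
    for sid in ds.values.columns:
        label, frac = predict_tsp(model, ds.values[sid])
        rows.append({"sample_id": sid, "label": label, "vote_fraction": frac})
    return pd.DataFrame(rows).set_index("sample_id")
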