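"""Core containers and I/O for expression matrices, gene sets and sample metadata.

Orientation convention, used everywhere in this package: genes are rows,
samples are columns.  No operation transposes implicitly.

Expression values live on one of two scales: ``linear`` (non-negative counts
or intensities) or ``log2`` (log2(x + pseudocount); any real value).  All
scoring downstream requires log2-scaled data; :func:`to_log2` performs the
transform exactly once and records the pseudocount, refusing to double
transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TISSUE_TYPES = (
    "primary_tumor",
    "metastasis",
    "cell_line",
    "pdx",
    "caf",
    "normal_pancreas",
    "normal_other",
    "acc",
)

#: Metadata columns recognised by the analyses. ``purity`` is a fraction in
#: [0,1] (ABSOLUTE-style estimate or mean-VAF proxy; ``purity_source`` records
#: which). ``pair_id`` links matched samples (e.g. a primary tumor and the
#: cell line derived from it).
METADATA_COLUMNS = (
    "tissue_type",
    "histology_confirmed",
    "purity",
    "purity_source",
    "pair_id",
    "known_subtype",
)


class ParseError(ValueError):
    """Raised when a delimited input file violates the expected layout."""


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene identifiers (duplicate-free, non-empty)."""

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class GeneSetCollection:
    """Ordered, name-keyed collection of :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self._sets:
            raise ValueError(f"duplicate gene set name {gs.name!r}")
        self._sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def gene_union(self) -> list[str]:
        """Union of member genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for gs in self:
            for g in gs.genes:
                seen.setdefault(g)
        return list(seen)


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``metadata`` is indexed by sample id; it may cover a subset of samples but
    never extra ones.
    """

    values: pd.DataFrame
    scale: str = "linear"
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    log2_pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.scale == "linear":
            if (self.values.to_numpy() < 0).any():
                raise ValueError("linear-scale dataset contains negative values")
        else:
            if self.log2_pseudocount is None:
                raise ValueError("log2-scale dataset must record its pseudocount")
        if len(self.metadata):
            extra = self.metadata.index.difference(self.values.columns)
            if len(extra):
                raise ValueError(
                    f"metadata rows for unknown samples: {sorted(extra)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta_aligned(self) -> pd.DataFrame:
        """Metadata reindexed to the sample order (missing rows all-NA)."""
        return self.metadata.reindex(self.sample_ids)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionDataset":
        ids = list(sample_ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        meta = self.metadata.loc[self.metadata.index.intersection(ids)]
        return replace(self, values=self.values[ids].copy(), metadata=meta.copy())

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionDataset":
        ids = [g for g in gene_ids if g in self.values.index]
        return replace(self, values=self.values.loc[ids].copy())


def _infer_delimiter(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    scale: str = "linear",
    log2_pseudocount: float | None = None,
    metadata: pd.DataFrame | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table (first column gene ids, header = samples).

    ``scale`` defaults to linear; pass ``scale="log2"`` (with the pseudocount
    used) only when the file is already log2 transformed.
    """
    path = Path(path)
    delimiter = delimiter or _infer_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ParseError(f"{path}: duplicate gene ids: {dups}")
    non_numeric = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ParseError(
                    f"{path}: non-numeric value {bad.iloc[0]!r} "
                    f"at gene {bad.index[0]!r}, sample {col!r}"
                )
        df = df.astype(float)
    return ExpressionDataset(
        values=df.astype(float),
        scale=scale,
        metadata=metadata if metadata is not None else pd.DataFrame(),
        log2_pseudocount=log2_pseudocount,
    )


def write_expression(ds: ExpressionDataset, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    delimiter = delimiter or _infer_delimiter(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        ds.values.to_csv(fh, sep=delimiter, index_label="gene_id", lineterminator="\n")


_MISSING_TOKENS = {"", "NA", "NaN", "nan", "None"}


def read_metadata(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a sample metadata table; requires a ``sample_id`` column.

    Empty strings and "NA" become missing values (never empty strings).
    """
    path = Path(path)
    delimiter = delimiter or _infer_delimiter(path)
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False,
    )
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata requires a 'sample_id' column")
    df = df.replace({tok: pd.NA for tok in _MISSING_TOKENS})
    df = df.set_index("sample_id")
    if "purity" in df.columns:
        df["purity"] = pd.to_numeric(df["purity"], errors="raise")
        bad = df["purity"].dropna()
        out_of_range = bad[(bad < 0) | (bad > 1)]
        if len(out_of_range):
            raise ValueError(
                f"purity outside [0,1] for samples {list(out_of_range.index)}"
            )
    if "histology_confirmed" in df.columns:
        df["histology_confirmed"] = df["histology_confirmed"].map(
            {"True": True, "true": True, "False": False, "false": False, pd.NA: pd.NA},
            na_action="ignore",
        )
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    delimiter = delimiter or _infer_delimiter(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        meta.to_csv(fh, sep=delimiter, index_label="sample_id", na_rep="NA", lineterminator="\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name TAB description TAB gene...)."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                log.warning(
                    "gene set %r: removed %d duplicate gene(s)",
                    name, len(genes) - len(deduped),
                )
            coll.add(GeneSet(name=name, genes=tuple(deduped), source=desc))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.source, *gs.genes]) + "\n")


PredicateSpec = Mapping[str, object]


def filter_samples(ds: ExpressionDataset, predicate: PredicateSpec) -> ExpressionDataset:
    """Keep exactly the samples whose metadata satisfies every clause.

    A clause maps a metadata field to an accepted value, a list of accepted
    values, or a callable predicate over the field's values.  Samples with a
    missing value in a referenced field are dropped.  The input dataset is
    untouched.
    """
    meta = ds.meta_aligned()
    keep = pd.Series(True, index=meta.index)
    for field_name, accept in predicate.items():
        if field_name not in meta.columns:
            raise KeyError(
                f"unknown metadata field {field_name!r}; available: "
                f"{sorted(meta.columns)}"
            )
        col = meta[field_name]
        if callable(accept):
            clause = col.map(lambda v: bool(accept(v)) if pd.notna(v) else False)
        elif isinstance(accept, (list, tuple, set, frozenset)):
            clause = col.isin(list(accept)) & col.notna()
        else:
            clause = (col == accept) & col.notna()
        keep &= clause.astype(bool)
    kept = [s for s in ds.sample_ids if keep.get(s, False)]
    log.info("filter_samples: %d -> %d samples (%s)", ds.n_samples, len(kept), dict(predicate))
    return ds.subset_samples(kept)


def to_log2(ds: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """log2(x + pseudocount) transform of a linear-scale dataset.

    Refuses already-log2 input: the transform must never be applied twice.
    """
    if ds.scale == "log2":
        raise ValueError("dataset is already log2-scaled (no silent double transform)")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    vals = ds.values.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative values in linear-scale dataset")
    out = pd.DataFrame(
        np.log2(vals + pseudocount), index=ds.values.index, columns=ds.values.columns
    )
    return ExpressionDataset(
        values=out, scale="log2", metadata=ds.metadata.copy(), log2_pseudocount=pseudocount
    )
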