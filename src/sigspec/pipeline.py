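"""End-to-end specificity audit: configuration, stage orchestration,
report bundle and ordered-matrix export.

``run_audit`` chains the library stages — simulate/load, filter, log2,
score, purity correlation, compartment contrasts, paired retention,
(optional) consensus clustering and signature decomposition, verdicts —
and writes a bundle directory: ``report.json``, flat TSV tables, a config
echo, and a ``MANIFEST.json`` tracing every stage (operation, parameters,
outputs, status).  Runs are deterministic for a fixed config: every seed
comes from the config, never from the clock, and the report carries no
timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import consensus as consensus_mod
from .datasets import (
    ExpressionDataset,
    GeneSetCollection,
    filter_samples,
    read_expression,
    read_gmt,
    read_metadata,
    to_log2,
    write_gmt,
    write_metadata,
    write_expression,
)
from .scoring import ScoreVector, gene_set_score, score_panel
from .simulate import SimulationConfig, generate_cohort
from .specificity import (
    VerdictRules,
    compartment_panel,
    paired_retention,
    purity_correlation,
    signature_verdict,
)

log = logging.getLogger(__name__)

DEFAULT_CONTRASTS = [
    ["primary_tumor", "cell_line"],
    ["primary_tumor", "caf"],
    ["primary_tumor", "pdx"],
]


class AuditError(RuntimeError):
    """A pipeline stage failed; partial outputs were retained."""


@dataclass
class AuditResult:
    report: dict
    tables: dict[str, pd.DataFrame]
    manifest: list[dict]
    out_dir: Path | None = None


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return json.loads(json.dumps(config))  # deep copy, JSON-clean
    path = Path(config)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def _json_dump(obj: Any, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=index, na_rep="NA", lineterminator="\n")


def _load_inputs(
    cfg: dict, seed: int
) -> tuple[ExpressionDataset, GeneSetCollection, dict]:
    """Simulate a cohort or read the dataset trio named in the config."""
    if "simulate" in cfg:
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs.setdefault("seed", seed)
        sim_cfg = SimulationConfig(**sim_kwargs)
        ds, truth, sets = generate_cohort(sim_cfg)
        return ds, sets, {"source": "simulate", "config": asdict(sim_cfg)}
    data = cfg.get("data")
    if not data:
        raise ValueError("config needs either a 'simulate' or a 'data' block")
    for key in ("expression", "metadata", "gene_sets"):
        if key not in data:
            raise ValueError(f"data block missing {key!r}")
        if not Path(data[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {data[key]}")
    meta = read_metadata(data["metadata"])
    scale = data.get("scale", "linear")
    ds = read_expression(
        data["expression"],
        scale=scale,
        log2_pseudocount=data.get("pseudocount") if scale == "log2" else None,
        metadata=meta,
    )
    sets = read_gmt(data["gene_sets"])
    return ds, sets, {"source": "files", "paths": dict(data)}


def run_audit(config: str | Path | dict, out_dir: str | Path | None = None) -> AuditResult:
    """Run the full specificity audit described by ``config``.

    Raises :class:`AuditError` on the first failing stage after writing the
    partial bundle (when ``out_dir`` is given) with the failure recorded in
    MANIFEST.json.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    rules = VerdictRules(**(cfg.get("verdict_rules") or {}))
    contrasts = [tuple(c) for c in cfg.get("contrasts", DEFAULT_CONTRASTS)]
    retention_cfg = cfg.get("retention") or {
        "source_type": "primary_tumor",
        "derived_type": "cell_line",
    }
    purity_tissue = cfg.get("purity_tissue", "primary_tumor")

    manifest: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}
    report: dict[str, Any] = {
        "config": cfg,
        "seed": seed,
        "verdict_rules": asdict(rules),
        "gene_sets": {},
    }
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name: str, operation: str, params: dict, fn):
        entry = {"stage": name, "operation": operation, "params": params,
                 "outputs": [], "status": "pending"}
        manifest.append(entry)
        try:
            result = fn()
        except Exception as exc:
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            _finalize(out, report, tables, manifest, complete=False)
            raise AuditError(f"stage {name!r} failed: {exc}") from exc
        entry["status"] = "ok"
        return result, entry

    (ds, sets, load_info), e = stage(
        "load", "simulate/load", {"seed": seed}, lambda: _load_inputs(cfg, seed)
    )
    e["params"].update(load_info)

    if cfg.get("filter"):
        (ds,), e = stage(
            "filter", "filter_samples", {"predicate": cfg["filter"]},
            lambda: (filter_samples(ds, cfg["filter"]),),
        )
        e["params"]["n_samples_after"] = ds.n_samples

    if ds.scale == "linear":
        pc = float(cfg.get("pseudocount", 1.0))
        (ds,), _ = stage("log2", "to_log2", {"pseudocount": pc}, lambda: (to_log2(ds, pc),))

    def do_score():
        table, failures = score_panel(ds, sets, standardize=False)
        if failures:
            raise ValueError(f"unscorable gene sets: {failures}")
        return table

    score_table, e = stage("score", "score_panel", {"n_sets": len(sets)}, do_score)
    tables["scores"] = score_table
    e["outputs"].append("scores.tsv")

    meta = ds.meta_aligned()
    per_set: dict[str, dict[str, Any]] = {name: {} for name in sets.names}

    def do_purity():
        sub = filter_samples(ds, {"tissue_type": purity_tissue}) if "tissue_type" in meta.columns else ds
        rows = {}
        for gs in sets:
            sv = gene_set_score(sub, gs)
            try:
                res = purity_correlation(sv, sub.meta_aligned())
            except ValueError as exc:
                log.info("purity correlation skipped for %s: %s", gs.name, exc)
                continue
            rows[gs.name] = {
                "purity_rho": res.rho, "purity_p": res.p, "purity_n": res.n_used,
            }
        return rows

    purity_rows, e = stage(
        "purity", "purity_correlation", {"tissue": purity_tissue}, do_purity
    )
    for name, row in purity_rows.items():
        per_set[name].update(row)

    def do_contrasts():
        return compartment_panel(score_table, meta, contrasts)

    contrast_table, e = stage(
        "contrasts", "compartment_panel",
        {"contrasts": [list(c) for c in contrasts], "standardization_cohort": "all_samples"},
        do_contrasts,
    )
    tables["contrasts"] = contrast_table
    e["outputs"].append("contrasts.tsv")
    for _, row in contrast_table.iterrows():
        if row["group_a"] == "primary_tumor" and row["group_b"] == "cell_line":
            per_set[row["gene_set"]].update(
                primary_mean=float(row["mean_a"]),
                cellline_mean=float(row["mean_b"]),
                cellline_p=float(row["p"]),
            )

    def do_retention():
        rows = []
        for gs in sets:
            sv = gene_set_score(ds, gs)
            try:
                res = paired_retention(sv, meta, **retention_cfg)
            except ValueError as exc:
                log.info("paired retention skipped for %s: %s", gs.name, exc)
                continue
            rows.append(
                {
                    "gene_set": gs.name, "rho": res.rho, "p": res.p,
                    "n_pairs": res.n_pairs, "loss": res.loss,
                }
            )
            per_set[gs.name].update(paired_rho=res.rho, paired_loss=res.loss,
                                    n_pairs=res.n_pairs)
        return pd.DataFrame(rows)

    retention_table, e = stage(
        "retention", "paired_retention", dict(retention_cfg), do_retention
    )
    tables["retention"] = retention_table
    e["outputs"].append("retention.tsv")

    if cfg.get("cluster"):
        ccfg = dict(cfg["cluster"])
        ccfg.setdefault("seed", seed)

        def do_cluster():
            labels, res = consensus_mod.assign_subtypes(
                ds, sets,
                resamples=int(ccfg.get("resamples", 250)),
                seed=int(ccfg["seed"]),
            )
            return labels

        labels, e = stage("cluster", "assign_subtypes", ccfg, do_cluster)
        tables["assignments"] = labels.rename_axis("sample_id").reset_index()
        e["outputs"].append("assignments.tsv")

    if cfg.get("decompose"):
        dcfg = dict(cfg["decompose"])
        dcfg.setdefault("seed", seed)

        def do_decompose():
            gs = sets[dcfg["gene_set"]]
            labels, profile, _ = consensus_mod.decompose_signature(
                ds, gs, k=int(dcfg.get("k", 2)),
                resamples=int(dcfg.get("resamples", 250)),
                seed=int(dcfg["seed"]),
            )
            return labels, profile

        (dlabels, dprofile), e = stage("decompose", "decompose_signature", dcfg, do_decompose)
        tables["decomposition"] = dlabels.rename_axis("gene_id").reset_index()
        tables["decomposition_profile"] = dprofile.reset_index()
        e["outputs"] += ["decomposition.tsv", "decomposition_profile.tsv"]

    def do_verdicts():
        for name in sets.names:
            v = signature_verdict(per_set[name], rules)
            per_set[name]["verdict"] = v.verdict
            per_set[name]["rules_triggered"] = list(v.rules_triggered)
        return per_set

    verdicts, e = stage("verdict", "signature_verdict", asdict(rules), do_verdicts)
    report["gene_sets"] = verdicts
    e["outputs"].append("report.json")

    _finalize(out, report, tables, manifest, complete=True, ds=ds, sets=sets,
              write_expression_file=bool(cfg.get("write_expression", False)))
    return AuditResult(report=report, tables=tables, manifest=manifest, out_dir=out)


def _finalize(
    out: Path | None,
    report: dict,
    tables: dict[str, pd.DataFrame],
    manifest: list[dict],
    complete: bool,
    ds: ExpressionDataset | None = None,
    sets: GeneSetCollection | None = None,
    write_expression_file: bool = False,
) -> None:
    if out is None:
        return
    name_map = {
        "scores": "scores.tsv",
        "contrasts": "contrasts.tsv",
        "retention": "retention.tsv",
        "assignments": "assignments.tsv",
        "decomposition": "decomposition.tsv",
        "decomposition_profile": "decomposition_profile.tsv",
    }
    for key, df in tables.items():
        _write_tsv(df, out / name_map.get(key, f"{key}.tsv"))
    if ds is not None:
        write_metadata(ds.metadata, out / "metadata.tsv")
        if write_expression_file:
            write_expression(ds, out / "expression.tsv")
    if sets is not None:
        write_gmt(sets, out / "gene_sets.gmt")
    if complete:
        _json_dump(report, out / "report.json")
    _json_dump(report.get("config", {}), out / "config_echo.json")
    _json_dump({"complete": complete, "stages": manifest}, out / "MANIFEST.json")


def export_ordered_matrix(
    ds: ExpressionDataset,
    path: str | Path,
    row_order: list[str] | pd.Series | None = None,
    col_order: list[str] | pd.Series | None = None,
) -> None:
    """Write the expression matrix with rows/columns permuted for heatmapping.

    An order spec is either an explicit id list (a permutation of the axis)
    or a Series keyed by id — e.g. a score vector or consensus assignments —
    sorted ascending with ties broken by id (so equal assignment values form
    contiguous blocks).  A sidecar ``<path>.order.json`` records both orders.
    """
    path = Path(path)

    def resolve(spec, ids: list[str], axis: str) -> list[str]:
        if spec is None:
            return ids
        if isinstance(spec, pd.Series):
            missing = set(ids) - set(spec.index)
            if missing:
                raise KeyError(f"{axis} ordering lacks ids: {sorted(missing)[:5]}")
            s = spec.reindex(ids)
            return sorted(ids, key=lambda i: (s[i], i))
        spec = list(spec)
        if sorted(spec) != sorted(ids):
            raise KeyError(f"{axis} ordering is not a permutation of the {axis} ids")
        return spec

    rows = resolve(row_order, ds.gene_ids, "row")
    cols = resolve(col_order, ds.sample_ids, "column")
    ordered = ds.values.loc[rows, cols]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        ordered.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")
    _json_dump({"rows": rows, "columns": cols}, Path(str(path) + ".order.json"))
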