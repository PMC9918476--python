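"""Synthetic bulk-expression cohorts with known purity and compartment structure.

The generator emulates the essential structure of curated pancreatic-cancer
expression cohorts: bulk primary tumors are mixtures of a neoplastic
compartment (basal-like or classical subtype) with non-neoplastic acinar,
immune and fibroblast (CAF) compartments, weighted by tumor purity.  Pure
model systems (cell lines, PDXs, CAF cultures), normal pancreas, metastases
with non-pancreas contamination, and rare high-purity acinar cell carcinomas
(ACC) round out the cohort.  Every sample carries full ground truth, so
downstream statistics can be tested as parameter-recovery problems.

Mixture model (per sample i, per gene g, linear scale):

    x_ig = p_i * T(s_i)_g + sum_c w_ci * C(c)_g

where p_i is neoplastic purity, T(s) the tumor profile for subtype s, C(c)
the profile of non-tumor compartment c, and p_i + sum_c w_ci = 1 exactly.
Every profile equals a shared housekeeping baseline except on the gene block
it elevates, where it is baseline * 2**delta.  Each tumor additionally
carries a program intensity t in (0,1] (Beta-distributed) scaling its
neoplastic elevation to baseline * (1 + t*(2**delta - 1)); a primary and
the model systems derived from it share t, so paired samples track each
other's signature levels continuously, not just by subtype.  The observed
value is
log2(x + 1) plus Gaussian noise (sd ``noise_sd``) on the log2 scale, i.e.
multiplicative noise on the linear scale.

Gene blocks: ``basal`` and ``classical`` (subtype-specific tumor genes),
``tumor_shared`` (elevated in both subtypes — its score rises with purity),
``acinar``, ``immune``, ``caf`` (compartment markers whose bulk scores fall
with purity), and ``background`` (never elevated).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .datasets import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_metadata,
)

BLOCKS = ("basal", "classical", "tumor_shared", "acinar", "immune", "caf", "background")

#: Non-tumor compartments carrying contamination weight.  ``normal_other`` is
#: a flat (baseline-only) non-pancreas normal profile used for metastasis
#: contamination.
CONTAMINATION_COMPARTMENTS = ("acinar", "immune", "caf", "normal_other")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``delta`` is the log2 elevation of a block over baseline in the
    compartment that expresses it; ``noise_sd`` is the per-gene Gaussian sd on
    the log2 scale.  Primary-tumor purity is Beta(purity_alpha, purity_beta),
    right-shifted to mimic resected-tumor cellularity.
    """

    n_primary: int = 150
    n_cell_line: int = 30
    n_pdx: int = 12
    n_caf: int = 10
    n_normal_pancreas: int = 12
    n_acc: int = 6
    n_metastasis: int = 24
    purity_alpha: float = 5.0
    purity_beta: float = 3.0
    subtype_fraction_basal: float = 0.5
    block_size: int = 40
    n_background: int = 220
    delta: float = 1.5
    noise_sd: float = 0.4
    paired_fraction: float = 0.8
    baseline: float = 100.0
    pdx_caf_weight: float = 0.05
    immunogenic_classical_fraction: float = 0.13
    adex_background_genes: int = 15
    contamination_dirichlet: tuple[float, float, float] = (2.0, 2.0, 2.0)
    acc_purity_alpha: float = 8.0
    acc_purity_beta: float = 2.0
    intensity_alpha: float = 5.0
    intensity_beta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_primary, self.n_cell_line, self.n_pdx, self.n_caf,
            self.n_normal_pancreas, self.n_acc, self.n_metastasis,
        )
        if any(c < 0 for c in counts):
            raise ValueError("sample counts must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.subtype_fraction_basal <= 1:
            raise ValueError("subtype_fraction_basal must be in [0,1]")
        if not 0 <= self.paired_fraction <= 1:
            raise ValueError("paired_fraction must be in [0,1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort.

    ``samples`` is indexed by sample_id with columns: tissue_type, purity,
    subtype, pair_id and one ``w_<compartment>`` column per contamination
    compartment (purity + weights sum to 1 for every sample).
    ``gene_blocks`` maps gene id -> block label.
    """

    samples: pd.DataFrame
    gene_blocks: pd.Series
    config: SimulationConfig

    def block_genes(self, block: str) -> list[str]:
        if block not in BLOCKS:
            raise KeyError(f"unknown block {block!r}; known: {BLOCKS}")
        return list(self.gene_blocks.index[self.gene_blocks == block])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "samples": self.samples.reset_index().to_dict(orient="records"),
            "gene_blocks": self.gene_blocks.to_dict(),
            "note": (
                "Synthetic ground truth. Compartment weights are plausibility "
                "choices of the generator, not estimates from real tumors."
            ),
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
            fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _gene_universe(cfg: SimulationConfig) -> pd.Series:
    """Gene ids and block labels: one contiguous block per signature, then background."""
    labels: list[str] = []
    for block in ("basal", "classical", "tumor_shared", "acinar", "immune", "caf"):
        labels.extend([block] * cfg.block_size)
    labels.extend(["background"] * cfg.n_background)
    ids = [f"G{i:04d}" for i in range(len(labels))]
    return pd.Series(labels, index=pd.Index(ids, name="gene_id"), name="block")


#: Which blocks each expression profile elevates.
_PROFILE_BLOCKS = {
    "tumor_basal": ("basal", "tumor_shared"),
    "tumor_classical": ("classical", "tumor_shared"),
    "tumor_acinar_like": ("acinar",),  # ACC neoplastic profile
    "acinar": ("acinar",),
    "immune": ("immune",),
    "caf": ("caf",),
    "normal_other": (),
}


def compartment_profiles(cfg: SimulationConfig, gene_blocks: pd.Series) -> pd.DataFrame:
    """Linear-scale mean profiles (genes x profiles); baseline everywhere
    except elevated blocks at baseline * 2**delta."""
    elev = cfg.baseline * 2.0 ** cfg.delta
    out = {}
    for prof, blocks in _PROFILE_BLOCKS.items():
        v = np.full(len(gene_blocks), cfg.baseline)
        for b in blocks:
            v[(gene_blocks == b).to_numpy()] = elev
        out[prof] = v
    return pd.DataFrame(out, index=gene_blocks.index)


def _sample_plan(cfg: SimulationConfig) -> list[tuple[str, str]]:
    """Fixed sample order: (sample_id, tissue_type). Primaries come first so
    that later additions never perturb their substreams."""
    plan = []
    for i in range(cfg.n_primary):
        plan.append((f"PT{i:03d}", "primary_tumor"))
    for i in range(cfg.n_cell_line):
        plan.append((f"CL{i:03d}", "cell_line"))
    for i in range(cfg.n_pdx):
        plan.append((f"PDX{i:03d}", "pdx"))
    for i in range(cfg.n_caf):
        plan.append((f"CAF{i:03d}", "caf"))
    for i in range(cfg.n_normal_pancreas):
        plan.append((f"NP{i:03d}", "normal_pancreas"))
    for i in range(cfg.n_acc):
        plan.append((f"ACC{i:03d}", "acc"))
    for i in range(cfg.n_metastasis):
        plan.append((f"MET{i:03d}", "metastasis"))
    return plan


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionDataset, SyntheticTruth, GeneSetCollection]:
    """Simulate a cohort; returns (log2 dataset, ground truth, gene sets).

    Deterministic for a fixed config: each sample draws from its own
    counter-based substream of the master seed, so extending the cohort never
    changes earlier samples.
    """
    gene_blocks = _gene_universe(cfg)
    if cfg.adex_background_genes > cfg.n_background:
        raise ValueError("adex_background_genes exceeds available background genes")
    profiles = compartment_profiles(cfg, gene_blocks)
    plan = _sample_plan(cfg)
    if not plan:
        raise ValueError("all-zero cohort: no samples requested")

    dir_alpha = np.asarray(cfg.contamination_dirichlet, dtype=float)
    n_paired_cl = round(cfg.paired_fraction * cfg.n_cell_line)
    n_paired_met = round(cfg.paired_fraction * cfg.n_metastasis)

    rows = []
    expr = np.empty((len(gene_blocks), len(plan)))
    primary_subtypes: list[str] = []
    primary_intensities: list[float] = []
    baseline_vec = np.full(len(gene_blocks), cfg.baseline)

    for j, (sid, ttype) in enumerate(plan):
        rng = np.random.default_rng([cfg.seed, j])
        subtype = None
        pair_id = None
        purity = 0.0
        intensity = np.nan
        w = dict.fromkeys(CONTAMINATION_COMPARTMENTS, 0.0)
        tumor_profile = None

        def draw_subtype():
            return "basal" if rng.random() < cfg.subtype_fraction_basal else "classical"

        def draw_intensity() -> float:
            return float(rng.beta(cfg.intensity_alpha, cfg.intensity_beta))

        if ttype == "primary_tumor":
            purity = float(rng.beta(cfg.purity_alpha, cfg.purity_beta))
            subtype = draw_subtype()
            intensity = draw_intensity()
            d = rng.dirichlet(dir_alpha)
            w["acinar"], w["immune"], w["caf"] = ((1.0 - purity) * d).tolist()
            tumor_profile = f"tumor_{subtype}"
            primary_subtypes.append(subtype)
            primary_intensities.append(intensity)
        elif ttype == "cell_line":
            idx = int(sid[2:])
            purity = 1.0
            if idx < n_paired_cl and idx < cfg.n_primary:
                subtype = primary_subtypes[idx]
                intensity = primary_intensities[idx]
                pair_id = f"pairCL{idx:03d}"
            else:
                subtype = draw_subtype()
                intensity = draw_intensity()
            tumor_profile = f"tumor_{subtype}"
        elif ttype == "pdx":
            purity = 1.0 - cfg.pdx_caf_weight
            w["caf"] = cfg.pdx_caf_weight
            subtype = draw_subtype()
            intensity = draw_intensity()
            tumor_profile = f"tumor_{subtype}"
        elif ttype == "caf":
            w["caf"] = 1.0
        elif ttype == "normal_pancreas":
            w["acinar"], w["immune"], w["caf"] = 0.8, 0.1, 0.1
        elif ttype == "acc":
            purity = float(rng.beta(cfg.acc_purity_alpha, cfg.acc_purity_beta))
            intensity = draw_intensity()
            d = rng.dirichlet(dir_alpha)
            w["acinar"], w["immune"], w["caf"] = ((1.0 - purity) * d).tolist()
            tumor_profile = "tumor_acinar_like"
        elif ttype == "metastasis":
            idx = int(sid[3:])
            purity = float(rng.beta(cfg.purity_alpha, cfg.purity_beta))
            d = rng.dirichlet(np.array([2.0, 2.0]))
            w["immune"], w["normal_other"] = ((1.0 - purity) * d).tolist()
            # metastases pair with primaries not already claimed by cell lines
            src = idx + n_paired_cl
            if idx < n_paired_met and src < cfg.n_primary:
                subtype = primary_subtypes[src]
                intensity = primary_intensities[src]
                pair_id = f"pairMET{idx:03d}"
            else:
                subtype = draw_subtype()
                intensity = draw_intensity()
            tumor_profile = f"tumor_{subtype}"

        linear = np.zeros(len(gene_blocks))
        if purity > 0:
            # neoplastic elevation scaled by the tumor program intensity
            prof = profiles[tumor_profile].to_numpy()
            linear += purity * (baseline_vec + intensity * (prof - baseline_vec))
        for comp, weight in w.items():
            if weight > 0:
                linear += weight * profiles[comp].to_numpy()
        log2_vals = np.log2(linear + 1.0)
        if cfg.noise_sd > 0:
            log2_vals = log2_vals + rng.normal(0.0, cfg.noise_sd, size=len(gene_blocks))
        expr[:, j] = log2_vals

        rows.append(
            {
                "sample_id": sid,
                "tissue_type": ttype,
                "purity": purity,
                "subtype": subtype,
                "tumor_intensity": intensity,
                "pair_id": pair_id,
                **{f"w_{c}": w[c] for c in CONTAMINATION_COMPARTMENTS},
            }
        )

    truth_df = pd.DataFrame(rows).set_index("sample_id")
    # primaries that seeded a paired cell line / metastasis share its pair_id
    for idx in range(min(n_paired_cl, cfg.n_primary, cfg.n_cell_line)):
        truth_df.loc[f"PT{idx:03d}", "pair_id"] = f"pairCL{idx:03d}"
    for idx in range(min(n_paired_met, cfg.n_metastasis)):
        src = idx + n_paired_cl
        if src < cfg.n_primary:
            truth_df.loc[f"PT{src:03d}", "pair_id"] = f"pairMET{idx:03d}"

    metadata = pd.DataFrame(
        {
            "tissue_type": truth_df["tissue_type"],
            "histology_confirmed": truth_df["tissue_type"].map(
                lambda t: True if t in ("primary_tumor", "metastasis", "cell_line", "pdx")
                else (False if t == "acc" else pd.NA)
            ),
            "purity": truth_df["purity"].where(
                truth_df["tissue_type"].isin(
                    ["primary_tumor", "metastasis", "acc", "cell_line", "pdx"]
                )
            ),
            "purity_source": "simulated_truth",
            "pair_id": truth_df["pair_id"],
            "known_subtype": truth_df["subtype"],
        }
    )

    values = pd.DataFrame(expr, index=gene_blocks.index, columns=truth_df.index)
    dataset = ExpressionDataset(
        values=values, scale="log2", metadata=metadata, log2_pseudocount=1.0
    )
    truth = SyntheticTruth(samples=truth_df, gene_blocks=gene_blocks, config=cfg)
    return dataset, truth, simulated_gene_sets(cfg, gene_blocks)


def simulated_gene_sets(cfg: SimulationConfig, gene_blocks: pd.Series) -> GeneSetCollection:
    """Signature lists anchored in the compartment blocks.

    ``sim_ADEX-like`` adds a handful of background genes to the acinar block
    (a nonspecific tail), and ``sim_immunogenic`` folds ~13% tumor-classical
    genes into the immune block — both deliberate impurities mirroring how
    published exocrine-like and immunogenic lists mix compartments.
    """
    def block(b: str) -> list[str]:
        return list(gene_blocks.index[gene_blocks == b])

    background = block("background")
    n_cls = round(
        cfg.immunogenic_classical_fraction
        / max(1e-12, 1.0 - cfg.immunogenic_classical_fraction)
        * cfg.block_size
    )
    n_cls = min(n_cls, cfg.block_size)
    coll = GeneSetCollection()
    coll.add(GeneSet("sim_basal", tuple(block("basal")), "tumor basal-like block"))
    coll.add(GeneSet("sim_classical", tuple(block("classical")), "tumor classical block"))
    coll.add(GeneSet("sim_tumor_shared", tuple(block("tumor_shared")), "pan-tumor block"))
    coll.add(
        GeneSet(
            "sim_ADEX-like",
            tuple(block("acinar") + background[: cfg.adex_background_genes]),
            "acinar block plus nonspecific background tail",
        )
    )
    coll.add(
        GeneSet(
            "sim_immunogenic",
            tuple(block("immune") + block("classical")[:n_cls]),
            "immune block contaminated with tumor-classical genes",
        )
    )
    coll.add(GeneSet("sim_caf", tuple(block("caf")), "fibroblast block"))
    coll.add(
        GeneSet(
            "sim_housekeeping",
            tuple(background[cfg.adex_background_genes : cfg.adex_background_genes + cfg.block_size]),
            "background genes, never elevated",
        )
    )
    return coll


def expected_score_slope(cfg: SimulationConfig, block: str, n_grid: int = 4000) -> float:
    """Analytic expected regression slope of a block's gene-set score on
    purity, over primary tumors.

    Noise is mean-zero additive on the log2 scale, so the conditional mean
    score given (purity, contamination split) is closed-form; the slope
    Cov(score, p)/Var(p) is evaluated by deterministic Beta-quantile-grid
    integration.  Contamination blocks come out negative, tumor_shared
    positive, subtype blocks positive scaled by the subtype mix, background
    zero.
    """
    if block not in BLOCKS:
        raise KeyError(f"unknown block {block!r}; known: {BLOCKS}")
    b = cfg.baseline
    kappa = 2.0 ** cfg.delta - 1.0
    q = (np.arange(n_grid) + 0.5) / n_grid
    p = beta_dist.ppf(q, cfg.purity_alpha, cfg.purity_beta)

    if block == "background":
        return 0.0
    if block in ("tumor_shared", "basal", "classical"):
        # elevation scaled by the tumor program intensity t ~ Beta
        m = max(256, n_grid // 8)
        qt = (np.arange(m) + 0.5) / m
        t_grid = beta_dist.ppf(qt, cfg.intensity_alpha, cfg.intensity_beta)
        elevated = np.log2(1.0 + b * (1.0 + kappa * p[:, None] * t_grid[None, :])).mean(axis=1)
        if block == "tumor_shared":
            score = elevated
        else:
            phi = (
                cfg.subtype_fraction_basal
                if block == "basal"
                else 1.0 - cfg.subtype_fraction_basal
            )
            score = phi * elevated + (1.0 - phi) * np.log2(1.0 + b)
    else:
        # contamination block: weight w = (1-p) * d, d ~ marginal Beta of the
        # Dirichlet split (acinar/immune/caf); normal_other never elevates.
        alpha = np.asarray(cfg.contamination_dirichlet, dtype=float)
        comp_index = {"acinar": 0, "immune": 1, "caf": 2}[block]
        a_c = alpha[comp_index]
        a_rest = alpha.sum() - a_c
        m = max(256, n_grid // 8)
        qd = (np.arange(m) + 0.5) / m
        d = beta_dist.ppf(qd, a_c, a_rest)
        wgrid = (1.0 - p)[:, None] * d[None, :]
        score = np.log2(1.0 + b * (1.0 + kappa * wgrid)).mean(axis=1)

    p_mean = p.mean()
    return float(((score - score.mean()) * (p - p_mean)).sum() / ((p - p_mean) ** 2).sum())


def write_cohort(
    out_dir: str | Path,
    dataset: ExpressionDataset,
    truth: SyntheticTruth,
    gene_sets: GeneSetCollection,
) -> dict[str, str]:
    """Write the standard trio (expression TSV, metadata TSV, GMT) + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "gene_sets": str(out / "gene_sets.gmt"),
        "truth": str(out / "truth.json"),
    }
    write_expression(dataset, paths["expression"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_gmt(gene_sets, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths
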