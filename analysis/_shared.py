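"""Shared helpers for the analysis drivers: cohort location and loading."""

from pathlib import Path

from sigspec.datasets import read_expression, read_gmt, read_metadata
from sigspec.simulate import SimulationConfig, generate_cohort, write_cohort

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"
SEED = 0


def load_or_generate_cohort():
    """Reuse the cohort written by 01_simulate_cohort.py, else generate it.

    Returns (dataset, truth, gene_sets); truth is None when loading from
    disk is enough (the drivers that need ground truth regenerate)."""
    cfg = SimulationConfig(seed=SEED)
    if (COHORT_DIR / "expression.tsv").exists():
        meta = read_metadata(COHORT_DIR / "metadata.tsv")
        ds = read_expression(
            COHORT_DIR / "expression.tsv", scale="log2", log2_pseudocount=1.0,
            metadata=meta,
        )
        sets = read_gmt(COHORT_DIR / "gene_sets.gmt")
        _, truth, _ = generate_cohort(cfg)  # cheap; keeps ground truth in hand
        return ds, truth, sets
    ds, truth, sets = generate_cohort(cfg)
    write_cohort(COHORT_DIR, ds, truth, sets)
    return ds, truth, sets
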