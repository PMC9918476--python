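"""Follow each signature from bulk primaries into pure compartments.

Two complementary views:
  * compartment contrasts — standardized score of primaries vs cell lines,
    CAFs and PDXs (two-sided rank-sum test per contrast);
  * paired retention — Spearman correlation and standardized loss across
    primary/cell-line and primary/metastasis pairs.
Tumor-intrinsic signatures survive the move into pure model systems;
contamination signatures collapse (negative loss, no pair correlation).
"""

import pandas as pd
from _shared import RESULTS, load_or_generate_cohort

from sigspec.scoring import gene_set_score, score_panel
from sigspec.specificity import compartment_panel, paired_retention


def main() -> None:
    ds, _, sets = load_or_generate_cohort()
    meta = ds.meta_aligned()
    table, _ = score_panel(ds, sets)
    contrasts = [
        ("primary_tumor", "cell_line"),
        ("primary_tumor", "caf"),
        ("primary_tumor", "pdx"),
        ("primary_tumor", "normal_pancreas"),
    ]
    panel = compartment_panel(table, meta, contrasts)
    RESULTS.mkdir(parents=True, exist_ok=True)
    panel.to_csv(RESULTS / "compartment_contrasts.tsv", sep="\t", index=False)

    rows = []
    for gs in sets:
        sv = gene_set_score(ds, gs)
        for derived in ("cell_line", "metastasis"):
            try:
                res = paired_retention(sv, meta, derived_type=derived)
            except ValueError:
                continue
            rows.append(
                {
                    "gene_set": gs.name, "derived_type": derived,
                    "rho": res.rho, "p": res.p,
                    "loss": res.loss, "n_pairs": res.n_pairs,
                }
            )
    ret = pd.DataFrame(rows)
    ret.to_csv(RESULTS / "paired_retention.tsv", sep="\t", index=False)

    cl = ret[ret.derived_type == "cell_line"].set_index("gene_set")
    lost = cl[cl.loss < 0].index.tolist()
    kept = cl[cl.loss >= 0].index.tolist()
    print(ret.to_string(index=False))
    print(f"\nlost in cell lines (negative standardized loss): {lost}")
    print(f"retained in cell lines: {kept}")


if __name__ == "__main__":
    main()
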