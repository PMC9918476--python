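"""Score every signature (mean log2 expression) and summarize cross-tissue
robustness.

Writes the long-format score table and the robustness panel (per-set size,
coverage, and spread of tissue-wise mean standardized scores).  A large
spread across non-tumor tissues is the first hint a signature is reading a
non-neoplastic compartment.
"""

from _shared import RESULTS, load_or_generate_cohort

from sigspec.scoring import score_panel
from sigspec.specificity import signature_robustness_panel


def main() -> None:
    ds, _, sets = load_or_generate_cohort()
    table, failures = score_panel(ds, sets)
    assert not failures, failures
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "scores.tsv", sep="\t", index=False)

    robust = signature_robustness_panel(sets, ds)
    robust.to_csv(RESULTS / "robustness_panel.tsv", sep="\t", index=False)
    print(f"scored {len(sets)} signatures on {ds.n_samples} samples")
    print(robust[["gene_set", "size", "spread"]].to_string(index=False))
    ranked = robust.sort_values("spread", ascending=False)
    print(
        f"widest cross-tissue swing: {ranked.iloc[0]['gene_set']} "
        f"(spread {ranked.iloc[0]['spread']:.2f}); "
        f"flattest: {ranked.iloc[-1]['gene_set']} ({ranked.iloc[-1]['spread']:.2f})"
    )


if __name__ == "__main__":
    main()
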