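"""Simulate the default synthetic cohort and write it under results/cohort/.

The cohort mimics a curated pancreatic-cancer compendium: 150 bulk primary
tumors with Beta(5,3) neoplastic purity, 30 cell lines and 24 metastases
(80% paired to primaries), 12 PDXs, 10 CAF cultures, 12 normal pancreata
and 6 high-purity acinar cell carcinomas, over 460 genes organised in
compartment blocks.  Alongside the expression/metadata/GMT trio it stores
the full ground truth (purity, subtype, compartment weights, gene blocks).
"""

from _shared import COHORT_DIR, SEED

from sigspec.simulate import SimulationConfig, generate_cohort, write_cohort


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    ds, truth, sets = generate_cohort(cfg)
    paths = write_cohort(COHORT_DIR, ds, truth, sets)
    counts = truth.samples["tissue_type"].value_counts().to_dict()
    print(f"simulated {ds.n_genes} genes x {ds.n_samples} samples (seed {SEED})")
    print(f"tissue composition: {counts}")
    print(f"gene sets: {', '.join(s.name for s in sets)}")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
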