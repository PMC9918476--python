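"""Train and stress-test the single-sample top-scoring-pairs classifier.

Train on one simulated cohort's primaries (true subtype labels), evaluate
on a fresh cohort, and chart accuracy as purity falls — the practical
question for biopsy-grade material.  The fitted model (gene pairs +
orientation) is serialized for the `sigspec classify` CLI.
"""

import pandas as pd
from _shared import RESULTS

from sigspec.classifier import predict_tsp_batch, train_tsp
from sigspec.datasets import filter_samples
from sigspec.simulate import SimulationConfig, generate_cohort


def main() -> None:
    train_ds, train_truth, _ = generate_cohort(SimulationConfig(seed=100))
    prim = filter_samples(train_ds, {"tissue_type": "primary_tumor"})
    labels = train_truth.samples.loc[prim.sample_ids, "subtype"]
    model = train_tsp(prim, labels, n_pairs=8)

    out = RESULTS / "classifier"
    out.mkdir(parents=True, exist_ok=True)
    model.to_json(out / "tsp_model.json")

    def purity_curve(sim_cfg):
        ds, truth, _ = generate_cohort(sim_cfg)
        tprim = filter_samples(ds, {"tissue_type": "primary_tumor"})
        pred = predict_tsp_batch(model, tprim)
        lab = truth.samples.loc[tprim.sample_ids, "subtype"]
        purity = truth.samples.loc[tprim.sample_ids, "purity"]
        rows = []
        for lo, hi in [(0.0, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.001)]:
            m = (purity >= lo) & (purity < hi)
            if m.sum() == 0:
                continue
            acc = (pred.loc[m.index[m], "label"] == lab[m]).mean()
            rows.append({"purity_bin": f"[{lo:.1f},{hi:.1f})", "n": int(m.sum()),
                         "accuracy": float(acc)})
        return (pred["label"] == lab).mean(), pd.DataFrame(rows)

    overall, curve = purity_curve(SimulationConfig(seed=101))
    curve.to_csv(out / "accuracy_by_purity.tsv", sep="\t", index=False)
    # stressed condition: weaker subtype program, noisier measurements
    _, stressed = purity_curve(
        SimulationConfig(seed=102, n_primary=400, delta=0.8, noise_sd=0.8)
    )
    stressed.to_csv(out / "accuracy_by_purity_stressed.tsv", sep="\t", index=False)

    print(f"model: {len(model.pairs)} pairs, classes {model.classes}")
    print(f"held-out accuracy (all primaries, default conditions): {overall:.3f}")
    print(curve.to_string(index=False))
    print("\nstressed condition (delta=0.8, noise_sd=0.8, n=400):")
    print(stressed.to_string(index=False))
    print("the calls are rank-based and cohort-free; under default "
          "conditions they are near-perfect at every purity, and only under "
          "a weakened, noisier subtype program does dilution visibly erode "
          "the within-sample gene-pair orderings the votes rely on.")


if __name__ == "__main__":
    main()
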