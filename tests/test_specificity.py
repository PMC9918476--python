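"""Rank statistics and the specificity analyses built on them."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from sigspec.datasets import GeneSet, GeneSetCollection, filter_samples
from sigspec.scoring import ScoreVector, gene_set_score, score_panel
from sigspec.specificity import (
    VerdictRules,
    compartment_panel,
    gene_list_overlap,
    label_concordance,
    paired_retention,
    purity_correlation,
    rank_sum_test,
    signature_robustness_panel,
    signature_verdict,
    spearman,
)


def brute_force_ranksum_p(a, b):
    """Independent enumeration oracle over all rank splits (average ranks)."""
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    na, n = len(a), len(combined)
    w_obs = ranks[:na].sum()
    mean_w = na * (n + 1) / 2.0
    hits = total = 0
    for pos in itertools.combinations(range(n), na):
        total += 1
        if abs(ranks[list(pos)].sum() - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            hits += 1
    return hits / total


class TestSpearman:
    def test_monotone_and_antitone(self):
        up = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert up.rho == 1.0 and up.p == 0.0 and up.degenerate
        down = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert down.rho == -1.0 and down.p == 0.0

    def test_tied_fixture_matches_manual_rank_table(self):
        # x=(1,2,2,3) -> ranks (1, 2.5, 2.5, 4); y=(3,1,2,2) -> (4, 1, 2.5, 2.5)
        res = spearman([1, 2, 2, 3], [3, 1, 2, 2])
        manual = np.corrcoef([1, 2.5, 2.5, 4], [4, 1, 2.5, 2.5])[0, 1]
        assert res.rho == pytest.approx(manual, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        x = rng.integers(0, 8, n).astype(float)  # ties likely
        y = rng.normal(size=n)
        if np.ptp(x) == 0:
            x[0] += 1
        ours = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_missing_pairs_dropped(self):
        res = spearman([1, 2, np.nan, 4, 5], [5, 4, 3, np.nan, 1])
        assert res.n_used == 3

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match=">= 3"):
            spearman([1, 2], [2, 1])

    @given(
        st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=4, max_size=25,
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_and_monotone_invariance(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        a = spearman(x, y)
        b = spearman(y, x)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        # strictly monotone (and fp-exact) transform of x leaves rho unchanged
        c = spearman(2.0 * x, y)
        assert a.rho == pytest.approx(c.rho, abs=1e-12)


class TestRankSum:
    def test_textbook_exact_case(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        res = rank_sum_test([1.0, 2.0], [1.0, 2.0])
        assert res.p == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=8)
        assert rank_sum_test(a, b).p == pytest.approx(rank_sum_test(b, a).p, abs=1e-12)

    @pytest.mark.parametrize("na,nb", [(1, 3), (2, 2), (3, 5), (5, 5), (7, 4), (9, 9)])
    def test_exact_path_matches_scipy_exact(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        res = rank_sum_test(a, b)
        assert res.method == "exact"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_path_matches_brute_force_with_small_groups(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=int(rng.integers(2, 7)))
            b = rng.normal(size=int(rng.integers(2, 7)))
            res = rank_sum_test(a, b)
            assert res.p == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    def test_exact_path_used_with_ties(self):
        """Tied data still enumerates (permutation test over average ranks)."""
        rng = np.random.default_rng(7)
        a = rng.integers(0, 4, 7).astype(float)
        b = rng.integers(0, 4, 6).astype(float)
        res = rank_sum_test(a, b)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_approx_close_to_enumeration(self, seed):
        """Just above the exact cutoff, the tie/continuity-corrected normal
        approximation stays within 10% of full enumeration."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 11)
        b = rng.normal(0.5, 1, 9)
        res = rank_sum_test(a, b)
        assert res.method == "normal"
        assert res.p == pytest.approx(brute_force_ranksum_p(a, b), rel=0.10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1, 2, 3])


class TestPurityCorrelation:
    def test_contamination_negative_tumor_positive(self, default_cohort):
        ds, truth, _ = default_cohort
        prim = filter_samples(ds, {"tissue_type": "primary_tumor"})
        meta = prim.meta_aligned()
        acinar = gene_set_score(prim, GeneSet("ac", tuple(truth.block_genes("acinar"))))
        res = purity_correlation(acinar, meta)
        assert res.rho < 0 and res.p < 0.01
        shared = gene_set_score(prim, GeneSet("sh", tuple(truth.block_genes("tumor_shared"))))
        assert purity_correlation(shared, meta).rho > 0

    def test_all_missing_purity_rejected(self, tiny_dataset):
        sv = gene_set_score(tiny_dataset, GeneSet("s", ("G1",)))
        meta = tiny_dataset.meta_aligned().assign(purity=np.nan)
        with pytest.raises(ValueError, match=">= 3"):
            purity_correlation(sv, meta)


class TestCompartmentPanel:
    def test_synthetic_contrasts(self, default_cohort):
        ds, _, sets = default_cohort
        table, failures = score_panel(ds, sets)
        assert not failures
        panel = compartment_panel(
            table, ds.meta_aligned(),
            contrasts=[("primary_tumor", "cell_line"), ("primary_tumor", "caf")],
        )
        row = panel.set_index(["gene_set", "group_b"])
        adex = row.loc[("sim_ADEX-like", "cell_line")]
        assert adex["mean_a"] > adex["mean_b"] and adex["p"] < 0.01
        basal = row.loc[("sim_basal", "cell_line")]
        assert basal["mean_b"] >= basal["mean_a"]  # retention: cell lines not lower
        caf = row.loc[("sim_basal", "caf")]
        assert caf["mean_a"] > caf["mean_b"]  # CAFs do not confound tumor blocks

    def test_self_contrast_p_one(self, default_cohort):
        ds, _, sets = default_cohort
        table, _ = score_panel(ds, sets)
        panel = compartment_panel(table, ds.meta_aligned(), [("caf", "caf")])
        assert (panel["p"] == 1.0).all()

    def test_unknown_group_rejected(self, default_cohort):
        ds, _, sets = default_cohort
        table, _ = score_panel(ds, sets)
        with pytest.raises(ValueError, match="organoid"):
            compartment_panel(table, ds.meta_aligned(), [("primary_tumor", "organoid")])

    def test_bh_adjustment_monotone(self, default_cohort):
        ds, _, sets = default_cohort
        table, _ = score_panel(ds, sets)
        panel = compartment_panel(
            table, ds.meta_aligned(), [("primary_tumor", "cell_line")], bh_adjust=True
        )
        assert (panel["q"] >= panel["p"] - 1e-12).all()


def _manual_pairs_meta(scores):
    """Metadata for len(scores) primary/cell-line pairs with given scores."""
    n = len(scores)
    idx = [f"P{i}" for i in range(n)] + [f"C{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "tissue_type": ["primary_tumor"] * n + ["cell_line"] * n,
            "pair_id": [f"pr{i}" for i in range(n)] * 2,
        },
        index=idx,
    )
    s = pd.Series(list(scores) + list(scores), index=idx)
    return ScoreVector("toy", s, 1.0, ("g",)), meta


class TestPairedRetention:
    def test_identical_scores_full_retention(self):
        sv, meta = _manual_pairs_meta([1.0, 2.0, 3.0, 4.0])
        res = paired_retention(sv, meta)
        assert res.rho == 1.0 and res.loss == pytest.approx(0.0, abs=1e-12)
        assert res.n_pairs == 4

    def test_duplicated_role_named(self):
        sv, meta = _manual_pairs_meta([1.0, 2.0, 3.0])
        meta.loc["C1", "pair_id"] = "pr0"  # pr0 now has two cell lines
        with pytest.raises(ValueError, match="pr0"):
            paired_retention(sv, meta)

    def test_too_few_pairs(self):
        sv, meta = _manual_pairs_meta([1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            paired_retention(sv, meta)

    def test_synthetic_tumor_block_retained_contamination_lost(self, default_cohort):
        ds, _, sets = default_cohort
        meta = ds.meta_aligned()
        basal = paired_retention(gene_set_score(ds, sets["sim_basal"]), meta)
        assert basal.rho >= 0.7 and basal.loss >= 0
        adex = paired_retention(gene_set_score(ds, sets["sim_ADEX-like"]), meta)
        assert adex.loss < 0 and abs(adex.rho) < 0.5


class TestOverlapAndConcordance:
    def test_overlap_cases(self):
        a = GeneSet("a", tuple(f"g{i}" for i in range(8)))
        b = GeneSet("b", ("g0", "g1", "x1", "x2"))
        assert gene_list_overlap(a, a) == (8, 1.0)
        assert gene_list_overlap(a, GeneSet("c", ("z",))) == (0, 0.0)
        count, frac = gene_list_overlap(a, b)
        assert count == 2 and frac == 0.25
        # asymmetric denominator
        assert gene_list_overlap(b, a)[1] == 0.5

    def test_concordance_identity_and_flip(self):
        a = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        same, _ = label_concordance(a, a)
        assert same == 1.0
        b = a.copy()
        b["a"] = "y"
        frac, mapping = label_concordance(a, b)
        assert frac == 0.75 and mapping == {"x": "x", "y": "y"}

    def test_vocabulary_mapping_inferred(self):
        a = pd.Series(["basal", "classical", "basal"], index=list("abc"))
        b = pd.Series(["sq", "prog", "sq"], index=list("abc"))
        frac, mapping = label_concordance(a, b)
        assert frac == 1.0 and mapping == {"basal": "sq", "classical": "prog"}

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(1000)]
        a = pd.Series(rng.choice(["x", "y"], 1000), index=idx)
        b = pd.Series(rng.choice(["u", "v"], 1000), index=idx)
        frac, _ = label_concordance(a, b)
        assert 0.5 <= frac <= 0.55  # best-of-two mapping is >= 0.5 by construction

    def test_id_mismatch_rejected(self):
        a = pd.Series(["x"], index=["s1"])
        b = pd.Series(["x"], index=["s2"])
        with pytest.raises(ValueError, match="different sample ids"):
            label_concordance(a, b)


class TestVerdict:
    BASE = {
        "purity_rho": 0.2, "purity_p": 0.2, "primary_mean": 0.0,
        "cellline_mean": 0.3, "cellline_p": 0.3, "paired_loss": 0.2,
    }

    def test_purity_confounded_is_non_tumor(self):
        frag = dict(self.BASE, purity_rho=-0.5, purity_p=1e-4)
        v = signature_verdict(frag)
        assert v.verdict == "non_tumor" and "purity_confounded" in v.rules_triggered

    def test_cellline_loss_is_non_tumor(self):
        frag = dict(self.BASE, cellline_mean=-0.8, cellline_p=1e-5, paired_loss=-1.0)
        v = signature_verdict(frag)
        assert v.verdict == "non_tumor" and "cellline_loss" in v.rules_triggered

    def test_retention_is_tumor_intrinsic(self):
        v = signature_verdict(dict(self.BASE))
        assert v.verdict == "tumor_intrinsic"
        assert v.rules_triggered == ("cellline_retention",)

    def test_missing_fields_ambiguous(self):
        v = signature_verdict({"purity_rho": -0.5})
        assert v.verdict == "ambiguous"
        assert v.rules_triggered == ("insufficient_evidence",)

    def test_deterministic_and_threshold_configurable(self):
        frag = dict(self.BASE, purity_rho=-0.2, purity_p=0.01)
        assert signature_verdict(frag).verdict == "non_tumor"
        lax = VerdictRules(rho_threshold=-0.3)
        assert signature_verdict(frag, lax).verdict == "tumor_intrinsic"
        assert signature_verdict(frag, lax) == signature_verdict(frag, lax)


class TestRobustnessPanel:
    def test_spread_structure(self, default_cohort):
        ds, _, sets = default_cohort
        panel = signature_robustness_panel(sets, ds).set_index("gene_set")
        assert panel.loc["sim_housekeeping", "spread"] < panel.loc["sim_ADEX-like", "spread"]
        adex = panel.loc["sim_ADEX-like"]
        tissue_means = adex[[c for c in panel.columns if c.startswith("mean_")]]
        assert tissue_means.astype(float).idxmax() in ("mean_normal_pancreas", "mean_acc")

    def test_sample_order_invariant(self, default_cohort):
        ds, _, sets = default_cohort
        shuffled = ds.subset_samples(list(reversed(ds.sample_ids)))
        p1 = signature_robustness_panel(sets, ds).set_index("gene_set")["spread"]
        p2 = signature_robustness_panel(sets, shuffled).set_index("gene_set")["spread"]
        assert np.allclose(p1, p2, atol=1e-12)
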