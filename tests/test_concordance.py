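"""Cross-method concordance, suite bookkeeping and group heterogeneity."""

import numpy as np
import pandas as pd
import pytest

import emtscore as es
from emtscore.concordance import EXPECTED_SIGN, pairwise_concordance


def frame(ks, mlr, gs=None, index=None):
    data = {"score_KS": ks, "score_MLR": mlr}
    if gs is not None:
        data["score_76GS"] = gs
    idx = index or [f"s{i}" for i in range(len(ks))]
    return pd.DataFrame(data, index=idx)


def correlated(r, n=200, seed=0):
    """Two vectors with sample Pearson correlation exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)  # orthogonalise
    z /= z.std()
    return x, r * x + np.sqrt(1 - r**2) * z


class TestPairwise:
    def test_identical_columns_correlate_perfectly(self):
        x = np.linspace(-1, 1, 30)
        res = pairwise_concordance(frame(x, x))
        row = res.iloc[0]
        assert row["R"] == pytest.approx(1.0)
        assert row["p"] < 1e-10
        assert row["expected_sign"] == 1 and row["passes"]

    def test_r_just_below_threshold_is_not_significant(self):
        x, y = correlated(0.29)
        res = pairwise_concordance(frame(x, y))
        row = res.iloc[0]
        assert row["R"] == pytest.approx(0.29, abs=1e-12)
        assert row["p"] < 0.001
        assert not row["significant"]

    def test_r_just_above_threshold_is_significant(self):
        x, y = correlated(0.31)
        row = pairwise_concordance(frame(x, y)).iloc[0]
        assert row["significant"] and row["passes"]

    def test_wrong_direction_does_not_pass(self):
        x, y = correlated(-0.9)  # KS-MLR should be positive
        row = pairwise_concordance(frame(x, y)).iloc[0]
        assert row["significant"] and not row["expected_direction"]
        assert not row["passes"]

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pairwise_concordance(frame([1.0] * 10, np.arange(10.0)))

    def test_affine_rescale_leaves_R_unchanged(self, score_table):
        scores, _ = score_table
        base = pairwise_concordance(scores)
        rescaled = scores.copy()
        rescaled["score_KS"] = 3.0 * rescaled["score_KS"] + 7.0
        again = pairwise_concordance(rescaled)
        assert np.allclose(base["R"].to_numpy(), again["R"].to_numpy())

    def test_synthetic_gradient_recovers_sign_structure(self, score_table):
        scores, _ = score_table
        res = pairwise_concordance(scores)
        assert res["passes"].all()
        by_pair = {(r.method_a, r.method_b): r.R for r in res.itertuples()}
        assert by_pair[("KS", "MLR")] > 0.3
        assert by_pair[("76GS", "KS")] < -0.3
        assert by_pair[("76GS", "MLR")] < -0.3

    def test_per_category_concordance_reported(self, score_table):
        scores, _ = score_table
        res = es.per_category_concordance(scores)
        assert not res.empty
        assert set(res["category"]) <= {"E", "E/M", "M"}
        assert res["R"].between(-1, 1).all()

    def test_expected_sign_map_is_fixed(self):
        assert EXPECTED_SIGN == {
            ("76GS", "KS"): -1, ("76GS", "MLR"): -1, ("KS", "MLR"): 1,
        }


def fake_table(passes_by_pair):
    rows = []
    for (a, b), ok in passes_by_pair.items():
        rows.append({"method_a": a, "method_b": b, "R": 0.5 if ok else 0.0,
                     "p": 1e-6 if ok else 0.9, "n": 50, "expected_sign": 1,
                     "significant": ok, "expected_direction": True, "passes": ok})
    return pd.DataFrame(rows)


class TestSuiteSummary:
    PAIRS = [("76GS", "KS"), ("76GS", "MLR"), ("KS", "MLR")]

    def test_full_agreement_intersection(self):
        tables = {name: fake_table({p: True for p in self.PAIRS}) for name in "ABC"}
        summ = es.multi_dataset_summary(tables)
        assert summ.intersection == ["A", "B", "C"]
        assert all(v == 3 for v in summ.pass_counts.values())

    def test_partial_overlap_set_algebra(self):
        # pair 1 passes in {A,B}, pair 2 in {A}, pair 3 in {A,C}
        memberships = [{"A", "B"}, {"A"}, {"A", "C"}]
        tables = {
            name: fake_table({p: name in members
                              for p, members in zip(self.PAIRS, memberships)})
            for name in "ABC"
        }
        summ = es.multi_dataset_summary(tables)
        assert summ.intersection == ["A"]
        assert summ.pass_counts == {("76GS", "KS"): 2, ("76GS", "MLR"): 1,
                                    ("KS", "MLR"): 2}

    def test_volcano_rows_cover_every_dataset_pair(self):
        tables = {name: fake_table({p: True for p in self.PAIRS}) for name in "AB"}
        summ = es.multi_dataset_summary(tables)
        assert summ.volcano.shape[0] == 6
        assert set(summ.volcano["dataset"]) == {"A", "B"}

    def test_planted_suite_outcomes_recovered(self, ref_model):
        datasets, sigs = es.generate_dataset_suite(12, 0.75, seed=2)
        assert sum(d.concordant for d in datasets) == 9
        per, truth = {}, {}
        for ds in datasets:
            table = (
                es.score_76gs(ds.expr, sigs["76GS"])
                .join(es.score_ks(ds.expr, sigs["KS"]))
                .join(es.score_mlr(ds.expr, sigs["MLR"], ref_model))
            )
            per[ds.name] = pairwise_concordance(table)
            truth[ds.name] = ds.concordant
        summ = es.multi_dataset_summary(per)
        planted = sorted(n for n, ok in truth.items() if ok)
        assert summ.intersection == planted
        assert summ.pass_counts == {pair: len(planted) for pair in summ.pass_counts}


class TestGroupHeterogeneity:
    def test_degenerate_group_has_zero_variance(self):
        scores = frame([0.5, 0.5, 0.1], [1.0, 1.0, 0.2])
        groups = pd.Series(["twins", "twins", "other2"], index=scores.index)
        # size-1 group is flagged, size-2 identical group has zero variance
        scores.loc["s3"] = [0.3, 0.4]
        groups.loc["s3"] = "other2"
        out = es.group_heterogeneity(scores, groups)
        assert out.loc["twins", "var_KS"] == 0.0
        assert out.loc["twins", "var_MLR"] == 0.0

    def test_size_one_group_excluded_from_ranking(self):
        scores = frame([0.1, 0.2, 0.9], [0.3, 0.4, 1.9])
        groups = pd.Series(["big", "big", "solo"], index=scores.index)
        out = es.group_heterogeneity(scores, groups)
        assert not out.loc["solo", "rankable"]
        assert np.isnan(out.loc["solo", "var_rank_KS"])

    def test_missing_group_label_rejected(self):
        scores = frame([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError, match="without a group"):
            es.group_heterogeneity(scores, pd.Series({"s0": "g"}))

    def test_mixed_group_is_most_variable_in_all_methods(self, ref_model):
        # one group spans E/hybrid/M, the others are homogeneous M cohorts
        mixed = es.generate_population(es.PopulationSpec(
            n_E=10, n_M=10, n_H=10, n_mix=0, seed=21))
        pure1 = es.generate_population(es.PopulationSpec(
            n_E=0, n_M=30, n_H=0, n_mix=0, seed=22))
        sigs = mixed[2]
        frames, labels = [], []
        for tag, (expr, _, _) in (("mixed", mixed), ("sarcoma", pure1)):
            renamed = es.ExpressionMatrix(
                expr.data.rename(columns=lambda c: f"{tag}_{c}"))
            table = (
                es.score_76gs(renamed, sigs["76GS"])
                .join(es.score_ks(renamed, sigs["KS"]))
                .join(es.score_mlr(renamed, sigs["MLR"], ref_model))
            )
            frames.append(table)
            labels += [tag] * renamed.n_samples
        scores = pd.concat(frames)
        groups = pd.Series(labels, index=scores.index)
        out = es.group_heterogeneity(scores, groups)
        for method in ("76GS", "KS", "MLR"):
            assert out.loc["mixed", f"var_rank_{method}"] == 1.0

    def test_hybrid_flags_from_planted_counts(self):
        n, n_em = 50, 12
        scores = pd.DataFrame(
            {
                "score_MLR": np.linspace(0, 2, n),
                "category_MLR": ["E/M"] * n_em + ["E"] * (n - n_em),
            },
            index=[f"s{i}" for i in range(n)],
        )
        groups = pd.Series(["g"] * n, index=scores.index)
        out = es.group_heterogeneity(scores, groups)
        assert out.loc["g", "n_EM"] == 12
        assert out.loc["g", "pct_EM"] == pytest.approx(24.0)
        assert bool(out.loc["g", "flag_count"]) and bool(out.loc["g", "flag_pct"])
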