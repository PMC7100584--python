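"""Mixture curve: reference selection, curve geometry, distance ranking."""

import math

import numpy as np
import pandas as pd
import pytest

import emtscore as es
from emtscore.mlr import compute_predictors


@pytest.fixture(scope="module")
def curve_setup(ref_model):
    """Cohort with grid-aligned noiseless admixtures plus E/M references."""
    fractions = [round(k / 1000, 3) for k in range(0, 1001, 40)]  # 26 on-grid f
    spec = es.PopulationSpec(
        n_E=40, n_M=40, n_H=10, n_mix=len(fractions),
        mix_fractions=fractions, noise_sd=0.0, seed=11,
    )
    expr, labels, sigs = es.generate_population(spec)
    scores = es.score_mlr(expr, sigs["MLR"], ref_model)
    pure_e, pure_m = es.select_reference_samples(scores, n=35)
    curve = es.build_mixture_curve(expr, pure_e, pure_m, sigs["MLR"],
                                   offset=ref_model.offset)
    points = compute_predictors(expr, sigs["MLR"], offset=ref_model.offset)
    return expr, labels, sigs, curve, points


class TestReferenceSelection:
    def test_top_and_bottom_35_of_100(self):
        scores = pd.DataFrame({"score_MLR": np.linspace(0, 2, 100)},
                              index=[f"s{i:03d}" for i in range(100)])
        low, high = es.select_reference_samples(scores, n=35)
        assert low == [f"s{i:03d}" for i in range(35)]
        assert high == [f"s{i:03d}" for i in range(65, 100)]

    def test_minimal_two_sample_case(self):
        scores = pd.DataFrame({"score_MLR": [1.5, 0.2]}, index=["a", "b"])
        low, high = es.select_reference_samples(scores, n=1)
        assert (low, high) == (["b"], ["a"])

    def test_ties_resolved_deterministically(self):
        scores = pd.DataFrame({"score_MLR": [1.0] * 6},
                              index=["f", "a", "d", "b", "e", "c"])
        first = es.select_reference_samples(scores, n=2)
        second = es.select_reference_samples(scores.iloc[::-1], n=2)
        assert first == second == (["a", "b"], ["e", "f"])

    def test_too_few_samples_rejected(self):
        scores = pd.DataFrame({"score_MLR": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="at least"):
            es.select_reference_samples(scores, n=2)


class TestCurve:
    def test_endpoints_are_pure_profile_images(self, curve_setup, ref_model):
        expr, _, sigs, curve, _ = curve_setup
        pure = pd.DataFrame({"E": curve.pure_E_profile, "M": curve.pure_M_profile})
        ends = compute_predictors(
            es.ExpressionMatrix(pure), sigs["MLR"], offset=ref_model.offset
        )
        assert np.allclose(curve.points[0], ends.loc["E"].to_numpy(), atol=1e-9)
        assert np.allclose(curve.points[-1], ends.loc["M"].to_numpy(), atol=1e-9)

    def test_mid_curve_matches_independent_arithmetic(self, curve_setup, ref_model):
        # recompute f in {0.25, 0.5, 0.75} with plain python loops
        expr, _, sigs, curve, _ = curve_setup
        normalizers = sigs["MLR"].normalizer_genes
        for f in (0.25, 0.5, 0.75):
            i = int(round(f * (len(curve.grid) - 1)))
            assert curve.grid[i] == pytest.approx(f)
            mixed = {
                g: math.log2((1 - f) * 2 ** curve.pure_E_profile[g]
                             + f * 2 ** curve.pure_M_profile[g])
                for g in curve.pure_E_profile.index
            }
            med = sorted(mixed[g] for g in normalizers)
            n = len(med)
            median = (med[n // 2] if n % 2 else (med[n // 2 - 1] + med[n // 2]) / 2)
            adj = {g: mixed[g] - median + ref_model.offset
                   for g in ("VIM", "CDH1", "CLDN7")}
            assert curve.points[i, 0] == pytest.approx(adj["VIM"] / adj["CDH1"])
            assert curve.points[i, 1] == pytest.approx(adj["CLDN7"])

    def test_fraction_grid_strictly_increasing(self, curve_setup):
        curve = curve_setup[3]
        assert (np.diff(curve.grid) > 0).all()

    def test_invalid_aggregator_rejected(self, curve_setup, ref_model):
        expr, _, sigs, _, _ = curve_setup
        with pytest.raises(ValueError, match="aggregator"):
            es.build_mixture_curve(expr, expr.samples[:2], expr.samples[2:4],
                                   sigs["MLR"], aggregator="mode")


class TestDistance:
    def test_grid_point_has_zero_distance(self, curve_setup):
        curve = curve_setup[3]
        probe = pd.DataFrame(curve.points[[100]], columns=["x1", "x2"], index=["probe"])
        res = es.distance_to_curve(probe, curve)
        assert res.loc["probe", "distance"] == 0.0
        assert res.loc["probe", "f_hat"] == curve.grid[100]

    def test_noiseless_admixtures_recover_planted_fraction(self, curve_setup):
        _, labels, _, curve, points = curve_setup
        mix = labels.index[labels.label == "mixture"]
        res = es.distance_to_curve(points.loc[mix], curve)
        assert res["distance"].max() <= 1e-9
        err = (res["f_hat"] - labels.loc[mix, "true_f"]).abs()
        assert err.max() <= 0.001
        assert (res["pct_M"] == 100 * res["f_hat"]).all()

    def test_hybrids_sit_off_the_curve(self, curve_setup):
        _, labels, _, curve, points = curve_setup
        res = es.distance_to_curve(points, curve)
        hyb = res.loc[labels.index[labels.label == "hybrid"], "distance"]
        mix = res.loc[labels.index[labels.label == "mixture"], "distance"]
        assert (hyb > mix.quantile(0.9)).all()

    def test_result_invariant_to_sample_order(self, curve_setup):
        _, _, _, curve, points = curve_setup
        fwd = es.distance_to_curve(points, curve)
        rev = es.distance_to_curve(points.iloc[::-1], curve)
        assert np.allclose(fwd["distance"].to_numpy(),
                           rev["distance"].iloc[::-1].to_numpy())

    def test_grid_refinement_converges(self, curve_setup, ref_model):
        expr, _, sigs, _, points = curve_setup
        scores = es.score_mlr(expr, sigs["MLR"], ref_model)
        pe, pm = es.select_reference_samples(scores, n=35)
        coarse = es.build_mixture_curve(expr, pe, pm, sigs["MLR"], grid_size=101,
                                        offset=ref_model.offset)
        fine = es.build_mixture_curve(expr, pe, pm, sigs["MLR"], grid_size=201,
                                      offset=ref_model.offset)
        d_coarse = es.distance_to_curve(points, coarse)["distance"]
        d_fine = es.distance_to_curve(points, fine)["distance"]
        spacing = np.abs(np.diff(coarse.points, axis=0)).sum(axis=1).max()
        assert (d_coarse - d_fine).abs().max() <= spacing


class TestRanking:
    def test_sets_are_disjoint_and_sized(self, curve_setup):
        _, _, _, curve, points = curve_setup
        res = es.distance_to_curve(points, curve)
        closest, farthest = es.rank_by_curve_distance(res, 10)
        assert len(closest) == len(farthest) == 10
        assert not set(closest) & set(farthest)
        assert res.loc[closest, "distance"].mean() < res.loc[farthest, "distance"].mean()

    def test_equal_distances_resolved_by_sample_id(self):
        res = pd.DataFrame({"distance": [0.5] * 6},
                           index=["c", "a", "f", "b", "e", "d"])
        closest, farthest = es.rank_by_curve_distance(res, 2)
        assert (closest, farthest) == (["a", "b"], ["e", "f"])

    def test_requesting_too_many_rejected(self):
        res = pd.DataFrame({"distance": [0.1, 0.2, 0.3]}, index=list("abc"))
        with pytest.raises(ValueError, match="at least"):
            es.rank_by_curve_distance(res, 2)
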