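"""Mixture-curve analysis: true hybrids vs admixtures of E and M cells.

A bulk sample classified as hybrid E/M can either contain individually
hybrid cells or be a physical mixture of epithelial and mesenchymal
subpopulations.  The two are distinguished geometrically in the MLR
predictor space: purified E and M reference profiles are aggregated from
the extreme ends of the MLR score ranking, and the *mixture curve* is
the locus of all convex combinations of the two purified states.  A
bulk mixture of E and M cells must fall on (or near) this curve — bulk
transcript abundance adds linearly over cells — whereas a sample of
truly hybrid cells can sit far from it.  Each sample is summarised by
its l2 distance to the curve and by the mesenchymal fraction f at the
nearest curve point (reported as %M = 100 f).

Mixing is done on the linear intensity scale by default (unlog, combine
(1-f) E + f M, relog); a ``mix_space="log"`` option mixes the log2
profiles directly for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, GeneSignature
from .mlr import PREDICTOR_GENES, compute_predictors


@dataclass
class MixtureCurve:
    """Convex-combination curve between purified E and M profiles.

    ``grid`` holds the strictly increasing mesenchymal fractions f in
    [0, 1]; ``points`` the matching (x1, x2) predictor coordinates.  The
    endpoints are exactly the predictor images of the purified E (f=0)
    and M (f=1) profiles.
    """

    pure_E_profile: pd.Series
    pure_M_profile: pd.Series
    grid: np.ndarray
    points: np.ndarray  # (grid_size, 2)
    offset: float
    mix_space: str
    aggregator: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f": self.grid, "x1": self.points[:, 0], "x2": self.points[:, 1]}
        )


def select_reference_samples(
    scores: pd.DataFrame, n: int = 35
) -> tuple[list[str], list[str]]:
    """Bottom/top ``n`` samples by MLR score as pure-E / pure-M references.

    Ties across the cut are broken by sample ID, so the selection is
    stable across reruns and input orderings.
    """
    if "score_MLR" not in scores:
        raise ValueError("score table lacks a score_MLR column")
    if scores.shape[0] < 2 * n:
        raise ValueError(f"need at least {2 * n} samples, have {scores.shape[0]}")
    ordered = scores["score_MLR"].rename_axis("sample").reset_index()
    ordered = ordered.sort_values(["score_MLR", "sample"], kind="mergesort")
    ids = ordered["sample"].tolist()
    return ids[:n], ids[-n:]


def build_mixture_curve(
    expr: ExpressionMatrix,
    pure_E_ids: list[str],
    pure_M_ids: list[str],
    sig: GeneSignature,
    aggregator: str = "mean",
    grid_size: int = 1001,
    mix_space: str = "linear",
    offset: float | None = None,
) -> MixtureCurve:
    """Aggregate purified profiles and trace their convex combinations.

    The purified E and M expression profiles (over the MLR signature
    genes) are the per-gene mean or median of the reference samples.
    For each f on a uniform grid, the admixture profile is formed in
    the requested space and mapped back to predictor coordinates with
    the normalizer adjustment and positivity ``offset`` shared with the
    scored samples.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    if mix_space not in ("linear", "log"):
        raise ValueError(f"mix_space must be 'linear' or 'log', got {mix_space!r}")
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    genes = [g for g in sig.entries["gene"] if g in expr.data.index]
    needed = [g for g in PREDICTOR_GENES if g not in genes]
    if needed:
        raise ValueError(f"MLR signature genes missing from matrix: {needed}")
    agg = getattr(expr.data.loc[genes, pure_E_ids], aggregator)
    profile_e = agg(axis=1)
    profile_m = getattr(expr.data.loc[genes, pure_M_ids], aggregator)(axis=1)

    fractions = np.linspace(0.0, 1.0, grid_size)
    if mix_space == "linear":
        lin_e = np.exp2(profile_e.to_numpy())[:, None]
        lin_m = np.exp2(profile_m.to_numpy())[:, None]
        mixed = np.log2((1.0 - fractions) * lin_e + fractions * lin_m)
    else:
        mixed = (1.0 - fractions) * profile_e.to_numpy()[:, None] + fractions * profile_m.to_numpy()[:, None]
    mix_expr = ExpressionMatrix(
        pd.DataFrame(mixed, index=genes, columns=[f"f{i}" for i in range(grid_size)])
    )
    points = compute_predictors(mix_expr, sig, offset=offset).to_numpy()
    return MixtureCurve(
        pure_E_profile=profile_e,
        pure_M_profile=profile_m,
        grid=fractions,
        points=points,
        offset=offset if offset is not None else float("nan"),
        mix_space=mix_space,
        aggregator=aggregator,
    )


def distance_to_curve(points: pd.DataFrame, curve: MixtureCurve) -> pd.DataFrame:
    """l2 distance of each predictor point to the curve and nearest %M.

    The minimum is taken over the curve's grid points; ties go to the
    smaller mesenchymal fraction.  Returns a DataFrame indexed like
    ``points`` with columns ``distance``, ``f_hat`` and ``pct_M``.
    """
    xy = points[["x1", "x2"]].to_numpy(dtype=float)
    d2 = ((xy[:, None, :] - curve.points[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # argmin returns the first (smallest-f) minimiser
    out = pd.DataFrame(
        {
            "distance": np.sqrt(d2[np.arange(len(xy)), idx]),
            "f_hat": curve.grid[idx],
        },
        index=points.index,
    )
    out["pct_M"] = 100.0 * out["f_hat"]
    return out


def rank_by_curve_distance(
    results: pd.DataFrame, N: int
) -> tuple[list[str], list[str]]:
    """Closest-N and farthest-N sample IDs by curve distance (disjoint).

    Ordering is stable: ties are broken by sample ID.
    """
    if results.shape[0] < 2 * N:
        raise ValueError(f"need at least {2 * N} samples to take two disjoint sets of {N}")
    ordered = results["distance"].rename_axis("sample").reset_index()
    ordered = ordered.sort_values(["distance", "sample"], kind="mergesort")
    ids = ordered["sample"].tolist()
    return ids[:N], ids[-N:]
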