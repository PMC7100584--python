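"""Cross-method concordance and EMT heterogeneity summaries.

The three scorers point along the same E-M axis but with opposite
orientations: 76GS is epithelial-high while KS and MLR are
mesenchymal-high.  Concordance between methods therefore has a fixed
expected sign structure — (KS, MLR) positive, (76GS, KS) and
(76GS, MLR) negative.  A method pair on one dataset "passes" when its
Pearson correlation is significant (p below alpha), large in magnitude
(|R| above the threshold) and in the expected direction.

Heterogeneity summaries group samples (e.g. by tumor type) and report
per-method score means and variances plus hybrid-enrichment flags based
on the MLR category calls: an absolute hybrid count above 10 and a
hybrid percentage above 20%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CATEGORY_COLUMN, SCORE_COLUMNS

#: fixed expected correlation signs between method pairs
EXPECTED_SIGN = {
    ("76GS", "KS"): -1,
    ("76GS", "MLR"): -1,
    ("KS", "MLR"): 1,
}

DEFAULT_ALPHA = 0.05
DEFAULT_R_THRESHOLD = 0.3
HYBRID_COUNT_THRESHOLD = 10
HYBRID_PCT_THRESHOLD = 20.0


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def pairwise_concordance(
    scores: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> pd.DataFrame:
    """Pearson concordance for every available method pair.

    Returns one row per pair with columns ``method_a``, ``method_b``,
    ``R``, ``p``, ``n``, ``expected_sign``, ``significant`` (p < alpha
    and |R| > r_threshold), ``expected_direction`` and ``passes``
    (significant and in the expected direction).  p-values use the
    standard t-distribution transform of Pearson's R.
    """
    methods = [m for m, col in SCORE_COLUMNS.items() if col in scores.columns]
    if len(methods) < 2:
        raise ValueError("need score columns for at least two methods")
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            sub = scores[[SCORE_COLUMNS[a], SCORE_COLUMNS[b]]].dropna()
            if sub.shape[0] < 3:
                raise ValueError(f"pair ({a}, {b}): fewer than 3 complete samples")
            xa = sub[SCORE_COLUMNS[a]].to_numpy()
            xb = sub[SCORE_COLUMNS[b]].to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                raise ValueError(f"pair ({a}, {b}): constant score column")
            r, p = stats.pearsonr(xa, xb)
            expected = EXPECTED_SIGN[_pair_key(a, b)]
            significant = bool((p < alpha) and (abs(r) > r_threshold))
            direction = bool(np.sign(r) == expected)
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "R": float(r),
                    "p": float(p),
                    "n": int(sub.shape[0]),
                    "expected_sign": expected,
                    "significant": significant,
                    "expected_direction": direction,
                    "passes": significant and direction,
                }
            )
    return pd.DataFrame(rows)


def per_category_concordance(
    scores: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    min_n: int = 5,
) -> pd.DataFrame:
    """Concordance restricted to each MLR category (E, E/M, M) subset."""
    if CATEGORY_COLUMN not in scores:
        raise ValueError("score table lacks MLR category calls")
    frames = []
    for cat, sub in scores.groupby(CATEGORY_COLUMN):
        if sub.shape[0] < min_n:
            continue
        try:
            res = pairwise_concordance(sub, alpha=alpha, r_threshold=r_threshold)
        except ValueError:
            continue
        res.insert(0, "category", cat)
        frames.append(res)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


@dataclass
class SuiteSummary:
    """Aggregate of per-dataset concordance over a dataset collection."""

    pass_counts: dict[tuple[str, str], int]
    passing_datasets: dict[tuple[str, str], list[str]]
    intersection: list[str]
    volcano: pd.DataFrame  # dataset, pair, R, neg_log10_p, passes


def multi_dataset_summary(per_dataset: dict[str, pd.DataFrame]) -> SuiteSummary:
    """Count expected-direction-significant datasets per method pair.

    ``per_dataset`` maps dataset name to its :func:`pairwise_concordance`
    table.  The intersection lists datasets passing for *all* pairs
    present; the volcano table carries (R, -log10 p) per dataset/pair
    for plotting.
    """
    if not per_dataset:
        raise ValueError("no datasets supplied")
    passing: dict[tuple[str, str], list[str]] = {}
    volcano_rows = []
    all_pairs: set[tuple[str, str]] = set()
    for name, table in per_dataset.items():
        for _, row in table.iterrows():
            pair = _pair_key(row["method_a"], row["method_b"])
            all_pairs.add(pair)
            if row["passes"]:
                passing.setdefault(pair, []).append(name)
            volcano_rows.append(
                {
                    "dataset": name,
                    "pair": f"{pair[0]}-{pair[1]}",
                    "R": row["R"],
                    "neg_log10_p": float(-np.log10(max(row["p"], 1e-300))),
                    "passes": bool(row["passes"]),
                }
            )
    passing = {pair: sorted(passing.get(pair, [])) for pair in sorted(all_pairs)}
    inter: set[str] | None = None
    for names in passing.values():
        inter = set(names) if inter is None else inter & set(names)
    return SuiteSummary(
        pass_counts={pair: len(names) for pair, names in passing.items()},
        passing_datasets=passing,
        intersection=sorted(inter or set()),
        volcano=pd.DataFrame(volcano_rows),
    )


def group_heterogeneity(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group score means/variances, hybrid counts and enrichment flags.

    Every scored sample must carry a group label.  Variance is the
    unbiased sample variance; groups of size 1 are flagged
    (``rankable=False``) and excluded from the variance ranking.
    Returns one row per group with per-method ``mean_*``/``var_*``
    columns, variance ranks (1 = most variable), hybrid count ``n_EM``,
    ``pct_EM`` and the two enrichment flags.
    """
    groups = groups.reindex(scores.index)
    if groups.isna().any():
        missing = list(scores.index[groups.isna()])[:5]
        raise ValueError(f"samples without a group label: {missing}")
    method_cols = {m: c for m, c in SCORE_COLUMNS.items() if c in scores.columns}
    rows = []
    for label, idx in scores.groupby(groups).groups.items():
        sub = scores.loc[idx]
        n = sub.shape[0]
        row: dict = {"group": label, "n": n, "rankable": n > 1}
        for method, col in method_cols.items():
            row[f"mean_{method}"] = float(sub[col].mean())
            row[f"var_{method}"] = float(sub[col].var(ddof=1)) if n > 1 else np.nan
        if CATEGORY_COLUMN in sub:
            n_em = int((sub[CATEGORY_COLUMN] == "E/M").sum())
            pct_em = 100.0 * n_em / n
            row.update(
                n_EM=n_em,
                pct_EM=pct_em,
                flag_count=n_em > HYBRID_COUNT_THRESHOLD,
                flag_pct=pct_em > HYBRID_PCT_THRESHOLD,
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("group").sort_index()
    for method in method_cols:
        col = f"var_{method}"
        ranks = out.loc[out["rankable"], col].rank(ascending=False, method="min")
        out[f"var_rank_{method}"] = ranks.reindex(out.index)
    return out
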