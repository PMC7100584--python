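"""KS EMT score: signed uniform-norm distance between signature ECDFs.

For one sample, collect the expression values of the epithelial
signature genes and of the mesenchymal signature genes, and compare
their empirical cumulative distribution functions ``F_E`` and ``F_M``.
The test statistic is the uniform norm

    D = max_x | F_E(x) - F_M(x) |,

i.e. the classical two-sample Kolmogorov-Smirnov distance, with
``0 <= D <= 1``.  The sign is set by two one-sided two-sample KS tests:
if "F_E above F_M" is significant the sample is mesenchymal (epithelial
genes sit at low expression, so their ECDF rises first) and the score is
``+D``; if "F_M above F_E" is significant the sample is epithelial and
the score is ``-D``.  When neither one-sided test reaches the
significance level, the sign of the dominant ECDF deviation (the sign of
``F_E - F_M`` at the argmax of ``|F_E - F_M|``) is used, keeping the
score continuous along the E-M spectrum instead of collapsing to a hard
zero.

Because D is a rank statistic, any strictly increasing transform of a
sample's expression values leaves its score unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, GeneSignature

#: pooled-size cutoff below which exact one-sided p-values are used
EXACT_POOLED_N = 25


@dataclass(frozen=True)
class KSResult:
    """Per-sample KS scoring detail."""

    D: float
    p_M_gt_E: float  # p-value for "CDF of M signature above CDF of E signature"
    p_E_gt_M: float  # p-value for the opposite hypothesis
    score: float


def signed_ecdf_deviation(epi_values, mes_values) -> tuple[float, int]:
    """Uniform-norm ECDF distance and the sign of its dominant deviation.

    Returns ``(D, sign)`` where ``D = max_x |F_E(x) - F_M(x)|`` over the
    pooled support (right-continuous ECDFs, ties handled identically on
    both sides) and ``sign`` is the sign of ``F_E - F_M`` at the first
    argmax of the absolute deviation.
    """
    epi = np.asarray(epi_values, dtype=float)
    mes = np.asarray(mes_values, dtype=float)
    if epi.size == 0 or mes.size == 0:
        raise ValueError("both signature value lists must be non-empty")
    support = np.unique(np.concatenate([epi, mes]))
    f_e = np.searchsorted(np.sort(epi), support, side="right") / epi.size
    f_m = np.searchsorted(np.sort(mes), support, side="right") / mes.size
    diff = f_e - f_m
    idx = int(np.abs(diff).argmax())
    d = float(abs(diff[idx]))
    return d, int(np.sign(diff[idx]))


def ecdf_distance(epi_values, mes_values) -> float:
    """``max_x |F_E(x) - F_M(x)|`` over the pooled sample points."""
    return signed_ecdf_deviation(epi_values, mes_values)[0]


def ks_sample(epi_values, mes_values, alpha: float = 0.05) -> KSResult:
    """Score one sample's epithelial vs mesenchymal value sets."""
    epi = np.asarray(epi_values, dtype=float)
    mes = np.asarray(mes_values, dtype=float)
    d, dom_sign = signed_ecdf_deviation(epi, mes)
    method = "exact" if epi.size + mes.size <= EXACT_POOLED_N else "asymp"
    # alternative='greater' tests F(first sample) above F(second sample)
    p_e_gt_m = float(stats.ks_2samp(epi, mes, alternative="greater", method=method).pvalue)
    p_m_gt_e = float(stats.ks_2samp(mes, epi, alternative="greater", method=method).pvalue)
    e_dominant = p_e_gt_m < alpha  # epithelial ECDF on top -> mesenchymal sample
    m_dominant = p_m_gt_e < alpha
    if e_dominant and not m_dominant:
        sign = 1
    elif m_dominant and not e_dominant:
        sign = -1
    else:
        sign = dom_sign
    return KSResult(D=d, p_M_gt_E=p_m_gt_e, p_E_gt_M=p_e_gt_m, score=sign * d)


def score_ks(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    alpha: float = 0.05,
    min_genes_per_side: int = 3,
) -> pd.DataFrame:
    """KS scores for every sample in the matrix.

    Positive scores are mesenchymal, negative epithelial.  Returns a
    DataFrame indexed by sample with columns ``score_KS``, ``D_KS``,
    ``p_M_gt_E`` and ``p_E_gt_M``.
    """
    epi = [g for g in sig.epithelial_genes if g in expr.data.index]
    mes = [g for g in sig.mesenchymal_genes if g in expr.data.index]
    missing_side = []
    if len(epi) < min_genes_per_side:
        missing_side.append(
            f"epithelial ({len(epi)} present, need {min_genes_per_side}; "
            f"missing e.g. {sorted(set(sig.epithelial_genes) - set(epi))[:5]})"
        )
    if len(mes) < min_genes_per_side:
        missing_side.append(
            f"mesenchymal ({len(mes)} present, need {min_genes_per_side}; "
            f"missing e.g. {sorted(set(sig.mesenchymal_genes) - set(mes))[:5]})"
        )
    if missing_side:
        raise ValueError("KS signature side(s) too small after intersection: "
                         + "; ".join(missing_side))
    epi_block = expr.data.loc[epi].to_numpy()
    mes_block = expr.data.loc[mes].to_numpy()
    records = []
    for j, sample in enumerate(expr.samples):
        res = ks_sample(epi_block[:, j], mes_block[:, j], alpha=alpha)
        records.append((res.score, res.D, res.p_M_gt_E, res.p_E_gt_M))
    return pd.DataFrame(
        records,
        columns=["score_KS", "D_KS", "p_M_gt_E", "p_E_gt_M"],
        index=pd.Index(expr.samples, name="sample"),
    )
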