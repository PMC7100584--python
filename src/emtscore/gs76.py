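"""76GS EMT score: CDH1-anchored weighted sum of signature genes.

For a dataset with log2 expression ``G_ij`` (gene *j*, sample *i*) and a
signature gene list, each gene's weight ``w_j`` is its Pearson
correlation with CDH1 (E-cadherin) across the samples of that dataset.
The per-sample raw score ``sum_j w_j * G_ij`` is centered by subtracting
its grand mean, so scores always average to zero within a dataset.
Higher scores indicate a more epithelial sample: genes co-expressed with
CDH1 get positive weights and mesenchymal genes, anticorrelated with
CDH1, negative ones.

Because the weights are recomputed per dataset, the score is
dataset-relative — the same sample can score differently inside two
different cohorts.  This is intrinsic to the method, not an artifact.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)

ANCHOR_GENE = "CDH1"


class WeightError(ValueError):
    """Raised when CDH1-anchored weights cannot be computed."""


def compute_weights(
    expr: ExpressionMatrix, sig: GeneSignature, zscore_rows: bool = False
) -> pd.Series:
    """Pearson correlation of each signature gene with CDH1.

    Genes absent from the matrix are omitted (logged); a constant
    signature gene gets weight 0 with a warning, because its Pearson
    correlation is undefined but a zero contribution is the natural
    limit.  CDH1 itself, if listed, gets weight 1 by self-correlation.

    Parameters
    ----------
    zscore_rows
        Standardise each gene row before use.  Irrelevant for the
        weights themselves (Pearson is affine-invariant) but kept so
        the weight and scoring steps see the same matrix.
    """
    if expr.n_samples < 3:
        raise WeightError("need at least 3 samples to estimate correlations")
    if ANCHOR_GENE not in expr.data.index:
        raise WeightError("CDH1 is required in the expression matrix for 76GS weights")
    genes = sig.weighted_genes if sig.weighted_genes else list(sig.entries["gene"])
    present = [g for g in genes if g in expr.data.index]
    absent = sorted(set(genes) - set(present))
    if absent:
        logger.warning("76GS: %d signature genes absent from matrix: %s%s",
                       len(absent), absent[:5], "..." if len(absent) > 5 else "")
    if not present:
        raise WeightError("no signature gene present in the expression matrix")

    data = expr.data
    if zscore_rows:
        sd = data.std(axis=1, ddof=1)
        data = data.sub(data.mean(axis=1), axis=0).div(sd.replace(0.0, np.nan), axis=0)
        data = data.fillna(0.0)
    anchor = data.loc[ANCHOR_GENE].to_numpy()
    if np.std(anchor) == 0:
        raise WeightError("CDH1 is constant across samples; weights undefined")
    anchor_c = anchor - anchor.mean()
    anchor_norm = np.sqrt((anchor_c**2).sum())

    rows = data.loc[present].to_numpy()
    rows_c = rows - rows.mean(axis=1, keepdims=True)
    norms = np.sqrt((rows_c**2).sum(axis=1))
    weights = np.zeros(len(present))
    ok = norms > 0
    weights[ok] = rows_c[ok] @ anchor_c / (norms[ok] * anchor_norm)
    if (~ok).any():
        constant = [g for g, flag in zip(present, ok) if not flag]
        logger.warning("76GS: constant signature gene(s) %s given weight 0", constant[:5])
    return pd.Series(weights, index=pd.Index(present, name="gene"), name="weight")


def score_76gs(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    min_genes: int = 5,
    zscore_rows: bool = False,
) -> pd.DataFrame:
    """Centered 76GS scores for every sample in the matrix.

    Returns a DataFrame indexed by sample with columns ``score_76GS``
    (grand mean exactly centred to zero), ``n_genes_76GS`` (signature
    genes actually used) and ``coverage_76GS`` (fraction of the
    signature found in the matrix).
    """
    weights = compute_weights(expr, sig, zscore_rows=zscore_rows)
    if len(weights) < min_genes:
        raise WeightError(
            f"only {len(weights)} signature genes found; minimum is {min_genes}"
        )
    data = expr.data
    if zscore_rows:
        sd = data.std(axis=1, ddof=1)
        data = data.sub(data.mean(axis=1), axis=0).div(sd.replace(0.0, np.nan), axis=0)
        data = data.fillna(0.0)
    raw = weights.to_numpy() @ data.loc[weights.index].to_numpy()
    centered = raw - raw.mean()
    n_total = len(sig.weighted_genes) or len(sig.entries)
    return pd.DataFrame(
        {
            "score_76GS": centered,
            "n_genes_76GS": len(weights),
            "coverage_76GS": len(weights) / n_total,
        },
        index=pd.Index(expr.samples, name="sample"),
    )
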