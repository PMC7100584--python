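"""MLR EMT score: three-class logistic regression in a 2D marker space.

Each sample is mapped to a two-dimensional predictor point built from
three marker genes after a normalizer-gene platform adjustment:

    x1 = log2(VIM)_adj / log2(CDH1)_adj      (mesenchymal over epithelial)
    x2 = log2(CLDN7)_adj                     (epithelial claudin)

where "adj" subtracts, per sample, the median of the normalizer genes
from each predictor gene's log2 value, then adds a dataset-level offset
chosen so all adjusted predictor values are strictly positive (the ratio
x1 needs a positive denominator).  A three-class logistic model over
(x1, x2) yields probabilities (P_E, P_H, P_M) for the epithelial, hybrid
E/M and mesenchymal phenotypes, and the EMT score is their expectation
over the category values {0, 1, 2}:

    score = 0 * P_E + 1 * P_H + 2 * P_M  in [0, 2],

so 0 means pure E, 2 pure M, and 1 a maximally hybrid sample.  The
category call is the argmax probability.

The default model family is a nominal multinomial logit with L2
regularisation; the order structure of the phenotypes (mean score of
E-labelled < E/M-labelled < M-labelled training samples) is verified
after fitting.  A proportional-odds ordinal logit is available via
``kind="ordinal"`` for sensitivity analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data_model import CATEGORIES, ExpressionMatrix, GeneSignature

PREDICTOR_GENES = ("VIM", "CDH1", "CLDN7")


class PredictorError(ValueError):
    """Raised when predictor coordinates cannot be computed."""


def compute_predictors(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    offset: float | None = None,
) -> pd.DataFrame:
    """Map every sample into (x1, x2) predictor space.

    Parameters
    ----------
    offset
        Positivity offset added to all normalizer-adjusted predictor
        values.  When None, the smallest offset making every adjusted
        value >= 1 (and at least 0) is chosen from the data; a fitted
        :class:`MLRModel` stores the offset used at training time so
        new datasets are mapped into the same space.

    Returns
    -------
    DataFrame indexed by sample with columns ``x1``, ``x2``; the offset
    actually used is stored in ``result.attrs["offset"]``.
    """
    missing = [g for g in PREDICTOR_GENES if g not in expr.data.index]
    if missing:
        raise PredictorError(f"predictor gene(s) missing from matrix: {missing}")
    normalizers = [g for g in sig.normalizer_genes if g in expr.data.index]
    if not normalizers:
        raise PredictorError("no normalizer gene from the signature present in the matrix")
    norm_median = expr.data.loc[normalizers].median(axis=0)
    adjusted = expr.data.loc[list(PREDICTOR_GENES)].sub(norm_median, axis=1)
    if offset is None:
        offset = float(max(0.0, 1.0 - adjusted.to_numpy().min()))
    adjusted = adjusted + offset
    cdh1 = adjusted.loc["CDH1"]
    bad = cdh1 <= 0
    if bad.any():
        raise PredictorError(
            f"adjusted CDH1 <= 0 for sample(s) {list(cdh1.index[bad])[:5]}; "
            "increase the positivity offset"
        )
    points = pd.DataFrame(
        {
            "x1": adjusted.loc["VIM"] / cdh1,
            "x2": adjusted.loc["CLDN7"],
        }
    )
    points.index.name = "sample"
    if not np.isfinite(points.to_numpy()).all():
        raise PredictorError("non-finite predictor coordinate")
    points.attrs["offset"] = offset
    return points


@dataclass
class MLRModel:
    """Fitted three-class phenotype model over (x1, x2).

    For ``kind="nominal"``, ``coef`` is the (3, 2) multinomial-logit
    coefficient matrix and ``intercept`` the 3 intercepts.  For
    ``kind="ordinal"`` (proportional odds), ``coef`` is the shared
    (1, 2) slope and ``intercept`` the 2 interior thresholds.
    """

    kind: str
    coef: np.ndarray
    intercept: np.ndarray
    offset: float
    classes: tuple[str, ...] = CATEGORIES
    provenance: dict = field(default_factory=dict)

    def predict_proba(self, points: pd.DataFrame) -> np.ndarray:
        X = points[["x1", "x2"]].to_numpy(dtype=float)
        if self.kind == "nominal":
            logits = X @ self.coef.T + self.intercept
            logits -= logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            return expl / expl.sum(axis=1, keepdims=True)
        if self.kind == "ordinal":
            eta = X @ self.coef.ravel()
            cum = np.empty((X.shape[0], len(self.classes) + 1))
            cum[:, 0] = 0.0
            cum[:, -1] = 1.0
            from scipy.special import expit

            for k, tau in enumerate(self.intercept):
                cum[:, k + 1] = expit(tau - eta)
            probs = np.diff(cum, axis=1)
            return np.clip(probs, 0.0, 1.0) / np.clip(probs, 0.0, 1.0).sum(
                axis=1, keepdims=True
            )
        raise ValueError(f"unknown model kind {self.kind!r}")

    # -- persistence -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "kind": self.kind,
            "classes": list(self.classes),
            "coef": np.asarray(self.coef).tolist(),
            "intercept": np.asarray(self.intercept).tolist(),
            "offset": self.offset,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MLRModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            kind=payload["kind"],
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=np.asarray(payload["intercept"], dtype=float),
            offset=float(payload["offset"]),
            classes=tuple(payload["classes"]),
            provenance=payload.get("provenance", {}),
        )


def _training_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(",".join(map(str, y)).encode())
    return h.hexdigest()[:16]


def fit_mlr(
    points: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    kind: str = "nominal",
    C: float = 10.0,
) -> MLRModel:
    """Fit the three-class phenotype model on labelled reference points.

    ``labels`` must take the values E, E/M, M (all three present).
    Fitting is deterministic given the data, the seed and the solver
    settings.  After fitting, the phenotype order is verified on the
    training data: mean predicted score of E-labelled samples must be
    below that of E/M-labelled samples, which must be below that of
    M-labelled ones.
    """
    labels = labels.reindex(points.index)
    if labels.isna().any():
        raise ValueError("every predictor point needs a label")
    present = set(labels)
    missing = set(CATEGORIES) - present
    if missing:
        raise ValueError(f"class(es) absent from training labels: {sorted(missing)}")
    unknown = present - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    X = points[["x1", "x2"]].to_numpy(dtype=float)
    y = labels.to_numpy()
    offset = float(points.attrs.get("offset", 0.0))
    if kind == "nominal":
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, random_state=seed)
        clf.fit(X, y)
        order = np.argsort(clf.classes_)  # E < E/M < M lexicographically
        model = MLRModel(
            kind="nominal",
            coef=clf.coef_[order],
            intercept=clf.intercept_[order],
            offset=offset,
        )
    elif kind == "ordinal":
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        codes = pd.Categorical(y, categories=list(CATEGORIES), ordered=True).codes
        om = OrderedModel(codes.astype(int), X, distr="logit")
        res = om.fit(method="bfgs", maxiter=500, disp=False)
        thresholds = om.transform_threshold_params(res.params[-2:])[1:-1]
        model = MLRModel(
            kind="ordinal",
            coef=np.asarray(res.params[:2], dtype=float).reshape(1, 2),
            intercept=np.asarray(thresholds, dtype=float),
            offset=offset,
        )
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    model.provenance = {
        "seed": int(seed),
        "kind": kind,
        "C": C,
        "n_train": int(len(y)),
        "data_hash": _training_hash(X, y),
        "solver": "lbfgs" if kind == "nominal" else "bfgs",
    }
    # order check: the phenotype axis must run E -> E/M -> M
    scores = score_points(model, points)["score_MLR"]
    means = [scores[labels.to_numpy() == c].mean() for c in CATEGORIES]
    if not (means[0] < means[1] < means[2]):
        raise ValueError(
            "fitted model is not order-respecting on the training data: "
            f"mean scores E={means[0]:.3f}, E/M={means[1]:.3f}, M={means[2]:.3f}"
        )
    return model


def probability_to_score(probs: np.ndarray) -> np.ndarray:
    """Expectation of the category values {0, 1, 2}: ``P_H + 2 P_M``."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    return probs @ np.array([0.0, 1.0, 2.0])


def score_points(model: MLRModel, points: pd.DataFrame) -> pd.DataFrame:
    """Probabilities, EMT score and category call for predictor points."""
    probs = model.predict_proba(points)
    score = probability_to_score(probs)
    category = np.asarray(model.classes)[probs.argmax(axis=1)]
    return pd.DataFrame(
        {
            "score_MLR": score,
            "P_E": probs[:, 0],
            "P_H": probs[:, 1],
            "P_M": probs[:, 2],
            "category_MLR": category,
        },
        index=points.index,
    )


def score_mlr(
    expr: ExpressionMatrix, sig: GeneSignature, model: MLRModel
) -> pd.DataFrame:
    """Score a matrix with a fitted model (reusing its training offset)."""
    points = compute_predictors(expr, sig, offset=model.offset)
    return score_points(model, points)
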