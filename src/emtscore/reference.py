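"""Frozen reference MLR model for out-of-the-box scoring.

No published coefficients are shipped; instead, the package carries a
deterministic recipe: the default model is trained on the labelled
E / hybrid / M samples of the default synthetic population generated
with a fixed seed, so every installation reproduces the identical
model.  Because all generated datasets share one gene universe, this
model transfers to any matrix the generators emit; for real data, train
a cohort-specific model with :func:`emtscore.mlr.fit_mlr`.
"""

from __future__ import annotations

from functools import lru_cache

from .mlr import MLRModel, compute_predictors, fit_mlr
from .synthetic import PopulationSpec, generate_population, training_labels

#: seed of the frozen reference fit (population and solver)
REFERENCE_SEED = 17


@lru_cache(maxsize=4)
def reference_model(kind: str = "nominal") -> MLRModel:
    """Train (deterministically) and cache the default phenotype model."""
    spec = PopulationSpec(seed=REFERENCE_SEED)
    expr, labels, sigs = generate_population(spec)
    y = training_labels(labels)
    points = compute_predictors(expr.subset_samples(list(y.index)), sigs["MLR"])
    model = fit_mlr(points, y, seed=REFERENCE_SEED, kind=kind)
    model.provenance["reference"] = f"synthetic population, seed {REFERENCE_SEED}"
    return model
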