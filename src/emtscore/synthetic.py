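"""Synthetic log2 expression data with known EMT ground truth.

The generator emulates microarray-like log2 intensity matrices holding
four kinds of samples:

``E`` / ``M``
    Epithelial marker genes (including CDH1 and CLDN7) at the high base
    level and mesenchymal genes (including VIM) at the low one, or the
    reverse.
``hybrid``
    Co-expressing hybrid E/M samples: both marker programs at
    intermediate levels, with CLDN7 kept at its epithelial-state level
    (hybrid cells retain claudin junctions), which places them off the
    E-M admixture curve in MLR predictor space by construction.
``mixture``
    Bulk admixtures formed as convex combinations of the noiseless E
    and M prototypes on the linear intensity scale (transcript
    abundance of a physical cell mixture adds linearly), re-logged, at
    recorded mesenchymal fractions.

Every gene carries a fixed gene-specific baseline offset drawn once
from a dedicated RNG (the "gene universe"), shared by all generated
datasets, so the same gene means the same thing across populations,
time courses and dataset suites — a model trained on one generated
dataset transfers to another.  The three MLR marker genes carry no
baseline offset.  Gaussian noise on the log2 scale (default sd 0.5, a
typical microarray-scale dispersion) is added everywhere on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, GeneSignature

#: seed of the fixed gene-universe RNG (per-gene baseline offsets)
GENE_UNIVERSE_SEED = 20200320

#: sd (log2 units) of the per-gene baseline offsets
GENE_EFFECT_SD = 2.0


@dataclass
class PopulationSpec:
    """Parameters of a generated mixed E / hybrid / M / admixture cohort.

    Base levels are log2 intensities; ``base_high``/``base_low`` are
    the marker-on and marker-off states (default 10 and 4, a 64-fold
    dynamic range typical of strong marker genes on microarrays).
    ``noise_sd`` is the per-gene, per-sample Gaussian sd on the log2
    scale.  ``mix_fractions`` fixes the admixture mesenchymal fractions
    explicitly; when None they are drawn uniformly on [0, 1].

    Two EMT-orthogonal variance components (both 0 by default) exist to
    build cohorts whose scores should *not* correlate across methods:
    ``brightness_sd`` adds a per-sample intensity shift to every gene
    (un-normalised array brightness; it inflates the 76GS score but
    cancels in the KS ranks and in the MLR normalizer adjustment), and
    ``cldn7_jitter_sd`` adds EMT-independent claudin-7 variation (it
    moves the MLR predictor point but is one gene among many for the
    other two scorers).
    """

    n_E: int = 40
    n_M: int = 40
    n_H: int = 20
    n_mix: int = 20
    mix_fractions: list[float] | None = None
    noise_sd: float = 0.5
    n_epi_genes: int = 80
    n_mes_genes: int = 80
    n_normalizers: int = 20
    base_high: float = 10.0
    base_low: float = 4.0
    normalizer_base: float = 7.0
    hybrid_cldn7_boost: float = 3.0
    brightness_sd: float = 0.0
    cldn7_jitter_sd: float = 0.0
    n_76gs_genes: int = 76
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_E, self.n_M, self.n_H, self.n_mix) < 0:
            raise ValueError("sample counts must be non-negative")
        if self.n_E + self.n_M + self.n_H + self.n_mix == 0:
            raise ValueError("spec generates zero samples")
        if self.base_high <= self.base_low:
            raise ValueError("base_high must exceed base_low")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_epi_genes < 2 or self.n_mes_genes < 1 or self.n_normalizers < 1:
            raise ValueError("need >=2 epithelial, >=1 mesenchymal, >=1 normalizer genes")
        if self.mix_fractions is not None:
            fr = np.asarray(self.mix_fractions, dtype=float)
            if fr.size != self.n_mix:
                raise ValueError("mix_fractions length must equal n_mix")
            if ((fr < 0) | (fr > 1)).any():
                raise ValueError("mix_fractions must lie in [0, 1]")


@dataclass
class GeneUniverse:
    epi_genes: list[str]
    mes_genes: list[str]
    normalizer_genes: list[str]
    baseline: pd.Series  # per-gene fixed offset, markers at 0

    @property
    def all_genes(self) -> list[str]:
        return self.epi_genes + self.mes_genes + self.normalizer_genes


def gene_universe(
    n_epi: int = 80, n_mes: int = 80, n_norm: int = 20
) -> GeneUniverse:
    """Deterministic gene names and baseline offsets shared by all datasets."""
    epi = ["CDH1", "CLDN7"] + [f"EPI{i:03d}" for i in range(3, n_epi + 1)]
    mes = ["VIM"] + [f"MES{i:03d}" for i in range(2, n_mes + 1)]
    norm = [f"NRM{i:03d}" for i in range(1, n_norm + 1)]
    rng = np.random.default_rng(GENE_UNIVERSE_SEED)
    offsets = rng.normal(0.0, GENE_EFFECT_SD, size=len(epi) + len(mes) + len(norm))
    baseline = pd.Series(offsets, index=epi + mes + norm)
    baseline[["CDH1", "CLDN7", "VIM"]] = 0.0  # markers anchor the predictor space
    return GeneUniverse(epi, mes, norm, baseline)


def _prototypes(spec: PopulationSpec, uni: GeneUniverse) -> pd.DataFrame:
    """Noiseless E / M / hybrid mean profiles (columns E, M, H)."""
    mid = 0.5 * (spec.base_high + spec.base_low)
    proto = pd.DataFrame(index=uni.all_genes, columns=["E", "M", "H"], dtype=float)
    proto.loc[uni.epi_genes, "E"] = spec.base_high
    proto.loc[uni.mes_genes, "E"] = spec.base_low
    proto.loc[uni.epi_genes, "M"] = spec.base_low
    proto.loc[uni.mes_genes, "M"] = spec.base_high
    proto.loc[uni.epi_genes, "H"] = mid
    proto.loc[uni.mes_genes, "H"] = mid
    proto.loc["CLDN7", "H"] = mid + spec.hybrid_cldn7_boost
    proto.loc[uni.normalizer_genes, :] = spec.normalizer_base
    return proto.add(uni.baseline, axis=0)


def signatures_for(spec: PopulationSpec, uni: GeneUniverse) -> dict[str, GeneSignature]:
    """Signature files matching the generated gene universe.

    The 76GS signature draws half its genes from each marker program
    (weights are computed from data, never stored, and CDH1 is always
    included as the anchor); the KS signature uses the epithelial and
    mesenchymal genes *excluding* the three MLR predictor genes — the
    published gene lists behind the two methods were derived
    independently, and keeping the ECDF sets disjoint from the
    predictor trio means the two scorers share no single-gene channel;
    the MLR signature is the three predictors plus the normalizer
    panel.
    """
    n_each = spec.n_76gs_genes // 2
    gs76_genes = uni.epi_genes[:n_each] + uni.mes_genes[: spec.n_76gs_genes - n_each]
    sig76 = GeneSignature(
        "synthetic_76gs",
        pd.DataFrame({"gene": gs76_genes, "role": "weighted"}),
        "76GS",
    )
    ks_epi = [g for g in uni.epi_genes if g not in ("CDH1", "CLDN7")]
    ks_mes = [g for g in uni.mes_genes if g != "VIM"]
    sig_ks = GeneSignature(
        "synthetic_ks",
        pd.DataFrame(
            {
                "gene": ks_epi + ks_mes,
                "role": ["epithelial"] * len(ks_epi) + ["mesenchymal"] * len(ks_mes),
            }
        ),
        "KS_tumor",
    )
    sig_mlr = GeneSignature(
        "synthetic_mlr",
        pd.DataFrame(
            {
                "gene": ["VIM", "CDH1", "CLDN7"] + uni.normalizer_genes,
                "role": ["predictor"] * 3 + ["normalizer"] * len(uni.normalizer_genes),
            }
        ),
        "MLR",
    )
    return {"76GS": sig76, "KS": sig_ks, "MLR": sig_mlr}


def generate_population(
    spec: PopulationSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict[str, GeneSignature]]:
    """Generate a labelled cohort and its matching signatures.

    Returns ``(matrix, labels, signatures)``.  ``labels`` is indexed by
    sample with columns ``label`` in {E, M, hybrid, mixture} and
    ``true_f`` (mesenchymal fraction: 0 for E, 1 for M, the planted
    fraction for mixtures, NaN for hybrids).  Deterministic under
    ``spec.seed``.
    """
    uni = gene_universe(spec.n_epi_genes, spec.n_mes_genes, spec.n_normalizers)
    proto = _prototypes(spec, uni)
    rng = np.random.default_rng(spec.seed)

    columns: list[np.ndarray] = []
    names: list[str] = []
    label_rows: list[tuple[str, float]] = []

    for label, count, col, f in (("E", spec.n_E, "E", 0.0), ("M", spec.n_M, "M", 1.0),
                                 ("hybrid", spec.n_H, "H", np.nan)):
        base = proto[col].to_numpy()
        for i in range(count):
            columns.append(base)
            names.append(f"{label}{i + 1:03d}" if label != "hybrid" else f"H{i + 1:03d}")
            label_rows.append((label, f))

    if spec.n_mix:
        if spec.mix_fractions is not None:
            fractions = np.asarray(spec.mix_fractions, dtype=float)
        else:
            fractions = rng.uniform(0.0, 1.0, size=spec.n_mix)
        lin_e = np.exp2(proto["E"].to_numpy())
        lin_m = np.exp2(proto["M"].to_numpy())
        for i, f in enumerate(fractions):
            columns.append(np.log2((1.0 - f) * lin_e + f * lin_m))
            names.append(f"X{i + 1:03d}")
            label_rows.append(("mixture", float(f)))

    values = np.column_stack(columns)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    if spec.brightness_sd > 0:
        values = values + rng.normal(0.0, spec.brightness_sd, size=values.shape[1])
    if spec.cldn7_jitter_sd > 0:
        cldn7_row = uni.all_genes.index("CLDN7")
        values[cldn7_row] += rng.normal(0.0, spec.cldn7_jitter_sd, size=values.shape[1])
    expr = ExpressionMatrix(pd.DataFrame(values, index=uni.all_genes, columns=names))
    labels = pd.DataFrame(
        label_rows, columns=["label", "true_f"], index=pd.Index(names, name="sample")
    )
    return expr, labels, signatures_for(spec, uni)


def training_labels(labels: pd.DataFrame) -> pd.Series:
    """Map generator labels to MLR class labels, dropping admixtures."""
    keep = labels["label"].isin(["E", "hybrid", "M"])
    return labels.loc[keep, "label"].map({"E": "E", "hybrid": "E/M", "M": "M"})


def generate_timecourse(
    n_timepoints: int = 5,
    replicates: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
    spec: PopulationSpec | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict[str, GeneSignature]]:
    """EMT-induction time course: mean profiles run E -> M monotonically.

    Time point 0 is the pure-E prototype and the last time point the
    pure-M prototype, with log2-linear interpolation in between (a
    transitioning population, not a physical mixture).  Each time point
    carries ``replicates`` noised copies.  Returns ``(matrix, labels,
    signatures)`` with labels columns ``time`` and ``replicate``.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    spec = spec or PopulationSpec()
    uni = gene_universe(spec.n_epi_genes, spec.n_mes_genes, spec.n_normalizers)
    proto = _prototypes(spec, uni)
    rng = np.random.default_rng(seed)
    columns, names, rows = [], [], []
    for t in range(n_timepoints):
        w = t / (n_timepoints - 1)
        mean = (1.0 - w) * proto["E"].to_numpy() + w * proto["M"].to_numpy()
        for r in range(replicates):
            columns.append(mean)
            names.append(f"t{t}_r{r + 1}")
            rows.append((t, r + 1))
    values = np.column_stack(columns)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    expr = ExpressionMatrix(pd.DataFrame(values, index=uni.all_genes, columns=names))
    labels = pd.DataFrame(rows, columns=["time", "replicate"],
                          index=pd.Index(names, name="sample"))
    return expr, labels, signatures_for(spec, uni)


@dataclass
class SyntheticDataset:
    name: str
    expr: ExpressionMatrix
    labels: pd.DataFrame
    concordant: bool


def generate_dataset_suite(
    n_datasets: int = 20,
    fraction_concordant: float = 0.8,
    seed: int = 0,
    concordant_spec: PopulationSpec | None = None,
    discordant_spec: PopulationSpec | None = None,
) -> tuple[list[SyntheticDataset], dict[str, GeneSignature]]:
    """A collection of datasets with planted concordance outcomes.

    Concordant datasets carry a spread E-to-M gradient (E, M, hybrid
    and admixture samples), so all three scorers recover the shared
    axis and every method pair correlates strongly in the expected
    direction.  Discordant datasets contain only epithelial samples of
    near-constant EMT status, plus per-sample brightness shifts and
    EMT-independent CLDN7 variation so that no two scorers share a
    dominant variance component: each score is then driven by its own
    nuisance axis and the |R| > 0.3, p < 0.05 criterion is essentially
    never met.  Ground truth is recorded per dataset.
    """
    if not 0.0 <= fraction_concordant <= 1.0:
        raise ValueError("fraction_concordant must lie in [0, 1]")
    n_conc = round(n_datasets * fraction_concordant)
    concordant_spec = concordant_spec or PopulationSpec(
        n_E=15, n_M=15, n_H=10, n_mix=20
    )
    discordant_spec = discordant_spec or PopulationSpec(
        n_E=100, n_M=0, n_H=0, n_mix=0, brightness_sd=2.0, cldn7_jitter_sd=2.0
    )
    rng = np.random.default_rng(seed)
    datasets = []
    for i in range(n_datasets):
        concordant = i < n_conc
        spec = concordant_spec if concordant else discordant_spec
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec_i = PopulationSpec(**{**asdict(spec), "seed": sub_seed})
        expr, labels, sigs = generate_population(spec_i)
        datasets.append(
            SyntheticDataset(
                name=f"DS{i + 1:03d}", expr=expr, labels=labels, concordant=concordant
            )
        )
    uni = gene_universe(
        concordant_spec.n_epi_genes,
        concordant_spec.n_mes_genes,
        concordant_spec.n_normalizers,
    )
    return datasets, signatures_for(concordant_spec, uni)
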