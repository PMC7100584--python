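"""Core data containers and delimited-text I/O for EMT scoring.

Two containers carry everything the scorers need:

``ExpressionMatrix``
    A log2-scale expression matrix, genes (rows) x samples (columns),
    backed by a :class:`pandas.DataFrame`.  Gene symbols are normalised
    (whitespace-trimmed, upper-cased) and duplicate rows — typically
    multiple microarray probes mapping to one gene — are collapsed to
    their arithmetic mean.

``GeneSignature``
    A named list of genes with per-gene roles.  The role vocabulary is
    method-specific: the KS scorer needs ``epithelial``/``mesenchymal``
    sets, the MLR scorer needs ``predictor``/``normalizer`` genes, and
    the 76GS scorer a flat ``weighted`` list (its weights are computed
    from the data, never read from the file).

Score tables are plain :class:`pandas.DataFrame` objects indexed by
sample; :func:`validate_score_table` checks the cross-method invariants
(KS in [-1, 1], MLR in [0, 2], probabilities on the simplex, category =
argmax probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: roles a signature entry may carry, and the methods they belong to
ROLE_VOCABULARY = ("epithelial", "mesenchymal", "predictor", "normalizer", "weighted")

METHOD_ROLES = {
    "76GS": {"weighted"},
    "KS_tumor": {"epithelial", "mesenchymal"},
    "KS_cellline": {"epithelial", "mesenchymal"},
    "MLR": {"predictor", "normalizer"},
}

#: score-table column conventions shared across the package
SCORE_COLUMNS = {"76GS": "score_76GS", "KS": "score_KS", "MLR": "score_MLR"}
PROB_COLUMNS = ("P_E", "P_H", "P_M")
CATEGORY_COLUMN = "category_MLR"
CATEGORIES = ("E", "E/M", "M")


class ExpressionLoadError(ValueError):
    """Raised when an expression file fails validation."""


class SignatureError(ValueError):
    """Raised when a signature file or object fails validation."""


def _normalise_symbol(symbol: object) -> str:
    return str(symbol).strip().upper()


def _is_float(value: object) -> bool:
    try:
        float(value)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes x samples.

    Parameters
    ----------
    data
        DataFrame with unique gene symbols as the index and unique
        sample IDs as columns.  Values must be finite.
    metadata
        Optional per-sample annotations (e.g. tumor type), indexed by
        sample ID.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ExpressionLoadError("expression matrix is empty")
        df.index = pd.Index([_normalise_symbol(g) for g in df.index], name="gene")
        df.columns = pd.Index([str(c) for c in df.columns], name="sample")
        if df.index.duplicated().any():
            dupes = sorted(set(df.index[df.index.duplicated()]))
            raise ExpressionLoadError(
                f"duplicate gene symbols after normalisation: {dupes[:5]}"
                " (collapse probes before constructing the matrix)"
            )
        if df.columns.duplicated().any():
            dupes = sorted(set(df.columns[df.columns.duplicated()]))
            raise ExpressionLoadError(f"duplicate sample IDs: {dupes[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ExpressionLoadError("expression values must be numeric")
        if not np.isfinite(values).all():
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionLoadError(
                f"non-finite expression value at gene {df.index[gi]!r}, "
                f"sample {df.columns[si]!r}"
            )
        self.data = df.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        meta = self.metadata.loc[samples] if self.metadata is not None else None
        return ExpressionMatrix(self.data[samples].copy(), meta)

    def gene_row(self, gene: str) -> pd.Series:
        key = _normalise_symbol(gene)
        if key not in self.data.index:
            raise KeyError(f"gene {gene!r} not present in matrix")
        return self.data.loc[key]

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path, sep: str = "\t") -> None:
        """Write the matrix with a literal ``gene`` first-column header.

        Floats are written with Python's shortest-exact repr, so a
        write/load round trip reproduces values bit-identically.
        """
        self.data.rename_axis("gene").to_csv(path, sep=sep)


def load_expression(
    path,
    sep: str | None = None,
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Load a genes-x-samples delimited expression file.

    The first column holds gene identifiers and the header row sample
    IDs.  Duplicate gene rows (multiple probes per gene) are collapsed
    to their per-sample arithmetic mean.  Missing or non-numeric cells
    are rejected with the offending row/column named — imputation is
    deliberately out of scope because the downstream ECDF and
    correlation statistics are sensitive to it.

    Parameters
    ----------
    sep
        Field delimiter; inferred from the filename (``.csv`` -> comma,
        otherwise tab) when None.
    log2_transform
        Apply ``log2(x + 1)`` for raw-intensity input.  The default
        assumes values are already on the log2 scale, which is the
        scale all three scorers were defined on.
    """
    path = str(path)
    if sep is None:
        sep = "," if path.endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ExpressionLoadError(f"{path}: empty expression matrix")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        blank = raw[col].isna()
        if blank.any():
            gene = raw.index[blank.argmax()]
            raise ExpressionLoadError(f"{path}: blank cell at gene {gene!r}, sample {col!r}")
        try:
            # python float() parsing is the exact inverse of repr-based writing
            numeric[col] = [float(v) for v in raw[col]]
        except ValueError:
            bad = raw[col][[not _is_float(v) for v in raw[col]]]
            gene = bad.index[0]
            raise ExpressionLoadError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at gene {gene!r}, "
                f"sample {col!r}"
            ) from None
    if log2_transform:
        if (numeric.to_numpy() < 0).any():
            raise ExpressionLoadError(f"{path}: negative intensities cannot be log2(x+1) transformed")
        numeric = np.log2(numeric + 1.0)
    numeric.index = pd.Index([_normalise_symbol(g) for g in numeric.index], name="gene")
    if numeric.index.duplicated().any():
        n_before = numeric.shape[0]
        numeric = numeric.groupby(level=0, sort=False).mean()
        logger.info("collapsed %d probe rows into %d gene rows", n_before, numeric.shape[0])
    return ExpressionMatrix(numeric)


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by averaging probes.

    Each gene's row is the arithmetic mean of all probe rows mapping to
    it; probes absent from ``probe_to_gene`` are dropped (a count is
    logged).  Already gene-keyed input with an identity mapping passes
    through unchanged, so the operation is idempotent.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    mapping = {str(p): _normalise_symbol(g) for p, g in probe_to_gene.items()}
    probe_ids = [str(p) for p in probe_matrix.index]
    mapped = [p for p in probe_ids if p in mapping]
    dropped = len(probe_ids) - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    if not mapped:
        raise ValueError("no probe in the matrix is covered by the mapping")
    sub = probe_matrix.loc[mapped].astype(float)
    sub.index = pd.Index([mapping[p] for p in mapped], name="gene")
    collapsed = sub.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(collapsed)


@dataclass
class GeneSignature:
    """A named gene set with per-gene roles (and optional weights).

    ``intended_method`` constrains the roles that may appear:
    ``76GS`` -> ``weighted``; ``KS_tumor``/``KS_cellline`` ->
    ``epithelial``/``mesenchymal``; ``MLR`` -> ``predictor``/
    ``normalizer``.
    """

    name: str
    entries: pd.DataFrame  # columns: gene, role, weight
    intended_method: str = field(default="")

    def __post_init__(self) -> None:
        df = self.entries.copy()
        required = {"gene", "role"}
        if not required.issubset(df.columns):
            raise SignatureError(f"signature {self.name!r}: needs columns {sorted(required)}")
        if "weight" not in df.columns:
            df["weight"] = np.nan
        df["gene"] = [_normalise_symbol(g) for g in df["gene"]]
        df["role"] = [str(r).strip().lower() for r in df["role"]]
        unknown = sorted(set(df["role"]) - set(ROLE_VOCABULARY))
        if unknown:
            raise SignatureError(f"signature {self.name!r}: unknown role token(s) {unknown}")
        if df["gene"].duplicated().any():
            dupes = sorted(set(df["gene"][df["gene"].duplicated()]))
            raise SignatureError(f"signature {self.name!r}: duplicate gene(s) {dupes[:5]}")
        if df.shape[0] == 0:
            raise SignatureError(f"signature {self.name!r}: no entries")
        roles = set(df["role"])
        if not self.intended_method:
            self.intended_method = _infer_method(roles)
        allowed = METHOD_ROLES.get(self.intended_method)
        if allowed is None:
            raise SignatureError(
                f"signature {self.name!r}: unknown intended_method {self.intended_method!r}"
            )
        if not roles.issubset(allowed):
            raise SignatureError(
                f"signature {self.name!r}: roles {sorted(roles - allowed)} not allowed "
                f"for method {self.intended_method}"
            )
        self.entries = df.reset_index(drop=True)

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.entries.loc[self.entries["role"] == role, "gene"])

    @property
    def epithelial_genes(self) -> list[str]:
        return self.genes_with_role("epithelial")

    @property
    def mesenchymal_genes(self) -> list[str]:
        return self.genes_with_role("mesenchymal")

    @property
    def predictor_genes(self) -> list[str]:
        return self.genes_with_role("predictor")

    @property
    def normalizer_genes(self) -> list[str]:
        return self.genes_with_role("normalizer")

    @property
    def weighted_genes(self) -> list[str]:
        return self.genes_with_role("weighted")

    def swapped_roles(self) -> "GeneSignature":
        """Epithelial <-> mesenchymal role swap (KS antisymmetry checks)."""
        swap = {"epithelial": "mesenchymal", "mesenchymal": "epithelial"}
        df = self.entries.copy()
        df["role"] = [swap.get(r, r) for r in df["role"]]
        return GeneSignature(self.name + "_swapped", df, self.intended_method)

    def to_tsv(self, path) -> None:
        out = self.entries.copy()
        out.to_csv(path, sep="\t", index=False)


def _infer_method(roles: set[str]) -> str:
    if roles <= {"weighted"}:
        return "76GS"
    if roles <= {"epithelial", "mesenchymal"}:
        return "KS_tumor"
    if roles <= {"predictor", "normalizer"}:
        return "MLR"
    raise SignatureError(f"cannot infer intended method from roles {sorted(roles)}")


def load_signature(path, name: str | None = None, method: str | None = None) -> GeneSignature:
    """Load a ``gene<TAB>role[<TAB>weight]`` signature file.

    ``method`` overrides role-based inference, which matters only for
    distinguishing the tumor and cell-line variants of the KS signature
    (their file format is identical).
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    sig_name = name if name is not None else str(path)
    return GeneSignature(sig_name, df, method or "")


def validate_score_table(scores: pd.DataFrame, atol: float = 1e-9) -> None:
    """Assert the cross-method score-table invariants.

    Checks whichever of the conventional columns are present: the KS
    score lies in [-1, 1], the MLR score in [0, 2], MLR probabilities
    are non-negative and sum to one within ``atol``, and the MLR
    category equals the argmax of the probabilities.
    """
    if "score_KS" in scores:
        ks = scores["score_KS"].to_numpy()
        if not ((ks >= -1 - atol) & (ks <= 1 + atol)).all():
            raise ValueError("KS scores outside [-1, 1]")
    if "score_MLR" in scores:
        mlr = scores["score_MLR"].to_numpy()
        if not ((mlr >= -atol) & (mlr <= 2 + atol)).all():
            raise ValueError("MLR scores outside [0, 2]")
    if all(c in scores for c in PROB_COLUMNS):
        probs = scores[list(PROB_COLUMNS)].to_numpy()
        if (probs < -atol).any():
            raise ValueError("negative MLR probability")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=atol, rtol=0):
            raise ValueError("MLR probabilities do not sum to 1")
        if CATEGORY_COLUMN in scores:
            argmax = np.asarray(CATEGORIES)[probs.argmax(axis=1)]
            if not (scores[CATEGORY_COLUMN].to_numpy() == argmax).all():
                raise ValueError("MLR category does not match argmax probability")
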