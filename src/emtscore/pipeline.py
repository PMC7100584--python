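"""End-to-end orchestration: score -> concordance -> mixture analysis.

A run is a pure function of (inputs, config, seed): stage outputs are
written with fixed 6-significant-digit float formatting so repeated
runs on identical inputs are byte-identical, and the manifest records
input hashes, package version, seed and per-stage status for
reproducibility audits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import group_heterogeneity, pairwise_concordance
from .data_model import load_expression, load_signature
from .gs76 import score_76gs
from .ks import score_ks
from .mixture import (
    build_mixture_curve,
    distance_to_curve,
    rank_by_curve_distance,
    select_reference_samples,
)
from .mlr import MLRModel, compute_predictors, score_mlr
from .reference import reference_model

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

#: recognised configuration keys and their defaults (None = required/optional path)
CONFIG_DEFAULTS: dict = {
    "expr": None,  # required: expression matrix TSV
    "signatures": None,  # required: mapping method -> signature TSV
    "methods": ["76GS", "KS", "MLR"],
    "model": None,  # MLR model JSON; package reference model when omitted
    "groups": None,  # optional sample -> group TSV
    "out_dir": "emt_run",
    "seed": 0,
    "alpha": 0.05,
    "r_threshold": 0.3,
    "ks_variant": "tumor",
    "n_ref": 35,
    "aggregator": "mean",
    "grid_size": 1001,
    "mix_space": "linear",
    "top_n": [10, 20, 50, 100],
    "stages": ["score", "concordance", "mixture"],
    "log_level": "INFO",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_run_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    unknown = set(raw) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    config = {**CONFIG_DEFAULTS, **raw}
    for key in ("expr", "signatures"):
        if config[key] is None:
            raise ValueError(f"config key {key!r} is required")
    missing = [m for m in config["methods"] if m not in config["signatures"]]
    if missing:
        raise ValueError(f"no signature path for method(s): {missing}")
    if "mixture" in config["stages"] and "MLR" not in config["methods"]:
        raise ValueError("stage 'mixture' requires method 'MLR' (it ranks by MLR score)")
    if "concordance" in config["stages"] and len(config["methods"]) < 2:
        raise ValueError("stage 'concordance' requires at least two methods")
    return config


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(df: pd.DataFrame, path, index_label: str | None = "sample") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    config = validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(config["log_level"]).upper(), logging.INFO))

    manifest: dict = {
        "emtscore_version": __version__,
        "seed": config["seed"],
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    manifest["inputs"]["expr"] = _sha256(config["expr"])
    expr = load_expression(config["expr"])
    sigs = {}
    for method, sig_path in config["signatures"].items():
        manifest["inputs"][f"signature_{method}"] = _sha256(sig_path)
        method_key = {"KS": f"KS_{config['ks_variant']}"}.get(method, method)
        sigs[method] = load_signature(sig_path, method=method_key if method == "KS" else None)

    if config["model"]:
        model = MLRModel.from_json(config["model"])
        manifest["inputs"]["model"] = _sha256(config["model"])
    else:
        model = reference_model()
        manifest["inputs"]["model"] = "reference(seed=17)"

    scores = None
    if "score" in config["stages"]:
        try:
            parts = []
            if "76GS" in config["methods"]:
                parts.append(score_76gs(expr, sigs["76GS"]))
            if "KS" in config["methods"]:
                parts.append(score_ks(expr, sigs["KS"], alpha=config["alpha"]))
            if "MLR" in config["methods"]:
                parts.append(score_mlr(expr, sigs["MLR"], model))
            scores = parts[0].join(parts[1:]) if len(parts) > 1 else parts[0]
            write_table(scores, out_dir / "scores.tsv")
            manifest["outputs"].append("scores.tsv")
            manifest["stages"]["score"] = "completed"
        except Exception as exc:  # noqa: BLE001 - stage-named rewrap
            manifest["stages"]["score"] = f"failed: {exc}"
            _write_manifest(manifest, out_dir)
            raise PipelineError(f"stage 'score' failed: {exc}") from exc

    if "concordance" in config["stages"]:
        try:
            conc = pairwise_concordance(
                scores, alpha=config["alpha"], r_threshold=config["r_threshold"]
            )
            conc.to_csv(out_dir / "concordance.tsv", sep="\t",
                        float_format=FLOAT_FORMAT, index=False)
            manifest["outputs"].append("concordance.tsv")
            if config["groups"]:
                groups = pd.read_csv(config["groups"], sep="\t", index_col=0).iloc[:, 0]
                het = group_heterogeneity(scores, groups)
                write_table(het, out_dir / "group_summary.tsv", index_label="group")
                manifest["outputs"].append("group_summary.tsv")
            manifest["stages"]["concordance"] = "completed"
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["concordance"] = f"failed: {exc}"
            _write_manifest(manifest, out_dir)
            raise PipelineError(f"stage 'concordance' failed: {exc}") from exc

    if "mixture" in config["stages"]:
        try:
            pure_e, pure_m = select_reference_samples(scores, n=config["n_ref"])
            curve = build_mixture_curve(
                expr, pure_e, pure_m, sigs["MLR"],
                aggregator=config["aggregator"], grid_size=config["grid_size"],
                mix_space=config["mix_space"], offset=model.offset,
            )
            curve.as_frame().to_csv(out_dir / "mixture_curve.tsv", sep="\t",
                                    float_format=FLOAT_FORMAT, index=False)
            hybrids = scores.index[scores["category_MLR"] == "E/M"]
            points = compute_predictors(expr, sigs["MLR"], offset=model.offset)
            dist = distance_to_curve(points.loc[hybrids], curve)
            write_table(dist, out_dir / "curve_distances.tsv")
            membership_rows = []
            for n_top in config["top_n"]:
                if dist.shape[0] < 2 * n_top:
                    logger.warning("top_n=%d skipped: only %d hybrid samples",
                                   n_top, dist.shape[0])
                    continue
                closest, farthest = rank_by_curve_distance(dist, n_top)
                membership_rows += [(n_top, "closest", s) for s in closest]
                membership_rows += [(n_top, "farthest", s) for s in farthest]
            pd.DataFrame(membership_rows, columns=["N", "set", "sample"]).to_csv(
                out_dir / "curve_membership.tsv", sep="\t", index=False
            )
            manifest["outputs"] += ["mixture_curve.tsv", "curve_distances.tsv",
                                    "curve_membership.tsv"]
            manifest["stages"]["mixture"] = "completed"
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["mixture"] = f"failed: {exc}"
            _write_manifest(manifest, out_dir)
            raise PipelineError(f"stage 'mixture' failed: {exc}") from exc

    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
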