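"""Tabular input/output: expression + metadata loading and model serialization.

Expression tables are TSV/CSV with samples in rows (first column = sample id,
header = variable ids); metadata tables carry sample_id, study and class
columns.  A fitted model is serialized as a JSON container of metadata plus
TSV blocks for loadings, projections, scores and standardization parameters,
with floats written at full round-trip precision so a reloaded model predicts
bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MintModel
from .data import MultiStudyDataset, StandardizationParams

__all__ = ["load_dataset", "save_dataset", "save_model", "load_model"]

_FLOAT_FMT = "%.17g"  # lossless float64 round trip


def _read_table(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # round_trip parsing + %.17g writing makes float64 tables lossless
    return pd.read_csv(path, sep=sep, index_col=index_col, float_precision="round_trip")


def load_dataset(expression_path, metadata_path, require_class: bool = True) -> MultiStudyDataset:
    """Load an expression matrix and a sample metadata table, joined on sample id.

    The metadata must contain ``sample_id`` and ``study`` columns, plus
    ``class`` unless ``require_class`` is False.  Samples present in one table
    but not the other are an error.
    """
    x = _read_table(expression_path)
    meta = _read_table(metadata_path, index_col=None)
    if "sample_id" not in meta.columns or "study" not in meta.columns:
        raise ValueError("metadata must have 'sample_id' and 'study' columns")
    meta = meta.set_index("sample_id")
    unmatched = x.index.symmetric_difference(meta.index)
    if len(unmatched):
        raise ValueError(
            f"sample ids do not match between expression and metadata: "
            f"{unmatched.tolist()[:10]}{'...' if len(unmatched) > 10 else ''}"
        )
    meta = meta.loc[x.index]
    class_labels = None
    if "class" in meta.columns:
        class_labels = meta["class"]
    elif require_class:
        raise ValueError("metadata must have a 'class' column for training data")
    return MultiStudyDataset(
        expression=x, study_labels=meta["study"], class_labels=class_labels
    )


def save_dataset(dataset: MultiStudyDataset, expression_path, metadata_path) -> None:
    """Write the expression matrix and metadata as TSV."""
    x = dataset.expression
    x.to_csv(expression_path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)
    meta = pd.DataFrame({"sample_id": x.index, "study": dataset.study_labels.to_numpy()})
    if dataset.class_labels is not None:
        meta["class"] = dataset.class_labels.to_numpy()
    meta.to_csv(metadata_path, sep="\t", index=False)


def _write_block(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def save_model(model: MintModel, out_dir) -> Path:
    """Serialize a fitted model into ``out_dir``; returns the model.json path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    std = model.standardization
    blocks = {
        "loadings_x": (model.a, "variable"),
        "loadings_y": (model.b, "class"),
        "scores_x": (model.t_global, "sample_id"),
        "scores_y": (model.u_global, "sample_id"),
        "x_projection": (model.x_projection, "variable"),
        "y_regression": (model.y_regression, "class"),
        "std_x_mean": (std.x_mean, "study"),
        "std_x_sd": (std.x_sd, "study"),
        "std_y_mean": (std.y_mean, "study"),
    }
    if std.y_sd is not None:
        blocks["std_y_sd"] = (std.y_sd, "study")
    for name, (df, label) in blocks.items():
        _write_block(df, out / f"{name}.tsv", label)
    labels = pd.DataFrame(
        {
            "sample_id": model.t_global.index,
            "study": model.study_labels.to_numpy(),
            "class": model.class_labels.to_numpy(),
        }
    )
    labels.to_csv(out / "training_labels.tsv", sep="\t", index=False)
    meta = {
        "format": "mintpls-model",
        "version": 1,
        "n_components": model.n_components,
        "keep_x": [int(k) for k in model.keep_x],
        "class_order": list(model.class_order),
        "scale_y": bool(std.scale_y),
        "pooled_y_mean": {str(c): float(v) for c, v in std.pooled_y_mean.items()},
        "pooled_y_sd": {str(c): float(v) for c, v in std.pooled_y_sd.items()},
        "dropped_variables": list(std.dropped_variables),
        "diagnostics": model.diagnostics,
        "blocks": sorted(blocks),
    }
    path = out / "model.json"
    path.write_text(json.dumps(meta, indent=2))
    return path


def load_model(model_json_path) -> MintModel:
    """Restore a model serialized by :func:`save_model` (bit-identical predictor)."""
    path = Path(model_json_path)
    meta = json.loads(path.read_text())
    if meta.get("format") != "mintpls-model":
        raise ValueError(f"{path} is not a mintpls model container")
    d = path.parent

    def block(name):
        return pd.read_csv(d / f"{name}.tsv", sep="\t", index_col=0,
                           float_precision="round_trip")

    classes = meta["class_order"]
    labels = pd.read_csv(d / "training_labels.tsv", sep="\t", index_col=0)
    std = StandardizationParams(
        x_mean=block("std_x_mean"),
        x_sd=block("std_x_sd"),
        y_mean=block("std_y_mean"),
        y_sd=block("std_y_sd") if meta["scale_y"] else None,
        pooled_y_mean=pd.Series({c: meta["pooled_y_mean"][str(c)] for c in classes}),
        pooled_y_sd=pd.Series({c: meta["pooled_y_sd"][str(c)] for c in classes}),
        scale_y=meta["scale_y"],
        dropped_variables=meta.get("dropped_variables", []),
    )
    return MintModel(
        a=block("loadings_x"),
        b=block("loadings_y"),
        t_global=block("scores_x"),
        u_global=block("scores_y"),
        x_projection=block("x_projection"),
        y_regression=block("y_regression"),
        keep_x=[int(k) for k in meta["keep_x"]],
        standardization=std,
        class_order=classes,
        study_labels=labels["study"],
        class_labels=labels["class"],
        diagnostics=meta.get("diagnostics", []),
    )
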