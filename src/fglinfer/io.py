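"""Reading expression-style tables and writing test-result matrices.

Input orientation is samples x variables (one row per sample, header row of
variable names), the common export shape for expression matrices; a
``transpose`` flag accepts genes x samples files.  Missing values are
rejected — the method has no missing-data theory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import TestResultMatrix
from .simulate import GroupDataset

__all__ = ["read_expression_matrix", "write_results", "write_groups"]


def read_expression_matrix(
    path: str | Path,
    labels_path: str | Path,
    transpose: bool = False,
    label_column: str | None = None,
) -> GroupDataset:
    """Split a numeric sample table into per-group observation matrices.

    ``labels_path`` is a CSV with sample identifiers in the first column and
    the group label in ``label_column`` (default: the second column).  Every
    sample in the matrix must be labelled; groups keep the file's variable
    order and must contain at least two samples.
    """
    path, labels_path = Path(path), Path(labels_path)
    table = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if transpose:
        table = table.T
    bad = table.columns[~table.dtypes.apply(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric column(s) {list(bad)}")
    if table.isna().any().any():
        rows, cols = np.nonzero(table.isna().to_numpy())
        raise ValueError(
            f"{path}: missing value at row {table.index[rows[0]]!r}, "
            f"column {table.columns[cols[0]]!r}"
        )

    labels = pd.read_csv(labels_path, index_col=0)
    col = label_column if label_column is not None else labels.columns[0]
    if col not in labels.columns:
        raise ValueError(f"{labels_path}: no column named {col!r}")
    labels = labels[col].astype(str)

    missing = [s for s in labels.index if s not in table.index]
    if missing:
        raise ValueError(
            f"{labels_path}: sample {missing[0]!r} is absent from {path}"
        )
    unlabelled = [s for s in table.index if s not in labels.index]
    if unlabelled:
        raise ValueError(
            f"{path}: sample {unlabelled[0]!r} has no label in {labels_path}"
        )

    group_names = list(dict.fromkeys(labels.loc[table.index]))
    observations = []
    for g in group_names:
        members = [s for s in table.index if labels.loc[s] == g]
        block = table.loc[members].to_numpy(dtype=float)
        if block.shape[0] < 2:
            raise ValueError(
                f"group {g!r} has {block.shape[0]} sample(s); need at least 2"
            )
        observations.append(block)
    return GroupDataset(
        observations=observations,
        variable_names=list(table.columns),
        group_names=group_names,
    )


def write_groups(data: GroupDataset, out_dir: str | Path) -> list[Path]:
    """Write one samples-x-variables CSV per group; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, block in zip(data.group_names, data.observations):
        frame = pd.DataFrame(block, columns=data.variable_names)
        frame.index = [f"{name}_s{i + 1}" for i in range(block.shape[0])]
        path = out_dir / f"group_{name}.csv"
        frame.to_csv(path, index_label="sample")
        paths.append(path)
    return paths


def write_results(
    result: TestResultMatrix,
    out_dir: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write p-value/z-score/CI matrices as labelled CSVs plus metadata JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = result.variable_names or [f"V{j + 1}" for j in range(result.dimension)]
    written = {}
    matrices = {
        "pvalues": result.pvalues,
        "zscores": result.zscores,
        "statistic": result.statistic,
        "stderr": result.stderr,
        "ci_lower": result.ci_lower,
        "ci_upper": result.ci_upper,
    }
    for key, mat in matrices.items():
        path = out_dir / f"{key}.csv"
        pd.DataFrame(mat, index=names, columns=names).to_csv(path)
        written[key] = path
    meta = {
        "contrast": list(result.contrast.coefficients),
        "alpha": result.contrast.alpha,
        "variant": result.variant,
        "dimension": result.dimension,
    }
    meta.update(metadata or {})
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    written["metadata"] = meta_path
    return written
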