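"""Plain-text readers and writers for the pipeline's tables.

Everything is TSV/CSV/JSON: square matrix TSVs carry a node_id header row
and column, with a companion mask TSV for structurally missing pairs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GroundTruth
from .connectome import ConnectivityMatrix

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_node_table",
    "read_node_table",
    "write_subject_table",
    "read_subject_table",
    "write_truth_json",
    "read_truth_json",
    "read_run_tsv",
]


def write_matrix_tsv(
    matrix: ConnectivityMatrix, path: str | Path, mask_path: str | Path | None = None
) -> None:
    ids = list(matrix.node_ids)
    pd.DataFrame(matrix.weights, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="node_id"
    )
    if mask_path is not None:
        pd.DataFrame(
            matrix.structural_missing.astype(int), index=ids, columns=ids
        ).to_csv(mask_path, sep="\t", index_label="node_id")


def read_matrix_tsv(
    path: str | Path, mask_path: str | Path | None = None
) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mask = None
    if mask_path is not None:
        mask = (
            pd.read_csv(mask_path, sep="\t", index_col=0).to_numpy(dtype=int).astype(bool)
        )
    return ConnectivityMatrix(
        weights=df.to_numpy(dtype=float),
        structural_missing=mask,
        node_ids=tuple(map(str, df.columns)),
    )


def write_node_table(nodes: pd.DataFrame, path: str | Path) -> None:
    nodes.to_csv(path, sep="\t", index=False)


def read_node_table(path: str | Path) -> pd.DataFrame:
    nodes = pd.read_csv(path, sep="\t")
    nodes["node_id"] = nodes["node_id"].astype(str)
    nodes["dmn"] = nodes["dmn"].astype(bool)
    return nodes


def write_subject_table(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, index=False)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    subjects = pd.read_csv(path)
    subjects["subject_id"] = subjects["subject_id"].astype(str)
    return subjects


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "beta": {k: float(v) for k, v in truth.beta.items()},
        "sigma_e": truth.sigma_e,
        "sigma_b": truth.sigma_b,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        beta=pd.Series(payload["beta"]),
        sigma_e=float(payload["sigma_e"]),
        sigma_b=float(payload["sigma_b"]),
        seed=int(payload["seed"]),
    )


def read_run_tsv(path: str | Path) -> pd.DataFrame:
    """A run TSV: rows are time points, columns are node_ids."""
    return pd.read_csv(path, sep="\t")
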