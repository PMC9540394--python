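"""Plain-text readers and writers for the pipeline's file formats.

Everything is TSV or JSON: counts (probe_id + one column per sample),
sample metadata, training profiles with a side-car label table, log-ratio
matrices, viability and comet tables, and ground-truth JSON from the
simulator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DataError
from .normalization import LogRatioMatrix
from .seq_qc import CountMatrix
from .synthetic_data import SimTruth
from .tgx_classifier import TrainingSet


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def read_counts(
    path: str | Path, probe_to_gene: Mapping[str, str] | None = None
) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df, dict(probe_to_gene or {}))


def write_probe_map(probe_to_gene: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(probe_to_gene), "gene_id": list(probe_to_gene.values())}
    ).to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["probe_id"], df["gene_id"]))


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "is_vehicle" in df.columns:
        df["is_vehicle"] = df["is_vehicle"].astype(bool)
    return df


def write_training_set(train: TrainingSet, profiles_path, labels_path) -> None:
    df = train.profiles.copy()
    df.index.name = "gene_id"
    df.to_csv(profiles_path, sep="\t")
    pd.DataFrame(
        {"profile_id": train.labels.index, "label": train.labels.values}
    ).to_csv(labels_path, sep="\t", index=False)


def read_training_set(profiles_path, labels_path) -> TrainingSet:
    profiles = pd.read_csv(profiles_path, sep="\t", index_col=0)
    lab = pd.read_csv(labels_path, sep="\t")
    if not {"profile_id", "label"} <= set(lab.columns):
        raise DataError("labels TSV needs columns profile_id, label")
    return TrainingSet(profiles, pd.Series(lab["label"].values, index=lab["profile_id"]))


def write_log_ratios(lrm: LogRatioMatrix, path: str | Path) -> None:
    df = lrm.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_log_ratios(path: str | Path, meta: pd.DataFrame, pseudocount: float = 0.5) -> LogRatioMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    sub = meta[meta["sample_id"].isin(values.columns)].reset_index(drop=True)
    return LogRatioMatrix(values=values, meta=sub, pseudocount=pseudocount)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    import numpy as np

    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return o.__dict__
    raise TypeError(f"not JSON serializable: {type(o)}")
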