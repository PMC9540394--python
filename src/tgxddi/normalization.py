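"""Library-size normalization and construction of log2 treated/control ratios.

Counts are scaled by median-of-ratios size factors: for sample j,

    f_j = median_i ( k_ij / (prod_j k_ij)^(1/m) )

over reference probes i with positive counts in every sample. Normalized
probe values are averaged per gene symbol (multi-probe genes), and each
treated replicate is expressed as a log2 ratio to the mean of its matched
vehicle-control replicates, the expression input to the TGx-DDI classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    MissingGeneError,
    NoReferenceProbeError,
    PairingError,
)
from .seq_qc import CountMatrix

__all__ = [
    "size_factors",
    "normalize_counts",
    "aggregate_probes",
    "log2_ratios",
    "LogRatioMatrix",
]

#: metadata columns required by :func:`log2_ratios`
META_COLUMNS = ("sample_id", "chemical", "concentration_uM", "is_vehicle", "replicate")


@dataclass
class LogRatioMatrix:
    """Gene x treated-replicate log2 ratios with the metadata used to pair them."""

    values: pd.DataFrame  # genes x treated sample ids
    meta: pd.DataFrame  # rows = treated samples retained
    pseudocount: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def size_factors(
    matrix: CountMatrix, reference: pd.Series | None = None
) -> pd.Series:
    """Median-of-ratios size factor per sample.

    factor_j = median over reference probes i of count_ij / ref_i, where by
    default ref_i is the geometric mean of probe i across samples and
    reference probes are those with positive counts in every sample.

    Passing an explicit ``reference`` (probe id -> positive value) holds the
    pseudo-reference fixed; against a fixed reference the estimator is
    exactly scale-equivariant (scaling one sample's counts by c scales its
    factor by c and leaves the others untouched). With the default
    data-derived reference the exact statement is about ratios of factors,
    and re-running the estimator on its own normalized output returns equal
    factors for every sample (the fixed point).
    """
    X = matrix.counts.to_numpy(dtype=float)
    if reference is not None:
        ref_vals = reference.reindex(matrix.counts.index).to_numpy(dtype=float)
        usable = np.isfinite(ref_vals) & (ref_vals > 0)
        if not usable.any():
            raise NoReferenceProbeError("supplied reference has no usable probe")
        with np.errstate(divide="ignore"):
            log_ratios_ = np.log(X[usable]) - np.log(ref_vals[usable])[:, None]
        keep = np.isfinite(log_ratios_).all(axis=1)
        if not keep.any():
            raise NoReferenceProbeError(
                "no probe with positive counts in every sample against the reference"
            )
        factors = np.exp(np.median(log_ratios_[keep], axis=0))
    else:
        ref = (X > 0).all(axis=1)
        if not ref.any():
            raise NoReferenceProbeError(
                "no probe has positive counts in every sample; size factors undefined"
            )
        logs = np.log(X[ref])
        log_geomean = logs.mean(axis=1)
        factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=matrix.counts.columns, name="size_factor")


def normalize_counts(matrix: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    missing = [s for s in matrix.sample_ids if s not in factors.index]
    if missing:
        raise DataError(f"no size factor for samples: {missing}")
    if (factors.loc[matrix.sample_ids] <= 0).any():
        raise DataError("size factors must be positive")
    return matrix.counts / factors.loc[matrix.sample_ids]


def aggregate_probes(
    normalized: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average normalized probe values per gene symbol.

    Probes with no gene mapping are dropped. If ``genes`` is given, the
    output is restricted to (and checked against) that panel; a requested
    gene with zero mapped probes raises :class:`MissingGeneError`.
    """
    mapped = [p for p in normalized.index if p in probe_to_gene]
    sub = normalized.loc[mapped]
    gene_of = pd.Series({p: probe_to_gene[p] for p in mapped})
    out = sub.groupby(gene_of).mean()
    if genes is not None:
        missing = [g for g in genes if g not in out.index]
        if missing:
            raise MissingGeneError(f"genes with no mapped probe: {missing}")
        out = out.loc[list(genes)]
    out.index.name = "gene_id"
    return out


def log2_ratios(
    gene_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    pseudocount: float = 0.5,
) -> LogRatioMatrix:
    """Per-replicate log2 ratio of treated expression to matched vehicle mean.

    value = log2((treated + pc) / (mean of matched vehicle replicates + pc)).

    Vehicle matching keys on the chemical (each chemical carries its own
    solvent control series); an optional ``vehicle_batch`` metadata column
    additionally restricts matching to the same dose band when several
    vehicle concentrations were run.
    """
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise DataError(f"metadata missing required column {col!r}")
    meta = meta.set_index("sample_id", drop=False)
    present = [s for s in gene_matrix.columns if s in meta.index]
    if len(present) < len(gene_matrix.columns):
        missing = sorted(set(gene_matrix.columns) - set(present))
        raise DataError(f"samples missing from metadata: {missing}")

    use_batch = "vehicle_batch" in meta.columns
    vehicles = meta.loc[meta["is_vehicle"].astype(bool)]
    treated_ids, columns = [], []
    for sid in gene_matrix.columns:
        row = meta.loc[sid]
        if bool(row["is_vehicle"]):
            continue
        match = vehicles[vehicles["chemical"] == row["chemical"]]
        if use_batch:
            match = match[match["vehicle_batch"] == row["vehicle_batch"]]
        ctrl_ids = [s for s in match.index if s in gene_matrix.columns]
        if not ctrl_ids:
            raise PairingError(
                f"treated sample {sid!r} ({row['chemical']}) has no matched "
                "vehicle control among the retained samples"
            )
        ctrl_mean = gene_matrix[ctrl_ids].mean(axis=1)
        with np.errstate(divide="raise"):
            vals = np.log2(
                (gene_matrix[sid] + pseudocount) / (ctrl_mean + pseudocount)
            )
        treated_ids.append(sid)
        columns.append(vals)
    values = pd.concat(columns, axis=1)
    values.columns = treated_ids
    return LogRatioMatrix(
        values=values,
        meta=meta.loc[treated_ids].reset_index(drop=True),
        pseudocount=pseudocount,
    )
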