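"""Sample-level quality control for targeted RNA-seq count matrices.

Targeted panels (e.g. a ~3,000-probe TempO-Seq tox panel) produce a probe x
sample matrix of raw counts. Before normalization, low-quality libraries are
removed using five criteria applied to the raw counts:

1. sequencing depth below 10% of the median library size;
2. Tukey outer-fence outliers (|value - quartile| beyond 3x IQR) on the
   number of probes capturing the top 80% of the signal;
3. outer-fence outliers on the Gini coefficient of the probe-count
   distribution (inequality of read allocation across probes);
4. outer-fence outliers on the number of active probes (>= 5 mapped reads);
5. samples clustering as singletons under complete linkage on
   1 - Spearman correlation, cut at dissimilarity 0.1.

A sample is removed iff it is flagged by at least one criterion; the report
records every flag with the thresholds used so a run is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import (
    DataError,
    InsufficientSamplesError,
    UndefinedMetricError,
)

__all__ = [
    "CountMatrix",
    "QCReport",
    "gini",
    "probes_for_top_signal",
    "active_probes",
    "outer_fence_flags",
    "low_depth_flags",
    "singleton_flags",
    "run_qc",
]


@dataclass
class CountMatrix:
    """Probe-level nonnegative integer counts (probes x samples).

    Parameters
    ----------
    counts
        DataFrame indexed by probe id with one column per sample id.
    probe_to_gene
        Partial map probe id -> gene symbol. Probes absent from the map are
        panel background and are dropped at gene aggregation.
    """

    counts: pd.DataFrame
    probe_to_gene: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DataError("duplicate probe identifiers in count matrix")
        if self.counts.columns.has_duplicates:
            raise DataError("duplicate sample identifiers in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative counts in count matrix")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def drop_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s not in set(sample_ids)]
        return CountMatrix(self.counts[keep], dict(self.probe_to_gene))


@dataclass
class QCReport:
    """Per-sample QC metrics, flags and the thresholds that produced them."""

    table: pd.DataFrame  # one row per sample: metrics, flags, removed
    thresholds: dict

    @property
    def removed(self) -> list[str]:
        return list(self.table.loc[self.table["removed"], "sample_id"])

    @property
    def retained(self) -> list[str]:
        return list(self.table.loc[~self.table["removed"], "sample_id"])


def gini(counts: np.ndarray) -> float:
    """Gini coefficient of a nonnegative count vector.

    G = sum_i (2i - n - 1) x_(i) / (n * sum x) over ascending-sorted values,
    equal to the mean absolute difference divided by twice the mean.
    Ranges over [0, 1 - 1/n]: 0 for perfect equality, high when reads
    concentrate on few probes.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise UndefinedMetricError("gini undefined for empty vector")
    if (x < 0).any():
        raise UndefinedMetricError("gini requires nonnegative values")
    total = x.sum()
    if total <= 0:
        raise UndefinedMetricError("gini undefined for all-zero vector")
    xs = np.sort(x)
    n = xs.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def probes_for_top_signal(counts: np.ndarray, fraction: float = 0.8) -> int:
    """Smallest number of probes whose largest counts sum to >= fraction of total."""
    if not 0 < fraction <= 1:
        raise UndefinedMetricError("fraction must be in (0, 1]")
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if x.size == 0 or total <= 0:
        raise UndefinedMetricError("top-signal probe count undefined for zero total")
    desc = np.sort(x)[::-1]
    cum = np.cumsum(desc)
    # float-tolerant comparison so fraction=1.0 counts exactly the nonzero probes
    k = int(np.searchsorted(cum, fraction * total - 1e-9 * total) + 1)
    return min(k, int((x > 0).sum())) if fraction == 1.0 else k


def active_probes(counts: np.ndarray, min_reads: int = 5) -> int:
    """Number of probes with at least ``min_reads`` mapped reads (inclusive)."""
    x = np.asarray(counts)
    return int((x >= min_reads).sum())


def outer_fence_flags(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Flag values outside Tukey's fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use the linear-interpolation convention (numpy default).
    ``k=3`` is the outer fence (extreme outliers); flags are strict
    inequalities, so a value exactly on a fence is retained.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientSamplesError(
            f"outer fences need >= 4 values, got {v.size}"
        )
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    # strict "outside" comparison, robust to float error at the fence itself
    tol = 1e-9 * (np.abs(v).max() + 1.0)
    return (v < lo - tol) | (v > hi + tol)


def low_depth_flags(totals: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Flag samples with total reads strictly below fraction x median total."""
    t = np.asarray(totals, dtype=float)
    if t.size == 0:
        raise InsufficientSamplesError("no samples")
    cutoff = fraction * np.median(t)
    return t < cutoff


def singleton_flags(
    matrix: CountMatrix, dissimilarity: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Flag samples that cluster as singletons under 1 - Spearman, complete linkage.

    The dendrogram over samples is cut at the given dissimilarity; any
    resulting cluster of size one is flagged. Samples whose probe counts are
    constant (zero rank variance, correlation undefined) are flagged
    separately and excluded from the clustering.

    Returns
    -------
    (singleton, degenerate)
        Two boolean arrays aligned with ``matrix.sample_ids``.
    """
    sids = matrix.sample_ids
    n = len(sids)
    if n < 3:
        raise InsufficientSamplesError("singleton clustering needs >= 3 samples")
    X = matrix.counts.to_numpy(dtype=float)
    degenerate = np.array([np.ptp(X[:, j]) == 0 for j in range(n)])
    singleton = np.zeros(n, dtype=bool)
    usable = np.where(~degenerate)[0]
    if usable.size < 2:
        return singleton, degenerate
    rho = pd.DataFrame(X[:, usable]).corr(method="spearman").to_numpy()
    d = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(d, 0.0)
    if usable.size == 2:
        if d[0, 1] > dissimilarity:
            singleton[usable] = True
        return singleton, degenerate
    Z = linkage(squareform(d, checks=False), method="complete")
    labels = fcluster(Z, t=dissimilarity, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    for pos, lab in zip(usable, labels):
        if sizes[lab] == 1:
            singleton[pos] = True
    return singleton, degenerate


def run_qc(
    matrix: CountMatrix,
    *,
    fence_k: float = 3.0,
    depth_fraction: float = 0.1,
    singleton_dissimilarity: float = 0.1,
    min_reads: int = 5,
    top_fraction: float = 0.8,
) -> QCReport:
    """Apply all five QC criteria and report per-sample flags.

    Metric failures (e.g. an all-zero library) never abort the run: the
    affected sample is flagged with reason ``undefined_metric`` and excluded
    from the fence computation for that metric.
    """
    sids = matrix.sample_ids
    X = matrix.counts.to_numpy(dtype=float)
    n = len(sids)
    totals = X.sum(axis=0)

    metric_vals: dict[str, list[float]] = {"n_top80": [], "gini": [], "n_active": []}
    undefined = np.zeros(n, dtype=bool)
    for j in range(n):
        col = X[:, j]
        try:
            metric_vals["n_top80"].append(probes_for_top_signal(col, top_fraction))
            metric_vals["gini"].append(gini(col))
        except UndefinedMetricError:
            metric_vals["n_top80"].append(np.nan)
            metric_vals["gini"].append(np.nan)
            undefined[j] = True
        metric_vals["n_active"].append(active_probes(col, min_reads))

    flags: dict[str, set[str]] = {s: set() for s in sids}
    thresholds: dict = {
        "fence_k": fence_k,
        "depth_fraction": depth_fraction,
        "singleton_dissimilarity": singleton_dissimilarity,
        "min_reads": min_reads,
        "top_fraction": top_fraction,
        "quartile_convention": "linear interpolation",
    }

    for j in np.where(undefined)[0]:
        flags[sids[j]].add("undefined_metric")

    low = low_depth_flags(totals, depth_fraction)
    thresholds["depth_cutoff"] = float(depth_fraction * np.median(totals))
    for j in np.where(low)[0]:
        flags[sids[j]].add("low_depth")

    for name in ("n_top80", "gini", "n_active"):
        vals = np.asarray(metric_vals[name], dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() >= 4:
            fenced = outer_fence_flags(vals[ok], fence_k)
            q1, q3 = np.percentile(vals[ok], [25, 75])
            iqr = q3 - q1
            thresholds[f"{name}_fences"] = [
                float(q1 - fence_k * iqr),
                float(q3 + fence_k * iqr),
            ]
            for pos, bad in zip(np.where(ok)[0], fenced):
                if bad:
                    flags[sids[pos]].add(f"fence_{name}")
        else:
            thresholds[f"{name}_fences"] = None

    try:
        singleton, degenerate = singleton_flags(matrix, singleton_dissimilarity)
        for j in np.where(singleton)[0]:
            flags[sids[j]].add("singleton")
        for j in np.where(degenerate)[0]:
            flags[sids[j]].add("constant_counts")
    except InsufficientSamplesError:
        thresholds["singleton_skipped"] = "fewer than 3 samples"

    rows = []
    for j, s in enumerate(sids):
        fl = sorted(flags[s])
        rows.append(
            {
                "sample_id": s,
                "total_reads": float(totals[j]),
                "n_top80": metric_vals["n_top80"][j],
                "gini": metric_vals["gini"][j],
                "n_active": metric_vals["n_active"][j],
                "flags": ";".join(fl),
                "removed": bool(fl),
            }
        )
    return QCReport(table=pd.DataFrame(rows), thresholds=thresholds)
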