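"""Synthetic fixtures with the statistical structure the pipeline assumes.

Emulates the study design end to end without any external data: a 64-gene
biomarker training set of labelled reference profiles, 2,977-probe targeted
RNA-seq count matrices with optional injected QC failures, 10-concentration
dose series (2-1,000 uM) with matched vehicle controls in triplicate,
comet %-tail-DNA datasets, and viability curves crossing the 50% threshold.

Ground truth (labels, injected failures, effect doses) travels in a separate
:class:`SimTruth` object and is never embedded in the generated data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .seq_qc import CountMatrix
from .tgx_classifier import DDI, NON_DDI, TrainingSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "FAILURE_KINDS",
    "generate_training_set",
    "generate_count_matrix",
    "generate_comet_dataset",
    "generate_viability",
    "expected_viability",
]

#: study dose series in uM
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (
    2.0, 3.9, 7.8, 15.6, 31.3, 62.5, 125.0, 250.0, 500.0, 1000.0,
)

FAILURE_KINDS = ("low_depth", "distribution_outlier", "singleton")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror the emulated study design.

    seed
        Root seed; the same config and seed give byte-identical output.
    n_genes, n_ddi, n_nonddi
        Biomarker panel size and training profiles per class (64, 14/14).
    effect_size, noise_sd, n_responsive
        Mean |log2 ratio| shift carried by the responsive half of the panel
        in DDI profiles, per-gene Gaussian noise SD, and how many genes
        respond.
    n_probes, depth_mean, depth_dispersion, count_dispersion
        Targeted panel size (2,977), mean library size, squared CV of
        library sizes across samples, and negative-binomial dispersion of
        probe counts.
    concentrations, n_reps
        Dose series in uM and replicates per condition (3).
    """

    seed: int = 0
    n_genes: int = 64
    n_ddi: int = 14
    n_nonddi: int = 14
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_responsive: int = 32
    n_probes: int = 2977
    depth_mean: float = 1_000_000.0
    depth_dispersion: float = 0.05
    count_dispersion: float = 0.02
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_reps: int = 3

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_ddi", "n_nonddi", "n_probes", "n_reps"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.effect_size < 0:
            raise InvalidConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if not 0 <= self.n_responsive <= self.n_genes:
            raise InvalidConfigError("n_responsive must be in [0, n_genes]")
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or (np.diff(c) <= 0).any() or (c <= 0).any():
            raise InvalidConfigError("concentrations must be positive, strictly increasing")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0 or self.count_dispersion <= 0:
            raise InvalidConfigError("depth/count model parameters must be > 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth emitted alongside generated data, never inside it."""

    labels: dict[str, str] = field(default_factory=dict)
    qc_bad_samples: dict[str, str] = field(default_factory=dict)
    comet_effect_doses: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "labels": dict(self.labels),
            "qc_bad_samples": dict(self.qc_bad_samples),
            "comet_effect_doses": list(self.comet_effect_doses),
        }


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n)]


def _responsive_signs(cfg: SimConfig) -> np.ndarray:
    """Per-gene response direction: responsive genes alternate up/down.

    Deterministic in the gene index (not the seed) so count-matrix signal
    and training-set signal point the same way for any seed pair.
    """
    signs = np.zeros(cfg.n_genes)
    signs[: cfg.n_responsive] = [1.0 if i % 2 == 0 else -1.0 for i in range(cfg.n_responsive)]
    return signs


def generate_training_set(cfg: SimConfig) -> tuple[TrainingSet, SimTruth]:
    """Labelled gene x profile log2-ratio matrix with class-dependent shifts.

    DDI profiles carry a +/- ``effect_size`` mean shift on the responsive
    genes; non-DDI profiles and non-responsive genes are pure noise. With
    ``effect_size=0`` the two classes are exchangeable in distribution.
    """
    if cfg.n_ddi < 2 or cfg.n_nonddi < 2:
        raise InvalidConfigError(
            "need >= 2 training profiles per class (within-class SD)"
        )
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    ids = [f"DDI_{i + 1:02d}" for i in range(cfg.n_ddi)] + [
        f"NON_{i + 1:02d}" for i in range(cfg.n_nonddi)
    ]
    labels = pd.Series([DDI] * cfg.n_ddi + [NON_DDI] * cfg.n_nonddi, index=ids)
    means = np.zeros((cfg.n_genes, len(ids)))
    means[:, : cfg.n_ddi] = (cfg.effect_size * _responsive_signs(cfg))[:, None]
    values = means + rng.normal(0.0, cfg.noise_sd, size=means.shape)
    profiles = pd.DataFrame(values, index=genes, columns=ids)
    return TrainingSet(profiles, labels), SimTruth(labels=dict(labels))


def _meta_rows(cfg: SimConfig, chemical: str) -> list[dict]:
    rows = []
    for rep in range(1, cfg.n_reps + 1):
        rows.append(
            {
                "sample_id": f"{chemical}_VEH_r{rep}",
                "chemical": chemical,
                "concentration_uM": 0.0,
                "is_vehicle": True,
                "replicate": rep,
            }
        )
    for conc in cfg.concentrations:
        for rep in range(1, cfg.n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{chemical}_{conc:g}uM_r{rep}",
                    "chemical": chemical,
                    "concentration_uM": float(conc),
                    "is_vehicle": False,
                    "replicate": rep,
                }
            )
    return rows


def generate_count_matrix(
    cfg: SimConfig,
    inject: Mapping[int, str] | Sequence[tuple[int, str]] | None = None,
    chemical: str = "CHEM1",
    ddi_log2fc: float = 0.0,
    excluded_concentrations: Sequence[float] = (),
) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Negative-binomial probe counts for one chemical's dose series.

    Samples are the matched vehicle controls plus every concentration not in
    ``excluded_concentrations``, each in ``cfg.n_reps`` replicates. The first
    ``2 * n_genes`` probes map two-per-gene onto the biomarker panel; when
    ``ddi_log2fc`` is nonzero, responsive-gene probes in treated samples are
    shifted by ``ddi_log2fc * c / max(c)`` (a graded, DDI-like dose response).

    ``inject`` maps sample indices (column order) to a failure kind:

    * ``low_depth`` — library thinned to ~5% of the median depth;
    * ``distribution_outlier`` — reads concentrated on 5 probes (high Gini);
    * ``singleton`` — probe intensities rank-scrambled.

    Returns (counts, metadata, truth).
    """
    if cfg.n_probes < 10:
        raise InvalidConfigError("n_probes must be >= 10")
    meta = pd.DataFrame(
        [
            r
            for r in _meta_rows(cfg, chemical)
            if r["concentration_uM"] not in set(excluded_concentrations)
        ]
    )
    n_samples = len(meta)
    if n_samples < 4:
        raise InvalidConfigError("need >= 4 samples")
    spec: dict[int, str] = dict(inject) if inject else {}
    for idx, kind in spec.items():
        if not 0 <= idx < n_samples:
            raise InvalidConfigError(f"inject index {idx} out of range [0, {n_samples})")
        if kind not in FAILURE_KINDS:
            raise InvalidConfigError(f"unknown failure kind {kind!r}")

    rng = np.random.default_rng(cfg.seed)
    probe_ids = [f"P{i:04d}" for i in range(cfg.n_probes)]
    probe_to_gene = {
        probe_ids[i]: _gene_ids(cfg.n_genes)[i % cfg.n_genes]
        for i in range(min(2 * cfg.n_genes, cfg.n_probes))
    }
    # wide dynamic range across probes, as in targeted tox panels; rank
    # stability between replicate libraries then matches real assays
    base = rng.lognormal(mean=0.0, sigma=2.0, size=cfg.n_probes)
    abundance = base / base.sum()
    shape = 1.0 / cfg.depth_dispersion
    lib_sizes = rng.gamma(shape, cfg.depth_mean * cfg.depth_dispersion, size=n_samples)

    signs = _responsive_signs(cfg)
    max_c = max(cfg.concentrations)
    counts = np.empty((cfg.n_probes, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = abundance.copy()
        conc = meta.loc[j, "concentration_uM"]
        if ddi_log2fc and conc > 0:
            fc = np.ones(cfg.n_probes)
            for i in range(min(2 * cfg.n_genes, cfg.n_probes)):
                s = signs[i % cfg.n_genes]
                if s:
                    fc[i] = 2.0 ** (s * ddi_log2fc * conc / max_c)
            p = p * fc
            p = p / p.sum()
        mu = lib_sizes[j] * p
        lam = rng.gamma(1.0 / cfg.count_dispersion, cfg.count_dispersion * mu)
        counts[:, j] = rng.poisson(lam)

    truth = SimTruth()
    totals = counts.sum(axis=0)
    median_total = np.median(totals)
    for idx, kind in sorted(spec.items()):
        sid = meta.loc[idx, "sample_id"]
        col = counts[:, idx]
        if kind == "low_depth":
            target = 0.05 * median_total
            pthin = min(1.0, target / col.sum()) if col.sum() > 0 else 0.0
            counts[:, idx] = rng.binomial(col, pthin)
        elif kind == "distribution_outlier":
            hot = rng.choice(cfg.n_probes, size=5, replace=False)
            q = np.full(cfg.n_probes, 0.05 / (cfg.n_probes - 5))
            q[hot] = 0.95 / 5
            counts[:, idx] = rng.multinomial(int(col.sum()), q)
        elif kind == "singleton":
            counts[:, idx] = rng.permutation(col)
        truth.qc_bad_samples[sid] = kind

    cm = CountMatrix(
        pd.DataFrame(counts, index=probe_ids, columns=list(meta["sample_id"])),
        probe_to_gene,
    )
    return cm, meta, truth


def generate_comet_dataset(
    cfg: SimConfig,
    control_mean: float = 5.0,
    shifts: Mapping[float, float] | None = None,
    sd: float = 2.0,
    n: int | None = None,
    chemical: str = "CHEM1",
) -> tuple[pd.DataFrame, SimTruth]:
    """Gaussian %-tail-DNA values truncated to [0, 100], per dose + vehicle.

    ``shifts`` maps concentrations to additive mean shifts (in % tail DNA);
    unmentioned doses sit at ``control_mean``. Each value stands for one
    independent experiment's per-well median % tail DNA.
    """
    if not 0 <= control_mean <= 100:
        raise InvalidConfigError("control_mean must be in [0, 100]")
    if sd <= 0:
        raise InvalidConfigError("sd must be > 0")
    n = cfg.n_reps if n is None else n
    if n < 2:
        raise InvalidConfigError("need >= 2 replicates per group")
    shifts = dict(shifts or {})
    unknown = set(shifts) - set(cfg.concentrations)
    if unknown:
        raise InvalidConfigError(f"shift doses not in the series: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for conc in (0.0, *cfg.concentrations):
        mean = control_mean + (0.0 if conc == 0.0 else shifts.get(conc, 0.0))
        vals = np.clip(rng.normal(mean, sd, size=n), 0.0, 100.0)
        for rep, v in enumerate(vals, start=1):
            rows.append(
                {
                    "chemical": chemical,
                    "concentration_uM": float(conc),
                    "replicate": rep,
                    "pct_tail_dna": float(v),
                }
            )
    truth = SimTruth(
        comet_effect_doses=tuple(c for c, s in sorted(shifts.items()) if s != 0)
    )
    return pd.DataFrame(rows), truth


def expected_viability(cfg: SimConfig, ec50: float, hill: float = 4.0) -> pd.Series:
    """Noise-free Hill-curve mean viability (%) at each study concentration."""
    if ec50 <= 0:
        raise InvalidConfigError("ec50 must be > 0")
    c = np.asarray(cfg.concentrations, dtype=float)
    v = 100.0 / (1.0 + (c / ec50) ** hill)
    return pd.Series(v, index=c, name="viability_pct")


def generate_viability(
    cfg: SimConfig,
    ec50: float,
    hill: float = 4.0,
    rep_sd: float = 3.0,
    chemical: str = "CHEM1",
) -> pd.DataFrame:
    """Replicate % viability along a monotone-decreasing Hill curve.

    Expectation is 100% at zero dose and falls through 50% at ``ec50``;
    replicates add Gaussian noise (floored at 0).
    """
    means = expected_viability(cfg, ec50, hill)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for conc in (0.0, *cfg.concentrations):
        mean = 100.0 if conc == 0.0 else float(means[conc])
        vals = np.clip(rng.normal(mean, rep_sd, size=cfg.n_reps), 0.0, None)
        for rep, v in enumerate(vals, start=1):
            rows.append(
                {
                    "chemical": chemical,
                    "concentration_uM": float(conc),
                    "replicate": rep,
                    "viability_pct": float(v),
                }
            )
    return pd.DataFrame(rows)
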