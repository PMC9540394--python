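"""End-to-end orchestration: simulate -> QC -> normalize -> viability filter
-> TGx-DDI classification -> comet decision, from a single config.

A run writes, under the output directory, the generated inputs, a QC report,
the log-ratio matrix, the classification grid, per-contrast comet tables, a
consolidated ``report.json`` and a ``manifest.json`` recording every
effective parameter, the seed, and the package version.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .comet_stats import CometResult, analyze_comet
from .dose_filters import cytotoxic_exclusions
from .errors import InvalidConfigError, TgxddiError
from .normalization import aggregate_probes, log2_ratios, normalize_counts, size_factors
from .seq_qc import run_qc
from .synthetic_data import SimConfig, generate_comet_dataset, generate_count_matrix, generate_training_set, generate_viability
from .tgx_classifier import classify_conditions, select_delta_cv

log = logging.getLogger("tgxddi")

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)} - {"seed"}


@dataclass
class ChemicalSpec:
    """Per-chemical simulation settings."""

    name: str
    ddi_log2fc: float = 0.0
    ec50: float = 10_000.0
    hill: float = 4.0
    comet_shifts: dict[float, float] = field(default_factory=dict)
    comet_sd: float = 2.0
    comet_control_mean: float = 5.0
    inject: dict[int, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Complete, explicit parameterization of one pipeline run."""

    seed: int = 0
    outdir: str = "tgxddi_run"
    sim: dict[str, Any] = field(default_factory=dict)
    chemicals: list[ChemicalSpec] = field(
        default_factory=lambda: [ChemicalSpec(name="CHEM1")]
    )
    qc: dict[str, Any] = field(default_factory=dict)
    normalization: dict[str, Any] = field(default_factory=dict)
    classifier: dict[str, Any] = field(default_factory=dict)
    viability: dict[str, Any] = field(default_factory=dict)
    comet: dict[str, Any] = field(default_factory=dict)

    _SECTION_KEYS = {
        "qc": {"fence_k", "depth_fraction", "singleton_dissimilarity", "min_reads", "top_fraction"},
        "normalization": {"pseudocount"},
        "classifier": {"delta", "pa_threshold", "priors", "class_size_factor", "per_replicate"},
        "viability": {"threshold"},
        "comet": {"alpha", "assumption_alpha", "mc_draws"},
    }

    def __post_init__(self) -> None:
        unknown = set(self.sim) - _SIM_KEYS
        if unknown:
            raise InvalidConfigError(f"unknown sim keys: {sorted(unknown)}")
        if "concentrations" in self.sim:  # canonical YAML-friendly form
            self.sim["concentrations"] = [float(c) for c in self.sim["concentrations"]]
        for section, allowed in self._SECTION_KEYS.items():
            unknown = set(getattr(self, section)) - allowed
            if unknown:
                raise InvalidConfigError(f"unknown {section} keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        chems = d.pop("chemicals", None)
        specs = []
        for c in chems or [{"name": "CHEM1"}]:
            c = dict(c)
            bad = set(c) - {f.name for f in dataclasses.fields(ChemicalSpec)}
            if bad:
                raise InvalidConfigError(f"unknown chemical keys: {sorted(bad)}")
            if "comet_shifts" in c:
                c["comet_shifts"] = {float(k): float(v) for k, v in c["comet_shifts"].items()}
            if "inject" in c:
                c["inject"] = {int(k): str(v) for k, v in c["inject"].items()}
            specs.append(ChemicalSpec(**c))
        return cls(chemicals=specs, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def sim_config(self, seed: int) -> SimConfig:
        kw = dict(self.sim)
        if "concentrations" in kw:
            kw["concentrations"] = tuple(kw["concentrations"])
        return SimConfig(seed=seed, **kw)


def _chem_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + 7919 * (i + 1)) % (2**31 - 1))


def _comet_summary(res: CometResult) -> dict:
    return {
        "path": res.path,
        "anova_f": res.anova_f,
        "anova_p": res.anova_p,
        "vehicle_mean": res.vehicle_mean,
        "vehicle_median": res.vehicle_median,
        "any_significant": res.any_significant,
        "positive": res.positive,
        "notes": res.notes,
        "contrasts": [dataclasses.asdict(c) for c in res.contrasts],
        "normality_reject": None if res.normality is None else res.normality.reject,
        "variance_reject": (
            None
            if res.variance_homogeneity is None
            else res.variance_homogeneity.reject
        ),
    }


def run_pipeline(cfg: RunConfig, write: bool = True) -> dict:
    """Execute every stage for every chemical; failures are captured per
    chemical and abort the run only if all chemicals fail."""
    outdir = Path(cfg.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    train_cfg = cfg.sim_config(seed=int(cfg.seed) % (2**31 - 1))
    train, train_truth = generate_training_set(train_cfg)
    delta_param = cfg.classifier.get("delta", 0.0)
    if delta_param == "auto":
        delta = select_delta_cv(train, seed=cfg.seed)
    else:
        delta = float(delta_param)

    report: dict[str, Any] = {"chemicals": {}, "errors": {}}
    classification_frames = []
    for i, chem in enumerate(cfg.chemicals):
        try:
            report["chemicals"][chem.name] = _run_chemical(
                cfg, chem, train, delta, _chem_seed(cfg.seed, i), outdir, write
            )
        except TgxddiError as e:
            log.error("chemical %s failed: %s", chem.name, e)
            report["errors"][chem.name] = str(e)
    if not report["chemicals"]:
        raise TgxddiError(f"all chemicals failed: {report['errors']}")

    for chem, res in report["chemicals"].items():
        if res.get("classification") is not None:
            classification_frames.append(pd.DataFrame(res["classification"]))
    if write:
        tio.write_training_set(train, outdir / "training_profiles.tsv", outdir / "training_labels.tsv")
        tio.write_truth(train_truth, outdir / "training_truth.json")
        if classification_frames:
            pd.concat(classification_frames).to_csv(
                outdir / "classification_grid.tsv", sep="\t", index=False
            )
        write_report(report, cfg, delta, outdir)
    report["delta"] = delta
    return report


def _run_chemical(
    cfg: RunConfig,
    chem: ChemicalSpec,
    train,
    delta: float,
    seed: int,
    outdir: Path,
    write: bool,
) -> dict:
    sim = cfg.sim_config(seed)
    out: dict[str, Any] = {}

    viab = generate_viability(sim, ec50=chem.ec50, hill=chem.hill, chemical=chem.name)
    excluded = cytotoxic_exclusions(viab, **cfg.viability).get(chem.name, [])
    out["excluded_concentrations"] = excluded

    cm, meta, truth = generate_count_matrix(
        sim,
        inject=chem.inject or None,
        chemical=chem.name,
        ddi_log2fc=chem.ddi_log2fc,
        excluded_concentrations=excluded,
    )
    qc = run_qc(cm.drop_samples([]), **cfg.qc)
    out["qc_removed"] = qc.removed
    out["qc_truth"] = truth.qc_bad_samples
    retained = cm.drop_samples(qc.removed)
    meta_kept = meta[meta["sample_id"].isin(retained.sample_ids)].reset_index(drop=True)

    factors = size_factors(retained)
    normed = normalize_counts(retained, factors)
    genes = aggregate_probes(normed, retained.probe_to_gene, genes=train.gene_ids)
    lrm = log2_ratios(genes, meta_kept, **cfg.normalization)

    cls_kw = {k: v for k, v in cfg.classifier.items() if k not in ("delta",)}
    grid = classify_conditions(train, lrm, delta=delta, **cls_kw)
    out["classification"] = grid.to_dict(orient="records")

    comet_data, comet_truth = generate_comet_dataset(
        sim,
        control_mean=chem.comet_control_mean,
        shifts=chem.comet_shifts,
        sd=chem.comet_sd,
        chemical=chem.name,
    )
    comet_res = analyze_comet(
        comet_data, {chem.name: excluded}, seed=seed, **cfg.comet
    )[chem.name]
    out["comet"] = _comet_summary(comet_res)
    out["comet_truth"] = list(comet_truth.comet_effect_doses)

    if write:
        cdir = outdir / chem.name
        cdir.mkdir(parents=True, exist_ok=True)
        tio.write_counts(cm, cdir / "counts.tsv")
        tio.write_probe_map(cm.probe_to_gene, cdir / "probe_map.tsv")
        tio.write_meta(meta, cdir / "metadata.tsv")
        qc.table.to_csv(cdir / "qc_report.tsv", sep="\t", index=False)
        tio.write_json(qc.thresholds, cdir / "qc_thresholds.json")
        viab.to_csv(cdir / "viability.tsv", sep="\t", index=False)
        tio.write_json({"excluded_concentrations": excluded}, cdir / "cytotoxic.json")
        tio.write_log_ratios(lrm, cdir / "log_ratios.tsv")
        grid.to_csv(cdir / "classification.tsv", sep="\t", index=False)
        comet_data.to_csv(cdir / "comet_data.tsv", sep="\t", index=False)
        tio.write_json(out["comet"], cdir / "comet_result.json")
    return out


def write_report(report: dict, cfg: RunConfig, delta: float, outdir: Path) -> None:
    """Consolidated JSON report + manifest of every effective parameter."""
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_json(report, outdir / "report.json")
    sim_defaults = dataclasses.asdict(cfg.sim_config(cfg.seed))
    manifest = {
        "package": "tgxddi",
        "version": __version__,
        "seed": cfg.seed,
        "sim": sim_defaults,
        "qc": {**_defaults_qc(), **cfg.qc},
        "normalization": {"pseudocount": 0.5, **cfg.normalization},
        "classifier": {
            "delta": delta,
            "pa_threshold": 0.9,
            "priors": "size",
            "class_size_factor": "minus",
            **{k: v for k, v in cfg.classifier.items() if k != "delta"},
        },
        "viability": {"threshold": 50.0, **cfg.viability},
        "comet": {
            "alpha": 0.05,
            "assumption_alpha": 0.05,
            "mc_draws": 100_000,
            **cfg.comet,
        },
        "chemicals": [dataclasses.asdict(c) for c in cfg.chemicals],
    }
    tio.write_json(manifest, outdir / "manifest.json")


def _defaults_qc() -> dict:
    return {
        "fence_k": 3.0,
        "depth_fraction": 0.1,
        "singleton_dissimilarity": 0.1,
        "min_reads": 5,
        "top_fraction": 0.8,
    }
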