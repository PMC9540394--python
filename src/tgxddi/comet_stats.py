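"""Dose-response decision procedure for comet-assay % tail DNA.

Per chemical, one-way ANOVA across the vehicle and dose groups with two
assumption checks — Anderson-Darling normality of the residuals and
Fligner-Killeen homogeneity of group variances. If either fails at the
assumption alpha, the whole analysis is repeated on global midranks (the
rank-transform nonparametric ANOVA). Each dose is then contrasted against
the vehicle with pooled-variance t statistics, and the raw p-values are
FWER-adjusted by Dunnett's many-to-one method (the null distribution of
max_j |T_j| over the equicorrelated multivariate t, estimated by seeded
Monte Carlo).

A chemical is called positive iff some NON-cytotoxic concentration shows a
significant (adjusted p < alpha) increase in mean % tail DNA over the
vehicle. Cytotoxic concentrations are analysed and reported but never drive
the call. Each input value is a per-experiment summary (the per-well median
% tail DNA); group summaries report both the mean and median of those
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DataError,
    DegenerateSampleError,
    InvalidConfigError,
)

__all__ = [
    "ADResult",
    "FKResult",
    "ContrastResult",
    "CometResult",
    "anderson_darling_normal",
    "fligner_killeen",
    "oneway_anova",
    "rank_anova",
    "dunnett_adjust",
    "analyze_comet",
]

_AD_MC_SEED = 186283  # fixed: the null critical table is part of the method
_AD_MC_REPS = 20000
_ad_critical_cache: dict[tuple[int, float], float] = {}


def _ad_statistic(values: np.ndarray) -> tuple[float, float]:
    """A^2 for the composite normal hypothesis and its small-sample correction."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero variance: normality test undefined")
    z = (x - mu) / sd
    logcdf = stats.norm.logcdf(z)
    logsf = stats.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - ((2 * i - 1) * (logcdf + logsf[::-1])).sum() / n
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    return float(a2), float(a2_star)


def _ad_critical(n: int, alpha: float) -> float:
    """Monte-Carlo (1 - alpha) quantile of the corrected null statistic.

    Seeded and cached: the same critical value is reproduced in every run.
    """
    key = (n, round(alpha, 6))
    if key not in _ad_critical_cache:
        rng = np.random.default_rng(_AD_MC_SEED)
        sims = np.empty(_AD_MC_REPS)
        draws = rng.standard_normal((_AD_MC_REPS, n))
        for r in range(_AD_MC_REPS):
            _, sims[r] = _ad_statistic(draws[r])
        _ad_critical_cache[key] = float(np.quantile(sims, 1.0 - alpha))
    return _ad_critical_cache[key]


@dataclass
class ADResult:
    a2: float
    a2_star: float
    critical: float
    alpha: float
    reject: bool


@dataclass
class FKResult:
    statistic: float
    df: int
    p: float
    reject: bool


@dataclass
class ContrastResult:
    concentration_uM: float
    n: int
    mean_pct_tail: float
    median_pct_tail: float
    t: float
    p_raw: float
    p_adjusted: float
    cytotoxic: bool
    significant: bool
    positive: bool  # significant AND mean above vehicle AND non-cytotoxic


@dataclass
class CometResult:
    chemical: str
    normality: ADResult | None
    variance_homogeneity: FKResult | None
    path: str  # "parametric" | "rank"
    anova_f: float
    anova_p: float
    vehicle_mean: float
    vehicle_median: float
    vehicle_n: int
    contrasts: list[ContrastResult]
    alpha: float
    any_significant: bool  # FWER event over non-cytotoxic contrasts
    positive: bool  # directional overall call
    notes: list[str] = field(default_factory=list)


def anderson_darling_normal(values, alpha: float = 0.05) -> ADResult:
    """Anderson-Darling composite-normality test at the given alpha.

    The decision compares A*^2 = A^2 (1 + 0.75/n + 2.25/n^2) with a seeded
    Monte-Carlo null critical value for the sample size at hand.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise DataError("Anderson-Darling needs n >= 5")
    a2, a2_star = _ad_statistic(x)
    crit = _ad_critical(x.size, alpha)
    return ADResult(a2, a2_star, crit, alpha, a2_star > crit)


def fligner_killeen(groups: Sequence[np.ndarray], alpha: float = 0.05) -> FKResult:
    """Fligner-Killeen homogeneity-of-variances test (normal scores on ranks
    of |x - group median|, chi-square reference with k - 1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise DataError("Fligner-Killeen needs >= 2 groups of >= 2 values")
    absdev = np.concatenate([np.abs(g - np.median(g)) for g in groups])
    if np.all(absdev == 0):
        raise DegenerateSampleError("all absolute deviations zero")
    stat, p = stats.fligner(*groups)
    return FKResult(float(stat), len(groups) - 1, float(p), p < alpha)


def oneway_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p with (k - 1, N - k) df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DataError("ANOVA needs >= 2 groups")
    n_total = sum(g.size for g in groups)
    if n_total <= len(groups):
        raise DataError("ANOVA needs total n > number of groups")
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within == 0:
        raise DegenerateSampleError("zero within-group variance everywhere")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def rank_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA on global midranks (rank-transform nonparametric ANOVA)."""
    ranked = _rank_transform(groups)
    return oneway_anova(ranked)


def _rank_transform(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = stats.rankdata(flat, method="average")
    out, pos = [], 0
    for g in groups:
        k = len(g)
        out.append(ranks[pos : pos + k])
        pos += k
    return out


def dunnett_adjust(
    treated: Sequence[np.ndarray],
    control: np.ndarray,
    alternative: str = "two-sided",
    mc_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Many-to-one contrasts vs control with Dunnett FWER adjustment.

    Pooled-variance t statistics t_i = (mean_i - mean_0) / sqrt(MSE (1/n_i +
    1/n_0)) with df = N - k. The adjusted p-value is P(max_j |T_j| >= |t_i|)
    under the joint null multivariate t (correlation induced by the shared
    control; 0.5 at equal n), estimated by seeded Monte Carlo, and floored at
    the raw p so adjusted >= raw always holds.
    """
    if alternative != "two-sided":
        raise InvalidConfigError("only two-sided contrasts are supported")
    control = np.asarray(control, dtype=float)
    treated = [np.asarray(g, dtype=float) for g in treated]
    if len(treated) < 1:
        raise DataError("need >= 1 treated group")
    if control.size < 2 or any(g.size < 2 for g in treated):
        raise DataError("each tested group needs n >= 2")
    groups = [control, *treated]
    n = np.array([g.size for g in groups])
    N = int(n.sum())
    k = len(groups)
    df = N - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    if mse == 0:
        raise DegenerateSampleError("zero pooled variance: contrasts undefined")
    t_obs = np.array(
        [
            (g.mean() - control.mean()) / np.sqrt(mse * (1.0 / g.size + 1.0 / control.size))
            for g in treated
        ]
    )
    p_raw = 2.0 * stats.t.sf(np.abs(t_obs), df)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((mc_draws, k))
    s2 = rng.chisquare(df, size=mc_draws) / df
    scale = np.sqrt(1.0 / n[1:] + 1.0 / n[0])
    t_null = (z[:, 1:] / np.sqrt(n[1:]) - z[:, [0]] / np.sqrt(n[0])) / (
        np.sqrt(s2)[:, None] * scale
    )
    max_abs = np.abs(t_null).max(axis=1)
    p_adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
    p_adj = np.maximum(p_adj, p_raw)
    return pd.DataFrame(
        {
            "t": t_obs,
            "p_raw": p_raw,
            "p_adjusted": np.minimum(p_adj, 1.0),
            "df": df,
        }
    )


def analyze_comet(
    data: pd.DataFrame,
    cytotoxic: Mapping[str, Iterable[float]] | Iterable[float] | None = None,
    alpha: float = 0.05,
    assumption_alpha: float = 0.05,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> dict[str, CometResult]:
    """Full comet decision per chemical in ``data``.

    ``data`` needs columns chemical, concentration_uM (0 = vehicle),
    replicate, pct_tail_dna. ``cytotoxic`` is either {chemical: doses} or a
    flat dose collection applied to every chemical. Assumption checks run on
    the parametric ANOVA residuals / groups; failure of either switches
    contrasts and ANOVA to the rank scale. The overall call is positive iff
    some non-cytotoxic dose has adjusted p < alpha and a group mean above the
    vehicle mean.
    """
    required = {"chemical", "concentration_uM", "replicate", "pct_tail_dna"}
    missing = required - set(data.columns)
    if missing:
        raise DataError(f"comet table missing columns: {sorted(missing)}")
    vals = data["pct_tail_dna"].to_numpy(dtype=float)
    if ((vals < 0) | (vals > 100)).any():
        raise DataError("% tail DNA values must be in [0, 100]")

    results: dict[str, CometResult] = {}
    for chem, g in data.groupby("chemical", sort=True):
        cyt: set[float] = set()
        if cytotoxic:
            if isinstance(cytotoxic, Mapping):
                cyt = {float(c) for c in cytotoxic.get(chem, ())}
            else:
                cyt = {float(c) for c in cytotoxic}
        results[chem] = _analyze_one(
            chem, g, cyt, alpha, assumption_alpha, mc_draws, seed
        )
    return results


def _analyze_one(
    chem: str,
    g: pd.DataFrame,
    cytotoxic: set[float],
    alpha: float,
    assumption_alpha: float,
    mc_draws: int,
    seed: int,
) -> CometResult:
    notes: list[str] = []
    by_conc = {
        float(c): sub["pct_tail_dna"].to_numpy(dtype=float)
        for c, sub in g.groupby("concentration_uM", sort=True)
    }
    if 0.0 not in by_conc:
        raise DataError(f"chemical {chem!r} has no vehicle group (concentration 0)")
    control = by_conc.pop(0.0)
    if control.size < 2:
        raise DataError(f"chemical {chem!r}: vehicle group needs n >= 2")
    doses, dropped = [], []
    for c in sorted(by_conc):
        if by_conc[c].size < 2:
            dropped.append(c)
        else:
            doses.append(c)
    if dropped:
        warnings.warn(
            f"{chem}: single-replicate dose groups excluded from testing: {dropped}",
            stacklevel=2,
        )
        notes.append(f"excluded single-replicate doses: {dropped}")
    if not doses:
        raise DataError(f"chemical {chem!r}: no testable dose group (n >= 2)")
    groups = [control] + [by_conc[c] for c in doses]

    ad: ADResult | None
    fk: FKResult | None
    assumptions_ok = True
    residuals = np.concatenate([gr - gr.mean() for gr in groups])
    try:
        ad = anderson_darling_normal(residuals, assumption_alpha)
        if ad.reject:
            assumptions_ok = False
    except (DegenerateSampleError, DataError) as e:
        ad = None
        assumptions_ok = False
        notes.append(f"normality check degenerate ({e}); rank path")
    try:
        fk = fligner_killeen(groups, assumption_alpha)
        if fk.reject:
            assumptions_ok = False
    except DegenerateSampleError as e:
        fk = None
        assumptions_ok = False
        notes.append(f"variance check degenerate ({e}); rank path")

    path = "parametric" if assumptions_ok else "rank"
    analysis_groups = groups if assumptions_ok else _rank_transform(groups)
    try:
        f, p = oneway_anova(analysis_groups)
    except DegenerateSampleError:
        f, p = 0.0, 1.0
        notes.append("degenerate ANOVA (zero within-group variance); F set to 0")
    adj = dunnett_adjust(
        analysis_groups[1:], analysis_groups[0], mc_draws=mc_draws, seed=seed
    )

    contrasts = []
    any_sig = False
    positive = False
    veh_mean = float(control.mean())
    for i, c in enumerate(doses):
        arr = by_conc[c]
        is_cyt = c in cytotoxic
        sig = bool(adj.loc[i, "p_adjusted"] < alpha)
        pos = sig and (arr.mean() > veh_mean) and not is_cyt
        if sig and not is_cyt:
            any_sig = True
        positive = positive or pos
        contrasts.append(
            ContrastResult(
                concentration_uM=c,
                n=arr.size,
                mean_pct_tail=float(arr.mean()),
                median_pct_tail=float(np.median(arr)),
                t=float(adj.loc[i, "t"]),
                p_raw=float(adj.loc[i, "p_raw"]),
                p_adjusted=float(adj.loc[i, "p_adjusted"]),
                cytotoxic=is_cyt,
                significant=sig,
                positive=pos,
            )
        )
    return CometResult(
        chemical=chem,
        normality=ad,
        variance_homogeneity=fk,
        path=path,
        anova_f=f,
        anova_p=p,
        vehicle_mean=veh_mean,
        vehicle_median=float(np.median(control)),
        vehicle_n=control.size,
        contrasts=contrasts,
        alpha=alpha,
        any_significant=any_sig,
        positive=positive,
        notes=notes,
    )
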