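"""Three-pronged TGx-DDI classification of exposure expression profiles.

A transcriptomic biomarker panel (64 genes in the published application)
trained on reference chemicals with known DNA-damage-inducing (DDI) status
classifies a test exposure by three parallel analyses:

* **PA** — nearest-shrunken-centroid (NSC) class probabilities; a call is
  made only when the winning class probability exceeds 0.90 (strictly),
  otherwise the condition is *unclassified*.
* **PCA** — the profile is projected onto the training set's principal
  components; PC1 < 0 means DDI (the stored loading orientation makes the
  mean DDI training score negative), otherwise non-DDI.
* **HC** — the profile is clustered jointly with the training profiles
  (average linkage, Euclidean distance); it inherits the majority label of
  the training profiles in its cluster at the two-cluster cut, or *unknown*
  if it forms a singleton.

Integration: any DDI prong => DDI; all three prongs non-DDI => non-DDI;
anything else => unclassified.

The NSC model follows the shrunken-centroid method: per-gene t-like scores

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),

soft-thresholded by the shrinkage Delta, with s_i the pooled within-class
SD, s0 the median of the s_i, and m_k a class-size factor (two conventions
exist in the literature, sqrt(1/n_k - 1/n) and sqrt(1/n_k + 1/n); both are
supported, default "minus"). Class probabilities come from the Gaussian
discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import (
    AlignmentError,
    DataError,
    DegenerateDispersionError,
    InvalidConfigError,
    StratifiedFoldingError,
)
from .normalization import LogRatioMatrix

__all__ = [
    "DDI",
    "NON_DDI",
    "UNCLASSIFIED",
    "UNKNOWN",
    "TrainingSet",
    "NSCModel",
    "PCAModel",
    "fit_nsc",
    "class_probabilities",
    "pa_call",
    "fit_pca",
    "pca_call",
    "hc_call",
    "integrate",
    "classify_conditions",
    "select_delta_cv",
]

DDI = "DDI"
NON_DDI = "nonDDI"
UNCLASSIFIED = "unclassified"
UNKNOWN = "unknown"


@dataclass
class TrainingSet:
    """Reference-chemical expression profiles with DDI / non-DDI labels.

    ``profiles`` is a gene x profile matrix of log2 ratios; ``labels`` maps
    each profile id to "DDI" or "nonDDI".
    """

    profiles: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.profiles.columns)
        if self.labels.isna().any():
            raise DataError("every training profile needs a label")
        bad = set(self.labels.unique()) - {DDI, NON_DDI}
        if bad:
            raise DataError(f"unexpected training labels: {sorted(bad)}")
        counts = self.labels.value_counts()
        if counts.get(DDI, 0) < 2 or counts.get(NON_DDI, 0) < 2:
            raise DataError("need >= 2 training profiles per class")
        if self.profiles.isna().any().any():
            raise DataError("training profiles contain missing values")
        if self.profiles.shape[0] == 0:
            raise DataError("empty gene panel")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def classes(self) -> list[str]:
        return [DDI, NON_DDI]


@dataclass
class NSCModel:
    gene_ids: list[str]
    classes: list[str]
    overall_centroid: np.ndarray  # (genes,)
    class_centroids: np.ndarray  # (genes, classes)
    shrunken_centroids: np.ndarray  # (genes, classes)
    pooled_sd: np.ndarray  # s_i, (genes,)
    s0: float
    m_k: np.ndarray  # (classes,)
    delta: float
    d_scores: np.ndarray  # d_ik, (genes, classes)
    d_shrunk: np.ndarray  # d'_ik, (genes, classes)
    priors: np.ndarray  # (classes,)
    class_size_factor: str = "minus"

    @property
    def n_nonzero_genes(self) -> int:
        """Genes with a surviving (nonzero) shrunken score in any class."""
        return int((np.abs(self.d_shrunk) > 0).any(axis=1).sum())


@dataclass
class PCAModel:
    gene_ids: list[str]
    center: np.ndarray  # training gene means, (genes,)
    loadings: np.ndarray  # (components, genes), orthonormal rows
    explained_variance: np.ndarray


def _align(gene_ids: Sequence[str], profile: pd.Series | np.ndarray) -> np.ndarray:
    if isinstance(profile, pd.Series):
        missing = [g for g in gene_ids if g not in profile.index]
        extra = [g for g in profile.index if g not in set(gene_ids)]
        if missing or extra:
            raise AlignmentError(
                f"gene mismatch: missing={missing[:5]} extra={extra[:5]}"
            )
        return profile.loc[list(gene_ids)].to_numpy(dtype=float)
    arr = np.asarray(profile, dtype=float)
    if arr.shape != (len(gene_ids),):
        raise AlignmentError(
            f"profile length {arr.shape} does not match panel of {len(gene_ids)}"
        )
    return arr


def fit_nsc(
    train: TrainingSet,
    delta: float = 0.0,
    priors: Literal["size", "equal"] | Sequence[float] = "size",
    class_size_factor: Literal["minus", "plus"] = "minus",
) -> NSCModel:
    """Fit the shrunken-centroid model at shrinkage ``delta``.

    ``delta=0`` reproduces the plain class centroids; as ``delta`` grows the
    centroids shrink toward the overall centroid and genes drop out of the
    discriminant.
    """
    if delta < 0:
        raise InvalidConfigError("delta must be >= 0")
    X = train.profiles.to_numpy(dtype=float)  # genes x n
    n = X.shape[1]
    classes = train.classes
    members = [np.asarray(train.labels.to_numpy() == c) for c in classes]
    n_k = np.array([m.sum() for m in members])

    overall = X.mean(axis=1)
    cents = np.column_stack([X[:, m].mean(axis=1) for m in members])
    within_ss = sum(
        ((X[:, m] - cents[:, [k]]) ** 2).sum(axis=1) for k, m in enumerate(members)
    )
    pooled_sd = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    if s0 == 0 and (pooled_sd == 0).all():
        raise DegenerateDispersionError(
            "all pooled within-class SDs are zero; discriminant undefined"
        )
    if class_size_factor == "minus":
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    elif class_size_factor == "plus":
        m_k = np.sqrt(1.0 / n_k + 1.0 / n)
    else:
        raise InvalidConfigError("class_size_factor must be 'minus' or 'plus'")

    denom = (m_k[None, :]) * (pooled_sd + s0)[:, None]
    d = (cents - overall[:, None]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + denom * d_shrunk

    if isinstance(priors, str):
        if priors == "size":
            pi = n_k / n
        elif priors == "equal":
            pi = np.full(len(classes), 1.0 / len(classes))
        else:
            raise InvalidConfigError("priors must be 'size', 'equal' or a sequence")
    else:
        pi = np.asarray(priors, dtype=float)
        if pi.shape != (len(classes),) or (pi <= 0).any():
            raise InvalidConfigError("priors must be positive, one per class")
        pi = pi / pi.sum()

    return NSCModel(
        gene_ids=train.gene_ids,
        classes=classes,
        overall_centroid=overall,
        class_centroids=cents,
        shrunken_centroids=shrunken,
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        delta=float(delta),
        d_scores=d,
        d_shrunk=d_shrunk,
        priors=pi,
        class_size_factor=class_size_factor,
    )


def discriminant_scores(model: NSCModel, profile) -> np.ndarray:
    """Gaussian discriminant delta_k(x) for each class (smaller = closer)."""
    x = _align(model.gene_ids, profile)
    w = (model.pooled_sd + model.s0) ** 2
    sq = ((x[:, None] - model.shrunken_centroids) ** 2 / w[:, None]).sum(axis=0)
    return sq - 2.0 * np.log(model.priors)


def class_probabilities(model: NSCModel, profile) -> tuple[float, float]:
    """(p_DDI, p_nonDDI): softmax of -delta_k/2, shifted for stability."""
    delta_k = discriminant_scores(model, profile)
    shifted = delta_k - delta_k.min()
    w = np.exp(-shifted / 2.0)
    p = w / w.sum()
    return float(p[model.classes.index(DDI)]), float(p[model.classes.index(NON_DDI)])


def pa_call(probs: tuple[float, float], threshold: float = 0.90) -> str:
    """Probability-analysis call: a class wins only with probability > threshold."""
    p_ddi, p_non = probs
    if not np.isclose(p_ddi + p_non, 1.0, atol=1e-8):
        raise DataError("class probabilities must sum to 1")
    if p_ddi > threshold:
        return DDI
    if p_non > threshold:
        return NON_DDI
    return UNCLASSIFIED


def fit_pca(train: TrainingSet) -> PCAModel:
    """PCA of the training profiles (observations = profiles, centered, unscaled).

    PC1's sign is fixed so the mean score of the DDI training profiles is
    negative, anchoring the published decision rule PC1 < 0 => DDI.
    """
    if train.profiles.shape[1] < 2:
        raise DataError("PCA needs >= 2 training profiles")
    X = train.profiles.to_numpy(dtype=float).T  # n x genes
    center = X.mean(axis=0)
    Xc = X - center
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    explained = s**2 / (X.shape[0] - 1)
    ddi_mask = train.labels.to_numpy() == DDI
    pc1_scores = Xc @ vt[0]
    if pc1_scores[ddi_mask].mean() > 0:
        vt = vt.copy()
        vt[0] = -vt[0]
    return PCAModel(
        gene_ids=train.gene_ids,
        center=center,
        loadings=vt,
        explained_variance=explained,
    )


def pca_call(model: PCAModel, profile) -> tuple[float, str]:
    """Project onto PC1; PC1 < 0 => DDI, otherwise (including 0) non-DDI."""
    x = _align(model.gene_ids, profile)
    pc1 = float((x - model.center) @ model.loadings[0])
    return pc1, (DDI if pc1 < 0 else NON_DDI)


def hc_call(train: TrainingSet, profile) -> str:
    """Cluster the query with the training profiles; inherit the cluster label.

    Average-linkage, Euclidean-distance agglomerative clustering of the
    training profiles plus the query, cut at two clusters. The query takes
    the majority training label of its cluster; a singleton query (or a tied
    vote) is *unknown*.
    """
    x = _align(train.gene_ids, profile)
    M = np.column_stack([train.profiles.to_numpy(dtype=float), x]).T
    Z = linkage(M, method="average", metric="euclidean")
    labels = fcluster(Z, t=2, criterion="maxclust")
    q = labels[-1]
    mates = np.where(labels[:-1] == q)[0]
    if mates.size == 0:
        return UNKNOWN
    votes = train.labels.iloc[mates].value_counts()
    n_ddi, n_non = votes.get(DDI, 0), votes.get(NON_DDI, 0)
    if n_ddi == n_non:
        return UNKNOWN
    return DDI if n_ddi > n_non else NON_DDI


def integrate(pa: str, pca: str, hc: str) -> str:
    """Any-positive integration of the three prong calls."""
    calls = (pa, pca, hc)
    if DDI in calls:
        return DDI
    if all(c == NON_DDI for c in calls):
        return NON_DDI
    return UNCLASSIFIED


def classify_conditions(
    train: TrainingSet,
    lrm: LogRatioMatrix,
    *,
    delta: float = 0.0,
    priors: Literal["size", "equal"] | Sequence[float] = "size",
    pa_threshold: float = 0.90,
    per_replicate: bool = False,
    class_size_factor: Literal["minus", "plus"] = "minus",
) -> pd.DataFrame:
    """Run all three prongs + integration per chemical x concentration.

    The condition profile is the mean of its replicate log-ratio profiles
    (``per_replicate=True`` calls each replicate separately instead, n=1 per
    row). Conditions reduced to zero surviving replicates upstream simply do
    not appear; single-replicate conditions are handled (n=1).
    """
    missing = [g for g in train.gene_ids if g not in lrm.values.index]
    if missing:
        raise AlignmentError(f"log-ratio matrix lacks panel genes: {missing[:5]}")
    values = lrm.values.loc[train.gene_ids]
    nsc = fit_nsc(train, delta=delta, priors=priors, class_size_factor=class_size_factor)
    pca_model = fit_pca(train)
    meta = lrm.meta.set_index("sample_id", drop=False)

    if per_replicate:
        units = [
            (row["chemical"], row["concentration_uM"], row["replicate"], [sid])
            for sid, row in meta.iterrows()
            if sid in values.columns
        ]
    else:
        grouped = meta.loc[[s for s in values.columns]].groupby(
            ["chemical", "concentration_uM"], sort=True
        )
        units = [
            (chem, conc, None, list(g["sample_id"]))
            for (chem, conc), g in grouped
        ]

    rows = []
    for chem, conc, rep, sids in units:
        profile = values[sids].mean(axis=1)
        probs = class_probabilities(nsc, profile)
        pa = pa_call(probs, pa_threshold)
        pc1, pca = pca_call(pca_model, profile)
        hc = hc_call(train, profile)
        rows.append(
            {
                "chemical": chem,
                "concentration_uM": conc,
                "replicate": rep,
                "n_replicates": len(sids),
                "p_ddi": probs[0],
                "p_nonddi": probs[1],
                "pa_call": pa,
                "pc1": pc1,
                "pca_call": pca,
                "hc_call": hc,
                "overall_call": integrate(pa, pca, hc),
            }
        )
    return pd.DataFrame(rows)


def select_delta_cv(
    train: TrainingSet,
    folds: int = 5,
    seed: int = 0,
    n_grid: int = 30,
    priors: Literal["size", "equal"] | Sequence[float] = "size",
    class_size_factor: Literal["minus", "plus"] = "minus",
) -> float:
    """Pick the shrinkage minimizing stratified-CV misclassification.

    The grid spans [0, max |d_ik|] of the full-data fit; ties resolve to the
    smallest delta (least shrinkage at equal error).
    """
    if folds < 2:
        raise InvalidConfigError("folds must be >= 2")
    full = fit_nsc(train, 0.0, priors, class_size_factor)
    grid = np.linspace(0.0, float(np.abs(full.d_scores).max()), n_grid)
    rng = np.random.default_rng(seed)

    # stratified fold assignment: shuffle within class, deal round-robin
    assign = pd.Series(index=train.profiles.columns, dtype=int)
    for cls in train.classes:
        ids = [p for p in train.profiles.columns if train.labels[p] == cls]
        ids = list(rng.permutation(ids))
        for i, pid in enumerate(ids):
            assign[pid] = i % folds
    errors = np.zeros(n_grid)
    total = 0
    for f in range(folds):
        test_ids = list(assign.index[assign == f])
        train_ids = list(assign.index[assign != f])
        if not test_ids:
            continue
        sub_labels = train.labels.loc[train_ids]
        if sub_labels.nunique() < 2 or sub_labels.value_counts().min() < 2:
            raise StratifiedFoldingError(
                f"fold {f}: a class has < 2 training profiles"
            )
        sub = TrainingSet(train.profiles[train_ids], sub_labels)
        total += len(test_ids)
        for gi, dl in enumerate(grid):
            model = fit_nsc(sub, dl, priors, class_size_factor)
            for tid in test_ids:
                p_ddi, _ = class_probabilities(model, train.profiles[tid])
                pred = DDI if p_ddi > 0.5 else NON_DDI
                if pred != train.labels[tid]:
                    errors[gi] += 1
    best = int(np.argmin(errors))  # argmin takes the first (smallest delta) tie
    return float(grid[best])
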