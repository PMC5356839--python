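"""Uncorrelated shrunken centroid classification.

Class centroids are compared to the overall centroid in standardized units,
soft-thresholded by ``delta``, and the surviving genes are passed through a
greedy correlation filter that drops any gene whose absolute Pearson
correlation with a higher-ranked kept gene exceeds ``rho``.  Hyperparameters
are chosen by leave-one-out cross-validation over a grid, preferring
sparser models (larger delta, then smaller rho) on ties.

Standardized difference for gene i and class k:

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0))

with ``s_i`` the within-class pooled standard deviation, ``s0`` the median
of the ``s_i`` and ``m_k = sqrt(1/n_k - 1/n)``.  A plain-standard-deviation
mode (``m_k = 1``, ``s0 = 0``) is available as a configuration switch.

Classification minimizes

    score_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

over the filtered gene set; the discriminant score of a prediction is the
nonnegative margin between the losing and winning class scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class USCError(ValueError):
    pass


@dataclass(frozen=True)
class USCHyperparams:
    delta: float
    rho: float

    def __post_init__(self):
        if self.delta < 0:
            raise USCError("delta must be >= 0")
        if not 0 <= self.rho <= 1:
            raise USCError("rho must be in [0, 1]")


DEFAULT_GRID = tuple(
    USCHyperparams(delta=d, rho=r)
    for r in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    for d in np.arange(0.0, 2.25, 0.25)
)


@dataclass(frozen=True)
class Prediction:
    sample_id: str
    molecular_class: str
    discriminant_score: float
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class USCModel:
    genes_all: list[str]
    classes: list[str]
    overall_centroid: np.ndarray          # (g,)
    class_centroids: np.ndarray           # (g, K)
    pooled_sd: np.ndarray                 # (g,)
    s0: float
    m_k: np.ndarray                       # (K,)
    d: np.ndarray                         # (g, K) standardized differences
    priors: np.ndarray                    # (K,)
    hyperparams: USCHyperparams | None = None
    d_shrunk: np.ndarray | None = None    # (g, K)
    selected_genes: list[str] = field(default_factory=list)
    log_scale: bool = True
    plain_sd: bool = False
    dropped_zero_variance: list[str] = field(default_factory=list)

    @property
    def shrunken_centroids(self) -> np.ndarray:
        """x'_ik = xbar_i + m_k (s_i + s0) d'_ik over all genes."""
        if self.d_shrunk is None:
            raise USCError("model not shrunk yet")
        scale = (self.pooled_sd + self.s0)[:, None] * self.m_k[None, :]
        return self.overall_centroid[:, None] + scale * self.d_shrunk

    def candidate_genes(self) -> list[str]:
        if self.d_shrunk is None:
            raise USCError("model not shrunk yet")
        keep = np.max(np.abs(self.d_shrunk), axis=1) > 0
        return [g for g, k in zip(self.genes_all, keep) if k]

    def to_json(self) -> str:
        payload = {
            "genes_all": self.genes_all,
            "classes": self.classes,
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "d": self.d.tolist(),
            "priors": self.priors.tolist(),
            "hyperparams": (None if self.hyperparams is None else
                            {"delta": self.hyperparams.delta,
                             "rho": self.hyperparams.rho}),
            "d_shrunk": (None if self.d_shrunk is None
                         else self.d_shrunk.tolist()),
            "selected_genes": self.selected_genes,
            "log_scale": self.log_scale,
            "plain_sd": self.plain_sd,
            "dropped_zero_variance": self.dropped_zero_variance,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "USCModel":
        p = json.loads(text)
        hp = p["hyperparams"]
        return cls(
            genes_all=p["genes_all"],
            classes=p["classes"],
            overall_centroid=np.array(p["overall_centroid"]),
            class_centroids=np.array(p["class_centroids"]),
            pooled_sd=np.array(p["pooled_sd"]),
            s0=p["s0"],
            m_k=np.array(p["m_k"]),
            d=np.array(p["d"]),
            priors=np.array(p["priors"]),
            hyperparams=None if hp is None else USCHyperparams(**hp),
            d_shrunk=None if p["d_shrunk"] is None else np.array(p["d_shrunk"]),
            selected_genes=p["selected_genes"],
            log_scale=p["log_scale"],
            plain_sd=p["plain_sd"],
            dropped_zero_variance=p["dropped_zero_variance"],
        )


@dataclass
class TrainingReport:
    mistakes: int
    average_genes: float
    predictive_genes: list[str]
    best: USCHyperparams
    grid: pd.DataFrame  # columns: delta, rho, mistakes, average_genes


def to_log_scale(X: pd.DataFrame) -> pd.DataFrame:
    return np.log2(X + 1.0)


def fit_centroids(X: pd.DataFrame, labels: Sequence[str], *,
                  plain_sd: bool = False, log_scale: bool = True) -> USCModel:
    """Unshrunk model from a genes x samples expression frame.

    ``log_scale`` records whether X is already on the log2(count+1) scale
    used for classification; the caller is responsible for the transform.
    Genes with zero variance across all samples are dropped with a note.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise USCError("need at least 2 classes")
    n = X.shape[1]
    n_k = np.array([(labels == c).sum() for c in classes])
    if np.any(n_k < 2):
        bad = [c for c, m in zip(classes, n_k) if m < 2]
        raise USCError(f"classes with <2 samples: {bad}")

    values = X.to_numpy(float)
    var_ok = values.std(axis=1) > 0
    dropped = [g for g, ok in zip(X.index, var_ok) if not ok]
    values = values[var_ok]
    genes = [g for g, ok in zip(X.index, var_ok) if ok]

    overall = values.mean(axis=1)
    cents = np.column_stack([values[:, labels == c].mean(axis=1)
                             for c in classes])
    ss = np.zeros(values.shape[0])
    for j, c in enumerate(classes):
        sub = values[:, labels == c]
        ss += ((sub - cents[:, [j]]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss / (n - len(classes)))

    if plain_sd:
        s0 = 0.0
        m_k = np.ones(len(classes))
    else:
        s0 = float(np.median(pooled_sd))
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)

    denom = (pooled_sd + s0)[:, None] * m_k[None, :]
    if np.any(denom == 0):
        raise USCError("zero denominator in standardized difference")
    d = (cents - overall[:, None]) / denom

    return USCModel(
        genes_all=genes,
        classes=classes,
        overall_centroid=overall,
        class_centroids=cents,
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        d=d,
        priors=n_k / n,
        log_scale=log_scale,
        plain_sd=plain_sd,
        dropped_zero_variance=dropped,
    )


def shrink(model: USCModel, delta: float) -> USCModel:
    """Soft-threshold standardized differences by delta (in place on a copy)."""
    if delta < 0:
        raise USCError("delta must be >= 0")
    d_shrunk = np.sign(model.d) * np.maximum(np.abs(model.d) - delta, 0.0)
    out = USCModel(**{**model.__dict__})
    out.d_shrunk = d_shrunk
    out.hyperparams = USCHyperparams(delta=delta,
                                     rho=model.hyperparams.rho
                                     if model.hyperparams else 1.0)
    return out


def correlation_filter(model: USCModel, X: pd.DataFrame, rho: float) -> list[str]:
    """Greedy removal of candidates too correlated with higher-ranked ones.

    Candidates are ranked by max_k |d'_ik| descending (gene name breaks
    ties); a gene is kept iff its absolute Pearson correlation with every
    already-kept gene is <= rho.
    """
    if not 0 <= rho <= 1:
        raise USCError("rho must be in [0, 1]")
    candidates = model.candidate_genes()
    if not candidates:
        raise USCError("no genes survive shrinkage; decrease delta")
    strength = {g: float(np.max(np.abs(model.d_shrunk[i])))
                for i, g in enumerate(model.genes_all)}
    ranked = sorted(candidates, key=lambda g: (-strength[g], g))
    if rho >= 1.0:
        kept = ranked
    else:
        data = X.loc[ranked].to_numpy(float)
        r = np.corrcoef(data)
        pos = {g: i for i, g in enumerate(ranked)}
        kept = []
        for g in ranked:
            i = pos[g]
            if all(abs(r[i, pos[h]]) <= rho for h in kept):
                kept.append(g)
    model.selected_genes = kept
    model.hyperparams = USCHyperparams(
        delta=model.hyperparams.delta if model.hyperparams else 0.0, rho=rho)
    return kept


def fit_usc(X: pd.DataFrame, labels: Sequence[str], hp: USCHyperparams, *,
            plain_sd: bool = False, log_scale: bool = True) -> USCModel:
    """Centroid fit + shrink + correlation filter at fixed hyperparameters."""
    model = fit_centroids(X, labels, plain_sd=plain_sd, log_scale=log_scale)
    model = shrink(model, hp.delta)
    correlation_filter(model, X, hp.rho)
    return model


def discriminant(model: USCModel, x: pd.Series | dict,
                 sample_id: str = "") -> Prediction:
    """Classify one sample given expression on the model's scale."""
    if not model.selected_genes:
        raise USCError("model has no selected genes")
    idx = {g: i for i, g in enumerate(model.genes_all)}
    try:
        xv = np.array([float(x[g]) for g in model.selected_genes])
    except KeyError as e:
        raise USCError(f"sample {sample_id!r} missing gene {e.args[0]!r}") from e
    rows = np.array([idx[g] for g in model.selected_genes])
    cents = model.shrunken_centroids[rows]            # (m, K)
    scale = (model.pooled_sd + model.s0)[rows]        # (m,)
    raw = (((xv[:, None] - cents) / scale[:, None]) ** 2).sum(axis=0)
    scores = raw - 2.0 * np.log(model.priors)
    order = np.argsort(scores, kind="stable")
    best, second = order[0], order[1]
    if np.isclose(scores[best], scores[second]):
        # tie: prefer the larger-prior class
        if model.priors[second] > model.priors[best]:
            best, second = second, best
    margin = float(scores[second] - scores[best])
    return Prediction(
        sample_id=sample_id,
        molecular_class=model.classes[best],
        discriminant_score=max(margin, 0.0),
        scores={c: float(s) for c, s in zip(model.classes, scores)},
    )


def predict(model: USCModel, X: pd.DataFrame) -> list[Prediction]:
    """Predictions for each column of a genes x samples frame."""
    return [discriminant(model, X[col], sample_id=str(col)) for col in X.columns]


def loocv_errors(X: pd.DataFrame, labels: Sequence[str],
                 grid: Sequence[USCHyperparams], *,
                 plain_sd: bool = False) -> pd.DataFrame:
    """Leave-one-out misclassification count and mean selected-set size per
    grid point.  Each fold refits centroids, shrinkage and the correlation
    filter from scratch on the remaining samples."""
    labels = np.asarray(labels)
    n = X.shape[1]
    records = {(hp.delta, hp.rho): {"mistakes": 0, "sizes": [], "failures": 0}
               for hp in grid}
    for held in range(n):
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        Xtr = X.iloc[:, mask]
        ytr = labels[mask]
        base = fit_centroids(Xtr, ytr, plain_sd=plain_sd)
        for hp in grid:
            rec = records[(hp.delta, hp.rho)]
            shrunk = shrink(base, hp.delta)
            try:
                correlation_filter(shrunk, Xtr, hp.rho)
                pred = discriminant(shrunk, X.iloc[:, held],
                                    sample_id=str(X.columns[held]))
                correct = pred.molecular_class == labels[held]
            except USCError:
                # empty selection: the fold cannot classify the held-out sample
                correct = False
                rec["failures"] += 1
                rec["sizes"].append(0)
            else:
                rec["sizes"].append(len(shrunk.selected_genes))
            if not correct:
                rec["mistakes"] += 1
    rows = []
    for hp in grid:
        rec = records[(hp.delta, hp.rho)]
        rows.append({
            "delta": hp.delta, "rho": hp.rho,
            "mistakes": rec["mistakes"],
            "average_genes": float(np.mean(rec["sizes"])),
            "failed_folds": rec["failures"],
        })
    return pd.DataFrame(rows)


def train_usc(X: pd.DataFrame, labels: Sequence[str],
              grid: Sequence[USCHyperparams] = DEFAULT_GRID, *,
              plain_sd: bool = False,
              log_scale: bool = True) -> tuple[USCModel, TrainingReport]:
    """Grid-search hyperparameters by LOOCV and refit on all data.

    Ties on LOOCV error prefer larger delta then smaller rho (sparser
    models).  Grid points whose final full-data selection is empty are
    not eligible.
    """
    if len(grid) == 0:
        raise USCError("hyperparameter grid is empty")
    errs = loocv_errors(X, labels, grid, plain_sd=plain_sd)

    best_model, best_hp, best_row = None, None, None
    # sort: fewest mistakes, then larger delta, then smaller rho
    errs_sorted = errs.sort_values(
        by=["mistakes", "delta", "rho"], ascending=[True, False, True],
        kind="stable",
    )
    for row in errs_sorted.itertuples():
        hp = USCHyperparams(delta=row.delta, rho=row.rho)
        try:
            model = fit_usc(X, labels, hp, plain_sd=plain_sd,
                            log_scale=log_scale)
        except USCError:
            continue
        best_model, best_hp, best_row = model, hp, row
        break
    if best_model is None:
        raise USCError("every grid point yields an empty gene selection")

    report = TrainingReport(
        mistakes=int(best_row.mistakes),
        average_genes=float(best_row.average_genes),
        predictive_genes=list(best_model.selected_genes),
        best=best_hp,
        grid=errs,
    )
    return best_model, report
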