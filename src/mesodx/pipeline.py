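"""End-to-end orchestration: simulate or load counts, normalize, test,
cluster, train the classifier and score a blind set, writing per-stage
artifacts to an output directory."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cut_two
from .core import CountMatrix, default_codeset
from .diffexp import (age_correlation, count_significant, results_to_frame,
                      run_diffexp)
from .normalization import normalize
from .simulate import SimConfig, make_blind_set, simulate_cohort
from .usc import DEFAULT_GRID, USCHyperparams, predict, train_usc, to_log_scale

log = logging.getLogger("mesodx")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    n_blind_a: int = 9
    n_blind_b: int = 5
    background_estimator: str = "mean"
    alphas: tuple[float, float] = (0.05, 0.005)
    linkage: str = "average"
    centering: str = "mean"
    grid_rho: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    grid_delta: tuple[float, ...] = tuple(np.arange(0.0, 2.25, 0.25))
    out_dir: str = "mesodx_run"
    seed: int = 42

    def grid(self):
        return [USCHyperparams(delta=d, rho=r)
                for r in self.grid_rho for d in self.grid_delta]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=str)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: RunConfig, *, training: CountMatrix | None = None,
                 blind: CountMatrix | None = None) -> dict:
    """Run every stage; returns a summary dict (also written to disk).

    When ``training``/``blind`` matrices are not supplied they are drawn
    from the synthetic generator in ``cfg.sim``.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    summary: dict = {"seed": cfg.seed, "version": __version__}

    def _stage(name):
        log.info("stage: %s", name)

    truth = blind_truth = None
    try:
        if training is None:
            _stage("simulate")
            cfg.sim.seed = cfg.seed
            training, truth = simulate_cohort(cfg.sim, rng=rng)
            with open(os.path.join(cfg.out_dir, "truth.json"), "w") as fh:
                fh.write(truth.to_json())
        if blind is None and (cfg.n_blind_a or cfg.n_blind_b):
            blind, blind_truth = make_blind_set(
                cfg.sim, cfg.n_blind_a, cfg.n_blind_b, rng=rng)
            with open(os.path.join(cfg.out_dir, "blind_truth.json"), "w") as fh:
                fh.write(blind_truth.to_json())
    except Exception as e:  # noqa: BLE001
        raise StageFailure("simulate", e) from e

    try:
        _stage("normalize")
        norm_train, report = normalize(
            training, estimator=cfg.background_estimator)
        report.write_tsv(os.path.join(cfg.out_dir, "normalization.tsv"))
        summary["normalization"] = {
            "n_input": len(training.samples),
            "n_retained": len(norm_train.samples),
            "excluded_technical": report.excluded_technical,
            "excluded_biological": report.excluded_biological,
        }
    except Exception as e:  # noqa: BLE001
        raise StageFailure("normalize", e) from e

    try:
        _stage("diffexp")
        de = run_diffexp(norm_train)
        de_frame = results_to_frame(de)
        de_frame.to_csv(os.path.join(cfg.out_dir, "de_table.tsv"),
                        sep="\t", index=False)
        summary["diffexp"] = {
            f"alpha_{a}": count_significant(de, a) for a in cfg.alphas
        }
        if all(s.age is not None for s in norm_train.samples):
            ages = pd.DataFrame([
                {"gene": a.gene, "group": a.group, "rho": a.rho_spearman,
                 "p": a.p} for a in age_correlation(norm_train)
            ])
            ages.to_csv(os.path.join(cfg.out_dir, "age_correlation.tsv"),
                        sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageFailure("diffexp", e) from e

    try:
        _stage("cluster")
        cluster = cut_two(norm_train, linkage=cfg.linkage,
                          centering=cfg.centering)
        for name, tree in (("samples", cluster.sample_tree),
                           ("genes", cluster.gene_tree)):
            with open(os.path.join(cfg.out_dir, f"tree_{name}.nwk"), "w") as fh:
                fh.write(tree.to_newick() + "\n")
        pd.DataFrame({
            "sample_id": list(cluster.k_cut_assignments),
            "cluster": list(cluster.k_cut_assignments.values()),
        }).to_csv(os.path.join(cfg.out_dir, "sample_clusters.tsv"),
                  sep="\t", index=False)
        summary["clustering"] = {
            "within_cluster_correlation": cluster.within_cluster_correlation,
            "crosstab": cluster.label_crosstab.to_dict(),
        }
    except Exception as e:  # noqa: BLE001
        raise StageFailure("cluster", e) from e

    try:
        _stage("train")
        X = to_log_scale(norm_train.endogenous_frame())
        model, train_report = train_usc(X, norm_train.labels,
                                        grid=cfg.grid())
        with open(os.path.join(cfg.out_dir, "model.json"), "w") as fh:
            fh.write(model.to_json())
        train_report.grid.to_csv(os.path.join(cfg.out_dir, "loocv_grid.tsv"),
                                 sep="\t", index=False)
        summary["usc_training"] = {
            "mistakes": train_report.mistakes,
            "average_genes": train_report.average_genes,
            "n_predictive_genes": len(train_report.predictive_genes),
            "predictive_genes": train_report.predictive_genes,
            "delta": train_report.best.delta,
            "rho": train_report.best.rho,
        }
    except Exception as e:  # noqa: BLE001
        raise StageFailure("train", e) from e

    if blind is not None and len(blind.samples) > 0:
        try:
            _stage("predict")
            norm_blind, _ = normalize(blind,
                                      estimator=cfg.background_estimator)
            Xb = to_log_scale(norm_blind.endogenous_frame())
            preds = predict(model, Xb)
            pred_frame = pd.DataFrame([
                {"sample_id": p.sample_id,
                 "molecular_class": p.molecular_class,
                 "discriminant_score": p.discriminant_score}
                for p in preds
            ])
            pred_frame.to_csv(os.path.join(cfg.out_dir, "predictions.tsv"),
                              sep="\t", index=False)
            counts = pred_frame.molecular_class.value_counts().to_dict()
            summary["predictions"] = {"class_counts": counts}
            if blind_truth is not None:
                correct = sum(
                    1 for p in preds
                    if blind_truth.labels.get(p.sample_id) == p.molecular_class
                )
                summary["predictions"]["n_correct_vs_truth"] = correct
                summary["predictions"]["n_blind"] = len(preds)
        except Exception as e:  # noqa: BLE001
            raise StageFailure("predict", e) from e

    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
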