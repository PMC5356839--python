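"""Synthetic two-class nCounter-like cohorts.

Endogenous probes are negative-binomial around gene baselines, with a
configurable set of planted differentially expressed genes (multiplicative
2**log2fc effect in class A), log-normal lane-to-lane scale factors,
housekeeping probes that track only the lane scale, a deterministic
geometric positive-control ladder with Poisson noise, Poisson negative
controls, and optional degraded lanes whose non-spike-in signal collapses.
Ground truth is emitted alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import CodeSet, CountMatrix, SampleMeta, Stage, default_codeset

#: Positive-control ladder (fmol-equivalent input per spike-in).
POS_LADDER = np.array([128.0, 32.0, 8.0, 2.0, 0.5, 0.125])


@dataclass
class CorrelatedBlock:
    """Genes sharing a per-sample log-normal factor (induces intra-block r)."""
    gene_indices: list[int]
    sigma: float = 0.8


@dataclass
class SimConfig:
    n_class_a: int = 25              # class A = MPM-like
    n_class_b: int = 15              # class B = MH-like
    n_genes: int = 117
    n_de: int = 66
    n_up_in_a: int = 35
    log2fc_range: tuple[float, float] = (1.0, 2.5)
    dispersion: float = 10.0         # negative-binomial size
    lane_scale_sd: float = 0.15      # sd of log(laneScale)
    background_mean: float = 4.0     # Poisson mean of negative controls
    hk_mean: float = 2000.0
    baseline_log_mean: float = np.log(400.0)
    baseline_log_sd: float = 1.0
    pos_counts_per_fmol: float = 60.0
    n_degraded_a: int = 0
    n_degraded_b: int = 0
    collapse_factor: float = 1.0 / 20.0
    correlated_blocks: list[CorrelatedBlock] = field(default_factory=list)
    age_range: tuple[float, float] = (40.0, 85.0)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_de > self.n_genes:
            problems.append("n_de > n_genes")
        if self.n_up_in_a > self.n_de:
            problems.append("n_up_in_a > n_de")
        if min(self.dispersion, self.hk_mean, self.background_mean,
               self.pos_counts_per_fmol) <= 0:
            problems.append("dispersion/means must be > 0")
        if self.n_degraded_a > self.n_class_a or self.n_degraded_b > self.n_class_b:
            problems.append("more degraded lanes than lanes")
        if not 0 < self.collapse_factor <= 1:
            problems.append("collapse_factor must be in (0, 1]")
        for b in self.correlated_blocks:
            if any(i >= self.n_genes for i in b.gene_indices):
                problems.append(f"block indices out of range: {b.gene_indices}")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SimTruth:
    de_genes: dict[str, dict]            # gene -> {direction, log2fc}
    degraded_sample_ids: list[str]
    labels: dict[str, str]
    lane_scales: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _negbin(rng: np.random.Generator, mean, size_param):
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_cohort(cfg: SimConfig, *, codeset: CodeSet | None = None,
                    rng: np.random.Generator | None = None,
                    id_prefix: str = "S", labeled: bool = True
                    ) -> tuple[CountMatrix, SimTruth]:
    """Draw one cohort as a raw CountMatrix plus its ground truth.

    Panel-level parameters (gene baselines, which genes carry effects and
    their sizes, housekeeping baselines) are a pure function of
    ``cfg.seed``, while per-sample noise comes from ``rng`` (defaulting to
    an independent stream of the same seed).  Cohorts built from configs
    sharing a seed therefore come from one generative model, which is what
    makes a held-out blind set meaningful.
    """
    cfg.validate()
    codeset = codeset or default_codeset()
    panel_rng = np.random.default_rng([cfg.seed, 0])
    rng = rng if rng is not None else np.random.default_rng([cfg.seed, 1])

    endo = codeset.names_of("Endogenous")
    if len(endo) < cfg.n_genes:
        raise ValueError(f"codeset has {len(endo)} endogenous probes, "
                         f"config wants {cfg.n_genes}")
    genes = endo[:cfg.n_genes]
    hk = codeset.names_of("Housekeeping")
    pos = codeset.names_of("Positive")
    neg = codeset.names_of("Negative")
    if len(pos) != len(POS_LADDER):
        raise ValueError("codeset must carry 6 positive spike-ins")

    n = cfg.n_class_a + cfg.n_class_b
    labels = ["MPM"] * cfg.n_class_a + ["MH"] * cfg.n_class_b
    sample_ids = [f"{id_prefix}{j+1:02d}" for j in range(n)]

    # panel-level truth: a pure function of cfg.seed
    baselines = np.exp(panel_rng.normal(cfg.baseline_log_mean,
                                        cfg.baseline_log_sd,
                                        size=cfg.n_genes))
    de_idx = panel_rng.choice(cfg.n_genes, size=cfg.n_de, replace=False)
    lfc = np.zeros(cfg.n_genes)
    magnitudes = panel_rng.uniform(*cfg.log2fc_range, size=cfg.n_de)
    signs = np.array([1.0] * cfg.n_up_in_a +
                     [-1.0] * (cfg.n_de - cfg.n_up_in_a))
    lfc[de_idx] = magnitudes * signs
    hk_baselines = cfg.hk_mean * np.exp(panel_rng.normal(0, 0.3, size=len(hk)))

    lane_scales = np.exp(rng.normal(0.0, cfg.lane_scale_sd, size=n))
    degraded = ([f"{id_prefix}{j+1:02d}" for j in range(cfg.n_degraded_a)] +
                [f"{id_prefix}{cfg.n_class_a+j+1:02d}"
                 for j in range(cfg.n_degraded_b)])
    degraded_set = set(degraded)

    block_factors = np.ones((cfg.n_genes, n))
    for block in cfg.correlated_blocks:
        shared = np.exp(rng.normal(0.0, block.sigma, size=n))
        for gi in block.gene_indices:
            block_factors[gi, :] *= shared

    n_probes = len(codeset)
    counts = np.zeros((n_probes, n))
    probe_index = {p.name: i for i, p in enumerate(codeset.probes)}
    for j in range(n):
        scale = lane_scales[j]
        collapse = cfg.collapse_factor if sample_ids[j] in degraded_set else 1.0
        class_mult = np.where(labels[j] == "MPM", 2.0 ** lfc, 1.0)
        mean_endo = baselines * class_mult * block_factors[:, j] * scale * collapse
        counts[[probe_index[g] for g in genes], j] = \
            _negbin(rng, mean_endo, cfg.dispersion)
        counts[[probe_index[g] for g in hk], j] = \
            _negbin(rng, hk_baselines * scale * collapse, cfg.dispersion)
        counts[[probe_index[g] for g in pos], j] = \
            rng.poisson(POS_LADDER * cfg.pos_counts_per_fmol * scale)
        counts[[probe_index[g] for g in neg], j] = \
            rng.poisson(cfg.background_mean, size=len(neg))

    ages = rng.uniform(*cfg.age_range, size=n)
    samples = [
        SampleMeta(sample_id=sid,
                   label=lab if labeled else "UNKNOWN",
                   age=round(float(age), 1))
        for sid, lab, age in zip(sample_ids, labels, ages)
    ]
    matrix = CountMatrix(codeset=codeset, samples=samples, counts=counts,
                         stage=Stage.RAW)
    truth = SimTruth(
        de_genes={
            genes[i]: {"direction": "up_in_MPM" if lfc[i] > 0 else "down_in_MPM",
                       "log2fc": float(lfc[i])}
            for i in sorted(de_idx)
        },
        degraded_sample_ids=degraded,
        labels=dict(zip(sample_ids, labels)),
        lane_scales=dict(zip(sample_ids, lane_scales.astype(float))),
    )
    return matrix, truth


def make_blind_set(cfg: SimConfig, n_a: int, n_b: int, *,
                   codeset: CodeSet | None = None,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None,
                   id_prefix: str = "B") -> tuple[CountMatrix, SimTruth]:
    """Unlabeled cohort from the same generative model; truth is sealed in
    the returned SimTruth.

    The panel (baselines, planted effects) stays tied to ``cfg.seed``;
    ``seed`` controls only the fresh per-sample noise stream.
    """
    blind_cfg = SimConfig(**{**cfg.__dict__,
                             "n_class_a": n_a, "n_class_b": n_b,
                             "n_degraded_a": 0, "n_degraded_b": 0,
                             "correlated_blocks": list(cfg.correlated_blocks)})
    if n_a == 0 and n_b == 0:
        empty = CountMatrix(codeset=codeset or default_codeset(), samples=[],
                            counts=np.zeros(((len(codeset or default_codeset())), 0)))
        return empty, SimTruth({}, [], {}, {})
    if rng is None:
        rng = np.random.default_rng([cfg.seed if seed is None else seed, 1])
    return simulate_cohort(blind_cfg, codeset=codeset, rng=rng,
                           id_prefix=id_prefix, labeled=False)


def write_cohort_rcc(matrix: CountMatrix, truth: SimTruth, directory) -> None:
    """Emit one RCC file per lane plus truth JSON and a labels TSV."""
    import os
    from .rcc import write_rcc

    os.makedirs(directory, exist_ok=True)
    for j, meta in enumerate(matrix.samples):
        counts = {
            (p.code_class, p.name): int(matrix.counts[i, j])
            for i, p in enumerate(matrix.codeset.probes)
        }
        write_rcc(meta, counts, os.path.join(directory, f"{meta.sample_id}.RCC"))
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
    with open(os.path.join(directory, "labels.tsv"), "w") as fh:
        fh.write("sample_id\tlabel\tage\n")
        for s in matrix.samples:
            fh.write(f"{s.sample_id}\t{s.label}\t{'' if s.age is None else s.age}\n")
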