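"""Count normalization: background subtraction, technical (positive-control)
scaling and biological (housekeeping) scaling, with QC exclusion.

Per sample the technical scaling factor is

    pos_factor = mean_over_samples(geomean(positive counts)) / geomean(positive counts)

and samples whose factor falls outside ``TECH_RANGE`` are excluded before
any biological factor is computed.  The biological factor is the analogous
ratio over housekeeping probes among technically retained samples, with
exclusion range ``BIO_RANGE``.  Both exclusions are irrevocable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .core import CodesetError, CountMatrix, Stage

TECH_RANGE = (0.3, 3.0)
BIO_RANGE = (0.1, 10.0)

BackgroundEstimator = Literal["mean", "mean+2sd", "max"]


@dataclass
class NormalizationFactors:
    sample_id: str
    background: float = np.nan
    pos_factor: float = np.nan
    bio_factor: float = np.nan


@dataclass
class NormalizationReport:
    factors: dict[str, NormalizationFactors] = field(default_factory=dict)
    excluded_technical: list[str] = field(default_factory=list)
    excluded_biological: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def status(self, sample_id: str) -> str:
        if sample_id in self.excluded_technical:
            return "excluded_technical"
        if sample_id in self.excluded_biological:
            return "excluded_biological"
        return "retained"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, f in self.factors.items():
            rows.append({
                "sample_id": sid,
                "background": f.background,
                "pos_factor": f.pos_factor,
                "bio_factor": f.bio_factor,
                "status": self.status(sid),
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# background estimator and control geometric means are "
                     "configuration assumptions, not measured settings\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _geomean(values: np.ndarray, pseudocount: float,
             notes: list[str] | None, context: str) -> float:
    v = np.asarray(values, dtype=float).copy()
    bad = v <= 0
    if bad.any():
        v[bad] = pseudocount
        if notes is not None:
            notes.append(f"{context}: {int(bad.sum())} nonpositive control "
                         f"count(s) replaced by pseudocount {pseudocount}")
    return float(np.exp(np.mean(np.log(v))))


def subtract_background(m: CountMatrix, *,
                        estimator: BackgroundEstimator = "mean",
                        report: NormalizationReport | None = None
                        ) -> tuple[CountMatrix, NormalizationReport]:
    """Estimate per-sample background from Negative probes and subtract it
    from all non-Negative counts, flooring at zero."""
    if m.stage != Stage.RAW:
        raise CodesetError(f"expected raw counts, got stage={m.stage.value}")
    neg_idx = m.codeset.indices_of("Negative")
    if neg_idx.size == 0:
        raise CodesetError("codeset has no Negative probes")
    report = report or NormalizationReport()

    neg = m.counts[neg_idx, :]
    if estimator == "mean":
        bg = neg.mean(axis=0)
    elif estimator == "mean+2sd":
        bg = neg.mean(axis=0) + 2 * neg.std(axis=0, ddof=1)
    elif estimator == "max":
        bg = neg.max(axis=0)
    else:
        raise ValueError(f"unknown background estimator {estimator!r}")

    out = m.copy()
    non_neg = np.ones(len(m.codeset), dtype=bool)
    non_neg[neg_idx] = False
    out.counts[non_neg, :] = np.maximum(out.counts[non_neg, :] - bg, 0.0)
    out.advance_stage(Stage.BACKGROUND_SUBTRACTED)
    for sid, b in zip(m.sample_ids, bg):
        report.factors.setdefault(sid, NormalizationFactors(sid)).background = float(b)
    return out, report


def technical_normalize(m: CountMatrix, report: NormalizationReport, *,
                        pseudocount: float = 0.5
                        ) -> tuple[CountMatrix, NormalizationReport]:
    """Scale each sample so Positive-probe geometric means are equalized;
    exclude samples whose scaling factor leaves ``TECH_RANGE``."""
    if m.stage != Stage.BACKGROUND_SUBTRACTED:
        raise CodesetError(f"expected background-subtracted counts, got {m.stage.value}")
    pos_idx = m.codeset.indices_of("Positive")
    if pos_idx.size == 0:
        raise CodesetError("codeset has no Positive probes")

    geo = np.array([
        _geomean(m.counts[pos_idx, j], pseudocount, report.notes,
                 f"technical:{sid}")
        for j, sid in enumerate(m.sample_ids)
    ])
    ref = geo.mean()
    factors = ref / geo

    keep = []
    for j, sid in enumerate(m.sample_ids):
        report.factors.setdefault(sid, NormalizationFactors(sid)).pos_factor = \
            float(factors[j])
        if TECH_RANGE[0] <= factors[j] <= TECH_RANGE[1]:
            keep.append(j)
        else:
            report.excluded_technical.append(sid)

    out = CountMatrix(
        codeset=m.codeset,
        samples=[m.samples[j] for j in keep],
        counts=m.counts[:, keep] * factors[keep],
        stage=m.stage,
    )
    out.advance_stage(Stage.TECH_NORMALIZED)
    return out, report


def biological_normalize(m: CountMatrix, report: NormalizationReport, *,
                         pseudocount: float = 0.5
                         ) -> tuple[CountMatrix, NormalizationReport]:
    """Scale technically retained samples by housekeeping geometric means;
    exclude samples whose factor leaves ``BIO_RANGE``."""
    if m.stage != Stage.TECH_NORMALIZED:
        raise CodesetError(f"expected tech-normalized counts, got {m.stage.value}")
    hk_idx = m.codeset.indices_of("Housekeeping")
    if hk_idx.size == 0:
        raise CodesetError("codeset has no Housekeeping probes")

    geo = np.array([
        _geomean(m.counts[hk_idx, j], pseudocount, report.notes,
                 f"biological:{sid}")
        for j, sid in enumerate(m.sample_ids)
    ])
    ref = geo.mean()
    factors = ref / geo

    keep = []
    for j, sid in enumerate(m.sample_ids):
        report.factors.setdefault(sid, NormalizationFactors(sid)).bio_factor = \
            float(factors[j])
        if BIO_RANGE[0] <= factors[j] <= BIO_RANGE[1]:
            keep.append(j)
        else:
            report.excluded_biological.append(sid)
            report.notes.append(f"biological:{sid}: factor {factors[j]:.4g} "
                                f"outside {BIO_RANGE}")

    out = CountMatrix(
        codeset=m.codeset,
        samples=[m.samples[j] for j in keep],
        counts=m.counts[:, keep] * factors[keep],
        stage=m.stage,
    )
    out.advance_stage(Stage.BIO_NORMALIZED)
    report.retained = out.sample_ids
    return out, report


def normalize(m: CountMatrix, *, estimator: BackgroundEstimator = "mean",
              pseudocount: float = 0.5
              ) -> tuple[CountMatrix, NormalizationReport]:
    """Full chain: background subtraction, technical then biological scaling."""
    out, report = subtract_background(m, estimator=estimator)
    out, report = technical_normalize(out, report, pseudocount=pseudocount)
    out, report = biological_normalize(out, report, pseudocount=pseudocount)
    return out, report
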