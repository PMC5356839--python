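"""Domain types shared across the pipeline.

A :class:`CountMatrix` carries probe-by-sample counts together with the
:class:`CodeSet` describing the probes and per-sample metadata, and tracks
which processing stage the counts are at (raw through fully normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")

#: Gene-symbol variants reconciled to a single canonical spelling.
GENE_SYNONYMS = {
    "MK167": "MKI67",
    "PKM2": "PKM",
    "DNMT3": "DNMT3A",
    "DNTM1": "DNMT1",
    "TGFR2": "TGFBR2",
    "Gli1": "GLI1",
    "Gli2": "GLI2",
}


def canonical_gene(name: str) -> str:
    """Map a gene-symbol variant to its canonical spelling."""
    return GENE_SYNONYMS.get(name, name)


class Stage(str, Enum):
    """Forward-only processing stages of a CountMatrix."""

    RAW = "raw"
    BACKGROUND_SUBTRACTED = "background_subtracted"
    TECH_NORMALIZED = "tech_normalized"
    BIO_NORMALIZED = "bio_normalized"

    @property
    def order(self) -> int:
        return list(Stage).index(self)


class CodesetError(ValueError):
    """Raised when a codeset or count table violates its invariants."""


@dataclass(frozen=True)
class Probe:
    name: str
    code_class: str
    accession: str = ""

    def __post_init__(self):
        if not self.name:
            raise CodesetError("probe name must be nonempty")
        if self.code_class not in CODE_CLASSES:
            raise CodesetError(
                f"probe {self.name!r}: code_class {self.code_class!r} "
                f"not in {CODE_CLASSES}"
            )


@dataclass(frozen=True)
class CodeSet:
    probes: tuple[Probe, ...]
    name: str = "codeset"

    def __post_init__(self):
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CodesetError(f"duplicate probe names: {dupes}")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_names(self) -> list[str]:
        return [p.name for p in self.probes]

    def names_of(self, code_class: str) -> list[str]:
        return [p.name for p in self.probes if p.code_class == code_class]

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CODE_CLASSES}
        for p in self.probes:
            out[p.code_class] += 1
        return out

    def indices_of(self, code_class: str) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.probes) if p.code_class == code_class],
            dtype=int,
        )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    label: str = "UNKNOWN"  # MPM | MH | UNKNOWN
    age: Optional[float] = None
    batch_id: Optional[str] = None

    def __post_init__(self):
        if self.label not in ("MPM", "MH", "UNKNOWN"):
            raise ValueError(f"label {self.label!r} not in {{MPM, MH, UNKNOWN}}")


@dataclass
class CountMatrix:
    """Probes x samples counts with codeset, metadata and stage tracking."""

    codeset: CodeSet
    samples: list[SampleMeta]
    counts: np.ndarray  # shape (n_probes, n_samples), float, >= 0
    stage: Stage = Stage.RAW

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.codeset), len(self.samples)):
            raise CodesetError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.codeset)} probes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise CodesetError("counts must be finite and nonnegative")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise CodesetError("duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def advance_stage(self, new: Stage) -> None:
        if new.order <= self.stage.order:
            raise CodesetError(f"stage may only move forward: {self.stage} -> {new}")
        self.stage = new

    def class_counts(self, code_class: str) -> np.ndarray:
        """Submatrix of counts for one code class (rows in codeset order)."""
        return self.counts[self.codeset.indices_of(code_class), :]

    def subset_samples(self, keep_ids: Sequence[str]) -> "CountMatrix":
        keep = set(keep_ids)
        idx = [i for i, s in enumerate(self.samples) if s.sample_id in keep]
        return CountMatrix(
            codeset=self.codeset,
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx].copy(),
            stage=self.stage,
        )

    def endogenous_frame(self) -> pd.DataFrame:
        """Endogenous counts as genes x samples DataFrame."""
        idx = self.codeset.indices_of("Endogenous")
        return pd.DataFrame(
            self.counts[idx, :],
            index=[self.codeset.probes[i].name for i in idx],
            columns=self.sample_ids,
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            codeset=self.codeset,
            samples=list(self.samples),
            counts=self.counts.copy(),
            stage=self.stage,
        )


def _data_path(fname: str):
    return resources.files("mesodx.data").joinpath(fname)


def load_codeset_tsv(path) -> CodeSet:
    """Read a codeset from TSV with columns Name, CodeClass, Accession."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"Name", "CodeClass"}
    if not required.issubset(df.columns):
        raise CodesetError(f"codeset TSV needs columns {sorted(required)}")
    probes = tuple(
        Probe(r.Name, r.CodeClass, getattr(r, "Accession", ""))
        for r in df.itertuples()
    )
    return CodeSet(probes=probes, name=str(path))


def default_codeset() -> CodeSet:
    """The packaged 117-gene panel: 117 Endogenous + 6 Housekeeping probes,
    6 Positive and 8 Negative spike-ins."""
    with resources.as_file(_data_path("codeset.tsv")) as p:
        cs = load_codeset_tsv(p)
    return replace(cs, name="default-117")
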