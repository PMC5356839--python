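"""Reading and writing nCounter lane files (RCC) and count-matrix TSVs.

The RCC dialect handled here is the sectioned comma-separated text format
with ``<Tag>``/``</Tag>`` delimiters (Header, Sample_Attributes,
Lane_Attributes, Code_Summary).  Unknown sections and attributes are
tolerated and ignored.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CodeSet, CodesetError, CountMatrix, SampleMeta, Stage

ProbeKey = tuple[str, str]  # (code_class, name)


class RCCFormatError(ValueError):
    """Malformed RCC file (missing sections, duplicate probes, ...)."""


class AssemblyError(ValueError):
    """A lane does not cover the probes a codeset expects."""


def _parse_sections(text: str, path: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections.setdefault(current, [])
        elif current is not None:
            sections[current].append(line)
        # free text outside sections is ignored
    if not sections:
        raise RCCFormatError(f"{path}: no RCC sections found")
    return sections


def _attrs(lines: Iterable[str]) -> dict[str, str]:
    out = {}
    for line in lines:
        key, _, value = line.partition(",")
        out[key.strip()] = value.strip()
    return out


def read_rcc(path) -> tuple[SampleMeta, dict[ProbeKey, int]]:
    """Parse one RCC lane file into sample metadata and per-probe counts.

    Counts are keyed by ``(code_class, name)``; unknown sections are
    ignored.  Raises :class:`RCCFormatError` for structural problems and
    :class:`ValueError` for bad count values.
    """
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    sections = _parse_sections(text, path)
    if "Code_Summary" not in sections:
        raise RCCFormatError(f"{path}: missing Code_Summary section")

    attrs = _attrs(sections.get("Sample_Attributes", []))
    age = None
    if attrs.get("Age", "") not in ("", "n.a."):
        age = float(attrs["Age"])
    meta = SampleMeta(
        sample_id=attrs.get("ID", os.path.basename(path)),
        label=attrs.get("Label", "UNKNOWN") or "UNKNOWN",
        age=age,
        batch_id=attrs.get("BatchID") or None,
    )

    counts: dict[ProbeKey, int] = {}
    seen_names: set[str] = set()
    lines = sections["Code_Summary"]
    if not lines:
        raise RCCFormatError(f"{path}: empty Code_Summary")
    header = [c.strip() for c in lines[0].split(",")]
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as e:
        raise RCCFormatError(f"{path}: bad Code_Summary header {header}") from e
    for line in lines[1:]:
        fields = line.split(",")
        code_class, name = fields[i_class].strip(), fields[i_name].strip()
        if name in seen_names:
            raise RCCFormatError(f"{path}: duplicate probe {name!r}")
        seen_names.add(name)
        raw = fields[i_count].strip()
        try:
            value = int(raw)
        except ValueError as e:
            raise ValueError(f"{path}: non-numeric count {raw!r} for {name}") from e
        if value < 0:
            raise ValueError(f"{path}: negative count {value} for {name}")
        counts[(code_class, name)] = value
    return meta, counts


def write_rcc(meta: SampleMeta, counts: Mapping[ProbeKey, int], path,
              accessions: Mapping[str, str] | None = None) -> None:
    """Write one lane as a sectioned RCC file that :func:`read_rcc` inverts."""
    accessions = accessions or {}
    for (cc, name), v in counts.items():
        if v < 0 or int(v) != v:
            raise ValueError(f"count for {name} must be a nonnegative integer")
    buf = io.StringIO()
    buf.write("<Header>\nFileVersion,1.7\nSoftwareVersion,mesodx\n</Header>\n")
    buf.write("<Sample_Attributes>\n")
    buf.write(f"ID,{meta.sample_id}\n")
    buf.write(f"Label,{meta.label}\n")
    buf.write("Age,%s\n" % ("" if meta.age is None else f"{meta.age:g}"))
    buf.write(f"BatchID,{meta.batch_id or ''}\n")
    buf.write("</Sample_Attributes>\n")
    buf.write("<Lane_Attributes>\nID,1\n</Lane_Attributes>\n")
    buf.write("<Code_Summary>\nCodeClass,Name,Accession,Count\n")
    for (cc, name), v in counts.items():
        buf.write(f"{cc},{name},{accessions.get(name, 'NA')},{int(v)}\n")
    buf.write("</Code_Summary>\n")
    try:
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    except OSError as e:
        raise OSError(f"cannot write RCC to {path}: {e}") from e


def mismatch_report(counts: Mapping[ProbeKey, int],
                    codeset: CodeSet) -> dict[str, list[str]]:
    """Names present in the lane but not the codeset and vice versa."""
    lane = {name for (_, name) in counts}
    expected = set(codeset.probe_names)
    return {
        "extra": sorted(lane - expected),
        "missing": sorted(expected - lane),
    }


def assemble_matrix(lanes: Sequence[tuple[SampleMeta, Mapping[ProbeKey, int]]],
                    codeset: CodeSet) -> CountMatrix:
    """Stack per-lane counts into a raw CountMatrix in codeset probe order.

    Lane probe order is irrelevant; a lane missing a codeset probe raises
    :class:`AssemblyError` naming the sample and probe.
    """
    n_probes = len(codeset)
    mat = np.zeros((n_probes, len(lanes)))
    metas = []
    for j, (meta, counts) in enumerate(lanes):
        by_name = {name: v for (_, name), v in counts.items()}
        for i, probe in enumerate(codeset.probes):
            if probe.name not in by_name:
                raise AssemblyError(
                    f"lane {meta.sample_id!r} missing probe {probe.name!r}"
                )
            mat[i, j] = by_name[probe.name]
        metas.append(meta)
    return CountMatrix(codeset=codeset, samples=metas, counts=mat,
                      stage=Stage.RAW)


def read_rcc_dir(directory, codeset: CodeSet) -> CountMatrix:
    """Read every ``*.RCC`` (case-insensitive) lane in a directory."""
    paths = sorted(
        p for p in os.listdir(directory) if p.lower().endswith(".rcc")
    )
    if not paths:
        raise RCCFormatError(f"no RCC files in {directory}")
    lanes = [read_rcc(os.path.join(directory, p)) for p in paths]
    return assemble_matrix(lanes, codeset)


def write_counts_tsv(m: CountMatrix, path) -> None:
    """Counts as TSV: CodeClass, Name, then one column per sample."""
    df = pd.DataFrame(m.counts, columns=m.sample_ids)
    df.insert(0, "Name", m.codeset.probe_names)
    df.insert(0, "CodeClass", [p.code_class for p in m.codeset.probes])
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, meta: Sequence[SampleMeta] | None = None,
                    stage: Stage = Stage.RAW) -> CountMatrix:
    """Inverse of :func:`write_counts_tsv`.

    Sample metadata defaults to UNKNOWN labels unless supplied.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["CodeClass", "Name"]:
        raise CodesetError(f"{path}: first columns must be CodeClass, Name")
    from .core import Probe

    codeset = CodeSet(
        probes=tuple(Probe(n, c) for n, c in zip(df["Name"], df["CodeClass"])),
        name=str(path),
    )
    sample_ids = list(df.columns[2:])
    if meta is None:
        meta = [SampleMeta(sample_id=s) for s in sample_ids]
    else:
        by_id = {m_.sample_id: m_ for m_ in meta}
        meta = [by_id.get(s, SampleMeta(sample_id=s)) for s in sample_ids]
    return CountMatrix(codeset=codeset, samples=list(meta),
                      counts=df[sample_ids].to_numpy(float), stage=stage)


def read_labels_tsv(path) -> list[SampleMeta]:
    """Sample metadata TSV with columns sample_id, label[, age, batch_id]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out = []
    for r in df.itertuples():
        age = getattr(r, "age", None)
        out.append(SampleMeta(
            sample_id=str(r.sample_id),
            label=getattr(r, "label", "UNKNOWN"),
            age=None if age is None or pd.isna(age) else float(age),
            batch_id=str(getattr(r, "batch_id")) if hasattr(r, "batch_id") else None,
        ))
    return out
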