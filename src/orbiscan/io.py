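"""Readers and writers for the on-disk formats.

Count matrices, panels and sample metadata travel as TSV; gene sets as GMT;
native NanoString lane files are read from the RCC dialect (bracketed
sections with CSV content). Readers reject malformed input with the file
location in the message rather than coercing silently.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    PanelDefinition,
    Probe,
    ProbeClass,
    SampleMetadata,
    Stage,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------- count matrix

def read_count_matrix(path: str | Path, panel: PanelDefinition | None = None) -> CountMatrix:
    """Read a RAW gene-by-sample TSV (header row = sample names)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene row {dup[0]!r}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for ci, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy())[0]
        if len(bad):
            ri = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[ri]!r} at row {ri + 2}, column {ci + 2}"
            )
        neg = np.nonzero((converted < 0).to_numpy())[0]
        if len(neg):
            ri = int(neg[0])
            raise ValueError(
                f"{path}: negative value {converted.iloc[ri]} at row {ri + 2}, column {ci + 2}"
            )
        values[col] = converted
    if panel is not None:
        unknown = [g for g in values.index if g not in set(panel.names())]
        if unknown:
            raise ValueError(f"{path}: genes absent from panel: {unknown[:5]}")
    return CountMatrix(values, Stage.RAW, panel)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    df = matrix.values
    if matrix.stage is Stage.RAW:
        df = df.round().astype(int)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------- panel

def read_panel(path: str | Path) -> PanelDefinition:
    """Panel TSV: probe_name, probe_class, concentration (blank unless POSITIVE)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_name", "probe_class"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: panel TSV needs columns {sorted(required)}")
    probes = []
    for i, row in df.iterrows():
        cls_name = str(row["probe_class"]).strip().upper()
        try:
            cls = ProbeClass[cls_name]
        except KeyError:
            raise ValueError(
                f"{path}: unknown probe class {row['probe_class']!r} at row {i + 2}"
            ) from None
        conc = None
        if "concentration" in df.columns:
            raw = row["concentration"]
            if isinstance(raw, str) and raw.strip():
                conc = float(raw)
            elif pd.notna(raw):
                conc = float(raw)
        probes.append(Probe(str(row["probe_name"]), cls, conc))
    return PanelDefinition(tuple(probes))


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    rows = [
        {
            "probe_name": p.name,
            "probe_class": p.probe_class.value,
            "concentration": "" if p.concentration is None else _FLOAT_FMT % p.concentration,
        }
        for p in panel.probes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- metadata

def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: metadata TSV needs columns ['sample', 'group']")
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample {dup.iloc[0]!r}")
    return SampleMetadata(dict(zip(df["sample"], df["group"])))


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(metadata.assignments), "group": list(metadata.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------------ GMT

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: one set per line — name, description, members..."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped: list[str] = []
            seen: set[str] = set()
            for m in members:
                if m in seen:
                    log.warning("%s:%d: duplicate member %r in set %r", path, lineno, m, name)
                else:
                    seen.add(m)
                    deduped.append(m)
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(desc, tuple(deduped))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, gs in collection:
            fh.write("\t".join([name, gs.description, *gs.members]) + "\n")


# ------------------------------------------------------------------------ RCC

_RCC_SECTION = re.compile(r"^<(/?)([A-Za-z_]+)>\s*$")
_POS_CONC = re.compile(r"\(([\d.]+)\)\s*$")

_CODECLASS_MAP = {
    "Endogenous": ProbeClass.ENDOGENOUS,
    "Housekeeping": ProbeClass.HOUSEKEEPING,
    "Positive": ProbeClass.POSITIVE,
    "Negative": ProbeClass.NEGATIVE,
}

_KNOWN_SECTIONS = {"Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary"}


def _parse_rcc(path: Path) -> tuple[str, list[tuple[ProbeClass, str, float | None, int]]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            m = _RCC_SECTION.match(line.strip())
            if m:
                closing, name = m.groups()
                if closing:
                    current = None
                else:
                    current = name
                    sections.setdefault(name, [])
                    if name not in _KNOWN_SECTIONS:
                        log.warning("%s: ignoring unknown RCC section %r", path, name)
                continue
            if current is not None and line.strip():
                sections[current].append(line.strip())

    if "Code_Summary" not in sections:
        raise ValueError(f"{path}: missing Code_Summary section")

    sample_id = path.stem
    for row in sections.get("Sample_Attributes", []):
        parts = row.split(",")
        if len(parts) >= 2 and parts[0] == "ID" and parts[1]:
            sample_id = parts[1]

    rows: list[tuple[ProbeClass, str, float | None, int]] = []
    body = sections["Code_Summary"]
    start = 1 if body and body[0].startswith("CodeClass") else 0
    for row in body[start:]:
        parts = row.split(",")
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed Code_Summary row {row!r}")
        code_class, name, _accession, count = parts[0], parts[1], parts[2], parts[3]
        if code_class not in _CODECLASS_MAP:
            raise ValueError(f"{path}: unknown CodeClass {code_class!r}")
        cls = _CODECLASS_MAP[code_class]
        conc = None
        if cls is ProbeClass.POSITIVE:
            m = _POS_CONC.search(name)
            if m:
                conc = float(m.group(1))
        rows.append((cls, name, conc, int(count)))
    return sample_id, rows


def read_rcc(
    paths: list[str | Path], panel: PanelDefinition | None = None
) -> tuple[CountMatrix, PanelDefinition]:
    """Read one lane per RCC file into a RAW matrix; infer the panel."""
    if not paths:
        raise ValueError("no RCC files given")
    lanes = [_parse_rcc(Path(p)) for p in paths]

    ref_names = [name for _cls, name, _c, _n in lanes[0][1]]
    for (sample, rows), p in zip(lanes[1:], paths[1:]):
        names = [name for _cls, name, _c, _n in rows]
        if names != ref_names:
            diff = sorted(set(names) ^ set(ref_names))
            raise ValueError(
                f"{p}: probe list differs from {paths[0]}; symmetric difference: {diff}"
            )

    probes = []
    for cls, name, conc, _count in lanes[0][1]:
        if cls is ProbeClass.POSITIVE and conc is None:
            raise ValueError(
                f"{paths[0]}: positive probe {name!r} lacks a '(conc)' name suffix"
            )
        probes.append(Probe(name, cls, conc))
    inferred = PanelDefinition(tuple(probes))
    if panel is not None and panel.names() != inferred.names():
        diff = sorted(set(panel.names()) ^ set(inferred.names()))
        raise ValueError(f"RCC probes do not match supplied panel; difference: {diff}")

    data = {
        sample: [count for _cls, _name, _c, count in rows] for sample, rows in lanes
    }
    values = pd.DataFrame(data, index=ref_names, dtype=float)
    return CountMatrix(values, Stage.RAW, panel or inferred), inferred
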