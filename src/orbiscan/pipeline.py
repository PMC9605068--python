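"""End-to-end orchestration: normalize -> differential -> GSEA -> projection.

A run consumes a raw count matrix, panel, sample metadata and a gene-set
collection, executes every stage for each one-vs-rest contrast, and writes a
self-contained results directory. A manifest records the config, input
digests, seed and per-stage row counts; re-running with the same inputs and
seed reproduces byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import Contrast, differential_table
from .gsea import score_gene_sets
from .model import (
    CountMatrix,
    GeneSetCollection,
    PanelDefinition,
    RunConfig,
    SampleMetadata,
    filter_gene_sets,
)
from .normalization import normalize_pipeline
from .projection import project_pathway

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    version: str
    seed: int
    created: str
    stage_counts: dict[str, int]
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _safe_name(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label)


def run_pipeline(
    matrix: CountMatrix,
    panel: PanelDefinition,
    metadata: SampleMetadata,
    collection: GeneSetCollection,
    config: RunConfig,
    out_dir: str | Path,
    input_paths: dict[str, str | Path] | None = None,
) -> RunManifest:
    """Execute the full chain and write a results directory.

    Outputs: normalized_counts.tsv, normalization_report.json,
    differential_<contrast>.tsv, gsea_<contrast>.tsv,
    projection_<contrast>_<set>.tsv (for sets at fdr_q <= alpha),
    manifest.json and report.md. On a stage error the partially written
    outputs of this run are removed and the stage name is reported.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    metadata.validate_against(matrix)

    def _write_tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)
        written.append(path)

    stage = "normalize"
    try:
        normalized, report = normalize_pipeline(matrix, panel, config)
        _write_tsv(normalized.values, "normalized_counts.tsv", index=True)
        (out / "normalization_report.json").write_text(report.to_json())
        written.append(out / "normalization_report.json")
        stage_counts = {"normalized_genes": normalized.shape[0]}

        contrasts = [Contrast(g, None) for g in metadata.groups]
        for contrast in contrasts:
            stage = f"differential[{contrast.label}]"
            diff = differential_table(normalized, metadata, contrast, config)
            _write_tsv(diff, f"differential_{_safe_name(contrast.label)}.tsv")
            stage_counts[f"differential_{contrast.label}"] = len(diff)

            stage = f"gsea[{contrast.label}]"
            usable = filter_gene_sets(
                collection, normalized.gene_names,
                config.min_set_size, config.max_set_size, logger=log,
            )
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 101, contrasts.index(contrast)))
            )
            gsea = score_gene_sets(
                normalized, metadata, contrast, usable, config, rng=rng
            )
            _write_tsv(gsea, f"gsea_{_safe_name(contrast.label)}.tsv")
            stage_counts[f"gsea_{contrast.label}"] = len(gsea)

            stage = f"projection[{contrast.label}]"
            hits = gsea[gsea["fdr_q"] <= config.alpha]["set"]
            for set_name in hits:
                proj = project_pathway(
                    diff, set_name, usable.members(set_name),
                    config.projection_threshold, contrast.label,
                )
                _write_tsv(
                    proj.to_frame(),
                    f"projection_{_safe_name(contrast.label)}_{_safe_name(set_name)}.tsv",
                )
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageFailure(stage, exc) from exc

    digests = {}
    if input_paths:
        digests = {k: _sha256(Path(v)) for k, v in input_paths.items()}
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_digests=digests,
        version=__version__,
        seed=config.seed,
        created=datetime.now(timezone.utc).isoformat(),
        stage_counts=stage_counts,
        outputs=sorted(p.name for p in written),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    render_report(out)
    return manifest


def render_report(results_dir: str | Path) -> Path:
    """Assemble report.md purely from the TSV/JSON outputs (no recomputation).

    Missing stage outputs are noted as gaps rather than failing.
    """
    out = Path(results_dir)
    lines = ["# Run report", ""]

    rep_path = out / "normalization_report.json"
    if rep_path.exists():
        rep = json.loads(rep_path.read_text())
        lines += ["## Normalization", ""]
        lines += ["| lane | technical factor | background threshold | biological factor |",
                  "|---|---|---|---|"]
        for lane in rep["technical_factors"]:
            lines.append(
                f"| {lane} | {rep['technical_factors'][lane]:.4g} "
                f"| {rep['background_thresholds'][lane]:.4g} "
                f"| {rep['biological_factors'][lane]:.4g} |"
            )
        lines += ["",
                  f"Retained genes: {len(rep['retained_genes'])}; "
                  f"excluded as not relevantly expressed: {len(rep['excluded_genes'])}.",
                  ""]
        if rep["excluded_genes"]:
            lines += ["| excluded gene | one-sided p |", "|---|---|"]
            for g, p in rep["excluded_genes"]:
                lines.append(f"| {g} | {p:.4g} |")
            lines.append("")
    else:
        lines += ["(normalization report missing)", ""]

    for gsea_path in sorted(out.glob("gsea_*.tsv")):
        contrast = gsea_path.stem.removeprefix("gsea_")
        df = pd.read_csv(gsea_path, sep="\t")
        lines += [f"## Enriched pathways: {contrast}", "",
                  "| set | size | ES | NES | p | FDR q |", "|---|---|---|---|---|---|"]
        for _, r in df.head(15).iterrows():
            lines.append(
                f"| {r['set']} | {r['size_used']} | {r['es']:.3f} | {r['nes']:.3f} "
                f"| {r['p_nominal']:.4g} | {r['fdr_q']:.4g} |"
            )
        lines.append("")
    if not list(out.glob("gsea_*.tsv")):
        lines += ["(no GSEA outputs found)", ""]

    for proj_path in sorted(out.glob("projection_*.tsv")):
        df = pd.read_csv(proj_path, sep="\t")
        lines += [f"## Projection: {proj_path.stem.removeprefix('projection_')}", "",
                  "| gene | log2FC | state |", "|---|---|---|"]
        for _, r in df.iterrows():
            lines.append(f"| {r['gene']} | {r['log2fc']:.3f} | {r['state']} |")
        lines.append("")

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
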