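"""Core data model for nCounter-style panel experiments.

An nCounter CodeSet measures a fixed catalogue of probes per lane (sample).
Four probe classes drive the processing chain: endogenous targets,
housekeeping/reference genes (biological normalization), positive controls
spiked at known concentrations (technical normalization), and negative
controls with no target (background estimation).
"""

from __future__ import annotations

import dataclasses
import enum
import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class ProbeClass(enum.Enum):
    ENDOGENOUS = "ENDOGENOUS"
    HOUSEKEEPING = "HOUSEKEEPING"
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class Stage(enum.Enum):
    """Position of a count matrix in the normalization chain."""

    RAW = "RAW"
    TECH_NORMALIZED = "TECH_NORMALIZED"
    BACKGROUND_SUBTRACTED = "BACKGROUND_SUBTRACTED"
    BIO_NORMALIZED = "BIO_NORMALIZED"


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class Probe:
    """One probe of the code set.

    ``concentration`` is the spike-in concentration in fM and is required for
    (and restricted to) positive control probes.
    """

    name: str
    probe_class: ProbeClass
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.probe_class is ProbeClass.POSITIVE:
            if self.concentration is None or not self.concentration > 0:
                raise PanelError(
                    f"positive probe {self.name!r} requires a positive concentration"
                )
        elif self.concentration is not None:
            raise PanelError(
                f"probe {self.name!r} ({self.probe_class.value}) must not carry a concentration"
            )


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered probe catalogue; the contract every matrix is checked against."""

    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", tuple(self.probes))
        names = [p.name for p in self.probes]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise PanelError(f"duplicate probe name {n!r} in panel")
            seen.add(n)

    def names(self, probe_class: ProbeClass | None = None) -> list[str]:
        if probe_class is None:
            return [p.name for p in self.probes]
        return [p.name for p in self.probes if p.probe_class is probe_class]

    @property
    def endogenous(self) -> list[str]:
        return self.names(ProbeClass.ENDOGENOUS)

    @property
    def housekeeping(self) -> list[str]:
        return self.names(ProbeClass.HOUSEKEEPING)

    @property
    def positive(self) -> list[str]:
        return self.names(ProbeClass.POSITIVE)

    @property
    def negative(self) -> list[str]:
        return self.names(ProbeClass.NEGATIVE)

    def concentration(self, name: str) -> float:
        for p in self.probes:
            if p.name == name:
                if p.concentration is None:
                    raise PanelError(f"probe {name!r} has no concentration")
                return p.concentration
        raise KeyError(name)

    def validate_for_normalization(self) -> None:
        """Minimum control content the normalization chain needs."""
        if len(self.housekeeping) < 1:
            raise PanelError("panel needs at least 1 housekeeping probe")
        if len(self.negative) < 2:
            raise PanelError("panel needs at least 2 negative control probes")
        if len(self.positive) < 2:
            raise PanelError("panel needs at least 2 positive control probes")

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class CountMatrix:
    """Gene-by-sample count grid with its processing stage.

    ``values`` keeps genes as rows (the dominant convention of expression file
    formats) and lanes/samples as columns. RAW matrices must hold non-negative
    integers; every later stage holds non-negative finite reals.
    """

    values: pd.DataFrame
    stage: Stage = Stage.RAW
    panel: PanelDefinition | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene name {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample name {dup!r}")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("count matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("count matrix contains negative values")
        if self.stage is Stage.RAW and not np.allclose(arr, np.round(arr)):
            raise ValueError("RAW-stage counts must be integers")
        if self.panel is not None:
            unknown = set(v.index) - set(self.panel.names())
            if unknown:
                raise ValueError(
                    f"genes not present in panel: {sorted(unknown)[:5]}"
                )

    @property
    def gene_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(genes)].copy(), self.stage, self.panel)

    def with_values(self, values: pd.DataFrame, stage: Stage) -> "CountMatrix":
        return CountMatrix(values, stage, self.panel)


@dataclass(frozen=True)
class SampleMetadata:
    """Sample-to-group assignment (the response variable of the contrasts)."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))

    @property
    def groups(self) -> list[str]:
        out: list[str] = []
        for g in self.assignments.values():
            if g not in out:
                out.append(g)
        return out

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def validate_against(self, matrix: CountMatrix, min_per_group: int = 2) -> None:
        missing = [s for s in matrix.sample_names if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        for g in self.groups:
            n = len([s for s in self.samples_in(g) if s in matrix.sample_names])
            if 0 < n < min_per_group:
                raise ValueError(
                    f"group {g!r} has {n} sample(s); at least {min_per_group} required"
                )


@dataclass(frozen=True)
class GeneSet:
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError("gene set must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene set members must be unique")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (KEGG-pathway style), e.g. parsed from a GMT file."""

    sets: Mapping[str, GeneSet]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", dict(self.sets))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name].members


def filter_gene_sets(
    collection: GeneSetCollection,
    universe: Sequence[str],
    min_size: int = 5,
    max_size: int = 500,
    logger=None,
) -> GeneSetCollection:
    """Intersect each set with the measured universe and drop sets outside
    [min_size, max_size]."""
    if len(universe) == 0:
        raise ValueError("gene universe is empty")
    uni = set(universe)
    kept: dict[str, GeneSet] = {}
    for name, gs in collection:
        inter = tuple(m for m in gs.members if m in uni)
        if min_size <= len(inter) <= max_size:
            kept[name] = GeneSet(gs.description, inter)
        elif logger is not None:
            logger.info(
                "dropping gene set %s: %d members in universe (bounds %d..%d)",
                name, len(inter), min_size, max_size,
            )
    if not kept:
        raise ValueError(
            "no gene set survives size filtering; relax min/max set size bounds"
        )
    return GeneSetCollection(kept)


_PERMUTATION_MODES = ("GENE_SET", "PHENOTYPE")


@dataclass
class RunConfig:
    """Run-level knobs shared across the pipeline.

    The defaults mirror the conventional GSEA setup: 1000 permutations,
    weight-1 enrichment statistic, gene-set (gene-label) permutation, set
    size bounds 5..500, and |log2FC| >= 0.25 for the pathway projection.
    """

    seed: int = 0
    n_permutations: int = 1000
    alpha: float = 0.05
    gsea_weight: float = 1.0
    permutation_mode: str = "GENE_SET"
    min_set_size: int = 5
    max_set_size: int = 500
    projection_threshold: float = 0.25
    # normalization knobs
    tech_factor: str = "sum"          # "sum" | "geomean" of positive probes
    filter_stage: str = "post"        # background filter "pre" | "post" bio-normalization
    subtract_before_technical: bool = False
    welch_filter: bool = True         # Welch vs pooled-variance background filter
    # statistics knobs
    fdr_method: str = "bh"            # "bh" | "by" for differential tables
    gsea_fdr: str = "nes_ratio"       # "nes_ratio" | "bh"
    rank_metric: str = "SIGNAL2NOISE"  # or "LOG2_MEDIAN_RATIO"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.gsea_weight < 0:
            raise ValueError("gsea_weight must be non-negative")
        if self.permutation_mode not in _PERMUTATION_MODES:
            raise ValueError(f"permutation_mode must be one of {_PERMUTATION_MODES}")
        if self.min_set_size < 1 or self.max_set_size < self.min_set_size:
            raise ValueError("require 1 <= min_set_size <= max_set_size")
        if self.projection_threshold < 0:
            raise ValueError("projection_threshold must be non-negative")
        if self.tech_factor not in ("sum", "geomean"):
            raise ValueError("tech_factor must be 'sum' or 'geomean'")
        if self.filter_stage not in ("pre", "post"):
            raise ValueError("filter_stage must be 'pre' or 'post'")
        if self.fdr_method not in ("bh", "by"):
            raise ValueError("fdr_method must be 'bh' or 'by'")
        if self.gsea_fdr not in ("nes_ratio", "bh"):
            raise ValueError("gsea_fdr must be 'nes_ratio' or 'bh'")
        if self.rank_metric not in ("SIGNAL2NOISE", "LOG2_MEDIAN_RATIO"):
            raise ValueError("unknown rank_metric")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config YAML must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
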