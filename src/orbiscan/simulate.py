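"""Synthetic nCounter-like count panels with known ground truth.

The generative model is a negative binomial hybridization count with a
multiplicative per-lane technical factor plus additive Poisson background:

    endogenous gene i, lane j in group g:
        count ~ NB(mean = t_j * 2**(b_i + delta_{i,g}), dispersion) + Pois(bg)
    housekeeping:  delta = 0
    positive probe with concentration c:  count ~ Pois(t_j * c * POS_SCALE) + Pois(bg)
    negative probe:  count ~ Pois(bg)             (independent of t_j)

with t_j ~ LogNormal(0, lane_factor_sd) and NB variance mu + dispersion*mu^2.
Lane effects multiply everything except negatives, which is exactly what
positive-control normalization can remove; background is additive and common
to all classes, which is what the negative-control mean+2SD threshold targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

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

#: counts per fM of positive-control spike at technical factor 1
POS_SCALE = 150.0

_MAX_MEAN = float(2**31)


@dataclass(frozen=True)
class SpikedSet:
    """A gene set whose target_group gets a log2 fold change spiked into
    ``affected_fraction`` of its members (the leading members, in order)."""

    name: str
    members: tuple[str, ...]
    log2fc: float
    affected_fraction: float
    target_group: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not 0 < self.affected_fraction <= 1:
            raise ValueError("affected_fraction must be in (0, 1]")

    @property
    def affected_members(self) -> tuple[str, ...]:
        n = max(1, round(self.affected_fraction * len(self.members)))
        return self.members[:n]


@dataclass(frozen=True)
class SimulationDesign:
    n_endogenous: int
    n_housekeeping: int
    n_positive: int
    n_negative: int
    groups: dict[str, int]
    baseline_log2_mean_range: tuple[float, float] = (5.0, 10.0)
    nb_dispersion: float = 0.1
    lane_factor_sd: float = 0.2
    background_mean: float = 10.0
    spiked_sets: tuple[SpikedSet, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", dict(self.groups))
        object.__setattr__(self, "spiked_sets", tuple(self.spiked_sets))
        if self.n_negative < 2 or self.n_positive < 2 or self.n_housekeeping < 1:
            raise ValueError(
                "need >= 2 negative, >= 2 positive and >= 1 housekeeping probes"
            )
        if self.n_endogenous < 1:
            raise ValueError("need at least one endogenous gene")
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("every group needs at least 2 samples")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ValueError("baseline_log2_mean_range must be (low, high)")
        if self.nb_dispersion < 0 or self.lane_factor_sd < 0 or self.background_mean < 0:
            raise ValueError("dispersion, lane_factor_sd and background_mean must be >= 0")
        endo = set(_endogenous_names(self.n_endogenous))
        for s in self.spiked_sets:
            if not set(s.members) <= endo:
                raise ValueError(
                    f"spiked set {s.name!r} has members outside the endogenous genes"
                )
            if s.target_group not in self.groups:
                raise ValueError(
                    f"spiked set {s.name!r} targets unknown group {s.target_group!r}"
                )


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually planted, for recovery testing."""

    log2fc: pd.DataFrame          # endogenous genes x groups, true delta
    lane_factors: pd.Series       # per-lane technical factor t_j
    enriched_sets: tuple[str, ...]


def _endogenous_names(n: int) -> list[str]:
    return [f"GENE_{i + 1:04d}" for i in range(n)]


def positive_ladder(n: int, top: float = 128.0, step: float = 4.0) -> list[float]:
    """Concentration ladder for positive probes: 128, 32, 8, ... (fM)."""
    return [top / step**i for i in range(n)]


def simulate_panel(design: SimulationDesign) -> PanelDefinition:
    """Deterministic panel matching the design's class counts."""
    probes: list[Probe] = []
    probes += [Probe(n, ProbeClass.ENDOGENOUS) for n in _endogenous_names(design.n_endogenous)]
    probes += [
        Probe(f"HK_{i + 1:02d}", ProbeClass.HOUSEKEEPING)
        for i in range(design.n_housekeeping)
    ]
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for i, conc in enumerate(positive_ladder(design.n_positive)):
        probes.append(Probe(f"POS_{letters[i]}({conc:g})", ProbeClass.POSITIVE, conc))
    probes += [
        Probe(f"NEG_{i + 1:02d}", ProbeClass.NEGATIVE) for i in range(design.n_negative)
    ]
    return PanelDefinition(tuple(probes))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2 (Poisson when dispersion == 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def simulate_counts(
    panel: PanelDefinition, design: SimulationDesign
) -> tuple[CountMatrix, SampleMetadata, GroundTruth]:
    """Draw a RAW count matrix from the generative model.

    Reproducible from ``design.seed``: one RNG stream, draw order fixed
    (baselines, lane factors, then lanes outer / probe classes inner).
    """
    rng = np.random.default_rng(design.seed)
    endo = panel.endogenous
    hk = panel.housekeeping
    pos = panel.positive
    neg = panel.negative
    if len(endo) != design.n_endogenous or len(hk) != design.n_housekeeping:
        raise ValueError("panel does not match design")

    lo, hi = design.baseline_log2_mean_range
    b_endo = rng.uniform(lo, hi, size=len(endo))
    b_hk = rng.uniform(lo, hi, size=len(hk))

    samples: list[str] = []
    sample_group: dict[str, str] = {}
    for g, n in design.groups.items():
        for i in range(n):
            name = f"{g}_{i + 1:02d}"
            samples.append(name)
            sample_group[name] = g

    t = rng.lognormal(mean=0.0, sigma=design.lane_factor_sd, size=len(samples))

    # true per-gene, per-group log2 shifts
    delta = pd.DataFrame(0.0, index=endo, columns=list(design.groups))
    for s in design.spiked_sets:
        for m in s.affected_members:
            delta.loc[m, s.target_group] += s.log2fc

    conc = np.array([panel.concentration(p) for p in pos])

    max_mean = t.max() * 2.0 ** (
        max(b_endo.max(initial=-np.inf), b_hk.max(initial=-np.inf))
        + max((abs(s.log2fc) for s in design.spiked_sets), default=0.0)
    )
    if max_mean > _MAX_MEAN or t.max() * conc.max() * POS_SCALE > _MAX_MEAN:
        raise ValueError(
            "simulated means exceed 2^31; use a smaller baseline_log2_mean_range"
        )

    cols: dict[str, np.ndarray] = {}
    for j, s in enumerate(samples):
        g = sample_group[s]
        mu_endo = t[j] * 2.0 ** (b_endo + delta[g].to_numpy())
        c_endo = _nb_draw(rng, mu_endo, design.nb_dispersion)
        c_endo = c_endo + rng.poisson(design.background_mean, size=len(endo))
        c_hk = _nb_draw(rng, t[j] * 2.0**b_hk, design.nb_dispersion)
        c_hk = c_hk + rng.poisson(design.background_mean, size=len(hk))
        c_pos = rng.poisson(t[j] * conc * POS_SCALE) + rng.poisson(
            design.background_mean, size=len(pos)
        )
        c_neg = rng.poisson(design.background_mean, size=len(neg))
        cols[s] = np.concatenate([c_endo, c_hk, c_pos, c_neg])

    values = pd.DataFrame(cols, index=endo + hk + pos + neg, dtype=float)
    matrix = CountMatrix(values, Stage.RAW, panel)
    metadata = SampleMetadata(sample_group)
    truth = GroundTruth(
        log2fc=delta,
        lane_factors=pd.Series(t, index=samples),
        enriched_sets=tuple(s.name for s in design.spiked_sets),
    )
    return matrix, metadata, truth


# ------------------------------------------------------------- canned designs

#: documented default seed of the canned design (publication date digits)
PAPER_LIKE_SEED = 20221020


def paper_like_design(seed: int = PAPER_LIKE_SEED) -> SimulationDesign:
    """A reduced three-entity design: groups of 6/3/3 samples, 300 endogenous
    genes, 30 reference genes, 6 positive and 8 negative controls, with three
    spiked gene sets (an ECM-like and an adipocytokine-like set up in the
    lymphoma-like group B, one set up in group C)."""
    endo = _endogenous_names(300)
    spiked = (
        SpikedSet("ECM_LIKE", tuple(endo[0:24]), 1.5, 0.75, "B"),
        SpikedSet("ADIPOCYTOKINE_LIKE", tuple(endo[24:44]), 1.0, 0.6, "B"),
        SpikedSet("INNATE_IMMUNE_LIKE", tuple(endo[44:74]), 1.0, 0.6, "C"),
    )
    return SimulationDesign(
        n_endogenous=300,
        n_housekeeping=30,
        n_positive=6,
        n_negative=8,
        groups={"A": 6, "B": 3, "C": 3},
        baseline_log2_mean_range=(5.0, 10.0),
        nb_dispersion=0.1,
        lane_factor_sd=0.2,
        background_mean=10.0,
        spiked_sets=spiked,
        seed=seed,
    )


def design_gene_sets(
    design: SimulationDesign,
    n_null_sets: int = 7,
    size_range: tuple[int, int] = (15, 40),
) -> GeneSetCollection:
    """Gene-set collection to analyse a simulated design with: the spiked sets
    plus ``n_null_sets`` random sets drawn from the endogenous genes
    (deterministic from design.seed)."""
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 911)))
    endo = _endogenous_names(design.n_endogenous)
    sets: dict[str, GeneSet] = {
        s.name: GeneSet(f"spiked {s.log2fc:+g} in {s.target_group}", s.members)
        for s in design.spiked_sets
    }
    lo, hi = size_range
    for i in range(n_null_sets):
        k = int(rng.integers(lo, hi + 1))
        members = tuple(sorted(rng.choice(endo, size=k, replace=False)))
        sets[f"NULL_SET_{i + 1:02d}"] = GeneSet("random null set", members)
    return GeneSetCollection(sets)
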