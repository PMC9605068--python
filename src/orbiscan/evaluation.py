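"""Operating-characteristic studies of the pipeline on simulated panels.

Since the original patient counts are not public, the pipeline is validated
by simulation: does normalization equalize what it is defined to equalize,
does the expression filter separate background from signal, is the GSEA
nominal p calibrated under the null, and are planted differential genes and
enriched sets recovered? Each function here runs one such study from scratch
and returns the measured quantities; the test suite and the acceptance
script both call them.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import Contrast, differential_table
from .gsea import score_gene_sets
from .model import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    PanelDefinition,
    Probe,
    ProbeClass,
    RunConfig,
    SampleMetadata,
    Stage,
)
from .normalization import (
    background_threshold,
    biological_normalize,
    normalize_pipeline,
    subtract_background,
    technical_normalize,
)
from .pipeline import run_pipeline
from .simulate import SimulationDesign, SpikedSet, simulate_counts, simulate_panel


def _subseed(seed: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(seed) % 2**31, *tags))


def _random_panel_matrix(rng: np.random.Generator, n_samples: int) -> tuple[PanelDefinition, CountMatrix]:
    probes = tuple(
        [Probe(f"G{i:02d}", ProbeClass.ENDOGENOUS) for i in range(8)]
        + [Probe(f"HK{i}", ProbeClass.HOUSEKEEPING) for i in range(3)]
        + [Probe("P1(128)", ProbeClass.POSITIVE, 128.0),
           Probe("P2(32)", ProbeClass.POSITIVE, 32.0),
           Probe("P3(8)", ProbeClass.POSITIVE, 8.0)]
        + [Probe(f"N{i}", ProbeClass.NEGATIVE) for i in range(6)]
    )
    panel = PanelDefinition(probes)
    neg = set(panel.negative)
    rows = [
        rng.integers(1, 30, size=n_samples) if p in neg
        else rng.integers(500, 5000, size=n_samples)
        for p in panel.names()
    ]
    values = pd.DataFrame(
        np.array(rows, dtype=float), index=panel.names(),
        columns=[f"S{i:02d}" for i in range(n_samples)],
    )
    return panel, CountMatrix(values, Stage.RAW, panel)


def normalization_equalization(seed: int, n_matrices: int = 50) -> dict[str, float]:
    """Worst-case relative spread, across random matrices, of the quantities
    normalization is defined to equalize: per-lane positive-probe sums after
    technical normalization and housekeeping geometric means after
    biological normalization."""
    rng = np.random.default_rng(_subseed(seed, 1))
    worst_pos = worst_hk = 0.0
    for _ in range(n_matrices):
        panel, raw = _random_panel_matrix(rng, int(rng.integers(3, 9)))
        tech, _ = technical_normalize(raw, panel)
        sums = tech.values.loc[panel.positive].sum(axis=0).to_numpy()
        worst_pos = max(worst_pos, np.abs(sums / sums.mean() - 1).max())
        thr = background_threshold(tech, panel)
        bio, _ = biological_normalize(subtract_background(tech, thr), panel)
        hk = bio.values.loc[panel.housekeeping]
        usable = hk[(hk > 0).all(axis=1)]
        gms = np.exp(np.log(usable).mean(axis=0)).to_numpy()
        worst_hk = max(worst_hk, np.abs(gms / gms.mean() - 1).max())
    return {
        "max_rel_dev_positive_sums": float(worst_pos),
        "max_rel_dev_housekeeping_geomeans": float(worst_hk),
    }


def filter_operating_characteristics(
    seed: int, n_genes: int = 1000, n_samples: int = 12, background: float = 50.0
) -> dict[str, float]:
    """Exclusion rate for genes at negative-control level and retention rate
    for genes 10x above background, through the full normalization chain."""
    rng = np.random.default_rng(_subseed(seed, 2))
    n_null = n_genes // 2
    n_expr = n_genes - n_null
    probes = tuple(
        [Probe(f"NULLG{i:04d}", ProbeClass.ENDOGENOUS) for i in range(n_null)]
        + [Probe(f"EXPRG{i:04d}", ProbeClass.ENDOGENOUS) for i in range(n_expr)]
        + [Probe(f"HK{i:02d}", ProbeClass.HOUSEKEEPING) for i in range(10)]
        + [Probe("P1(128)", ProbeClass.POSITIVE, 128.0),
           Probe("P2(32)", ProbeClass.POSITIVE, 32.0),
           Probe("P3(8)", ProbeClass.POSITIVE, 8.0),
           Probe("P4(2)", ProbeClass.POSITIVE, 2.0)]
        + [Probe(f"N{i:02d}", ProbeClass.NEGATIVE) for i in range(8)]
    )
    panel = PanelDefinition(probes)
    means = {p.name: background for p in probes}
    for i in range(n_expr):
        means[f"EXPRG{i:04d}"] = 10.0 * background
    for i in range(10):
        means[f"HK{i:02d}"] = 2000.0
    for p in panel.positive:
        means[p] = panel.concentration(p) * 150.0 + background
    values = pd.DataFrame(
        {s: rng.poisson([means[p] for p in panel.names()]).astype(float)
         for s in [f"S{i:02d}" for i in range(n_samples)]},
        index=panel.names(),
    )
    raw = CountMatrix(values, Stage.RAW, panel)
    _, report = normalize_pipeline(raw, panel, RunConfig())
    excluded = {g for g, _ in report.excluded_genes}
    retained = set(report.retained_genes)
    return {
        "background_gene_exclusion_rate": sum(
            1 for i in range(n_null) if f"NULLG{i:04d}" in excluded
        ) / n_null,
        "expressed_gene_retention_rate": sum(
            1 for i in range(n_expr) if f"EXPRG{i:04d}" in retained
        ) / n_expr,
    }


def _endogenous_bio_matrix(design: SimulationDesign):
    panel = simulate_panel(design)
    matrix, metadata, truth = simulate_counts(panel, design)
    endo = CountMatrix(
        matrix.values.loc[panel.endogenous], Stage.BIO_NORMALIZED, panel
    )
    return endo, metadata, truth


def gsea_null_calibration(
    seed: int, n_seeds: int = 20, n_sets: int = 50, n_permutations: int = 1000
) -> dict[str, float]:
    """Fraction of gene sets with nominal p < 0.05 on unspiked data.

    Calibration means this fraction sits near 0.05 (the add-one estimator is
    slightly conservative)."""
    base = np.random.default_rng(_subseed(seed, 3))
    p_values: list[float] = []
    for i in range(n_seeds):
        design = SimulationDesign(
            n_endogenous=300, n_housekeeping=10, n_positive=4, n_negative=8,
            groups={"A": 6, "B": 6}, nb_dispersion=0.1, lane_factor_sd=0.0,
            background_mean=0.0, seed=int(base.integers(2**31)),
        )
        matrix, metadata, _ = _endogenous_bio_matrix(design)
        rng = np.random.default_rng(int(base.integers(2**31)))
        genes = matrix.gene_names
        coll = GeneSetCollection({
            f"SET_{j:02d}": GeneSet("null", tuple(
                rng.choice(genes, size=int(rng.integers(15, 41)), replace=False)
            ))
            for j in range(n_sets)
        })
        cfg = RunConfig(seed=int(base.integers(2**31)), n_permutations=n_permutations)
        table = score_gene_sets(
            matrix, metadata, Contrast("A"), coll, cfg,
            rng=np.random.default_rng(int(base.integers(2**31))),
        )
        p_values.extend(table["p_nominal"].tolist())
    p = np.asarray(p_values)
    return {
        "null_fraction_p_below_05": float(np.mean(p < 0.05)),
        "n_set_tests": int(len(p)),
    }


def gsea_spike_recovery(
    seed: int, n_seeds: int = 20, n_permutations: int = 1000
) -> dict[str, float]:
    """How often a spiked set (60% of 20 members at log2FC = 1, group vs
    rest) reaches NES > 0 with fdr_q < 0.05."""
    base = np.random.default_rng(_subseed(seed, 4))
    successes = 0
    for i in range(n_seeds):
        endo_names = [f"GENE_{j + 1:04d}" for j in range(300)]
        spike = SpikedSet("SPIKED", tuple(endo_names[:20]), 1.0, 0.6, "A")
        design = SimulationDesign(
            n_endogenous=300, n_housekeeping=10, n_positive=4, n_negative=8,
            groups={"A": 6, "B": 6}, nb_dispersion=0.1, lane_factor_sd=0.0,
            background_mean=0.0, spiked_sets=(spike,),
            seed=int(base.integers(2**31)),
        )
        matrix, metadata, _ = _endogenous_bio_matrix(design)
        rng = np.random.default_rng(int(base.integers(2**31)))
        sets = {"SPIKED": GeneSet("spiked", spike.members)}
        for j in range(19):
            sets[f"NULL_{j:02d}"] = GeneSet("null", tuple(
                rng.choice(endo_names[20:], size=20, replace=False)
            ))
        cfg = RunConfig(seed=int(base.integers(2**31)), n_permutations=n_permutations)
        table = score_gene_sets(
            matrix, metadata, Contrast("A"), GeneSetCollection(sets), cfg,
            rng=np.random.default_rng(int(base.integers(2**31))),
        ).set_index("set")
        row = table.loc["SPIKED"]
        if row["nes"] > 0 and row["fdr_q"] < 0.05:
            successes += 1
    return {"spiked_set_recovered_seeds": float(successes), "n_seeds": float(n_seeds)}


def differential_recovery(seed: int, n_seeds: int = 20) -> dict[str, float]:
    """Sensitivity and false-discovery proportion at FDR <= 0.05 for 20
    genes spiked at log2FC = 2 among 300 (n = 6 vs 6, NB dispersion 0.1)."""
    base = np.random.default_rng(_subseed(seed, 5))
    sens, fdp = [], []
    for i in range(n_seeds):
        endo_names = [f"GENE_{j + 1:04d}" for j in range(300)]
        spike = SpikedSet("DE", tuple(endo_names[:20]), 2.0, 1.0, "A")
        design = SimulationDesign(
            n_endogenous=300, n_housekeeping=10, n_positive=4, n_negative=8,
            groups={"A": 6, "B": 6}, nb_dispersion=0.1, lane_factor_sd=0.0,
            background_mean=0.0, spiked_sets=(spike,),
            seed=int(base.integers(2**31)),
        )
        matrix, metadata, _ = _endogenous_bio_matrix(design)
        table = differential_table(matrix, metadata, Contrast("A"), RunConfig())
        called = set(table[table["fdr_p"] <= 0.05]["gene"])
        true = set(endo_names[:20])
        tp = len(called & true)
        sens.append(tp / len(true))
        fdp.append((len(called) - tp) / max(1, len(called)))
    return {
        "differential_sensitivity": float(np.mean(sens)),
        "differential_fdp": float(np.mean(fdp)),
    }


def determinism_check(seed: int, work_dir: str | Path) -> dict[str, float]:
    """Run the full pipeline twice with one seed; 1.0 if every stage output
    is byte-identical (the manifest is compared without its timestamp)."""
    from .simulate import design_gene_sets, paper_like_design

    design = paper_like_design(int(seed) % 2**31)
    panel = simulate_panel(design)
    matrix, metadata, _ = simulate_counts(panel, design)
    collection = design_gene_sets(design)
    cfg = RunConfig(seed=int(seed) % 2**31, n_permutations=200)
    work = Path(work_dir)
    out1, out2 = work / "run1", work / "run2"
    run_pipeline(matrix, panel, metadata, collection, cfg, out1)
    run_pipeline(matrix, panel, metadata, collection, cfg, out2)
    names1 = sorted(p.name for p in out1.iterdir())
    names2 = sorted(p.name for p in out2.iterdir())
    identical = names1 == names2
    for name in names1 if identical else []:
        if name == "manifest.json":
            a = json.loads((out1 / name).read_text())
            b = json.loads((out2 / name).read_text())
            a.pop("created"), b.pop("created")
            identical &= a == b
        else:
            identical &= (out1 / name).read_bytes() == (out2 / name).read_bytes()
    return {"byte_identical_runs": 1.0 if identical else 0.0}
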