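"""Control-probe normalization chain for nCounter count data.

Order of operations (each falsifiable on simulated data):

1. technical normalization — scale each lane so positive-control signal is
   equal across lanes (removes assay-efficiency differences);
2. background threshold — per lane, mean + 2*SD of the negative controls;
3. background subtraction — subtract the lane threshold from endogenous and
   housekeeping counts, clamping at zero;
4. biological normalization — scale each lane so the geometric mean of the
   housekeeping genes is equal across lanes (removes input-amount
   differences);
5. background filter — one-sided two-sample t-test of each endogenous gene's
   counts against the pooled negative-control counts; genes not significantly
   above the negatives are excluded as not relevantly expressed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CountMatrix, PanelDefinition, RunConfig, Stage

log = logging.getLogger(__name__)


class StageError(ValueError):
    pass


def _require_stage(matrix: CountMatrix, stage: Stage) -> None:
    if matrix.stage is not stage:
        raise StageError(f"expected {stage.value} matrix, got {matrix.stage.value}")


@dataclass
class NormalizationReport:
    technical_factors: pd.Series      # per lane
    background_thresholds: pd.Series  # per lane, counts
    biological_factors: pd.Series     # per lane
    excluded_genes: list[tuple[str, float]]   # (gene, one-sided p)
    retained_genes: list[str]

    def to_dict(self) -> dict:
        return {
            "technical_factors": {k: float(v) for k, v in self.technical_factors.items()},
            "background_thresholds": {
                k: float(v) for k, v in self.background_thresholds.items()
            },
            "biological_factors": {k: float(v) for k, v in self.biological_factors.items()},
            "excluded_genes": [[g, float(p)] for g, p in self.excluded_genes],
            "retained_genes": list(self.retained_genes),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def technical_normalize(
    raw: CountMatrix, panel: PanelDefinition, factor: str = "sum"
) -> tuple[CountMatrix, pd.Series]:
    """Scale each lane by mean(positive summary over lanes) / lane summary.

    The per-lane summary of the positive probes is their sum (default) or
    geometric mean. After scaling, every lane has the same summary.
    """
    _require_stage(raw, Stage.RAW)
    pos = panel.positive
    if len(pos) < 2:
        raise ValueError("technical normalization needs >= 2 positive probes")
    sub = raw.values.loc[pos]
    if factor == "sum":
        summary = sub.sum(axis=0)
    elif factor == "geomean":
        if (sub.to_numpy() <= 0).any():
            raise ValueError("geomean technical factor requires positive counts")
        summary = np.exp(np.log(sub).mean(axis=0))
    else:
        raise ValueError("factor must be 'sum' or 'geomean'")
    zero = summary.index[summary <= 0]
    if len(zero):
        raise ValueError(f"lane {zero[0]!r} has zero positive-probe signal")
    factors = summary.mean() / summary
    values = raw.values.mul(factors, axis=1)
    return raw.with_values(values, Stage.TECH_NORMALIZED), factors


def background_threshold(matrix: CountMatrix, panel: PanelDefinition) -> pd.Series:
    """Per-lane threshold: mean + 2*SD (ddof=1) of that lane's negative probes."""
    _require_stage(matrix, Stage.TECH_NORMALIZED)
    neg = panel.negative
    if len(neg) < 2:
        raise ValueError("background threshold needs >= 2 negative probes (SD undefined)")
    sub = matrix.values.loc[neg]
    return sub.mean(axis=0) + 2.0 * sub.std(axis=0, ddof=1)


def subtract_background(matrix: CountMatrix, thresholds: pd.Series) -> CountMatrix:
    """Subtract each lane's threshold from endogenous and housekeeping counts,
    clamped at zero; control probes are left untouched."""
    _require_stage(matrix, Stage.TECH_NORMALIZED)
    panel = matrix.panel
    if panel is None:
        raise ValueError("matrix must carry a panel")
    values = matrix.values.copy()
    target = [g for g in values.index if g in set(panel.endogenous) | set(panel.housekeeping)]
    adjusted = values.loc[target].sub(thresholds, axis=1).clip(lower=0.0)
    values.loc[target] = adjusted
    return matrix.with_values(values, Stage.BACKGROUND_SUBTRACTED)


def biological_normalize(
    matrix: CountMatrix, panel: PanelDefinition
) -> tuple[CountMatrix, pd.Series]:
    """Scale each lane by mean(housekeeping geomean over lanes) / lane geomean.

    Housekeeping genes with a zero in any lane are dropped from the geometric
    mean (a pseudocount would break the equal-geomean invariant); if none
    remain, the error points at background subtraction.
    """
    _require_stage(matrix, Stage.BACKGROUND_SUBTRACTED)
    hk = [g for g in panel.housekeeping if g in matrix.values.index]
    if not hk:
        raise ValueError("no housekeeping genes present in matrix")
    sub = matrix.values.loc[hk]
    usable = sub.index[(sub > 0).all(axis=1)]
    if len(usable) == 0:
        raise ValueError(
            "no housekeeping gene is positive in every lane; "
            "inspect background subtraction (thresholds may swallow the reference genes)"
        )
    if len(usable) < len(hk):
        log.warning(
            "dropping %d housekeeping gene(s) with zeros from the geometric mean",
            len(hk) - len(usable),
        )
    g = np.exp(np.log(sub.loc[usable]).mean(axis=0))
    factors = g.mean() / g
    values = matrix.values.copy()
    target = [x for x in values.index if x in set(panel.endogenous) | set(panel.housekeeping)]
    values.loc[target] = values.loc[target].mul(factors, axis=1)
    return matrix.with_values(values, Stage.BIO_NORMALIZED), factors


def background_filter(
    matrix: CountMatrix,
    panel: PanelDefinition,
    alpha: float = 0.05,
    welch: bool = True,
) -> tuple[list[str], list[tuple[str, float]]]:
    """One-sided test of each endogenous gene vs the pooled negative controls.

    For each endogenous gene, the gene's counts across all samples are tested
    against the negative-control counts pooled across probes and samples
    (alternative: gene > negatives; Welch by default, pooled-variance
    optionally). A gene is retained iff p < alpha.
    """
    neg = [g for g in panel.negative if g in matrix.values.index]
    if len(neg) < 2:
        raise ValueError("background filter needs >= 2 negative probes")
    if matrix.shape[1] < 2:
        raise ValueError("background filter needs >= 2 samples")
    pooled = matrix.values.loc[neg].to_numpy().ravel()
    retained: list[str] = []
    excluded: list[tuple[str, float]] = []
    for gene in panel.endogenous:
        if gene not in matrix.values.index:
            continue
        vals = matrix.values.loc[gene].to_numpy()
        combined = np.concatenate([vals, pooled])
        if np.ptp(combined) == 0:
            log.warning("gene %s: all values identical to negatives; excluded (p=1)", gene)
            excluded.append((gene, 1.0))
            continue
        res = stats.ttest_ind(vals, pooled, equal_var=not welch, alternative="greater")
        p = float(res.pvalue)
        if not np.isfinite(p):
            log.warning("gene %s: degenerate background test; excluded (p=1)", gene)
            p = 1.0
        if p < alpha:
            retained.append(gene)
        else:
            excluded.append((gene, p))
    return retained, excluded


def normalize_pipeline(
    raw: CountMatrix, panel: PanelDefinition, config: RunConfig | None = None
) -> tuple[CountMatrix, NormalizationReport]:
    """Full chain: technical -> background -> biological -> expression filter.

    Returns the BIO_NORMALIZED matrix restricted to retained endogenous genes
    plus a report of every factor, threshold and exclusion.

    ``config.subtract_before_technical`` reverses the order of positive-probe
    scaling and negative-control subtraction; ``config.filter_stage = "pre"``
    applies the expression filter on background-subtracted rather than
    bio-normalized values.
    """
    config = config or RunConfig()
    _require_stage(raw, Stage.RAW)
    panel.validate_for_normalization()

    if config.subtract_before_technical:
        # estimate background on raw negatives, subtract, then lane-scale
        neg = raw.values.loc[panel.negative]
        thresholds = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
        shifted = dataclasses.replace(raw, stage=Stage.TECH_NORMALIZED)
        subtracted = subtract_background(shifted, thresholds)
        pos = subtracted.values.loc[panel.positive]
        if config.tech_factor == "sum":
            summary = pos.sum(axis=0)
        else:
            summary = pd.Series(
                np.exp(np.log(pos).mean(axis=0)), index=pos.columns
            )
        zero = summary.index[summary <= 0]
        if len(zero):
            raise ValueError(f"lane {zero[0]!r} has zero positive-probe signal")
        tech_factors = summary.mean() / summary
        subtracted = CountMatrix(
            subtracted.values.mul(tech_factors, axis=1),
            Stage.BACKGROUND_SUBTRACTED,
            panel,
        )
    else:
        tech, tech_factors = technical_normalize(raw, panel, config.tech_factor)
        thresholds = background_threshold(tech, panel)
        subtracted = subtract_background(tech, thresholds)

    bio, bio_factors = biological_normalize(subtracted, panel)

    filter_input = subtracted if config.filter_stage == "pre" else bio
    retained, excluded = background_filter(
        filter_input, panel, alpha=config.alpha, welch=config.welch_filter
    )
    for lane, f in tech_factors.items():
        log.info("lane %s: technical factor %.6g, threshold %.6g, biological factor %.6g",
                 lane, f, thresholds[lane], bio_factors[lane])
    for gene, p in excluded:
        log.info("excluding %s as not relevantly expressed (one-sided p=%.4g)", gene, p)

    report = NormalizationReport(
        technical_factors=tech_factors,
        background_thresholds=thresholds,
        biological_factors=bio_factors,
        excluded_genes=excluded,
        retained_genes=retained,
    )
    out = bio.subset_genes([g for g in panel.endogenous if g in set(retained)])
    return out, report
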