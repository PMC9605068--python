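"""Adaptive per-gene group comparisons with FDR control.

Each gene is first gated through a Shapiro–Wilk normality test per group.
If every group looks normal the parametric branch runs (Student's t-test for
two groups with a 95% CI on the mean difference, one-way ANOVA for more);
otherwise the rank-based branch runs (Mann–Whitney U, Kruskal–Wallis).
Effect sizes are log2 fold changes between group means (parametric) or
medians (non-parametric), with a pseudocount guarding zeros created by
background subtraction. P-values are adjusted across the whole gene table by
Benjamini–Hochberg (Benjamini–Yekutieli optionally).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CountMatrix, RunConfig, SampleMetadata, Stage

log = logging.getLogger(__name__)

T_TEST = "T_TEST"
WILCOXON = "WILCOXON"
ANOVA = "ANOVA"
KRUSKAL_WALLIS = "KRUSKAL_WALLIS"


@dataclass(frozen=True)
class Contrast:
    """``group`` against ``versus`` (another group) or, when ``versus`` is
    None, against all remaining samples (one-vs-rest)."""

    group: str
    versus: str | None = None

    @property
    def label(self) -> str:
        return f"{self.group}_vs_{self.versus or 'rest'}"


def normality_gate(
    values_by_group: dict[str, np.ndarray | list[float]], alpha: float = 0.05
) -> dict[str, bool]:
    """Shapiro–Wilk per group: True = compatible with normality (p >= alpha).

    Groups with fewer than 3 values or constant values cannot be tested and
    are flagged non-normal with a warning.
    """
    flags: dict[str, bool] = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 3:
            log.warning("group %s: %d value(s), too few for Shapiro-Wilk; flagged non-normal",
                        g, len(arr))
            flags[g] = False
        elif np.ptp(arr) == 0:
            log.warning("group %s: constant values; flagged non-normal", g)
            flags[g] = False
        else:
            flags[g] = bool(stats.shapiro(arr).pvalue >= alpha)
    return flags


def two_group_test(
    a, b, gate: dict[str, bool] | list[bool]
) -> tuple[str, float, tuple[float, float] | None]:
    """Student's t-test (all groups normal) or Mann–Whitney U otherwise.

    The rank branch uses the exact null distribution for small tie-free
    samples (min n <= 8) and the tie/continuity-corrected normal
    approximation otherwise. Returns (test_used, p, 95% CI or None).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    flags = list(gate.values()) if isinstance(gate, dict) else list(gate)
    parametric = all(flags)
    if np.ptp(np.concatenate([a, b])) == 0:
        log.warning("all values tied across both groups; p = 1")
        return (T_TEST if parametric else WILCOXON), 1.0, ((0.0, 0.0) if parametric else None)
    if parametric:
        res = stats.ttest_ind(a, b, equal_var=True)
        ci = res.confidence_interval(0.95)
        return T_TEST, float(res.pvalue), (float(ci.low), float(ci.high))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return WILCOXON, float(res.pvalue), None


def multi_group_test(
    values_by_group: dict[str, np.ndarray | list[float]],
    gate: dict[str, bool] | list[bool],
) -> tuple[str, float]:
    """One-way ANOVA (all groups normal) or tie-corrected Kruskal–Wallis."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 3:
        raise ValueError("multi-group test needs >= 3 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    flags = list(gate.values()) if isinstance(gate, dict) else list(gate)
    parametric = all(flags)
    if np.ptp(np.concatenate(groups)) == 0:
        log.warning("all values tied across groups; p = 1")
        return (ANOVA if parametric else KRUSKAL_WALLIS), 1.0
    if parametric:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.f_oneway(*groups)
        p = float(res.pvalue)
        return ANOVA, (1.0 if not np.isfinite(p) else p)
    res = stats.kruskal(*groups)
    return KRUSKAL_WALLIS, float(res.pvalue)


def log2_fold_change(a, b, parametric: bool, pseudocount: float = 1.0) -> float:
    """log2((m_a + c) / (m_b + c)); m = mean (parametric) or median."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = np.mean if parametric else np.median
    return float(np.log2((m(a) + pseudocount) / (m(b) + pseudocount)))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact Spearman p by enumerating rank permutations (n <= 9)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (ry[perms] * rx).mean(axis=1)
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def correlate(x, y) -> tuple[float, float, float, float]:
    """(pearson r, pearson p, spearman rho, spearman p), two-sided.

    Spearman p is exact (permutation enumeration) for n <= 9 without ties,
    else the usual t-approximation. Zero variance in either vector yields
    NaNs with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero variance input; correlation undefined")
        return math.nan, math.nan, math.nan, math.nan
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    rho, sp = float(sr.statistic), float(sr.pvalue)
    no_ties = len(set(x)) == len(x) and len(set(y)) == len(y)
    if len(x) <= 9 and no_ties:
        sp = _exact_spearman_p(x, y, rho)
    return float(pr.statistic), float(pr.pvalue), rho, sp


def bh_fdr(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_i = min over j >= i (in the ascending sort) of p_(j) * n / j, capped
    at 1. ``method='by'`` applies the Benjamini–Yekutieli correction instead.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    mt = "fdr_bh" if method == "bh" else "fdr_by"
    return multipletests(p, method=mt)[1]


def differential_table(
    matrix: CountMatrix,
    metadata: SampleMetadata,
    contrast: Contrast,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-gene adaptive two-group comparison for ``contrast``.

    Columns: gene, test_used, log2fc (group minus comparator, on the log2
    normalized-count scale), p_value, fdr_p, ci_low/ci_high (normalized-count
    difference scale, parametric branch only), normal_<side> flags.
    """
    config = config or RunConfig()
    if matrix.stage is not Stage.BIO_NORMALIZED:
        raise ValueError("differential table expects a BIO_NORMALIZED matrix")
    if contrast.group not in metadata.groups:
        raise ValueError(f"contrast group {contrast.group!r} absent from metadata")
    if contrast.versus is not None and contrast.versus not in metadata.groups:
        raise ValueError(f"contrast group {contrast.versus!r} absent from metadata")

    samples = set(matrix.sample_names)
    side_a = [s for s in metadata.samples_in(contrast.group) if s in samples]
    if contrast.versus is None:
        side_b = [
            s for s in matrix.sample_names
            if metadata.assignments[s] != contrast.group
        ]
    else:
        side_b = [s for s in metadata.samples_in(contrast.versus) if s in samples]
    if len(side_a) < 2 or len(side_b) < 2:
        raise ValueError("both sides of the contrast need >= 2 samples")

    rows = []
    for gene in matrix.gene_names:
        a = matrix.values.loc[gene, side_a].to_numpy(dtype=float)
        b = matrix.values.loc[gene, side_b].to_numpy(dtype=float)
        gate = normality_gate({"a": a, "b": b}, alpha=config.alpha)
        parametric = all(gate.values())
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append(
                dict(gene=gene, test_used=T_TEST if parametric else WILCOXON,
                     log2fc=0.0, p_value=1.0, ci_low=np.nan, ci_high=np.nan,
                     normal_a=gate["a"], normal_b=gate["b"])
            )
            continue
        test_used, p, ci = two_group_test(a, b, gate)
        lfc = log2_fold_change(a, b, parametric, config.pseudocount)
        rows.append(
            dict(gene=gene, test_used=test_used, log2fc=lfc, p_value=p,
                 ci_low=ci[0] if ci else np.nan, ci_high=ci[1] if ci else np.nan,
                 normal_a=gate["a"], normal_b=gate["b"])
        )
    table = pd.DataFrame(rows)
    table.insert(4, "fdr_p", bh_fdr(table["p_value"].to_numpy(), config.fdr_method))
    return table
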