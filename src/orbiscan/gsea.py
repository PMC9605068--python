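"""Permutation gene-set enrichment analysis (GSEA).

Genes are ranked by a differential metric (signal-to-noise by default); a
weighted Kolmogorov–Smirnov-style running sum over the ranked list gives each
set an enrichment score ES in [-1, 1]. A permutation null (random same-size
gene sets on the fixed ranking, or phenotype-label shuffles with re-ranking)
yields the normalized enrichment score NES = ES / mean(same-sign permuted
|ES|), an add-one nominal p, and an FDR q computed by the NES-ratio method
(fraction of permuted NES at least as extreme over fraction of observed NES
at least as extreme, capped at 1 and monotonized).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import Contrast, log2_fold_change
from .model import (
    CountMatrix,
    GeneSetCollection,
    RunConfig,
    SampleMetadata,
)

log = logging.getLogger(__name__)

SIGNAL2NOISE = "SIGNAL2NOISE"
LOG2_MEDIAN_RATIO = "LOG2_MEDIAN_RATIO"

#: signal-to-noise standard-deviation floor: sigma >= max(0.2*|mu|, _SD_FLOOR)
_SD_FLOOR = 0.2


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending score; ties broken by gene name ascending."""

    genes: tuple[str, ...]
    scores: np.ndarray
    metric_name: str
    contrast_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, members) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.genes)}
        return np.array(sorted(index[m] for m in members if m in index), dtype=int)


def _signal2noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(mu_A - mu_B) / (sigma_A + sigma_B) with floored sigmas, per gene row."""
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), np.maximum(_SD_FLOOR * np.abs(mu_a), _SD_FLOOR))
    sd_b = np.maximum(b.std(axis=1, ddof=1), np.maximum(_SD_FLOOR * np.abs(mu_b), _SD_FLOOR))
    return (mu_a - mu_b) / (sd_a + sd_b)


def rank_genes(
    matrix: CountMatrix,
    metadata: SampleMetadata,
    contrast: Contrast,
    metric: str = SIGNAL2NOISE,
    pseudocount: float = 1.0,
) -> RankedList:
    """Rank the matrix's genes for a group-vs-rest (or pairwise) contrast."""
    samples = set(matrix.sample_names)
    side_a = [s for s in metadata.samples_in(contrast.group) if s in samples]
    if contrast.versus is None:
        side_b = [s for s in matrix.sample_names if metadata.assignments[s] != contrast.group]
    else:
        side_b = [s for s in metadata.samples_in(contrast.versus) if s in samples]
    if len(side_a) < 2 or len(side_b) < 2:
        raise ValueError("each side of the contrast needs >= 2 samples")

    a = matrix.values[side_a].to_numpy(dtype=float)
    b = matrix.values[side_b].to_numpy(dtype=float)
    if metric == SIGNAL2NOISE:
        scores = _signal2noise(a, b)
    elif metric == LOG2_MEDIAN_RATIO:
        scores = np.log2(
            (np.median(a, axis=1) + pseudocount) / (np.median(b, axis=1) + pseudocount)
        )
    else:
        raise ValueError(f"unknown metric {metric!r}")

    names = np.array(matrix.gene_names)
    order = np.lexsort((names, -scores))
    return RankedList(
        genes=tuple(names[order]),
        scores=scores[order],
        metric_name=metric,
        contrast_label=contrast.label,
    )


# ------------------------------------------------------------ enrichment score

def _es_from_positions(
    abs_scores_w: np.ndarray, positions: np.ndarray
) -> tuple[float, int]:
    """ES for one set given 0-based hit positions (sorted ascending) on a
    ranked list whose weighted |score| vector is ``abs_scores_w``.

    Returns (es, extremum_hit_index) where the index points into
    ``positions`` at the hit achieving the extremum (for the leading edge).
    Exploits that running-sum maxima occur right after hits and minima right
    before hits, so only O(k) candidates need checking.
    """
    n = len(abs_scores_w)
    k = len(positions)
    if k == 0 or k >= n:
        raise ValueError("set must hit >= 1 and < all ranked genes")
    w = abs_scores_w[positions]
    nr = w.sum()
    if nr == 0:
        raise ZeroDivisionError("all hit weights are zero")
    hit = np.cumsum(w) / nr
    miss_step = 1.0 / (n - k)
    i = np.arange(1, k + 1)
    after = hit - (positions + 1 - i) * miss_step          # value right after hit i
    before = np.concatenate([[0.0], hit[:-1]]) - (positions - (i - 1)) * miss_step
    max_dev = max(after.max(), 0.0)
    min_dev = min(before.min(), 0.0)
    # ties in magnitude (common at weight 0, where steps are rational) go to
    # the positive extremum; the tolerance absorbs float round-off between
    # algebraically equal paths
    if max_dev + 1e-12 >= -min_dev:
        return float(max_dev), int(np.argmax(after))
    return float(min_dev), int(np.argmin(before))


def enrichment_score(
    ranked: RankedList, members, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running-sum enrichment of ``members`` in ``ranked``.

    At each hit the sum rises by |score|^weight / N_R (N_R = total hit
    weight); at each miss it falls by 1/(N - N_hits). ES is the deviation of
    maximal absolute value, sign retained. Returns (es, running_sum,
    leading_edge); the leading edge is the hits at or before the extremum
    (at or after it for negative ES).
    """
    n = len(ranked)
    positions = ranked.positions(members)
    k = len(positions)
    if k == 0:
        raise ValueError("gene set has no member in the ranked universe")
    if k >= n:
        raise ValueError("gene set equals the whole universe; misses undefined")
    abs_w = np.abs(ranked.scores) ** weight
    if weight > 0 and abs_w[positions].sum() == 0:
        log.warning("all hit scores are zero at weight %g; falling back to weight 0", weight)
        abs_w = np.ones(n)

    is_hit = np.zeros(n, dtype=bool)
    is_hit[positions] = True
    steps = np.where(is_hit, abs_w / abs_w[positions].sum(), -1.0 / (n - k))
    running = np.cumsum(steps)

    es, ext = _es_from_positions(abs_w, positions)
    genes = np.array(ranked.genes)
    if es >= 0:
        leading = list(genes[positions[: ext + 1]])
    else:
        leading = list(genes[positions[ext:]])
    return es, running, leading


def _es_batch(abs_scores_w: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Vectorized ES for a (B, k) matrix of hit positions (rows unsorted ok)."""
    n = len(abs_scores_w)
    b, k = hits.shape
    pos = np.sort(hits, axis=1)
    w = abs_scores_w[pos]
    nr = w.sum(axis=1, keepdims=True)
    flat = nr[:, 0] == 0
    if flat.any():
        # weight-0 fallback rows
        w[flat] = 1.0
        nr[flat] = k
    hit = np.cumsum(w, axis=1) / nr
    miss_step = 1.0 / (n - k)
    i = np.arange(1, k + 1)
    after = hit - (pos + 1 - i) * miss_step
    before = np.concatenate([np.zeros((b, 1)), hit[:, :-1]], axis=1) - (pos - (i - 1)) * miss_step
    max_dev = np.maximum(after.max(axis=1), 0.0)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dev + 1e-12 >= -min_dev, max_dev, min_dev)


# ------------------------------------------------------------ permutation null

def permutation_null(
    ranked: RankedList,
    members,
    config: RunConfig,
    rng: np.random.Generator,
    *,
    matrix: CountMatrix | None = None,
    metadata: SampleMetadata | None = None,
    contrast: Contrast | None = None,
) -> np.ndarray:
    """Null ES distribution for a set of this size.

    GENE_SET mode draws random member sets of identical size from the fixed
    ranking; PHENOTYPE mode shuffles group labels, re-ranks and rescores
    (falling back to exhaustive enumeration when fewer distinct shuffles
    exist than requested permutations).
    """
    if config.n_permutations < 100:
        log.warning("fewer than 100 permutations; FDR estimates will be unstable")
    n = len(ranked)
    k = len(ranked.positions(members))
    if k == 0 or k >= n:
        raise ValueError("set must hit >= 1 and < all ranked genes")

    if config.permutation_mode == "GENE_SET":
        abs_w = np.abs(ranked.scores) ** config.gsea_weight
        b = config.n_permutations
        # top-k of random keys = uniform sample without replacement, per row
        keys = rng.random((b, n))
        hits = np.argpartition(keys, k, axis=1)[:, :k]
        return _es_batch(abs_w, hits)

    if matrix is None or metadata is None or contrast is None:
        raise ValueError("PHENOTYPE mode needs matrix, metadata and contrast")
    labels = np.array([metadata.assignments[s] for s in matrix.sample_names])
    n_a = int((labels == contrast.group).sum())
    idx_all = np.arange(len(labels))
    n_distinct = math.comb(len(labels), n_a)
    member_set = set(members)

    def _es_for_assignment(a_idx: np.ndarray) -> float:
        perm_labels = np.full(len(labels), "__rest__", dtype=object)
        perm_labels[a_idx] = contrast.group
        meta = SampleMetadata(dict(zip(matrix.sample_names, perm_labels)))
        c = Contrast(contrast.group, None)
        r = rank_genes(matrix, meta, c, metric=ranked.metric_name)
        es, _, _ = enrichment_score(r, member_set, config.gsea_weight)
        return es

    if n_distinct <= config.n_permutations:
        log.info("only %d distinct label shuffles; enumerating exhaustively", n_distinct)
        combos = itertools.combinations(idx_all, n_a)
        return np.array([_es_for_assignment(np.array(c)) for c in combos])
    out = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        a_idx = rng.choice(idx_all, size=n_a, replace=False)
        out[i] = _es_for_assignment(a_idx)
    return out


# --------------------------------------------------------------- scoring sets

def _nes(es: float, null: np.ndarray) -> float:
    if es > 0:
        same = null[null > 0]
        return math.nan if len(same) == 0 else es / same.mean()
    if es < 0:
        same = null[null < 0]
        return math.nan if len(same) == 0 else es / np.abs(same).mean()
    return 0.0


def _p_nominal(es: float, null: np.ndarray) -> float:
    """Add-one permutation p against the same-sign tail."""
    if es == 0:
        return 1.0
    same = null[null > 0] if es > 0 else null[null < 0]
    return (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))


def _nes_ratio_fdr(obs_nes: np.ndarray, perm_nes: list[np.ndarray]) -> np.ndarray:
    """FDR q per observed NES: fraction of all permuted NES at least as
    extreme (same sign) over fraction of observed NES at least as extreme,
    capped at 1 and monotonized in |NES| (BH-style tail minimum)."""
    pooled = np.concatenate([p[np.isfinite(p)] for p in perm_nes]) if perm_nes else np.array([])
    q = np.full(len(obs_nes), np.nan)
    finite = np.isfinite(obs_nes)
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes) or nes == 0:
            q[i] = 1.0 if nes == 0 else np.nan
            continue
        if nes > 0:
            pp = pooled[pooled > 0]
            oo = obs_nes[finite & (obs_nes > 0)]
            num = np.mean(pp >= nes) if len(pp) else 0.0
            den = np.mean(oo >= nes)
        else:
            pp = pooled[pooled < 0]
            oo = obs_nes[finite & (obs_nes < 0)]
            num = np.mean(pp <= nes) if len(pp) else 0.0
            den = np.mean(oo <= nes)
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    # monotonize: a stronger |NES| never carries a larger q than a weaker one
    order = np.argsort(-np.abs(np.nan_to_num(obs_nes)))
    running = np.inf
    for i in order[::-1]:
        if np.isfinite(q[i]):
            running = min(running, q[i])
            q[i] = running
    return q


def score_gene_sets(
    matrix: CountMatrix,
    metadata: SampleMetadata,
    contrast: Contrast,
    collection: GeneSetCollection,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """ES/NES/p/FDR table for every gene set, sorted by fdr_q then |NES|.

    ``collection`` must already be size-filtered against the matrix's genes.
    Deterministic for a fixed config/seed: sets are processed in name order
    with an RNG derived from ``config.seed``.
    """
    config = config or RunConfig()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    ranked = rank_genes(matrix, metadata, contrast, metric=config.rank_metric,
                        pseudocount=config.pseudocount)

    rows = []
    perm_nes_all: list[np.ndarray] = []
    for name in sorted(collection.sets):
        members = collection.members(name)
        es, _, leading = enrichment_score(ranked, members, config.gsea_weight)
        null = permutation_null(
            ranked, members, config, rng,
            matrix=matrix, metadata=metadata, contrast=contrast,
        )
        nes = _nes(es, null)
        if math.isnan(nes):
            log.warning("set %s: no same-sign permutations; NES undefined", name)
        p = _p_nominal(es, null)
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        with np.errstate(invalid="ignore"):
            perm_nes = np.where(null > 0, null / pos_mean, null / neg_mean)
        perm_nes_all.append(perm_nes)
        rows.append(
            dict(set=name, size_used=len(ranked.positions(members)), es=es,
                 nes=nes, p_nominal=p, leading_edge=",".join(leading))
        )

    table = pd.DataFrame(rows)
    if config.gsea_fdr == "nes_ratio":
        table["fdr_q"] = _nes_ratio_fdr(table["nes"].to_numpy(), perm_nes_all)
    else:
        from .diffexpr import bh_fdr

        table["fdr_q"] = bh_fdr(table["p_nominal"].to_numpy())
    table = table[
        ["set", "size_used", "es", "nes", "p_nominal", "fdr_q", "leading_edge"]
    ]
    table = table.sort_values(
        ["fdr_q", "nes"], key=lambda c: c.abs() if c.name == "nes" else c,
        ascending=[True, False],
    ).reset_index(drop=True)
    return table
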