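"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (step-by-step walks,
exhaustive enumeration, textbook formulas) and never calls the code paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_enrichment_score(scores, is_hit, weight: float) -> float:
    """Step-by-step weighted KS running sum; returns the signed deviation of
    maximal absolute value."""
    scores = np.asarray(scores, dtype=float)
    is_hit = np.asarray(is_hit, dtype=bool)
    n = len(scores)
    n_hit = int(is_hit.sum())
    w = np.abs(scores) ** weight
    nr = w[is_hit].sum()
    if nr == 0:
        w = np.ones(n)
        nr = float(n_hit)
    running = []
    total = 0.0
    for i in range(n):
        if is_hit[i]:
            total += w[i] / nr
        else:
            total -= 1.0 / (n - n_hit)
        running.append(total)
    max_dev = max(max(running), 0.0)
    min_dev = min(min(running), 0.0)
    # tie rule shared with the implementation: positive wins on (near-)equal
    # magnitude, with 1e-12 absorbing float round-off
    return max_dev if max_dev + 1e-12 >= -min_dev else min_dev


def exact_mannwhitney_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(idx_a):
        xs = [pooled[i] for i in idx_a]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys)
        return u

    observed = u_stat(tuple(range(n_a)))
    n_b = len(b)
    mid = n_a * n_b / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - mid) >= abs(observed - mid) - 1e-12:
            count += 1
    return count / total


def student_t_p(a, b) -> float:
    """Pooled-variance two-sample t-test p from the textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    from scipy.stats import t as tdist

    return 2 * tdist.sf(abs(t), df)


def anova_p(groups) -> float:
    """One-way ANOVA p from the sums-of-squares decomposition."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    from scipy.stats import f as fdist

    return float(fdist.sf(f, df_b, df_w))


def kruskal_h(groups) -> float:
    """Kruskal-Wallis H from the rank-sum formula (no tie correction)."""
    groups = [list(g) for g in groups]
    pooled = sorted(x for g in groups for x in g)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free inputs only
    n = len(pooled)
    h = 12.0 / (n * (n + 1)) * sum(
        sum(ranks[v] for v in g) ** 2 / len(g) for g in groups
    ) - 3 * (n + 1)
    return h


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct application of the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = running
    out = np.empty(n)
    out[order] = q_sorted
    return out


def pearson_r(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def two_pass_mean_sd(values) -> tuple[float, float]:
    """Mean and n-1 sample SD via an explicit two-pass accumulation."""
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)
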