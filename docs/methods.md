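# Methods

## Setting and scope

orbiscan implements the analysis chain for multiplexed hybridization-count
panels (NanoString nCounter style): a fixed code set of endogenous genes,
housekeeping/reference genes, positive controls at known spike
concentrations, and target-free negative controls, measured per lane. The
package covers processing from raw counts to pathway-level statements;
instrument operation, identifier mapping and pathway-graph rendering are out
of scope.

## Normalization chain

**Technical normalization.** Lane efficiency differences are removed by
scaling lane *j* with `f_j = mean_k(P_k) / P_j`, where `P_j` is the lane's
positive-probe summary — the sum by default, the geometric mean via
`RunConfig.tech_factor = "geomean"`. After the step all lanes share the same
summary exactly; this is asserted (relative tolerance 1e-9) rather than
assumed.

**Background.** The per-lane threshold is `mean + 2·SD` of the negative
controls, with the n−1 sample SD. Subtraction applies to endogenous and
housekeeping probes only and clamps at zero: negative expression is
meaningless and zeros must remain representable downstream. Control probes
are left untouched so that later steps (and a second pass) can still see
them.

**Biological normalization.** Lane scale is equalized on the geometric mean
of the housekeeping genes. Housekeeping genes with a zero in any lane are
dropped from the geometric mean instead of pseudocounted — a pseudocount
would break the exact equal-geomean invariant the step is defined by. If no
housekeeping gene is positive in every lane the step fails with a pointer at
background subtraction, which is the usual culprit.

**Expression filter.** Each endogenous gene's values across all samples are
tested against the pooled negative-control values (all negative probes, all
lanes) with a one-sided two-sample t-test, alternative "gene above
negatives". Welch's form is the default (`welch_filter = False` gives the
pooled-variance form). A gene is retained iff p < alpha (default 0.05);
degenerate genes (no variation against the negatives) are excluded with
p recorded as 1. The filter runs after biological normalization by default;
`filter_stage = "pre"` applies it to background-subtracted values for
sensitivity analysis. Likewise `subtract_before_technical = True` reverses
the order of positive-control scaling and background subtraction; the
default order (scale, then subtract) is the conventional nCounter workflow.

The chain is monotone per lane, so within-lane rank order of genes is
preserved end to end; a second pass over normalized output yields factors of
exactly 1. Both properties are tested.

## Differential testing

Per gene and contrast (pairwise or one-vs-rest), a Shapiro–Wilk test per
group at the run alpha gates the branch: all groups normal → Student's
t-test (pooled variance, two-sided) with a 95% CI on the mean difference;
any group non-normal → Mann–Whitney U, exact when min(n) ≤ 8 without ties,
tie- and continuity-corrected normal approximation otherwise. Groups with
fewer than 3 values or constant values cannot be Shapiro–Wilk tested and are
conservatively routed non-parametric. For three or more groups the same gate
chooses one-way ANOVA or tie-corrected Kruskal–Wallis.

Effect sizes are `log2((m_a + c)/(m_b + c))` with m the mean (parametric) or
median (non-parametric) and pseudocount c = 1, needed because background
subtraction produces zeros. CIs are reported only for the parametric
two-group branch, on the normalized-count difference scale; the rank tests
have no canonical difference-scale CI. FDR control is Benjamini–Hochberg
across all genes of one table (Benjamini–Yekutieli by flag). Pearson and
Spearman correlation helpers round out the toolkit; Spearman p is exact (by
permutation enumeration) for n ≤ 9 without ties.

## GSEA

Genes are ranked by signal-to-noise `(μ_A − μ_B)/(σ_A + σ_B)` with each σ
floored at `max(0.2·|μ|, 0.2)` — the floor keeps low-variance genes from
dominating — or by a log2 median-ratio metric for a non-parametric ranking.
Ties are broken by gene name so rankings are platform-independent.

The enrichment score walks the ranked list: a hit adds
`|score|^w / N_R` (`N_R` = total hit weight, w = 1 by default), a miss
subtracts `1/(N − N_hits)`. ES is the running-sum deviation of maximal
absolute value; since hit steps sum to 1 and miss steps to −1, the sum ends
at 0 and ES ∈ [−1, 1]. Maxima can only occur immediately after hits and
minima immediately before them, so the implementation evaluates only those
O(k) candidates; the test suite proves it equal to a naive step-by-step walk.
When the positive and negative extrema tie in magnitude (routine at w = 0,
where steps are rational) the positive one wins, with a 1e-12 tolerance so
that algebraically equal paths cannot disagree through round-off. The
leading edge is the hits at or before the extremum (at or after, for
negative ES). If all hit scores are zero at w > 0 the statistic falls back
to w = 0 with a warning.

**Permutation null.** Default mode draws random same-size member sets on the
fixed ranking (gene-set permutation); with group sizes of 3–6 samples,
label permutation is too granular to be useful, but a PHENOTYPE mode
(shuffle labels, re-rank, rescore; exhaustive enumeration when fewer
distinct shuffles exist than requested) is provided for larger designs.
1000 permutations is the default.

**Summaries.** `NES = ES / mean(same-sign permuted |ES|)`, normalizing
positive and negative scores separately. Nominal p uses the add-one
estimator `(1 + #{same-sign |ES_perm| ≥ |ES|}) / (1 + #same-sign)`, which
cannot return 0. FDR q follows the NES-ratio construction of the GSEA
method family: the fraction of pooled permuted NES at least as extreme as
the set's NES (same sign) over the fraction of observed NES at least as
extreme, capped at 1 and monotonized BH-style (each set takes the minimum
raw q over sets with weaker or equal |NES|), so q never increases with
|NES|. BH on nominal p is available by flag for comparison.

## Pathway projection

Enriched sets (fdr_q ≤ alpha by default, any named set on request) are
projected gene-by-gene from the differential table: UP iff
log2FC ≥ +threshold, DOWN iff ≤ −threshold, else INDIFFERENT (including
undefined log2FC). The default threshold 0.25 is deliberately permissive —
the projection is a reading aid, not an inference — and is recorded in every
output.

## Synthetic data generator

The generator emulates the code-set structure: endogenous gene *i* in lane
*j* (group *g*) draws
`NB(mean = t_j · 2^(b_i + Δ_ig), dispersion) + Poisson(background)`, with
lane factor `t_j ~ LogNormal(0, lane_factor_sd)` shared by all probes except
negatives, baselines `b_i` uniform on a log2 range, NB variance
`μ + d·μ²`, and `Δ_ig` the planted log2 fold change for the affected
fraction of each spiked set's members in its target group. Housekeeping
genes have Δ = 0; positive probes are Poisson around
`t_j · concentration · 150` (a four-fold ladder from 128 fM down, ~19k
counts at the top at t = 1, the scale of a real positive ladder); negatives
are Poisson background only. This makes the chain falsifiable by
construction: positive-control scaling can remove exactly the lane effect,
and the mean+2SD threshold addresses exactly the additive background.

Defaults mirror the motivating study's shape: three groups of 6/3/3
samples, 300 endogenous genes (a reduced panel kept small so simulation
studies run in seconds), 30 reference genes, 6 positive and 8 negative
controls, dispersion 0.1, lane-factor σ 0.2, background mean 10, and three
spiked sets at +1 to +1.5 log2 units in 60–75% of members. One RNG stream
seeded from the design reproduces matrices bit-for-bit; spiked members are
the leading members of each set in listed order, so ground truth is
self-evident.

What the generator does *not* emulate: real probe identities and
cross-hybridization, probe-specific efficiency differences, FFPE RNA
degradation profiles, or correlated gene–gene expression structure within
pathways. Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated generative model, not performance guarantees on
real tissue data.

## Validation studies and sizes

The `evaluation` module runs the operating-characteristic studies the test
suite asserts (sizes chosen to give stable rates while keeping the whole
suite fast):

- normalization equalization on 50 random matrices (tolerance 1e-9);
- expression-filter characteristics on 1000 genes, half at background and
  half at 10× background: both error rates bounded at 5%;
- exact classical statistics (Mann–Whitney p = 0.1 on separated triples;
  Kruskal–Wallis H = 32/7 on three separated pairs — the rank-sum formula's
  value and the maximum for this layout; the BH ladder example);
- ES against the brute-force oracle on 200 random instances, N ≤ 50;
- GSEA null calibration over 50 sets × 20 seeds at 1000 permutations,
  judged by the 99% binomial interval around 0.05;
- spiked-set recovery (60% of 20 members at +1 log2, 6 vs 6) and
  differential recovery (20 genes at +2 log2 among 300, 6 vs 6,
  dispersion 0.1), both over 20 seeds;
- byte-level reproducibility of two identical full runs (the manifest's
  timestamp is the only permitted difference).

## Known limitations

- The expression filter compares post-normalization endogenous values to
  technically-normalized (unsubtracted) negative values; this is
  deliberate — subtracting the threshold from the negatives themselves would
  zero the comparator — but it makes the filter conservative for genes just
  above background.
- Gene-set permutation tests set membership against a fixed ranking; it
  does not propagate between-sample correlation into the null the way
  phenotype permutation would.
- NES is undefined (reported NaN with a warning) when the permutation null
  contains no same-sign values; this essentially only occurs for degenerate
  rankings.
- Classical per-gene tests are used as specified; no variance moderation is
  applied, so power at n = 3 per group is limited and the package reports
  that honestly rather than borrowing strength across genes.
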