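# Methods

This note documents the models, defaults and numerical choices behind
`cernet`, and what the synthetic-cohort tests do and do not establish about
real data.

## Differential screen

Each feature is tested with a two-sided, equal-variance two-sample Student
t (pooled variance, $n_1 + n_2 - 2$ df). The effect is mean(case) −
mean(control): a log2 fold change for expression layers, a delta-beta for
methylation. Significance calls require BH-adjusted $p < 0.05$ (strict)
and an effect magnitude of at least $\log_2 2 = 1$ (non-strict) for
expression, or $|\Delta\beta| \ge 0.2$ for methylation. The adjusted — not
raw — p-value governs the call; the p threshold is strict and the effect
threshold non-strict, stated here because conventions differ.

A moderated option (off by default) shrinks each pooled variance toward
the across-feature mean variance with a prior of 4 pseudo-degrees of
freedom, adding those df to the reference t distribution — a simple
empirical-Bayes stabilizer for very small cohorts. The plain Student t is
the default because it is the test the screen is defined by; the moderated
variant exists because microarray practice usually moderates.

Degenerate inputs: a variance floor of 1e−12 guards the t denominator;
features constant and equal in both groups short-circuit to $t = 0, p = 1$
(no evidence, rather than 0/0). BH adjustment is the exact step-up
($q_{(i)} = \min_{j \ge i} p_{(j)} m / j$, capped at 1, ties sharing
values); it is cross-checked against statsmodels in the tests.

## Reference (tissue-confound) filter

The case-vs-control contrast compares hippocampal against cortical tissue,
so region-specific expression masquerades as disease signal. Features
already differing between *normal* hippocampus and cortex in a paired
reference cohort are removed from the differential lists. Per feature the
within-pair differences are tested with a paired t when Shapiro–Wilk
accepts normality at $\alpha = 0.05$, otherwise a two-sided Wilcoxon
signed-rank (zeros dropped; exact p at small n without ties, normal
approximation with continuity correction otherwise, via scipy). The
reference significance cut is a raw $p < 0.05$ — deliberately aggressive
at flagging reference differences, hence conservative about what survives
as disease-specific. Features absent from the reference are kept and
flagged (`keep_unmeasured`, default true) rather than silently discarded.
All-zero difference vectors get $p = 1$ under the Wilcoxon label, since
the signed-rank statistic is undefined without nonzero differences.

## Correlation network and ceRNA triads

Correlations pool cases and controls — the screen deliberately uses
between-group separation as part of the co-expression signal, as
cohort-level co-expression analyses do. The p-value is the exact t
transform with $n - 2$ df. Thresholds are strict inequalities
($r < -0.5$, not $\le$), applied together with $p < 0.05$ on the raw
correlation p by default; a BH-FDR column is always computed and can be
made the gate (`pair_alpha_on="fdr"`). Constant rows have undefined
correlation and are skipped with a log line rather than propagating NaN.

Triads require both miRNA-anchored edges to be negative *and* present in
the target-prediction table; positive miRNA–lncRNA correlations survive
thresholding as network edges but never enter triads (they are not sponge
candidates). An optional positive lncRNA–mRNA confirmation edge can be
required (`require_lncrna_mrna_edge`, default off — the sponge logic only
needs the two miRNA edges; the confirmation edge is corroborative).
Output ordering is fixed (triads by id triple, edge lists by |r| then
ids) so repeated runs are byte-identical.

## Nine-quadrant integration

States come from the significance *calls*, not raw effect signs: a gene is
"hypo" only if its delta-beta call is down at the thresholds above. The
3×3 grid (rows hypo/none/hyper, columns down/none/up, quadrant
$= 3\,\text{row} + \text{col} + 1$) partitions the genes measured in both
layers; hypo-up candidates are reported most-hypomethylated first. Genes
present in only one layer are excluded and counted. The $|\Delta\beta| \ge
0.2$ default is a field convention, not a derived quantity.

## Enrichment

ORA is the upper-tail hypergeometric probability of the observed overlap
or more, with the gene set intersected with the universe first and BH
across the collection. GSEA uses the weighted KS running sum: hits advance
by $|s_i|^p / \sum_{hits} |s_j|^p$ (weight $p = 1$ by default, $p = 0$
unweighted), misses retreat by $1/(N - n_{hits})$, ES is the signed
maximal deviation. The null is **gene-label permutation** at matched set
size — scores stay attached to positions, membership is resampled — for
all GSEA modes, because the guilt-by-association ranking has no phenotype
to permute and one null keeps a single code path. NES divides ES by the
mean |null ES| of matching sign; sets with no same-sign null draws keep
NES = NaN and are flagged, not dropped. Permutation p-values carry the
add-one correction $(b+1)/(m+1)$, which makes them slightly conservative;
default 1000 permutations. Sets with fewer than 2 in-list members are
skipped. Ties in ranked lists break lexicographically by id for
determinism. Guilt-by-association ranks all mRNAs by Pearson correlation
with the hub's expression vector (an mRNA hub is excluded from its own
list; constant vectors are an error) and reports sets by |NES| descending.

## Synthetic cohorts and what they establish

The generator emulates post-normalization, log2-scale array data: i.i.d.
Normal(8, noise_sd) background, planted DE features shifted ±de_log2fc in
cases, methylation at per-gene baselines in (0.2, 0.8) with Gaussian
jitter clipped to [0.01, 0.99]. Each planted triad is driven by a latent
per-sample miRNA activity $a$: miRNA $= 8 + a + \varepsilon$,
mRNA and lncRNA $= 8 - c\,a + \varepsilon$ with coupling $c = 0.8$, and
$a$ shifted down by `activity_shift` in cases — inducing the full sponge
sign pattern without simulating binding kinetics, since the analysis
consumes only correlations. Tissue-confounded decoys get the same +2.0
log2 offset in cases as they show between reference tissues, so the
reference filter can (and should) remove them.

Default conditions: 20 vs 20 samples, 200 features per layer, 20 planted
DE features per layer, 5 triads, 2 hypo-up genes, 18 confounders (6 per
layer), noise_sd 0.5, 10 reference pairs, decoy fraction 0.3. The 20/20
size gives desk-scale power for recovery tests; a `pilot_scale()` preset
(6 vs 9) mirrors the motivating cohort for demonstration. `activity_shift
= 2.5` and `activity_sd = 0.75` were fixed from power considerations: they
give triad-member fold changes of 2–2.5 log2 units and within-triad
correlations near −0.85, so recovery failures reflect pipeline behavior
(thresholds, filtering, prediction support) rather than chance
non-expression of the planted signal.

What passing tests show: the pipeline recovers planted sponge structure,
removes planted tissue confounds with small collateral loss, holds its
nominal type-I error under the global null, and is deterministic and
internally consistent. What they do not show: behavior under probe-level
artifacts, batch effects, correlated backgrounds, non-Gaussian intensity
noise, or realistic target-prediction error structure — none of which the
generator models. The generator *does* reproduce one important real-world
failure mode: features co-dysregulated between groups correlate strongly
when samples are pooled, so decoy prediction edges yield plausible-looking
false triads. Recovery metrics therefore score recall of planted triads,
not precision over all emitted triads.

## Pipeline and numerical choices

Stages run in the order simulate → preprocess → differential → reference
filter → network → quadrant → enrichment, each writing its TSV so any
stage can be re-run from intermediates. A single run seed fans out to
per-stage seeds via a CRC32 hash of the stage name, keeping stages
individually reproducible. Quantile normalization (rank-mean reference,
ties averaging the reference values over tied positions) and log2
transformation are implemented and tested, but the pipeline skips
re-normalization by default (`already_normalized=True`): the generator's
output is defined as already normalized, and quantile normalization
assumes most features are unchanged between samples — re-applying it to a
cohort in which ~15% of features carry planted one-directional shifts
compresses those shifts by roughly a third, which is the normalization
behaving as designed, not a pipeline defect. Set
`already_normalized=False` to exercise the full preprocessing path.

Evaluation problem sizes (chosen to keep replicate counts high while each
replicate stays sub-second): recovery metrics average 20 replicate
cohorts at the default conditions; null calibration pools 50 seeds of a
100-feature, 10-vs-10 null cohort; GSEA calibration uses 50 random
rankings at 500 permutations.

## Known limitations

* Correlation-based triad inference cannot distinguish direct sponging
  from shared group-driven dysregulation; precision depends entirely on
  the prediction table's specificity.
* The reference filter tests raw p per feature; with many reference pairs
  it would over-remove (multiplicity is deliberately uncorrected on the
  reference side).
* Probe-to-gene collapsing is out of scope: feature ids are opaque
  strings, and multi-probe genes must be collapsed upstream.
* The Wilcoxon branch delegates to scipy's method selection (exact only
  without ties); p-values near the exact/approximate boundary may differ
  slightly from other implementations.
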