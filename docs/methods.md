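# Methods

`trendnet` reimplements, as a tested library, the analysis chain used in
short time-course LncRNA/mRNA expression studies: differential selection
against the baseline, series-test-of-cluster (STC) trend analysis with a
permutation/binomial null, term enrichment, a high-threshold coexpression
network, and 2^−ΔΔCT qPCR quantification. This note records the models,
the conventions chosen where the procedure is genuinely open, and what
the synthetic generator does and does not emulate.

## Data model

Expression values are log2 signal intensities for G transcripts (each
labelled `LncRNA` or `mRNA`) over T time points (default days 0, 1, 3,
7, 21) with R replicates per time point (default 3, mirroring three
animals per group). Sample labels are `d<day>_r<rep>`. A "pooled" view
averages replicates into one column per time point, emulating equal-mass
RNA pooling before hybridisation; analyses that need replicate variance
(t-tests, FDR) refuse pooled input unless explicitly switched to the
fold-change-only mode.

## Differential expression (vs day 0)

* log2FC at day t = mean log2 signal at t − mean at day 0 (difference of
  group means on the log scale, not a mean of ratios).
* Per-gene p-values from the classical pooled-variance two-sample
  t-test on the replicate values; degenerate zero-variance rows use the
  convention p = 1 for equal means and p = 0 otherwise.
* Benjamini–Hochberg adjustment within each time-point comparison
  (reporting is per time point).
* A gene is `up` iff log2FC ≥ log2(fc) and q ≤ fdr, `down` symmetric,
  with fc = 2 and fdr = 0.05 by default and both boundaries inclusive.
* The union set is every gene called at ≥ 1 time point; heat-map rows
  are ordered by the leaf order of average-linkage clustering on the
  1 − Pearson-r distance between per-gene time-mean profiles
  (zero-variance profiles get distance 1 to everything).

## STC trend analysis

Model profiles enumerate every sequence of T−1 unit steps in
{−c, …, +c}, anchored at 0, in lexicographic order; with T = 5, c = 1
and the flat profile excluded this is the classic catalogue of
3⁴ − 1 = 80 profiles. Genes are assigned to the profile maximising the
Pearson correlation between the gene's anchored time-mean vector and
the profile's value vector (a Euclidean-distance metric is available
behind a flag); ties break toward the lowest profile id, and
zero-variance genes are reported as unassignable rather than forced
into a profile. The null model treats each gene's time points as
exchangeable: each permutation shuffles every gene's T time-mean values
independently and re-assigns. With N assignable genes and e(k) the mean
permuted count of profile k, the count in k is Binomial(N, e(k)/N)
under the null, and the profile's p-value is the upper tail
P(X ≥ observed). BH adjustment runs across profiles; significance is
adj_p < 0.05. The default is 1000 permutations (minimum 100), seeded.
No floor is applied to e(k)/N; with ≥ 100 permutations over hundreds of
genes a never-visited profile is vanishingly rare, and an observed count
of 0 still yields p = 1.

The permutation engine is vectorised in chunks (permute → anchor →
standardise → one matrix product against the standardised profile
matrix → argmax), which keeps a 1000-gene, 1000-permutation run under a
second on one CPU.

## Term enrichment

For a gene list L against the background universe U (all genes on the
array; optionally only annotated genes), each term S yields the table
a = |L∩S|, b = |L∖S|, c = |S∖L|, d = |U| − a − b − c. The primary
p-value is the two-sided Fisher exact test under the point-probability
convention (sum of equally-or-less-probable tables at fixed margins); a
Pearson χ² p-value (1 df, no continuity correction by default) is
reported alongside when no margin is empty. BH q-values run across
terms; the significance gate is the raw Fisher p at 1e-4, with q
reported rather than gated on, since the two cut-offs are commonly
combined in unstated ways across enrichment services.

## Coexpression network

Pearson correlations are computed over the T per-gene time-mean values
(matching a design with one pooled expression profile per group). Pairs
with |r| ≥ 0.997 (inclusive) become edges; the sign is retained because
biologically meaningful pairs can move in opposite directions. The
default `lncrna-mrna` mode tests only cross-biotype pairs — the graph
is then bipartite and every clustering coefficient is structurally 0 —
while `all-pairs` admits every pair. Node metrics: degree (incident
edges), core number (largest k such that the node survives peeling of
all nodes of degree < k), and the local clustering coefficient
2·triangles/(deg·(deg−1)). Hubs rank by (core number, degree, id).

## qPCR quantification

Per replicate ΔCt = Ct(target) − Ct(reference); ΔΔCT at day t is mean
ΔCt(t) − mean ΔCt(day 0) and the fold change is 2^−ΔΔCT (efficiency
fixed at 2; no efficiency correction). Groups are compared by the
pooled-variance t-test on replicate ΔCt values — the approximately
normal scale — not on folds; p < 0.05 is flagged. Concordance with the
array reports, per gene, the sign-agreement fraction between
log2(qPCR fold) and the array log2FC across shared time points plus
their Pearson r, and an overall agreement fraction.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes,
not the platform: per-gene log2 baselines uniform in [4, 14] (typical
microarray range), a fraction `frac_trended` (default 0.3) of genes
following `baseline + trend_amplitude · profile values` with Gaussian
replicate noise (`noise_sd`, default 0.2 log2 units per replicate;
amplitude default 1.0 log2 units per step), and the remainder baseline
plus noise. Trended genes concentrate on a small pool of
`n_trend_profiles` profiles (default 4) so planted profiles carry
enough genes to be detectable. Planted LncRNA–mRNA pairs share their
latent profile (coregulation, not post-hoc adjustment); the shared
profile is drawn from the high-variance profiles (centered value
norm² ≥ 4 in amplitude units), without which the pair's time-mean
correlation could not stay near 1 once noise is added. Gene sets
over-sample trended genes at odds `planted_term_enrichment` (default 8)
for the planted terms, which are sized 30–50 members — panel-sized, so
the planted odds are detectable at the p < 1e-4 gate — against 10–50
for background terms. Ct tables shift the target ΔCt by −log2(fold)
relative to day 0 around a time-invariant reference.

A single RNG stream with a fixed draw order (baselines, profile pool,
trended-gene choice, pair profiles, remaining assignments, one noise
block) makes output byte-identical for a fixed config and seed; gene
sets and Ct tables use deterministic sub-streams of the same seed.

What the generator does **not** emulate: probe-level array artefacts,
normalisation residuals, heteroskedastic or correlated noise,
batch/array effects, heavy-tailed expression distributions, and
realistic gene-set overlap structure. Passing recovery tests therefore
demonstrates correctness of the algorithms under their own assumptions,
not performance on real GEO series.

## Calibration results the suite computes

All empirical claims in the tests are recomputed at run time, at these
problem sizes (chosen to exercise each stage on one CPU in seconds to
minutes):

* STC type-I: 1000 null genes × 1000 permutations × 100 seeds; the mean
  fraction of profiles at adj_p < 0.05 must stay ≤ 5%.
* STC recovery at amplitude 1.0 / noise 0.2: ≥ 90% of planted genes
  recover their true profile and every planted profile is significant
  (5 seeds × 300 permutations).
* DE calibration at planted log2FC 2 / noise 0.2 / 3 replicates:
  sensitivity ≥ 90%, null false-call rate ≤ 5% (10 seeds).
* Network recall of planted pairs at |r| ≥ 0.997: 100% at zero noise,
  ≥ 95% at noise 0.05 (10 seeds).
* Exact-oracle equivalences: Fisher vs integer hypergeometric
  enumeration for all 2×2 tables with total ≤ 30; K-core and clustering
  vs brute-force peeling/triangle counting on 100 random 30-node
  graphs; binomial tail vs pmf summation at 1e-12.
* qPCR: ΔΔCT identities exact; planted fold 2 at Ct noise 0.1
  recovered within [1.6, 2.5] in ≥ 90% of 20 seeds.

## Known limitations

* With one chip per group (pooled mode) there is no within-group
  variance; the FDR-based selection rule is then undefined and the
  package deliberately degrades to fold-change-only calling rather than
  inventing a variance model (no RVM-style moderated test is provided).
* The binomial null expectation is estimated from permutations, so
  profile p-values inherit Monte-Carlo error of order
  1/√(permutations).
* Whether the 0.997 edge rule should apply to signed or absolute
  correlation is ambiguous in the field; the package thresholds |r| and
  keeps the sign, and the choice matters for anti-correlated pairs.
* Enrichment reports both Fisher and χ² p-values but filters on Fisher
  only; combining the two tests is intentionally left to the user.
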