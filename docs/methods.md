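# Methods

## Scope and model

`screenaudit` treats reagent-level error rates in RNAi screening as
measurable quantities. Its probabilistic core is deliberately simple: each
reagent acts as an independent Bernoulli trial. On a gene with a genuine
phenotype a reagent fails to score with probability R_FN (insufficient
knockdown); on a gene without one it scores with probability R_FP
(off-target activity or noise). Independence across reagents targeting the
same gene is the key assumption — it is what makes redundancy informative,
and it is implied whenever screen error rates are written as products of
per-reagent rates. Correlated failure modes (shared amplicon regions,
common off-target seed sequences) are outside the model.

## Plate Z-scores

Raw readings are normalized per plate: Z = (x − μ)/σ with μ and σ over the
plate's *sample* wells. Two conventions needed fixing:

* σ is the sample (n−1) standard deviation. With n ≈ 300 sample wells the
  choice is numerically irrelevant, but n−1 keeps the estimator unbiased
  and makes small worked examples exact ([10, 20, 30] → [−1, 0, 1]);
  `ddof=0` is available.
* Empty perimeter wells and controls are excluded from μ and σ. Focused
  sub-library plates leave the outer perimeter empty precisely because
  those wells are not comparable to sample wells; folding constant empty
  values into the statistics would shift every score. Whether historical
  screens excluded controls is not documented, so `include_controls` is a
  flag (default False).

Plates with fewer than 3 sample wells or zero spread raise a
degenerate-plate error rather than emitting infinities. Missing matrix
entries stay missing; nothing is imputed.

## Signature clustering and concordance

Profiles (one Z per screen, replicates averaged) are clustered with average
linkage on Pearson correlation distance d = 1 − r. Correlations are
pairwise-complete; rows with fewer than 3 observed screens or zero variance
are excluded with a warning, and residual pairs lacking overlap get the
maximal distance 2. Flat clusters are cut at d = 0.5 by default — no
principled cut height exists for this kind of dendrogram, so the value is a
parameter; 0.5 reliably recovers planted blocks whose within-cluster
correlation exceeds ~0.5, which is also the regime in which a consensus
signature is meaningful at all.

A cluster becomes a *signature cluster* when it has at least
`min_cluster_size` (3) members and one annotation label covers strictly
more than half of them. Enrichment, not mere contact, is required: with a
panel of 16 screens, sample correlations of pure-noise profiles are spread
widely enough that chance co-clusters are common, and any rule that labels
a cluster after a single annotated member floods the discordance analysis
with spurious calls.

Whether a reagent *shows* a signature is judged against the cluster's
consensus (the per-screen mean Z of members): in-cluster means r ≥ 0.5
(`r_threshold`) to the best-matching labeled consensus. The dendrogram cut
defines the clusters and consensus profiles, but membership of the flat
cluster itself is not required — average-linkage flat clusters are
conservative at the margin and drop reagents whose profiles plainly track
the consensus (observed r up to 0.79), which would inflate the FN estimate
roughly twofold.

Gene calls for genes with ≥ 2 reagents in the matrix: all reagents in →
`concordant_in`; none → `concordant_out`; mixed → `discordant`. A
discordant gene whose annotation matches the cluster label is attributed
`false_negative` (the out-of-cluster reagent failed); a mismatching or
unannotated gene is attributed `false_positive` (the in-cluster reagent is
spurious); reagents landing in unlabeled or conflicting clusters give
`ambiguous`.

The FN-rate estimate divides attributed-FN reagents by all reagents of
*annotated-set* genes with at least one in-cluster reagent. Genes whose
reagents all miss the cluster are excluded — mis-annotation, redundancy and
double reagent failure are indistinguishable there — and unannotated
bystander genes carry no information about set-gene reagent efficacy. Note
the estimator therefore conditions on ≥ 1 active reagent: for 2-reagent
genes its expectation is r/(1+r) rather than r (≈ 7.3% at r = 8%), a
property shared by any estimate built this way. The pooled non-signature
rate (non-clustering set genes over set size) is the complementary upper
bound that charges every absent gene as a potential false negative.

### Degenerate (noise-free) input

With zero well noise every Z profile is constant across screens: plate
Z-scoring removes per-plate affine structure, and a screen-wide response
multiplier is exactly such a transform. Pearson correlation is then
undefined everywhere. The pipeline detects this and separates reagents by
Z level instead: mean-Z values are split at their largest gap, and the side
farther from zero becomes the candidate signature cluster, provided the gap
spans at least `z_active_threshold` (2) Z units. In this regime active and
inactive reagents are perfectly separated and the FN estimate is exact.

## Hit categories and screen rates

A reagent is a hit when |Z| ≥ 2 in *every* replicate and all replicate
Z-scores share a sign. The sign rule is a deliberate strengthening: a
reagent at +2.5 and −2.5 has not reproduced anything. Reagents with a
missing replicate are non-evaluable and leave all denominators. Categories:
1 = all reagents hit, 2 = ≥ 2 hit with ≥ 1 failure, 3 = exactly one hit,
none (0) = nothing hit (kept in the output so FN analyses can see them).

Screen-level estimates treat every category-3 gene's lone scoring reagent
as a false positive — justified when category 3 shows no enrichment for
expressed genes — giving an FP rate per library reagent and per hit gene;
the non-scoring reagents of category-1/2 genes (corroborated hits) give the
FN rate. The packaged worked-example table yields 15/1,545 ≈ 1% per
reagent, 15/24 ≈ 62% per hit gene, and 5/28 ≈ 18% FN among corroborated
genes' reagents; the FN figure is computed from the per-gene counts, whose
sum (28 reagents) is what the table actually contains.

Expression status uses FPKM ≥ 1 (expressed) and ≥ 5 (elevated). Published
wording supports both ≥ and > at the lower threshold; the comparator is a
flag (default ≥). Genes absent from the FPKM table are *unknown*, never
counted as unexpressed.

## The m-of-k model

Closed forms are binomial tails (`scipy.stats.binom`); the literal k ≤ 3
polynomial expansions are retained as an independent oracle and the two are
tested for equality to 1e-12 over a 21 × 21 rate grid. The Monte-Carlo
verifier draws every reagent's score as an explicit Bernoulli variable (in
chunks, so a 13,735-gene library at 10⁴ replicates stays within memory) —
it deliberately does not sample from the aggregated binomial being
verified. N defaults to genes − H (non-hit genes): with 13,735 genes and
100 hits the distinction is invisible on any plot, but the package treats N
as the non-hit count for internal consistency.

## What the generator emulates — and what it does not

`simdata` produces: a library of 1–4 reagents per gene; H hit genes;
i.i.d. reagent defects (ineffective with probability `reagent_fn_rate`,
off-target-active with `reagent_fp_rate`, both fixed properties of the
reagent, not of the screen); 384-well plates with an empty perimeter filled
row-major; per-well Gaussian noise; and per-screen response weights
w_s ~ U(0.2, 1.8) multiplying the effect size. The weights model how
differently unrelated assays respond to the same broad perturbation and are
what gives signature clusters an across-screen profile — with a constant
effect, plate Z-scoring leaves every profile flat and correlation
clustering has no signal. The range was chosen from a variance analysis:
Z-normalization partially compresses strong screens (active wells inflate
the plate SD), so the interval must be wide for the surviving profile
variance to support correlations above the 0.5 threshold; the mean response
is 1 so the nominal effect size keeps its meaning.

Defaults describe the reference recovery experiment: 1,000 genes × 2
reagents, 50 hit genes, R_FN = 0.08, R_FP = 0.01, effect −5 Z units
(negative: knockdown phenotypes in reporter assays typically reduce
signal), unit well noise, 16 screens × 2 replicates. Expression tables draw
expressed genes (53% per line) log-normally (ln FPKM ~ N(3, 1.5²)) and
unexpressed genes uniformly below 1.

Not emulated: sequence-level off-target structure (defects are i.i.d.
labels), spatial gradients within plates (the perimeter is simply empty),
graded knockdown strength (efficacy is binary — no published constraint
fixes the strength distribution of "weak" reagents), cell-to-cell
variability, and correlated reagent failures. Passing recovery tests
therefore show the estimators are correct *under the stated error model*,
not that real libraries satisfy it.

## Numerical and reproducibility choices

* Linkage uses `scipy.cluster.hierarchy` on a symmetrized distance matrix;
  merge heights are verified against an O(n³) exhaustive UPGMA
  re-computation in the tests. Tie order follows scipy's deterministic
  scan, so output is reproducible for identical input order.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; the pipeline derives per-stage seeds from the
  master seed via `SeedSequence([seed, stage])`, so stages can be re-run
  independently and reports are byte-identical under a fixed seed.
* TSV everywhere (UTF-8, '.' decimals, missing = empty field); dendrograms
  as Newick with branch lengths; reports as JSON with a schema version.
  Unknown configuration keys are rejected, not ignored.

## Problem sizes

The test suite and acceptance script run the recovery experiment at the
reference size (1,000 genes, 16 screens) over 10–20 independent panels and
the Monte-Carlo verification at 10⁴ replicates — sizes at which binomial
standard errors are small relative to the tolerances being checked while a
full run stays in the tens of seconds on one CPU.

## Known limitations

* The concordance estimator's denominator conditions on cluster contact
  (see above); it slightly understates the per-reagent rate by r/(1+r) vs
  r and should be read as the same kind of lower bound the discordance
  construction always yields.
* Cluster labeling needs an annotation that actually covers the signature
  gene set; with sparse annotations real signature clusters fall below the
  enrichment majority and are ignored.
* With fewer than ~12 screens in the panel, chance correlations among null
  profiles make the 0.5 cut and r-threshold markedly less selective.
* The error model's independence assumption makes its FP predictions
  optimistic for libraries with shared off-target sequences.
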