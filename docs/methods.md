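# Methods

This note documents the models and procedures implemented in `epireg`,
the synthetic study they are exercised on, the numerical choices, and the
limits of what the tests demonstrate.

## Monte Carlo feature selection with interdependency discovery

The selection engine builds many binary decision (or regression) trees on
random subsets of samples and features and scores each feature *g* by its
relative importance

RI(g) = Σ_τ q(τ)^u · Σ_{nodes n on g} IG(n) · (n(n)/n(root))^v ,

with information gain in bits (log base 2; any fixed base gives the same
ranking), population-variance reduction in the regression analog, and
held-out quality q — weighted accuracy (mean of per-class accuracies) for
classification, Pearson correlation of held-out predictions clipped to
[0, 1] for regression (the regression q is this package's definition; it
is bounded and matches the Pearson lens used to validate the regression
experiments).  Exponents default to u = v = 1.

**Projections.** `mode=2` (the default) partitions the features into
disjoint random blocks of `m` features each sweep, so every feature is
evaluated equally often; `mode=1` draws each projection independently.
The default schedule gives every feature at least 30 projections with
t = 5 train/test splits per projection and a train fraction of 0.66;
splits are class-stratified by default, which stabilizes both the node
statistics and q under class imbalance.  The default block size is
m = 200 (the splitSetSize used by the study the package reimplements,
chosen there for ~400 k features).  The analysis drivers and tests use
m = 50, 5 projections per feature and t = 3 — at 2 020 features per omic
a 200-wide block would hold ~20 informative features at once, forcing
them to shadow each other, and the smaller schedule keeps a full
four-run experiment with 20 cutoff permutations near two minutes of CPU.

**Trees.** Greedy binary splits maximizing IG (variance reduction),
thresholds at midpoints of consecutive sorted values, ties between
features broken by lexicographic feature ID, growth until a node is
pure, smaller than `min_samples_split` (default 2; the regression
experiments use 10 to limit variance) or admits no positive-gain split.
All-constant features yield a single leaf, not an error.

**Significance cutoff.** The full procedure is re-run `n_perm` (default
20) times on uniformly permuted targets; each permuted run contributes
its maximum RI, and the cutoff is the 95th percentile of those maxima
(a max-statistic percentile controls the family-wise rate of admitting
features no better than random; a mean-plus-t-interval variant is
available via `cutoff_method="mean_t"`).  Features strictly above the
cutoff are significant.

**ID-graph.** Direct parent/child node pairs add IG(child) ·
n(child)/n(parent) to the directed edge (parent feature → child
feature), summed over all trees; `idgraph_view` keeps the top-k nodes by
RI and then the strongest edges among them, ties lexicographic.

## The experiment designs

The **main experiment** runs selection four times: on the joined
multi-omics table restricted to samples complete across all three omics,
and per omic on every sample carrying that omic.  Per omic it reports
the joined-set, individual-set, intersection and union significant sets
(the union is the final significant set), and validates the union by
training a bagged random forest (100 of this package's trees, bootstrap
rows, √p features per tree) and an RBF SVM (scikit-learn, standardized
features, library defaults — logged, since the hyperparameters are
otherwise unspecified) on the complete samples and scoring weighted
accuracy on the held-out incomplete samples.

The **mass experiments** treat each chosen mRNA as a regression target
with miRNA (or chromosome-restricted methylation) predictors: one
regression-mode selection run per target, then a cross-validated
prediction on the significant set.  Expression targets are
log-transformed (multiplicative noise).  The cv prediction uses a bagged
ensemble of 30 regression trees per fold (k = 5): a single
piecewise-constant tree attenuates the Pearson correlation of a
multi-driver continuous target to ~0.75 at a few hundred samples even
when the planted signal correlation is 0.99, which would make the
well-predicted gate (cv Pearson ≥ 0.8) unreachable regardless of signal
strength; bagging is the same variance-reduction device the
classification validation uses and restores the gate's intended
behavior.  Aggregation over well-predicted targets counts, per
predictor, the number of significant sets containing it (Freq), the
summed RI (Sum RI) and Mean RI = Sum/Freq, sorted by Sum RI.

## Methylation genomics

CpG context: a site inside an annotated island is `island`; within
2 000 bp of an island edge `shore`; within a further 2 000 bp `shelf`;
otherwise `open_sea` — precedence island > shore > shelf > open sea when
flanks overlap.  Gene context: promoter = within 2 000 bp of the
strand-aware TSS, precedence promoter > gene body > intergenic; promoter
and intergenic sites pair with the nearest-TSS gene (ties lexicographic),
gene-body sites with their host gene.

Fold-change conventions (stated because the two omics differ):
methylation log2FC = log2(mean β normal / mean β cancer) with a 1e-6
pseudocount, so sites more methylated in cancer get log2FC ≤ −1 and the
label *hyper* (≥ +1 → *hypo*, otherwise *medium*); this is the unique
orientation under which the labeling rule reads correctly.  Expression
log2FC = log2(cancer/normal), so "down-expressed in cancer" is
log2FC ≤ −0.5 for the miRNA filter.

Differential testing uses the two-sided Mann–Whitney/Wilcoxon rank-sum
test with Benjamini–Hochberg FDR across the tested panel; a Shapiro–Wilk
normality check per feature is computed and logged (the nonparametric
test is applied regardless — the conservative choice for bounded
β-values).  Groups smaller than 3 are skipped with a warning.

Region enrichment is a per-region 2×2 chi-squared (tested set vs
background panel, in-region vs out), Bonferroni-corrected over regions,
with direction from the odds ratio.  Chromatin-state enrichment draws
size-matched site sets from the array panel without replacement
(default 1 000 draws; a draw models an alternative panel selection),
reports log2(observed % / mean null %) per state and empirical tail
probabilities (1 + exceedances)/(1 + draws) — never 0, never above 1 —
plus a Bonferroni correction over the tested states, matching the
correction discipline applied to the other region tests: with eight
compositional states a calibrated raw p is uniform under the null, so
only the corrected column supports "any state significant?" questions.

The cis screen tests Spearman correlation between a gene's expression
and the β-values of sites within ±1 Mbp of its TSS on the same
chromosome, keeping pairs with |rho| ≥ 0.6 and BH-FDR q ≤ 0.05.  The
survival screen is a two-group log-rank test (lifelines) on the
median-β split per site (ties to the low group; constant sites are
skipped), with a bootstrap null that draws same-sized site sets from the
panel (default 100 rounds) and counts per-round significant sites —
per-site p-values depend only on the site, so they are computed once.

## Motif analysis

PWMs are w×4 position probability matrices with a background
distribution; zero probabilities are floored at 1e-4 and renormalized
before log-odds (finite scores).  Exact p-values come from discretizing
per-position log-odds on a 1e-3-bit grid and convolving positionwise —
scanning uses the same discretized scores, so scan p-values match
exhaustive enumeration over all 4^w words exactly (tested to 1e-9 for
w ≤ 6).  Both strands are scanned (the reverse-complement PWM on the
forward sequence); windows containing non-ACGT bases yield no hits.
Window extraction around a methylation site takes site ±20 bp (41 bp),
clipping and flagging at chromosome ends; intersection of hits with
methylation sites happens in genomic, not window, coordinates.

Motif enrichment scores each PWM by the mean over foreground windows of
the best per-sequence log-odds score against a null of size-matched
resamples of the background windows (1 000 by default); the statistic
and null are this package's design — documented and calibration-tested —
since the upstream tool's statistic is not published.  PWM similarity is
the best ungapped local alignment of columns (all offsets, both
orientations, minimum overlap 4 columns) scored by mean per-column
Pearson correlation over the 4 base probabilities (constant columns
compare by identity); distance = 1 − similarity; trees come from a
hand-rolled UPGMA (size-weighted average linkage, merge height = half
the merge distance, lexicographic tie-breaks) so tie behavior is fully
specified.  Multiple alignment of PWMs is out of scope.

## NLP clustering

Documents are tokenized to lowercase unigrams plus adjacent-pair bigrams
(joined with `_`, formed after stopword removal so a bigram may bridge a
removed stopword), dropping a packaged ~120-word stopword list and
tokens of length ≤ 2.  tf = term count / document length; idf = ln(N/df)
unsmoothed, so a term in every document weighs exactly 0 (that is what
makes cluster keywords "unique"); a smoothed variant is available.
Clustering is average-linkage agglomeration on 1 − cosine similarity cut
at an explicit k (a silhouette-based suggestion is provided); keywords
rank terms by mean weight inside the cluster minus mean weight outside,
positive scores only.

## Linear regulatory models

Per target gene, ordinary least squares on the selected predictors plus
a 0/1 tissue indicator (normal/cancer); exactly collinear columns are
dropped with a warning before fitting.  Model F-test p-values are
BH-adjusted across targets ("adjusted p" read as BH-FDR, consistent with
the rest of the pipeline); *best-fitted* requires adjusted p ≤ 0.05 and
R² > 0.5.  The ablation refits without the tissue column (a refit, not
coefficient zeroing) and reports the full-fit Pearson correlation of
both models.  Edge tables connect, for each best-fitted model, every TF
to every DMS and every DMS to the target, plus miRNA→target edges from
the negative-correlation screen; duplicates collapse with weight =
count.

## The synthetic study

The generator emulates, at reduced scale, a TCGA-like breast-cancer
cohort: 120 samples (80 cancer / 40 normal by default), 2 020 features
per omic of which 20 carry planted effects, one third of samples
complete across all three omics and each remaining sample missing
exactly one omic (per-platform coverage ~78%, close to the emulated
cohort's ~72%).  Expression is log-normal with planted ±2-SD log-scale
shifts (alternating down/up in cancer); methylation is per-site
Beta-distributed with a common concentration (default 20) and planted
mean shifts of 0.11 per unit effect size (≈ the same number of
within-group SDs), always inside (0, 1); labels record the planted
direction under the log2FC sign convention.  Thirty mRNA targets are
rewired as noisy linear combinations of three miRNA drivers with
comparable coefficient magnitudes (|c| ~ U(0.8, 1.2), random signs) and
noise set so the target–signal correlation is 0.9.  The genome fixture
tiles each chromosome exactly once with eight chromatin states, places
non-overlapping genes and CpG islands, assigns each methylation feature
a unique coordinate, and can write sampled high-scoring motif instances
over chosen sites (kept inside the 41-bp window).  Descriptions mix a
shared vocabulary with disjoint per-topic vocabularies; survival times
are exponential with the hazard multiplied per effect site for samples
above that site's median β, independently censored.  Everything is
byte-deterministic under the spec seed.

**Class composition.**  The 80/40 default is a deliberate design point.
Under a 100/20 split the class-entropy ceiling (H ≈ 0.65 bits)
compresses the information gain of a 2-SD planted feature to ~0.2 bits,
at the level of the best spurious gain among 2 000 noise features at
n = 120 — planted and null features become statistically inseparable for
*any* selector, and the recovery contract the package promises
(≥ 90% of planted features in each omic's union set) cannot hold.  At
2:1 imbalance the planted gains sit well clear of the noise maximum and
recovery is 19–20/20 across seeds.  The extreme 7:1 imbalance of the
real cohort is still representable by passing `n_cancer`/`n_normal`
explicitly.

**Problem sizes.**  The mass-regression experiments run on a dedicated
fully-paired cohort (210 samples in the tests, 140/70, with the 897-wide
miRNA panel of the emulated study) because tree-based cross-validated
prediction needs a few hundred paired samples to clear the 0.8 gate —
at ~65 paired samples (what the 120-sample cohort's missingness leaves)
the gate is unreachable at any signal strength.  The null-calibration
loop runs 20 seeds at 300 features; the calibration property is
scale-free.  These sizes are the package's own choices for its shipped
experiments; all of them are parameters.

## What the tests do and do not show

Passing tests show that the algorithms implement their documented
formulas exactly (hand and enumeration oracles), that planted signals of
the stated sizes are recovered under the stated designs, and that the
constructed nulls are calibrated.  They do not show that real
RPKM/450K/miRNA-seq data satisfy the generator's distributional forms —
the generator makes no attempt to mimic batch structure, subtype
heterogeneity or probe chemistry — nor that the selected features of a
real cohort would validate biologically.  Empirical claims are limited
to what the test suite and `scripts/acceptance.py` themselves compute.

## Known limitations

- Mode 2's block partition evaluates every feature equally often but
  makes block-mates compete; very small blocks approximate univariate
  screening and weaken interdependency discovery.
- The exact-p machinery assumes an i.i.d. background; CpG-aware or
  methylation-adjusted scoring is not implemented.
- The survival screen is two-group log-rank only; no multivariate
  survival models.
- No genome-build conversion, probe-level normalization, or external
  database lookups.
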