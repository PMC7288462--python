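# Methods

This note documents the statistical models, numerical choices and design
decisions behind `musselpipe`, and what the synthetic study conditions do
and do not establish about real data.

## Data model

Diploid SNP calls are unordered allele pairs over 2–3 nucleotide symbols
per locus; gametic phase is never assumed or inferred anywhere in the
package. Missing calls are whole-genotype (`-1` in the integer array);
statistics exclude missing calls locus-wise rather than imputing. The
genotype matrix, locus annotation (coding/non-coding, synonymy, diagnostic
flags) and the per-population environmental table (12 variables plus a
categorical region with the fixed level set North Atlantic Ocean / Baltic
Sea / Barents Sea / Mediterranean and Black Seas) are cross-validated
before analysis: annotation rows for absent loci are tolerated with a
warning, missing environment rows are hard failures.

## Diversity statistics

* *Po* counts loci with ≥2 alleles observed in the sample — no minor-allele-
  frequency floor, so a single heterozygote makes a locus polymorphic.
* *H*<sub>E</sub> is Nei's unbiased gene diversity (2n/(2n−1))(1 − Σp²).
* Multilocus *F*<sub>IS</sub> is the ratio of averages 1 − ΣH<sub>O</sub>/ΣH<sub>E</sub>
  over polymorphic loci, not the average of per-locus ratios; ratios are
  unstable near monomorphism. Per-locus FIS is undefined (excluded) when
  H<sub>E</sub> = 0.
* The FIS permutation test shuffles gene copies among individuals; since
  allele frequencies — and hence H<sub>E</sub> — are invariant under the
  shuffle, the test compares observed heterozygosity directly. One-sided
  (homozygote excess), add-one smoothed.
* The exact Hardy–Weinberg test is the conditional test given allele
  counts, summing the Levene probabilities of all heterozygote
  configurations at most as probable as the observed one (tie tolerance
  1e−9 on the log scale). Biallelic loci always use full enumeration —
  it is cheap at any realistic n. Triallelic loci use a Markov chain that
  swaps gene copies between random individuals; because the uniform
  distribution over arrangements of the fixed gene copies induces exactly
  the conditional law over tables, every proposal is accepted and no
  Metropolis correction is needed. Default 20,000 steps after a 1,000-step
  burn-in.
* Multiple testing uses Benjamini–Yekutieli (valid under arbitrary
  dependence), delegated to statsmodels.
* Both HO/HE averaged over polymorphic loci and over all loci are emitted;
  the polymorphic-loci average is the documented default in summary rows,
  while "average gene diversity" is the all-loci mean (monomorphic loci
  contribute 0) — two deliberately distinct columns.
* Mean pairwise difference between two individuals at one locus is the
  number of gene copies not shared under optimal matching of the unordered
  pairs (0, 1 or 2), summed over co-scored loci and averaged over pairs.

## Differentiation

FST is Weir & Cockerham's (1984) θ. Per locus, the a (among populations),
b (among individuals within populations) and c (within individuals)
components are summed over alleles; the multilocus estimate is
Σa/Σ(a+b+c) over loci, with monomorphic loci contributing zero components
rather than being dropped. Negative estimates are reported as computed
and clamped to zero only when a distance matrix is required (NJ input).
This estimator stands in for AMOVA-style FST; for diploid data without a
within-individual level the two are numerically near-identical.

The outlier scan simulates neutral biallelic loci under a symmetric island
model at the observed multilocus θ: ancestral frequencies uniform on
(0.02, 0.98), per-population frequencies Balding–Nichols Beta with
F = θ, multinomial genotype sampling at the observed sample sizes. The
simulated loci are binned into heterozygosity deciles and the
(α/2, 1 − α/2) θ quantiles per bin form the envelope. Simulating at the
observed sampling configuration (rather than a fixed 50-deme design) makes
the scan self-calibrating: data generated from its own null are flagged at
≈α. The scan is skipped with a warning when multilocus θ ≤ 0.

Genotypic LD uses the G statistic on the two-locus genotype contingency
table with a null formed by permuting one locus's genotypes across
individuals — the same phase-free null semantics as classical genotypic
exact tests, with a different statistic; zero-variance tables give p = 1.

Neighbor joining is delegated to scikit-bio on the clamped θ matrix; the
suite verifies exact recovery of additive matrices (topology and branch
lengths). Correspondence analysis is the chi-square-standardized SVD of
the allele-count table; principal row coordinates are D_r^{-1/2} U Σ and
inertia percentages are σ²/Σσ² over all retained axes (zero-sum rows or
columns are dropped first).

## Hybrid composition

A locus is diagnostic for a taxon when some allele has frequency ≥ d_high
(default 0.9) in that taxon's reference samples and ≤ d_low in each other
taxon's. d_low defaults to 0.2; the "rare elsewhere" threshold is a free
design parameter and is config-exposed.

HI divides characteristic-allele copies by twice the number of *scored*
panel loci — missing loci shrink the denominator rather than being
imputed; individuals with no scored panel loci are excluded from
population aggregates with a log entry. V<sub>HI</sub> uses denominator
n − 1.

The six-category posterior is a plug-in empirical-Bayes classifier:
parental allele frequencies are estimated from reference samples with
Dirichlet(1) smoothing and treated as known; per class, genotype
probabilities follow from gamete-pool algebra (pure = HW; F1 = one gamete
from each parental pool; F2 = HW of the mixed pool; backcross = one
parental and one F1-pool gamete); loci are independent; the prior is
uniform over the six classes. This replaces a full Bayesian treatment
that integrates over latent parental frequencies; with near-fixed
diagnostic panels the plug-in posterior is essentially identical and the
smoothing constant is configurable. F1 vs F2 discrimination collapses as
panels become less diagnostic — the known limitation of any
genotype-frequency-based classifier.

Ancestry estimation is supervised: cluster allele frequencies come from
declared reference samples and only the per-individual mixing vector q is
estimated, by EM over allele copies (tolerance 1e−8 on max|Δq|, cap 5,000
iterations, non-convergence warns with the last iterate). Unsupervised
clustering, ΔK selection and related machinery are out of scope;
externally computed q-matrices can be imported from TSV. The q thresholds
are: resident > 0.8, admixed 0.2–0.8 inclusive, migrant < 0.2.

## Boosted regression trees

The learner is stagewise gradient boosting with depth-limited
least-squares trees on the negative gradient:

* Bernoulli: F₀ = logit(ȳ), residual y − p, Newton leaf step
  Σz/Σp(1−p); multinomial (K = 3): symmetric per-class logits with
  softmax, one tree per class per stage, leaf step
  ((K−1)/K)·Σz/Σ|z|(1−|z|). Leaf steps are clipped to ±4 before
  shrinkage for numerical safety.
* Splits maximize SSE reduction; candidate thresholds are midpoints of
  adjacent distinct values; the categorical region uses the ordered-mean
  heuristic (levels sorted by mean residual, then scanned as if ordinal),
  stored as an explicit level subset. Ties break toward the first feature
  and split found, making fits deterministic under a seed.
* Defaults follow the study design this engine reproduces: learning rate
  0.01, 20,000-tree cap, 10-fold CV, and a 1,000-tree rule-of-thumb
  warning; tree depth 2 and bag fraction 0.5 are common BRT practice (the
  original description leaves them open) and are config-exposed.
* CV folds are stratified by population: predictors are site-level
  constants, so unstratified folds can starve a fold of a site entirely.
  The optimal tree count minimizes mean held-out deviance; held-out MAP
  predictions at that count feed the adjusted-count pseudo-R². This
  pseudo-R² can legitimately be negative when the model CV-misclassifies
  more often than the majority rule.
* Relative influence sums per-split SSE improvements per predictor over
  the selected trees (across class trees for multinomial), normalized to
  percentages. Correlated or duplicated predictors share influence —
  the usual caveat applies when reading profiles.
* Partial dependence forces one predictor to each grid value and averages
  predictions over the training rows; probability scale.
* The response encoding treats each allele copy as one observation (two
  per genotyped individual), matching a model of allele *frequencies*;
  an individual-level encoding can be assembled from the same design
  helper if needed.

## Environment association

The collinearity screen reports pairwise Pearson r over populations and
flags |r| ≥ 0.7; flagged pairs are retained with a warning by default
(tree ensembles tolerate collinear predictors; a strongly correlated
temperature–ice pair is an expected feature of high-latitude data), with
a hard-exclude option. Abrupt transitions are operationalized as the
shortest grid interval containing ≥80% of the partial-dependence curve's
total variation — a flat curve yields no interval. ANOSIM
(R = (r̄_between − r̄_within)/(M/2), label-permutation p, exact
enumeration available for small problems) and SIMPER (per-variable
decomposition of mean between-group Bray–Curtis, an exact identity) run
on the matrix of per-locus influence profiles, grouped by the coding /
non-coding annotation; feeding influence percentages (optionally with
pseudo-R²) operationalizes "untransformed model results".

## Synthetic study conditions

The default scenario emulates the sampling design the pipeline targets:
12 sites × ~30 diploid individuals × 54 SNPs (16 trossulus-diagnostic, 6
per other taxon, 2 triallelic, the rest shared polymorphism with mild
Balding–Nichols taxon divergence F = 0.02), 2% missingness, a
trossulus/edulis logistic cline along salinity with midpoint 9.5 psu and
steepness 0.6 (10%→90% inside 8–11 psu), pure reference sites for all
three taxa, a 50/50 bimodal parental contact site, a matched unimodal
swarm, and one strongly inbred site (f = 0.6) reproducing the large
homozygote excesses of admixed Arctic samples. Diagnostic characteristic
alleles draw frequencies from U(0.95, 1.0) in their taxon and U(0, 0.05)
elsewhere: a near-fixed panel, the upper half of the "about 90–100%"
range such panels show in practice. This choice is deliberate — the
bimodal-vs-swarm V<sub>HI</sub> contrast (>0.2 vs <0.1) approaches the
theoretical ceiling of a [0,1]-valued index (variance ≤ 0.25), so only a
strongly parental mixture scored on a near-fixed panel exhibits it
robustly. The temperature and ice-cover columns are constructed (by
Gram–Schmidt) to have an empirical correlation of exactly −0.87; the
other ten variables are independent noise within field-realistic ranges.

What the generator does *not* emulate: linkage between SNPs, coalescent
ancestry and within-taxon geographic substructure beyond a single drift
parameter, selection through time, genotyping batch effects, and any
spatial autocorrelation of the environment. Passing parameter-recovery
tests therefore shows the estimators are correct and well calibrated
under the declared sampling model, not that real mussel data meet that
model.

## Problem sizes and determinism

Scenario-level checks run at the scales above; BRT-based checks use a
scaled configuration (learning rate 0.05, 300-tree cap, 5-fold CV) on a
subset of loci, chosen so the whole chain remains a desk-scale
computation — the engine's defaults remain the full-scale settings.
Permutation defaults in the pipeline config (200 replicates) are likewise
scaled; library defaults keep the canonical counts (10,000 for FIS,
1,000 for FST, 30,000 for the outlier scan). Every stochastic component
accepts a seed or Generator; the study generator derives one named
substream per site from the root seed, and reruns of the pipeline under a
fixed seed are byte-identical (hash-checked in the suite).

## Known limitations

* The Genepop reader infers allele symbols from observed codes; an allele
  declared but never observed is not reconstructed.
* The plug-in class posterior understates uncertainty in parental
  frequencies when reference samples are small.
* The island-model envelope ignores within-taxon hierarchical structure;
  in strongly structured data the outlier scan is anti-conservative, as
  is true of the classical approach it follows.
* The MC Hardy–Weinberg p-value is a visit-fraction estimate; its
  Monte-Carlo error is O(n_steps^{-1/2}) and chain autocorrelation is not
  corrected for.
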