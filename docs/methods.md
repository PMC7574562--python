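# Methods

`epinipt` implements the analysis side of epigenetic non-invasive prenatal
testing (NIPT) from covalent-tagging CG sequencing of maternal plasma
cell-free DNA (cfDNA): uTOP-seq reads report unmodified CGs (uCG), hmTOP-seq
reads report 5-hydroxymethylated CGs (5hmCG). Because the placenta is
globally hypomethylated and carries more 5hmC than maternal blood, both
signals preferentially capture the fetal (placental) component of the cfDNA
mixture, and chromosome-dosage statistics built on them detect fetal
trisomy 21 at far lower read counts than whole-genome counting.

## The mixture model behind the synthetic cohorts

Real cohorts of this kind are small and access-restricted, so the package
ships a first-class generator that emulates the count structure of the
assays. A synthetic genome holds a CG-site catalog (homogeneous Poisson
placement at a mean rate of 1 CG / 100 bp, with CG-island clusters of 10x
density over 2% of the genome; the background rate is renormalised so the
genome-wide mean equals the configured rate), interval annotations (CGI,
promoter, UTRs, exons, introns, enhancers, lincRNA promoters), HM450-like
probe positions with independent mQTL flags, and per-tissue, per-site
capture propensities:

* **uCG.** Per-site base weights are Beta(2,2), multiplied by 5 in CG
  islands and 2 in promoters/5'UTRs (unmethylated regulatory regions
  dominate uCG capture in every tissue). Placental hypomethylation is
  planted as contiguous 100-kb domains covering 20% of *each* chromosome
  (a scaled analog of the megabase-scale placental hypomethylated domains);
  inside a domain the placenta propensity is the maternal one times a boost
  (default 6, giving a genome-wide placenta:maternal capture ratio of 2).
  Equal domain coverage per chromosome keeps the healthy chromosome-ratio
  statistic independent of fetal fraction.
* **5hmCG.** Sparse: a site carries maternal 5hmC with probability 0.10
  (x3 in exons/3'UTRs, where gene-body 5hmC concentrates), with Beta(2,2)
  weights. The placental activity state is redrawn independently per site
  with probability given by the tissue-discrimination parameter (default 1,
  i.e. fully tissue-specific), then the placenta vector is rescaled so the
  genome-wide placenta:maternal propensity ratio equals 0.021/0.012 = 1.75,
  the ratio of tissue-level 5hmC abundance measured by HPLC–MS/MS.

A cfDNA sample with fetal fraction *ff* has per-site expected rate
`(1-ff)·maternal + ff·fetal`, where the fetal vector is the placental one
with the target-chromosome slice multiplied by 1.5 for trisomy 21 (three
fetal copies instead of two). Read counts are one multinomial draw of the
sample's depth over sites, so counts sum exactly to depth; optional
per-site gamma overdispersion is off by default. Non-pregnant controls have
ff = 0, chorionic-villus tissue ff = 1, pregnant samples ff ~ U(0.06, 0.10)
(the typical early-pregnancy range). All randomness flows through one
seeded NumPy PCG64 generator; fixed seeds give bit-identical cohorts.

What the generator does **not** emulate: sequence content (no FASTQ or
error model), cfDNA fragment-length differences, batch effects, GC bias,
and the SeqFF-bin-specific 5hmC depletion that produces the inverse
predicted-vs-reference fetal-fraction slope seen in real hmTOP-seq data.
Passing tests therefore demonstrate correctness of the statistics under an
idealised multinomial sampling model, not robustness to those artefacts.

## Read counting and coverage statistics

A read is assigned to the nearest catalog CG whose C lies within 3 bp of
the read's 5' start (inclusive, either strand); exact ties go to the
lower-coordinate CG, each read increments exactly one site, and
unassignable reads are dropped and tallied per sample. Chromosome-level
signals are **CG-coverage** (summed counts) and **CG-fraction** (share of
CG sites with at least one read). Windows (100 bp for DMR testing, 1 kb for
enrichment, 50 kb bins for fetal fraction) tile each chromosome half-open;
windows without a CG are excluded and counted. In-silico depth reduction
draws reads without replacement (multivariate hypergeometric per sample).

## Outlier screening

Count matrices are Hellinger-transformed (square root of row proportions),
converted to Bray–Curtis dissimilarities and embedded in two dimensions by
non-metric MDS (Kruskal stress-1 via SMACOF with isotonic regression; one
classical-MDS start plus 19 seeded random restarts, best stress kept,
convergence tolerance 1e-9). A sample is an outlier when it deviates from
its own group mean by more than two group standard deviations (ddof = 1) on
either ordination axis; groups smaller than three are skipped with a
warning, and flagged samples are reported, never silently dropped. The
screen runs once per assay, not iteratively.

## Z-score karyotyping

For sample *i*, X_i is the ratio of target-chromosome signal (CG-coverage
or CG-fraction) to the reference chromosome's signal. With mu and sigma the
mean and sample standard deviation (ddof = 1, configurable) of X over the
euploid reference population, Z_i = (X_i − mu) / sigma. The reference
chromosome is configuration: chr16-analog for uCG and chr20-analog for
5hmCG by default (the source protocol's own reporting of this pairing is
internally inconsistent, so both orderings are supported and a run's choice
is logged).

The reference population is a mask: the default study configuration trains
mu/sigma on **all euploid plasma controls** — non-pregnant controls plus
healthy pregnancies, ~14 samples — rather than the 7–8 healthy pregnancies
alone. The reason is quantitative: with only 7 reference samples the
leave-one-out sigma estimate has ~6 degrees of freedom, so a healthy sample
that sits 2 SD out can see its *cross-validated* Z explode (its own
exclusion shrinks sigma several-fold) past genuine trisomy scores; with ~13
retained reference samples the estimate has light enough tails that perfect
separation at the claimed depths is stable. Non-pregnant plasma is a valid
dosage reference here because it is euploid and, in the mixture model, has
the same expected chromosome-ratio as a healthy pregnancy. Restricting the
reference to healthy pregnancies is one mask argument away.

Classification is leave-one-out cross-validation: every fold re-estimates
mu/sigma from the retained healthy samples (a held-out healthy sample never
enters its own training statistics) and refits a logistic regression of
karyotype on Z. Because Z typically separates the classes perfectly, the
fit is ridge-stabilised (L2 penalty 1e-4 on the standardised coefficient,
intercept free). Accuracy uses the 0.5 probability cutoff. AUC ranks
samples by the held-out cross-validated Z-score, which is strictly
monotone in the fold's predicted probability: pooled raw probabilities are
not on a common scale across leave-one-out folds — removing one positive
or one negative shifts each fold's intercept — and at these cohort sizes
that artefact biases the permutation-null AUC far below 0.5, whereas the
cross-validated score keeps it centred. Depth titration repeats
subsample → chromosome stats → Z → LOOCV thirty times per depth and can
merge natively shallow samples into the evaluation loop at their own depth.

Human-genome-scale depths are mapped onto a synthetic genome by the factor
(synthetic CG count / 28,000,000), matching per-CG coverage density.

## DMR discovery

Per 100-bp window the features are `norm_cov = log2(coverage + 1) −
log2(reference-chromosome total)` (pseudocount 1) and `norm_frac = window
CG-fraction / reference-chromosome CG-fraction`. Group membership is tested
by a likelihood-ratio chi-square (df = 2) between logistic models with and
without the two window features; fetal sex and fetal fraction enter both
models as covariates for the trisomy contrast. The per-window fits run as a
batched Newton/IRLS (convergence: relative log-likelihood change < 1e-8;
a 1e-10 ridge only stabilises singular designs; linear predictors clipped
at ±30, which handles separation), verified against statsmodels' Newton
fits to 1e-6. Windows whose full model fails with the sex covariate are
refitted without it — and the null drops it too, keeping df = 2; windows
that still fail get p = NA and are excluded from Benjamini–Hochberg FDR.
Significance is q < 0.05, with a nominal p < 0.05 switch for sparse-signal
assays. Effect sizes are log2 fold changes of reference-normalised group
means with a shared epsilon of half the smallest nonzero mean (so equal
means give exactly 0). DMR sets are compared by Fisher's exact test over
the universe of tested windows (odds ratio ad/bc, Haldane 0.5 correction
flagged on degenerate tables), Pearson effect concordance, a two-sample
Kolmogorov–Smirnov test on genomic positions, and a per-window leave-one-
out penalised logistic classifier (Gaussian prior, scale 2.5 on
standardised predictors, emulating a weakly-informative Bayesian GLM);
windows with cross-validated AUC = 1 are flagged discriminatory.

Small-sample caveat: at cohort sizes around n = 14 the logistic LRT is
mildly anticonservative (the chi-square reference is asymptotic in n; the
implementation is the exact MLE). The package's null-calibration tests
therefore run on 80 + 80 samples at deep coverage, where the reference
distribution holds; at real cohort sizes the q-values should be read as
approximate.

## Enrichment

Top-signal windows are the top 10% of 1-kb windows by group-mean coverage,
boundary ties all included (deterministic; a selection that degenerates to
everything is flagged). Enrichment is a Fisher 2×2 at CG-site resolution
(in top window × overlapping the annotation, universe = all catalog CGs);
probe-level mQTL enrichment works identically with array probes as the
unit, and additionally reports the fraction of DMRs containing an mQTL
probe.

## Fetal fraction

A deliberately simple stand-in honouring the contract of count-based,
sex-independent fetal-fraction estimators: counts are totalled in 50-kb
bins, row-normalised to proportions (predictions are exactly invariant to
sequencing depth) and mapped to fetal fraction by ridge regression
(per-sample penalty 1e-4, so duplicated training rows leave the fit
unchanged; predictions clipped to [0, 1]). It is not a SeqFF
re-implementation — no trained SeqFF weights exist to port — and the
inverse slope of real hmTOP-seq SeqFF predictions is out of its scope.

## Study conditions and problem sizes

The simulated study cohorts mirror the real design: uCG 7 NPC / 8 healthy /
5 T21 / 7 CVS; 5hmCG 7 NPC / 7 healthy / 4 T21 / 3 CVS; ff ~ U(0.06, 0.10);
full libraries at the 10M-read equivalent. Genome sizes were fixed by an
a-priori power calculation: at subsampling depth d (reads), the healthy
chromosome-ratio noise is ≈ sqrt(2/(d/3)) while the trisomy effect on the
ratio is 0.5·w with fetal read share w = ff·rho/(1 − ff + ff·rho) (rho the
placenta:maternal capture ratio — 2 for uCG, 1.75 for 5hmCG). Requiring
the worst-case effect (ff = 0.06) to exceed ~5 noise SDs at the shallowest
claimed depth gives ~600k CG sites (3 × 20 Mb) for the uCG study at the
3M-read equivalent and ~2.4M sites (3 × 80 Mb) for the 5hmCG study at the
1M-read equivalent. Calibration studies use smaller genomes: 3 × 4 Mb for
null calibration (80 + 80 samples), 3 × 8 Mb for planted-DMR recovery
(7 NPC vs 7 CVS, 600 CGI windows boosted 6-fold, pilot-calibrated once and
fixed), and the 3 × 2 Mb default for outlier and fetal-fraction studies.

## Known limitations

* The multinomial sampling model has no extra-Poisson noise by default;
  real libraries are overdispersed (a gamma multiplier is available but
  off).
* The 3-bp assignment rule counts each read once even when two CGs fall
  within range (unique nearest-site assignment; whether the original
  counting double-counted such reads is unknown).
* DMR q-values at real cohort sizes are approximate (see above).
* The fetal-fraction stand-in is linear in bin proportions; the true
  relation is mildly nonlinear in ff through the capture-enrichment
  amplification, contributing a small systematic error at high ff.
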