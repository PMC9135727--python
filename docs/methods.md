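# Methods

## Statistical model

The pipeline treats a bulk tumor cohort as a mixture: each sample is a
fraction *purity* malignant cells and 1 − purity immune/stromal cells.
Immune transcriptional programs therefore co-vary with purity, and any
lncRNA tracking purity acquires spurious marginal correlations with immune
genes.  The discovery stage conditions every lncRNA–mRNA correlation on
purity (first-order partial correlation), so that only couplings to immune
*activity beyond what purity explains* survive.

The downstream stages are standard survival/bioinformatics machinery:
weighted-KS gene-set enrichment on the rank-score ordering, a hypergeometric
over-representation test against immune-cell marker sets, Monti-style
consensus clustering, single-sample GSEA, and Cox proportional-hazards
modelling with median risk-score stratification.

### Assumptions

- Purity enters expression *linearly* on the log2 scale; the partial
  correlation removes exactly this linear component.
- Expression values are log2-scale and roughly continuous; all rank-based
  steps (RS ordering, ssGSEA, rank-sum DE) need only monotone fidelity.
- Survival follows proportional hazards in the panel genes; ties are
  handled by lifelines' Efron approximation.

## Key numerical choices

**p-value for the partial correlation.** t distribution with
df = m − 2 − (number of covariates); one covariate (purity) gives m − 3.
In the purity-ignoring diagnostic mode df = m − 2.

**Rank-score clamping.** RS = −log10(p)·sign(PCC) is clamped to ±300 so
underflowed p-values cannot produce infinities.  Ties in RS are broken by
gene id, making rankings deterministic across runs.

**Enrichment-statistic weighting.** The running-sum hit increments are
|r_j|^p / N_R.  The scoring and screening default is p = 0 (the unweighted
two-sample KS statistic).  Reason: the analytic p-value below is the KS
tail, which describes the *unweighted* statistic; with p = 1 the analytic
p is anti-conservative by orders of magnitude against a permutation null
(absolute error up to ~0.7 at desk scale) and the 0.995 screen loses all
selectivity.  Rank-weighted scoring (p = 1, GSEA convention) remains
available via `weight_exponent`, and `enrichment_score` itself defaults to
p = 1 for standalone GSEA-style use.

**Analytic enrichment p-value.** Two-sided KS tail
2·Σ_{q≥1} (−1)^{q−1} exp(−2 q² λ²) with effective size
n = (N − N_I)·N_I / N, truncated when a term falls below 1e−12 (or at 100
terms) and clamped to [0, 1]; ES = 0 is defined as p = 1.  λ uses Stephens'
finite-sample correction λ = (√n + 0.12 + 0.11/√n)·|ES| by default, which
keeps the tail within Monte-Carlo error (<0.02) of a 10,000-permutation
null at N = 200, N_I = 20; `finite_sample=False` gives the uncorrected
series.  The tail (survival) orientation is used, so strong enrichment
gives small p and lncRES → +1, consistent with the lncRES > 0.995 screen;
the raw asymptotic CDF is available (`use_cdf=True`) for diagnostics.

**lncRES and the screen.** lncRES combines the *raw* analytic p with the
ES sign (1 − 2p or 2p − 1); BH-adjusted q-values are reported alongside but
do not enter the score.  The screen is one-sided (lncRES > 0.995), strict
inequality; a two-sided |lncRES| option exists.

**Marker association.** "Significantly related mRNAs" are those with
BH-adjusted correlation p < 0.05, with both the tested genes and the BH
family restricted to the marker universe so that k, n, M, N refer to one
urn.  The test is the standard upper-tail hypergeometric P[X ≥ k] (the
closed-form difference-of-binomial-coefficients expression sometimes
printed for this test is not a probability).  Overlaps k < 3 are never
significant, regardless of p.  No multiple-testing correction is applied
across cell types, mirroring common practice for this screen.

**Consensus clustering.** For each k: 80% sample subsampling without
replacement, inner k-means (Euclidean, 10 restarts) on per-feature
z-scored data, consensus = co-clustering frequency among co-drawn pairs.
k_opt minimizes PAC (consensus mass strictly inside (0.1, 0.9)); ties go to
the smaller k.  Final labels come from average-linkage hierarchical
clustering of 1 − consensus, relabelled 1..k in order of first appearance.
Pairs never co-drawn are an error when they exceed 1% of pairs.  Seeded
runs are bit-reproducible.

**ssGSEA.** Within-sample ranks (descending, position tie-break), weights
rank^α with α = 0.25; score = Σ (weighted in-set ECDF − out-of-set ECDF).
No cohort normalization step: only score *differences* between groups are
used downstream; a normalization flag can be added at the scoring call
site without affecting comparisons.

**Differential expression.** Two-sided rank-sum per gene, BH adjustment,
pass = raw p < 0.01 and |log2FC| > 1 (log2FC = mean difference on the log2
scale).  This is a deliberate nonparametric substitution for a count-model
DE package; the thresholds are preserved.

**Cox modelling.** Univariate screen: per-gene fit, Wald two-sided p;
constant or non-converging genes are skipped with a log entry, never
passed.  Multivariate fit: one proportional-hazards model over the panel,
guarded at <n/5 covariates (events-per-variable), with a ridge-stabilized
refit (penalty 0.1) on failure.  Risk score weights default to β (log-HR);
exp(β) is available (`score_mode="hr"`) since the "HR × expression" wording
of some reports is ambiguous between the two — the stratification itself
is invariant to that choice only when all coefficients share a sign, hence
the explicit flag.  The median split sends ties to the low-risk group.
External application keeps coefficients frozen and by default re-derives
the median within the external cohort (per-cohort split); the training
cutoff is a flag.  Time-dependent AUC is the IPCW cumulative/dynamic
estimator at 365/1095/1825 days; horizons beyond follow-up are skipped
with a warning.

## The synthetic-data generator

`synthdata.simulate` produces a cohort with known ground truth:

- purity ~ Beta(5, 2); z = standardized (1 − purity);
- each of 10 immune pathways has one latent activity a_k = ρ_k·z +
  √(1−ρ_k²)·ε, with ρ_k spread linearly over [0.35, 0.75]: some immune
  populations track overall infiltration tightly, others loosely;
- pathway genes (120 per pathway by default): 20% core genes at loading
  1.0 and 80% peripheral at 0.15 on a_k, plus N(0, 1) noise and a N(6, 1)
  baseline — expression programs have few strong and many weak members;
- 24 marker sets: the cell types assigned to a pathway share its core
  genes (related populations cite the same canonical markers) and split
  the peripheral genes; background genes fill the universe to
  min(2025, n_mrna) distinct markers (2000 at the defaults);
- driver lncRNAs: γ·a_k + N(0, 0.8²) plus a +2.2 shift in one of the
  K_true = 4 subtypes — coupling to immune activity itself, surviving
  purity adjustment;
- confounded lncRNAs: δ·z + N(0, 0.8²) — coupling to purity only,
  vanishing under adjustment (δ is on the standardized purity scale);
- null lncRNAs: pure noise;
- each subtype also up-regulates its own block of 30 background mRNAs by
  +1.5 log2 units, and the 5 true risk genes (alternating-sign β from 1.0
  down to 0.6 × β_scale) sit inside these programs, so the
  DE → univariate-Cox route of the pipeline has real signal to find;
- survival: exponential with hazard ∝ exp(Σ β·centered expression), base
  scale 1500 days; an exact censor_frac fraction of samples is censored at
  a uniform fraction of its event time.

Defaults (200 samples, 2000 mRNAs, 500 lncRNAs, 15 drivers at γ = 1, 15
confounded at δ = 2, 40% censoring) run the full discovery in seconds.
These constants were fixed at design time so that the generator exhibits
the qualitative structure the method assumes — recoverable drivers,
purity-explained decoys, separable subtypes — and were not revisited
afterwards.

**What the generator does not emulate:** read-count noise (negative
binomial, library size), batch effects, heavy-tailed expression,
correlated censoring, overlapping/hierarchical subtypes, or marker-set
misannotation.  Passing the recovery tests therefore shows the pipeline's
logic and implementation are sound under its own modelling assumptions,
not that real-cohort counts (e.g. numbers of screened lncRNAs) would be
reproduced; those depend on data versions and purity sources.

**A property worth knowing.** Because pathway genes share a latent factor,
a null lncRNA's chance correlation with that factor (~1/√m) shifts the
whole gene set coherently, and the independence-assuming KS p-value
overstates its significance: the lncRES screen alone is permissive for
null lncRNAs.  Selectivity comes from the *intersection* with the
marker-association stage, whose BH-corrected per-gene threshold removes
them; on defaults the final candidate set recovers the drivers with
precision and recall ≥ 0.9.  This mirrors the screen-then-intersect
narrowing the analysis is built around.

## Problem sizes

Tests and the acceptance script run at the generator defaults (200–500
samples, 2000 mRNAs, 500 lncRNAs) for end-to-end checks, 100–10,000
replicates for permutation and calibration oracles, and a 120-sample,
800-mRNA fixture for the CLI determinism run; the whole suite completes in
a few minutes on one CPU.

## Known limitations

- Gene identifiers are matched as exact strings; no symbol/accession
  mapping.
- Tumor purity must be supplied; it is never estimated.
- The analytic enrichment p-value ignores inter-gene correlation (see
  above); empirical permutation nulls are used only as test oracles.
- Clinical covariates can be passed into the multivariate Cox fit as extra
  rows, but the gene-only path is the tested default.
- No nomogram/decision-curve analysis, deconvolution, or GO/GSEA figure
  machinery.
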