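# Methods

## The model

`peradigm` maps candidate rare-disease genes by asking whether the rare
loss-of-function (LoF) variant carriers of a gene *look like* diagnosed
patients in phenotype space, rather than whether they *are* diagnosed.
The pipeline has two stages.

**Stage 1 — phenotype representation.** Each ICD-10 code's textual
description is tokenized (lowercase, punctuation stripped, a fixed English
stopword list removed). Each patient's chronological record of description
tokens is one "sentence"; a CBOW word2vec model with negative sampling is
trained on the sentence corpus, and a code's embedding e_k is the
unweighted mean of its in-vocabulary token vectors. Every code is scanned
for association with the target disease by logistic regression,

    logit P(c_ij = 1) = alpha + beta * d_j + gamma' z_j,

with d_j the disease status and z_j = (age, sex); the two-sided Wald
p-value of beta feeds the code weight

    w_k = sigmoid(-ln p_k) * IC_k,      IC_k = -ln r_k,

where r_k is the code's cohort prevalence. Since p in (0, 1] maps to
sigmoid(-ln p) in [0.5, 1), w_k lies in [0.5 IC_k, IC_k): significance can
at most double a code's information-content baseline. An individual's
embedding is the weight-normalized average of their *rare* distinct codes
(r_k <= 0.01):

    D_i = sum_k w_k e_k / sum_k w_k .

The normalization makes D_i invariant to weight rescaling; distinct-code
semantics make it invariant to event order and repeated records.
Individuals with no qualifying code are "empty" and excluded from every
similarity computation (cosine is undefined at the origin).

**Stage 2 — gene scan.** For every usable individual,
S_i = mean_k cosine(D_i, D_k) over the m diagnosed cases; a gene's risk
score R_G is the mean S over its carriers. Because a mean of cosines
against a fixed set is a dot product with the mean of the case unit
vectors, the cohort's S is one matrix–vector product. Significance uses an
empirical sampling null: 10,000 random groups of the same size n drawn
without replacement from the whole usable cohort (cases included,
carrier-status-agnostic) give (mu0, sigma), and Z = (R - mu0)/sigma is
referred to the upper tail of the standard normal. Null summaries are
cached per distinct carrier count — exactly equivalent to per-gene
resampling because the pool is shared. Bonferroni (default) or
Benjamini-Hochberg adjustment is applied across genes; reported p-values
are floored at 1e-25.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `freq_threshold` | 0.01 | only codes this rare enter D_i; common codes carry little disease-specific information |
| `d` (embedding dim) | 100 | standard word2vec capacity for a vocabulary of a few thousand tokens |
| `window` | whole sentence | the patient record is one bag of related diagnoses; a finite window (10 is used for large runs) trades a small context truncation for linear rather than quadratic cost in record length |
| `epochs` / `negative` | 10 / 5 | standard CBOW settings; training is single-threaded and bitwise-reproducible given the seed |
| `min_carriers` | 5 | genes with fewer carriers are not scanned |
| `n_reps` | 10,000 | null replicates per distinct carrier count |
| `maf_max`, `hwe_min_p` | 0.01, 1e-6 | variant QC thresholds |
| scheme | `pvalue_ic` | alternatives: `effect_ic`, `pvalue_only`, `ic_only`, `effect_only` ("effect size" is read as the absolute log-odds ratio) |
| `exclude_self` | off | whether a case's self-pair is dropped from its own S_i; off matches the plain mean-over-cases definition, and the option is surfaced because carriers who are themselves cases noticeably raise R_G |

Natural logarithms are used throughout (IC and the weight sigmoid), so the
[0.5, 1] sigmoid range holds exactly and IC is in nats.

## Numerical choices

- **Rare-code logistic fits.** Standard maximum likelihood
  (statsmodels) with a Jeffreys-penalized (Firth-type) Newton fallback
  when the fit separates or fails to converge; codes present in at most
  one individual are flagged excluded and not fitted. Codes without a fit
  keep the neutral weight 0.5 IC (p = 1), so they remain usable in
  embeddings rather than silently vanishing.
- **Sampling null.** Without-replacement sampling is O(n) per replicate
  (rejection sampling; partial Fisher-Yates when n > pool/2), jitted with
  numba and seeded deterministically per carrier count.
- **Ties and order.** Sentences order events chronologically with ties
  broken by code; gene tables sort by raw p with stable order.
- **Degenerate cases.** sigma = 0 (e.g. the sample is the whole pool) is
  an error for the Z test and is reported, not silently passed; empty
  embeddings and genes with no usable carrier are skipped with a log line.
- **p floor.** 1e-25; floored values are flagged and excluded from
  nothing downstream except that the chi-square transform of the
  inflation factor clips at the floor.

## The synthetic cohort: what it emulates, what it does not

The generator is the package's test bed and the study-condition
definition. It mirrors the analysis model in reverse:

- Codes are assigned per individual by independent logistic models with a
  latent "affected" status, age/sex effects, and a per-individual frailty
  term (sd 0.5 log-odds) modelling hospitalization-propensity
  heterogeneity.
- Disease relatedness is *graded*: 30 core codes with log-odds effects in
  [2, 4] (odds ratios ~7-55, the range seen for disease-specific
  phenotypes of Mendelian disorders) plus a Beta(0.25, 2.5) continuum of
  weak relatedness over all remaining codes — real phenome scans find
  hundreds of partially associated phenotypes, not a clean binary set.
- Descriptions draw from a synthetic word pool; a code with relatedness
  u_k replaces each word with probability 0.7 u_k by a shared
  disease-vocabulary word. Word sharing is the mechanism that lets CBOW
  place related codes near each other.
- The baseline prevalence spectrum is log-uniform on [3e-3, 0.03]. This
  straddles the 0.01 rare-code threshold (both filter branches are
  exercised) and gives each individual a few rare codes, so individual
  embeddings are genuine mixtures. A much wider spectrum at ~1,000 codes
  leaves most individuals with a single rare code; their embeddings
  collapse to isolated code vectors and the similarity distribution
  becomes a discrete bimodal mixture — an artifact of synthetic sparsity
  (real inpatient histories carry many rare codes) that has nothing to do
  with the method under test.
- The case-defining code is held by affected individuals minus a
  diagnosis-omission mechanism (default rate 0.1; carriers of a planted
  gene can have their own rate, up to 1.0 for the zero-overlap scenario).
  Planted causal-gene carriers become affected with probability equal to
  the penetrance.
- Carrier sets are Bernoulli per gene with log-uniform rates on
  [5e-4, 5e-3] (carrier counts roughly 10-100 at the default 20,000
  individuals, matching the 9-610 carrier range of genes reported in
  biobank-scale rare-disease analyses); kinship pairs are injected at
  random to exercise relatedness pruning.

What it does **not** emulate: the ICD-10 ontology hierarchy, longitudinal
disease progression, correlated comorbidity structure beyond the single
latent disease axis, ancestry structure, genotyping error, or linkage
between genes. A passing test therefore shows the statistical machinery is
correct and calibrated under a faithful generative analogue — not that the
method's biological discoveries on real data are reproduced.

## Calibration and its known limitation

On null cohorts (no planted genes) the pipeline's p-values are checked
for uniformity: empirical type-I error at 0.05/0.01 with Clopper-Pearson
intervals, a KS test, and genomic inflation factors lambda (median
chi-square) and lambda_q90 (0.9-quantile analogue). Under the default
conditions these sit at nominal (lambda ~ 0.91-0.98 across verification
seeds).

The Z-based p-value assumes the resampled risk-score mean is normal. For
carrier counts near the min_carriers = 5 floor the mean of a skewed
similarity distribution is itself skewed, which inflates the extreme tail
slightly (empirical rate at nominal 0.01 up to ~0.017 in one verification
seed). This is an intrinsic small-sample property of the normal
approximation itself; where exactness at
small counts matters, keep the raw null replicates
(`keep_null_scores=True`) and use the empirical-percentile p-value, which
is exact at any count and rank-agrees with the Z-based p (Spearman rho >
0.99 in the acceptance suite).

## Problem sizes used in the shipped checks

The acceptance script runs the full stated conditions: 20,000
individuals, 1,000 codes, 2,000 simulated null genes, 10,000-replicate
cached null, CBOW d=100 / 10 epochs / window 10. The pytest suite runs
the same checks at reduced sizes chosen to keep the default run fast
(6,000 individuals, 1,000 codes, 2,000 simulated genes and 3 fixed seeds
for calibration; 15 + 6 seeds at 4,000 individuals for the
power/monotonicity checks; 3,000 individuals and 200 genes for the
Z-vs-percentile agreement check), with interval widths computed at the
actual sample sizes. The power study plants one causal gene with 50 expected
carriers, penetrance 0.8 and carrier diagnosis-omission 1.0 (zero
carrier-case overlap — the regime where binary-status tests have no
signal at all), in a cohort of 4,000 with disease prevalence 0.008; the
prevalence is chosen so the diagnosed fraction stays below the 0.01
rare-code threshold while keeping the case group at the size (tens)
of real rare-disease analyses at desk scale.

## Design choices where the design was open

- **Self-pairs**: a carrier who is also a case contributes its self-pair
  to S_i by default (`exclude_self=False`), matching the plain definition
  of the mean over cases; the alternative is exposed because it
  materially lowers R_G for high-overlap genes.
- **Multiplicity**: Bonferroni by default for both the phenome scan and
  the gene scan; BH available. Adjusted p-values are reported alongside
  raw ones and significance is thresholded on the adjusted column.
- **"Effect size" in alternative schemes**: read as |beta|. Under this
  reading the effect schemes' weight vectors are anti-oriented with the
  p-value schemes (the sigmoid is decreasing in |beta|); weight-vector
  correlations are therefore reported signed, and scheme robustness is
  judged on gene-level rank concordance, which is high for all schemes.
- **Dialect**: ICD-10 codes are normalized to dotless uppercase; the
  frequency denominator is the full analysis cohort including
  zero-event individuals.
- **Kinship cutoff**: pairs at KING kinship >= 0.0442 (second degree or
  closer) are pruned, one random member kept per family.
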