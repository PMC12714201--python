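# peradigm

Phenotype-embedding similarity mapping of rare-disease candidate genes
from ICD-10 electronic health records and rare loss-of-function (LoF)
variant carriers.

## The problem

Rare diseases have few diagnosed patients even in biobank-scale cohorts,
so binary case/control gene tests (burden, SKAT, SKAT-O) are starved of
signal — especially for genes whose carriers are never formally
diagnosed. But carriers of a pathogenic variant usually *look* like
patients: their inpatient records accumulate the disease's secondary
manifestations even when the primary diagnosis code is absent. `peradigm`
exploits this by scoring each gene on how phenotypically similar its rare
LoF carriers are to the diagnosed patient group, in an embedding space
built from the text of ICD-10 code descriptions.

## The statistic

Stage 1 builds the representation:

- tokenize ICD-10 descriptions (no punctuation, no stopwords); one
  "sentence" per patient = the chronological concatenation of their codes'
  tokens; train CBOW word2vec; code embedding `e_k` = mean of its token
  vectors;
- phenome scan: per code, `logit P(c_ij) = α + β d_j + γ'z_j` (disease
  status `d`, age and sex `z`), giving a Wald p-value per code;
- code weight `w_k = σ(−ln p_k) · IC_k` with `IC_k = −ln r_k` (prevalence
  `r_k`), so `w_k ∈ [0.5·IC_k, IC_k)`;
- individual embedding over their rare (`r_k ≤ 0.01`) distinct codes:
  `D_i = Σ w_k e_k / Σ w_k`.

Stage 2 scans genes:

- `S_i = (1/m) Σ_k cosine(D_i, D_k)` over the `m` cases;
- gene risk score `R_G` = mean `S` over the gene's carriers;
- empirical null: 10,000 random same-size groups drawn from the whole
  cohort give `(μ₀, σ)`; `Z = (R_G − μ₀)/σ`, one-tailed normal p-value,
  Bonferroni (or BH) adjusted across genes.

Carrier sets come from variant QC (MAF ≤ 0.01, HWE exact p ≥ 1e-6, the
five LoF consequence classes, ≥5 carriers per gene), kinship pruning to
unrelated individuals, and a carrier-age (CHIP) filter.

## Worked example

Everything is runnable without any external data via the built-in
synthetic cohort generator, which plants a causal gene whose 50-odd
carriers are *never diagnosed* (zero overlap with the case group):

```python
from dataclasses import replace
from peradigm import synthetic_data as sd
from peradigm.pipeline import PipelineConfig, run_end_to_end
from peradigm.code_embedding import CbowParams

cfg = sd.SimulationConfig(
    n_individuals=4_000, n_codes=600, n_null_genes=60,
    n_causal_genes=1, causal_carrier_rate=50 / 4_000,
    carrier_omission_rate=1.0, penetrance=0.8,
    disease_prevalence=0.008, seed=1,
)
cohort = sd.generate_cohort(cfg)
pc = PipelineConfig(n_reps=4_000, cbow=CbowParams(d=50, epochs=10, window=10)).with_seed(1)
result = run_end_to_end(cohort, pc)
print(result.scan.head(3)[
    ["gene", "carrier_number", "overlap_with_disease", "riskscore", "p_raw", "p_adjusted"]
].to_string(index=False))
```

prints

```
    gene  carrier_number  overlap_with_disease  riskscore        p_raw   p_adjusted
CAUSAL00              39                     0   0.585204 1.218387e-09 4.142515e-08
   G0002              12                     0   0.449446 6.367539e-02 1.000000e+00
   G0025              10                     0   0.330064 1.415743e-01 1.000000e+00
```

The planted gene tops the scan at adjusted p ≈ 4e-8 although *none* of
its 39 carriers is diagnosed — `riskscore` 0.59 says the carriers'
phenotype embeddings lean well toward the patient centroid, far above the
sampling-null mean — while the 60 null genes stay flat. The same machinery is
exposed as a CLI (`peradigm simulate | embed-codes | weights |
embed-individuals | carriers | scan | intra-sim | calibrate | schemes`),
each command writing a JSON manifest with its seeds and parameters.

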