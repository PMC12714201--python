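"""Seeded synthetic EHR + genotype cohort with planted ground truth.

The generator mirrors the analysis model in reverse: each ICD-10-like
code is assigned to individuals through an independent logistic model with
a latent disease status and age/sex effects; disease-associated codes get
positive log-odds so affected individuals accumulate disease-related
codes. Carriers of a planted causal gene become phenotypically affected
with a configurable penetrance, while a diagnosis-omission mechanism can
withhold the case-defining code from affected individuals — modelling the
undiagnosed-carrier scenario the similarity statistic is designed to
detect. Code descriptions are drawn from a synthetic word pool in which
disease-related codes share a configurable fraction of words, giving the
word-level embedding genuine signal to exploit.

Disease relatedness is graded rather than binary: a small core of
strongly associated codes is surrounded by a continuum of weakly
associated ones (as real phenome scans show — hundreds of partially
associated phenotypes), and description word sharing scales with
relatedness. This grading also keeps the similarity-score distribution
smooth, as in real cohorts where phenotype profiles vary continuously.

Defaults describe a desk-scale biobank: 20,000 individuals, 1,000 codes
with a log-uniform prevalence spectrum on [3e-3, 0.03] (straddling the
0.01 rare-code threshold so both filter branches are exercised, and
giving each individual a realistic burden of several rare codes),
disease prevalence 0.005, 200 null genes with per-gene carrier rates
log-uniform on [2.5e-4, 5e-3], one causal gene with penetrance 0.8 and
~50 carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .ehr_io import PatientHistory
from .genotype_carriers import CarrierTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GeneratedCohort",
    "generate_cohort",
    "null_config",
    "power_curve",
    "write_cohort_files",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 20_000
    n_codes: int = 1_000
    freq_range: tuple[float, float] = (3e-3, 0.03)  # log-uniform baseline prevalence
    vocab_size: int = 2_000
    words_per_description: int = 4
    disease_word_fraction: float = 0.7  # shared-word fraction for disease codes
    disease_prevalence: float = 0.005
    n_disease_codes: int = 30
    disease_beta_range: tuple[float, float] = (2.0, 4.0)
    age_effect_sd: float = 0.01  # per-year log-odds on each code
    sex_effect_sd: float = 0.25
    frailty_sd: float = 0.5  # per-individual log-odds shift on all codes
    n_null_genes: int = 200
    n_causal_genes: int = 1
    carrier_rate_range: tuple[float, float] = (5e-4, 5e-3)
    causal_carrier_rate: float = 2.5e-3
    penetrance: float = 0.8
    diagnosis_omission_rate: float = 0.1
    carrier_omission_rate: float | None = None  # None -> diagnosis_omission_rate
    repeat_rate: float = 0.3  # Poisson mean of extra longitudinal repeats
    kinship_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for p in (
            self.disease_prevalence,
            self.penetrance,
            self.diagnosis_omission_rate,
            self.kinship_rate,
            self.disease_word_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} out of [0, 1]")
        if self.n_codes < self.n_disease_codes + 1:
            raise ValueError("need n_codes > n_disease_codes")
        if (
            self.n_causal_genes > 0
            and self.causal_carrier_rate * self.n_individuals < 5
        ):
            raise ValueError(
                "infeasible config: expected causal carriers "
                f"{self.causal_carrier_rate * self.n_individuals:.1f} < 5"
            )


@dataclass
class GroundTruth:
    causal_genes: list[str]
    case_code: str
    disease_codes: list[str]
    code_effects: pd.DataFrame  # code, baseline_freq, beta_disease, gamma_age, gamma_sex
    affected: pd.Series  # latent disease liability (bool per individual)
    diagnosed: pd.Series


@dataclass
class GeneratedCohort:
    config: SimulationConfig
    histories: dict[str, PatientHistory]
    dictionary: dict[str, str]
    covariates: pd.DataFrame
    carrier_table: CarrierTable
    kinship_pairs: list[tuple[str, str]]
    ground_truth: GroundTruth


def _code_name(i: int) -> str:
    return f"C{i:04d}"


def _make_descriptions(
    rng: np.random.Generator, cfg: SimulationConfig, relatedness: np.ndarray
) -> dict[str, str]:
    """Word-pool descriptions with graded vocabulary sharing.

    Each code draws ``words_per_description`` words from a common pool; a
    code with disease-relatedness u_k additionally replaces each word with
    probability ``disease_word_fraction * u_k`` by a word from a small
    shared disease vocabulary. Strongly related codes therefore share
    description words (the signal the embedding exploits) while weakly
    related ones shade continuously into the background — mirroring how
    real ICD-10 chapters share clinical terms to varying degrees.
    """
    pool = np.array([f"word{j:04d}" for j in range(cfg.vocab_size)])
    n_dis_words = max(cfg.words_per_description * 2, 8)
    disease_pool = np.array([f"dword{j:02d}" for j in range(n_dis_words)])
    out: dict[str, str] = {}
    for i in range(cfg.n_codes):
        code = _code_name(i)
        k = cfg.words_per_description
        k_dis = int(
            rng.binomial(k, min(1.0, cfg.disease_word_fraction * relatedness[i]))
        )
        words = list(
            rng.choice(disease_pool, size=min(k_dis, len(disease_pool)), replace=False)
        ) + list(rng.choice(pool, size=k - k_dis, replace=False))
        out[code] = " ".join(words)
    return out


def generate_cohort(config: SimulationConfig | None = None) -> GeneratedCohort:
    """Generate the full synthetic cohort; byte-reproducible given the seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    ids = np.array([f"I{i:06d}" for i in range(n)])

    age = rng.uniform(40, 70, size=n)
    sex = rng.integers(0, 2, size=n)
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=ids)
    covariates.index.name = "eid"

    # --- genes and carriers -------------------------------------------------
    genes = [f"G{i:04d}" for i in range(cfg.n_null_genes)] + [
        f"CAUSAL{i:02d}" for i in range(cfg.n_causal_genes)
    ]
    lo, hi = cfg.carrier_rate_range
    rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_null_genes))
    rates = np.concatenate([rates, np.full(cfg.n_causal_genes, cfg.causal_carrier_rate)])
    carriers: dict[str, set[str]] = {}
    carrier_mask = np.zeros(n, dtype=bool)  # union over causal genes
    for g, rate in zip(genes, rates):
        mask = rng.random(n) < rate
        carriers[g] = set(ids[mask])
        if g.startswith("CAUSAL"):
            carrier_mask |= mask
    carrier_table = CarrierTable(carriers)

    # --- latent disease and diagnosis --------------------------------------
    eta = logit(cfg.disease_prevalence) + 0.02 * (age - 55) + 0.2 * sex
    affected = rng.random(n) < expit(eta)
    affected = affected | (carrier_mask & (rng.random(n) < cfg.penetrance))
    omit = np.where(
        carrier_mask,
        cfg.carrier_omission_rate
        if cfg.carrier_omission_rate is not None
        else cfg.diagnosis_omission_rate,
        cfg.diagnosis_omission_rate,
    )
    diagnosed = affected & (rng.random(n) >= omit)

    # --- codes ---------------------------------------------------------------
    # Disease relatedness u_k is graded: the n_disease_codes "core" codes
    # are strongly related (u in [0.5, 1]); every other code draws a small
    # Beta-distributed relatedness, giving the long continuum of partially
    # associated phenotypes that real phenome scans show. Both the
    # disease log-odds and the description word sharing scale with u_k.
    case_code = _code_name(0)
    disease_codes = [_code_name(i) for i in range(1, cfg.n_disease_codes + 1)]
    f_lo, f_hi = cfg.freq_range
    base_freq = np.exp(
        rng.uniform(np.log(f_lo), np.log(f_hi), size=cfg.n_codes)
    )
    base_freq[0] = np.nan  # case code is purely diagnosis-driven
    beta_max = cfg.disease_beta_range[1]
    relatedness = np.empty(cfg.n_codes)
    relatedness[0] = 1.0
    relatedness[1 : cfg.n_disease_codes + 1] = rng.uniform(
        cfg.disease_beta_range[0] / beta_max, 1.0, size=cfg.n_disease_codes
    )
    relatedness[cfg.n_disease_codes + 1 :] = rng.beta(
        0.25, 2.5, size=cfg.n_codes - cfg.n_disease_codes - 1
    )
    beta = relatedness * beta_max
    beta[0] = 0.0
    gamma_age = rng.normal(0, cfg.age_effect_sd, size=cfg.n_codes)
    gamma_sex = rng.normal(0, cfg.sex_effect_sd, size=cfg.n_codes)

    age_c = age - age.mean()
    # per-individual hospitalization frailty: overall code-burden heterogeneity
    frailty = rng.normal(0, cfg.frailty_sd, size=n)
    pos_i: list[np.ndarray] = [np.flatnonzero(diagnosed)]
    pos_code: list[int] = [0] * int(diagnosed.sum())
    for k in range(1, cfg.n_codes):
        eta_k = (
            logit(base_freq[k])
            + beta[k] * affected
            + gamma_age[k] * age_c
            + gamma_sex[k] * sex
            + frailty
        )
        hit = np.flatnonzero(rng.random(n) < expit(eta_k))
        pos_i.append(hit)
        pos_code.extend([k] * hit.size)
    ii = np.concatenate(pos_i)
    kk = np.asarray(pos_code, dtype=np.int64)

    # longitudinal repeats and dates
    extra = rng.poisson(cfg.repeat_rate, size=ii.size)
    rep_i = np.repeat(ii, extra + 1)
    rep_k = np.repeat(kk, extra + 1)
    day0 = date(2000, 1, 1)
    offsets = rng.integers(0, 7305, size=rep_i.size)  # 20 years of records

    events: dict[int, list[tuple[date, str]]] = {}
    for i, k, off in zip(rep_i, rep_k, offsets):
        events.setdefault(int(i), []).append(
            (day0 + timedelta(days=int(off)), _code_name(int(k)))
        )
    histories: dict[str, PatientHistory] = {}
    for i, eid in enumerate(ids):
        h = PatientHistory(eid, events.get(i, []))
        h.sort()
        histories[eid] = h

    dictionary = _make_descriptions(rng, cfg, relatedness)

    # --- kinship pair injection ---------------------------------------------
    n_pairs = int(round(cfg.kinship_rate * n / 2))
    kin: list[tuple[str, str]] = []
    if n_pairs:
        chosen = rng.choice(n, size=2 * n_pairs, replace=False)
        kin = [
            (str(ids[a]), str(ids[b]))
            for a, b in zip(chosen[:n_pairs], chosen[n_pairs:])
        ]

    gt = GroundTruth(
        causal_genes=[g for g in genes if g.startswith("CAUSAL")],
        case_code=case_code,
        disease_codes=disease_codes,
        code_effects=pd.DataFrame(
            {
                "code": [_code_name(i) for i in range(cfg.n_codes)],
                "baseline_freq": base_freq,
                "relatedness": relatedness,
                "beta_disease": beta,
                "gamma_age": gamma_age,
                "gamma_sex": gamma_sex,
            }
        ),
        affected=pd.Series(affected, index=ids),
        diagnosed=pd.Series(diagnosed, index=ids),
    )
    logger.info(
        "generated cohort: %d individuals, %d diagnosed, %d genes",
        n,
        int(diagnosed.sum()),
        len(genes),
    )
    return GeneratedCohort(
        cfg, histories, dictionary, covariates, carrier_table, kin, gt
    )


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Copy with no planted causal genes; disease-code effects preserved so
    embeddings stay non-degenerate while every gene is null."""
    return replace(config, n_causal_genes=0)


def power_curve(
    config_grid: Sequence[SimulationConfig],
    n_seeds: int = 10,
    alpha: float = 0.05,
    pipeline_config=None,
) -> pd.DataFrame:
    """Detection rate of the planted causal gene over a config grid.

    Detection = adjusted p < alpha in an end-to-end scan. Seeds 0..n_seeds-1
    are combined with each config's own seed offset.
    """
    from .pipeline import PipelineConfig, run_end_to_end

    pc = pipeline_config or PipelineConfig()
    rows = []
    for cfg in config_grid:
        hits = 0
        for s in range(n_seeds):
            cohort = generate_cohort(replace(cfg, seed=cfg.seed + 1000 * s + 1))
            result = run_end_to_end(cohort, replace(pc, seed=pc.seed + s))
            scan = result.scan
            causal = cohort.ground_truth.causal_genes
            sig = set(scan.loc[scan["p_adjusted"] < alpha, "gene"])
            if causal and set(causal) <= sig:
                hits += 1
        rows.append(
            dict(
                penetrance=cfg.penetrance,
                carrier_rate=cfg.causal_carrier_rate,
                carrier_omission=cfg.carrier_omission_rate,
                n_seeds=n_seeds,
                detection_rate=hits / n_seeds,
            )
        )
    return pd.DataFrame(rows)


def write_cohort_files(cohort: GeneratedCohort, outdir) -> dict[str, str]:
    """Write the generated cohort in the exact formats the readers consume."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ehr = outdir / "ehr.tsv"
    with open(ehr, "w") as fh:
        fh.write("eid\tdate\ticd10\n")
        for eid in sorted(cohort.histories):
            for d, c in cohort.histories[eid].events:
                fh.write(f"{eid}\t{d.isoformat()}\t{c}\n")
    paths["ehr"] = str(ehr)
    dic = outdir / "dictionary.tsv"
    with open(dic, "w") as fh:
        fh.write("code\tdescription\n")
        for c in sorted(cohort.dictionary):
            fh.write(f"{c}\t{cohort.dictionary[c]}\n")
    paths["dictionary"] = str(dic)
    cov = outdir / "covariates.tsv"
    cohort.covariates.to_csv(cov, sep="\t")
    paths["covariates"] = str(cov)
    carr = outdir / "carriers.tsv"
    from .genotype_carriers import write_carrier_tsv

    write_carrier_tsv(cohort.carrier_table, carr)
    paths["carriers"] = str(carr)
    kin = outdir / "kinship.tsv"
    with open(kin, "w") as fh:
        fh.write("id1\tid2\tkinship\n")
        for a, b in cohort.kinship_pairs:
            fh.write(f"{a}\t{b}\t0.25\n")
    paths["kinship"] = str(kin)
    gt = outdir / "ground_truth.tsv"
    cohort.ground_truth.code_effects.to_csv(gt, sep="\t", index=False)
    paths["ground_truth"] = str(gt)
    return paths
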