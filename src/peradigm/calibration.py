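"""Null calibration of the gene-level similarity test.

Synthetic "gene carrier groups" matched to a realistic carrier-count
distribution are drawn at random from the usable cohort, scored with the
same risk-score machinery as real genes, and tested against the same
cached sampling null. Calibration is summarized by empirical type-I error
rates with Clopper-Pearson intervals, a Kolmogorov-Smirnov test against
Uniform(0,1), and genomic inflation factors lambda (median chi-square
method) and lambda_q90 (0.9-quantile analogue).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, kstest, norm, spearmanr
from statsmodels.stats.proportion import proportion_confint

from . import risk_mapping as rm
from .pipeline import PipelineConfig, run_end_to_end, run_stage1
from .synthetic_data import GeneratedCohort, SimulationConfig, generate_cohort, null_config

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationReport",
    "simulate_null_genes",
    "empirical_rate",
    "ks_uniform",
    "inflation_factor",
    "summarize_null_pvalues",
    "run_null_calibration",
    "rerun_with_schemes",
]


@dataclass
class CalibrationReport:
    p_values: np.ndarray
    lambda_: float
    lambda_q90: float
    ks_p: float
    rates: dict[float, tuple[float, float, float]]  # alpha -> (rate, lo, hi)
    n_sim_genes: int
    seed: int
    qq: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "lambda": self.lambda_,
            "lambda_q90": self.lambda_q90,
            "ks_p": self.ks_p,
            "rates": {
                str(a): {"rate": r, "ci_low": lo, "ci_high": hi}
                for a, (r, lo, hi) in self.rates.items()
            },
            "n_sim_genes": self.n_sim_genes,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def simulate_null_genes(
    carrier_counts: Sequence[int],
    pool_scores: np.ndarray,
    n_sim: int = 2_000,
    n_reps: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Null p-values for n_sim pseudo carrier groups.

    Each pseudo-gene draws its carrier count from ``carrier_counts`` (with
    replacement), samples that many members at random from the usable
    pool, averages their similarity scores, and is tested against the
    cached sampling null for its count — the same machinery as real genes.
    """
    counts = np.asarray(carrier_counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("carrier-count distribution is empty")
    pool = np.asarray(pool_scores, dtype=np.float64)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x51AB,)))
    drawn = rng.choice(counts, size=n_sim, replace=True)
    cache = rm.NullCache(pool, n_reps=n_reps, seed=seed)
    pvals = np.empty(n_sim)
    for n in np.unique(drawn):
        where = np.flatnonzero(drawn == n)
        gene_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(0x9E3779B9, int(n)))
        )
        scores = rm.sample_mean_scores(pool, int(n), where.size, gene_rng)
        summ = cache.get(int(n))
        pvals[where] = norm.sf((scores - summ.mu0) / summ.sigma)
    return np.clip(pvals, rm.P_FLOOR, 1.0)


def empirical_rate(
    p_values: np.ndarray, alpha: float
) -> tuple[float, tuple[float, float]]:
    """Fraction of p-values below alpha with a 95% Clopper-Pearson CI."""
    p = np.asarray(p_values)
    if p.size == 0:
        raise ValueError("empty p-value list")
    k = int((p < alpha).sum())
    lo, hi = proportion_confint(k, p.size, alpha=0.05, method="beta")
    return k / p.size, (float(lo), float(hi))


def ks_uniform(p_values: np.ndarray) -> float:
    """One-sample KS p-value against Uniform(0,1)."""
    p = np.asarray(p_values)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    return float(kstest(p, "uniform").pvalue)


def inflation_factor(
    p_values: np.ndarray, quantile: float = 0.5, floor: float = rm.P_FLOOR
) -> float:
    """Genomic inflation: quantile of chi2(1)-transformed statistics over
    the same quantile of the chi2(1) reference (0.5 -> lambda, 0.9 ->
    lambda_q90). Floored p-values are clipped before the transform."""
    p = np.clip(np.asarray(p_values, dtype=float), floor, 1.0)
    stats = chi2.isf(p, df=1)
    return float(np.quantile(stats, quantile) / chi2.ppf(quantile, df=1))


def summarize_null_pvalues(
    p_values: np.ndarray, alphas: Sequence[float] = (0.05, 0.01), seed: int = 0
) -> CalibrationReport:
    p = np.asarray(p_values)
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(np.sort(p))}
    )
    return CalibrationReport(
        p_values=p,
        lambda_=inflation_factor(p, 0.5),
        lambda_q90=inflation_factor(p, 0.9),
        ks_p=ks_uniform(p),
        rates={a: (lambda t: (t[0], *t[1]))(empirical_rate(p, a)) for a in alphas},
        n_sim_genes=n,
        seed=seed,
        qq=qq,
    )


def run_null_calibration(
    sim_config: SimulationConfig,
    pipeline_config: PipelineConfig | None = None,
    n_sim: int = 2_000,
    alphas: Sequence[float] = (0.05, 0.01),
) -> CalibrationReport:
    """End-to-end calibration on a synthetic null cohort.

    Generates the cohort with no planted genes, builds stage-1 embeddings,
    takes the generated genes' usable carrier counts as the carrier-count
    distribution, and simulates ``n_sim`` pseudo genes.
    """
    pc = pipeline_config or PipelineConfig()
    cohort = generate_cohort(null_config(sim_config))
    stage1 = run_stage1(
        cohort.histories,
        cohort.dictionary,
        cohort.covariates,
        [cohort.ground_truth.case_code],
        pc,
    )
    scores = rm.similarity_scores(
        stage1.embeddings, stage1.cohort.case_ids, pc.exclude_self
    )
    counts = [
        len({i for i in s if i in stage1.embeddings})
        for s in cohort.carrier_table.carriers.values()
    ]
    counts = [c for c in counts if c >= pc.min_carriers]
    pvals = simulate_null_genes(
        counts, scores.to_numpy(), n_sim=n_sim, n_reps=pc.n_reps, seed=pc.seed
    )
    return summarize_null_pvalues(pvals, alphas, seed=pc.seed)


def rerun_with_schemes(
    cohort: GeneratedCohort,
    schemes: Sequence[str],
    pipeline_config: PipelineConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, set]]:
    """Full gene scan per weighting scheme, plus cross-scheme concordance.

    Returns (scheme -> scan frame, Spearman rank-concordance matrix of
    -log10 raw p across common genes, scheme -> significant gene set).
    """
    from dataclasses import replace

    pc = pipeline_config or PipelineConfig()
    results: dict[str, pd.DataFrame] = {}
    emb = phen_scan = None
    for scheme in schemes:
        res = run_end_to_end(
            cohort, replace(pc, scheme=scheme), code_embeddings=emb, scan=phen_scan
        )
        # the trained embedding and phenome scan are scheme-independent
        emb = res.stage1.code_embeddings
        phen_scan = res.stage1.scan
        results[scheme] = res.scan
    common = set.intersection(*(set(df["gene"]) for df in results.values()))
    order = sorted(common)
    logp = {
        s: -np.log10(df.set_index("gene").loc[order, "p_raw"].to_numpy())
        for s, df in results.items()
    }
    conc = pd.DataFrame(np.eye(len(schemes)), index=schemes, columns=schemes)
    for i, a in enumerate(schemes):
        for j in range(i + 1, len(schemes)):
            b = schemes[j]
            rho = spearmanr(logp[a], logp[b]).statistic
            conc.loc[a, b] = conc.loc[b, a] = float(rho)
    sig = {
        s: set(df.loc[df["p_adjusted"] < 0.05, "gene"]) for s, df in results.items()
    }
    return results, conc, sig
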