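"""The gene-level similarity statistic and its empirical sampling null.

For each individual i with a usable embedding, the similarity score

    S_i = (1/m) * sum_k cosine(D_i, D_k)

averages cosine similarity to the m diagnosed cases; a gene's risk score
R_G is the mean S over its LoF carriers. Because the mean of cosines to a
fixed case set equals the dot product of the individual's unit vector with
the mean case unit vector, the whole cohort's S is a single matrix-vector
product.

Significance: the null distribution of R for a carrier count n is built by
repeatedly drawing n individuals at random from the whole usable cohort
(cases included, without regard to carrier status; default 10,000
replicates, sampling without replacement), summarized as (mu0, sigma);
Z = (R - mu0)/sigma is referred to the upper tail of the standard normal.
Null summaries are cached per distinct carrier count and reused across
genes — exactly equivalent to per-gene resampling given the shared pool.
Reported p-values are floored at 1e-25 (printed as "<1.0e-25").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .ehr_io import Cohort
from .genotype_carriers import CarrierTable
from .individual_embedding import EmbeddingSet

logger = logging.getLogger(__name__)

P_FLOOR = 1e-25
P_FLOOR_LABEL = "<1.0e-25"

__all__ = [
    "P_FLOOR",
    "NullSummary",
    "NullCache",
    "cosine",
    "similarity_scores",
    "individual_score",
    "gene_risk_score",
    "sample_mean_scores",
    "null_distribution",
    "risk_pvalue",
    "empirical_pvalue",
    "adjust_pvalues",
    "scan_genes",
]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for the zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def similarity_scores(
    embeddings: EmbeddingSet, case_ids: Iterable[str], exclude_self: bool = False
) -> pd.Series:
    """S_i for every usable individual: mean cosine to the case group.

    With ``exclude_self``, a case's own self-pair is omitted from its mean
    (divide by m-1).
    """
    case_idx = embeddings.subset_indices(case_ids)
    m = len(case_idx)
    if m < 1:
        raise ValueError("no usable case embeddings")
    cbar = embeddings.unit[case_idx].mean(axis=0)
    s = embeddings.unit @ cbar
    if exclude_self:
        if m == 1:
            only = embeddings.ids[case_idx[0]]
            raise ValueError(
                f"exclude_self leaves no comparison case for {only} (m=1)"
            )
        s = s.copy()
        s[case_idx] = (m * s[case_idx] - 1.0) / (m - 1)
    return pd.Series(s, index=embeddings.ids, name="S")


def individual_score(
    vector: np.ndarray,
    case_matrix: np.ndarray,
    exclude_self_row: int | None = None,
) -> float:
    """S for one embedding against an (m, d) case matrix (reference path)."""
    sims = [cosine(vector, row) for row in case_matrix]
    if exclude_self_row is not None:
        del sims[exclude_self_row]
        if not sims:
            raise ValueError("exclude_self leaves zero cases")
    return float(np.mean(sims))


def gene_risk_score(carrier_ids: Iterable[str], scores: pd.Series) -> float:
    """R_G = mean similarity score over the gene's usable carriers."""
    usable = [i for i in carrier_ids if i in scores.index]
    if not usable:
        raise ValueError("no carrier with a usable embedding")
    return float(scores.loc[usable].mean())


@dataclass
class NullSummary:
    n: int
    mu0: float
    sigma: float
    n_reps: int
    seed: int
    scores: np.ndarray | None = None  # raw replicate risk scores, optional

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        if self.sigma == 0:
            logger.warning("degenerate null: sigma=0 at n=%d", self.n)


def sample_mean_scores(
    values: np.ndarray, n: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_reps`` independent without-replacement samples of size n.

    Delegates to a numba kernel that is O(n) per replicate; the kernel
    seed is drawn from ``rng`` so the caller's generator governs
    reproducibility.
    """
    from ._kernels import _sample_means

    values = np.ascontiguousarray(values, dtype=np.float64)
    pool = values.shape[0]
    if n > pool:
        raise ValueError(f"sample size {n} exceeds pool size {pool}")
    if n == pool:
        return np.full(n_reps, values.mean())
    seed = int(rng.integers(0, 2**31 - 1))
    return _sample_means(values, int(n), int(n_reps), seed)


def null_distribution(
    n: int,
    pool_scores: np.ndarray,
    n_reps: int = 10_000,
    seed: int = 0,
    keep_scores: bool = False,
) -> NullSummary:
    """Empirical null of the risk score for carrier count n.

    Each replicate draws n individuals without replacement from the full
    usable pool and averages their similarity scores.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(n,)))
    reps = sample_mean_scores(np.asarray(pool_scores), n, n_reps, rng)
    return NullSummary(
        n=n,
        mu0=float(reps.mean()),
        sigma=float(reps.std(ddof=1)),
        n_reps=n_reps,
        seed=seed,
        scores=reps if keep_scores else None,
    )


class NullCache:
    """Null summaries keyed by carrier count; one pass per distinct n."""

    def __init__(
        self,
        pool_scores: np.ndarray,
        n_reps: int = 10_000,
        seed: int = 0,
        keep_scores: bool = False,
    ):
        self.pool_scores = np.asarray(pool_scores, dtype=np.float64)
        self.n_reps = n_reps
        self.seed = seed
        self.keep_scores = keep_scores
        self._cache: dict[int, NullSummary] = {}

    def get(self, n: int) -> NullSummary:
        if n not in self._cache:
            self._cache[n] = null_distribution(
                n, self.pool_scores, self.n_reps, self.seed, self.keep_scores
            )
        return self._cache[n]


def risk_pvalue(
    r: float, null_summary: NullSummary, floor: float = P_FLOOR
) -> tuple[float, float, bool]:
    """(z, one-tailed p, floored?) for an observed risk score."""
    if null_summary.sigma <= 0:
        raise ValueError("sigma=0: null distribution is degenerate")
    z = (r - null_summary.mu0) / null_summary.sigma
    p = float(norm.sf(z))
    if p < floor:
        return float(z), floor, True
    return float(z), max(p, np.finfo(float).tiny), False


def empirical_pvalue(r: float, null_scores: np.ndarray) -> float:
    """Percentile p from raw replicates: (1 + #{null >= r}) / (1 + reps)."""
    null_scores = np.asarray(null_scores)
    return float((1 + (null_scores >= r).sum()) / (1 + null_scores.size))


def adjust_pvalues(p_raw: Iterable[float], method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (min(1, p*m)) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(list(p_raw), dtype=float)
    if method not in ("bonferroni", "bh"):
        raise ValueError("method must be 'bonferroni' or 'bh'")
    return multipletests(p, method={"bonferroni": "bonferroni", "bh": "fdr_bh"}[method])[1]


def scan_genes(
    carrier_table: CarrierTable,
    embeddings: EmbeddingSet,
    cohort: Cohort,
    n_reps: int = 10_000,
    seed: int = 0,
    exclude_self: bool = False,
    adjustment: str = "bonferroni",
    keep_null_scores: bool = False,
    null_cache: NullCache | None = None,
) -> pd.DataFrame:
    """Genome-wide scan: one risk-score test per retained gene.

    Returns a frame with ``gene, carrier_number, n_usable,
    overlap_with_disease, riskscore, z, p_raw, p_emp (if kept),
    p_adjusted, p_floored``; deterministic given the seed. Genes whose
    carriers all lack usable embeddings are skipped with a log line.
    """
    scores = similarity_scores(embeddings, cohort.case_ids, exclude_self)
    vals = scores.to_numpy()
    cache = null_cache or NullCache(vals, n_reps, seed, keep_null_scores)
    rows = []
    for gene in carrier_table.genes():
        carriers = carrier_table[gene]
        usable = [i for i in carriers if i in embeddings]
        if not usable:
            logger.warning("gene %s skipped: no carrier with usable embedding", gene)
            continue
        r = float(scores.loc[usable].mean())
        summ = cache.get(len(usable))
        try:
            z, p, floored = risk_pvalue(r, summ)
        except ValueError as exc:
            logger.warning("gene %s skipped: %s", gene, exc)
            continue
        row = dict(
            gene=gene,
            carrier_number=len(carriers),
            n_usable=len(usable),
            overlap_with_disease=len(set(carriers) & cohort.case_ids),
            riskscore=r,
            mu0=summ.mu0,
            sigma=summ.sigma,
            z=z,
            p_raw=p,
            p_floored=floored,
        )
        if summ.scores is not None:
            row["p_emp"] = empirical_pvalue(r, summ.scores)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = adjust_pvalues(df["p_raw"], adjustment)
        df["adjustment"] = adjustment
        df = df.sort_values("p_raw", kind="stable").reset_index(drop=True)
    return df
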