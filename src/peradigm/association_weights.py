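"""Phenome scan and per-code weights for the individual embedding.

Each ICD-10 code is regressed on disease (or carrier) status with age and
sex as covariates, logit(c_ij) = alpha + beta*d_j + gamma*z_j, giving a
two-sided Wald p-value for beta. The code weight combines that
significance with the code's information content IC_k = -ln(r_k):

    w_k = sigmoid(-ln p_k) * IC_k        (primary scheme)

The sigmoid maps p in (0, 1] onto [0.5, 1), so w_k lies in
[0.5*IC_k, IC_k). Four alternative schemes (effect_ic, pvalue_only,
ic_only, effect_only) are provided for robustness analyses; "effect size"
there is |beta|, the absolute log-odds ratio.

Natural logarithms throughout.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .ehr_io import CodeFrequencyTable, PatientHistory

logger = logging.getLogger(__name__)

SCHEMES = ("pvalue_ic", "effect_ic", "pvalue_only", "ic_only", "effect_only")

__all__ = [
    "SCHEMES",
    "scan_phenotypes",
    "firth_logit",
    "information_content",
    "compute_weight",
    "build_weight_table",
    "compare_schemes",
]


def firth_logit(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-penalized (Firth-type) logistic regression.

    Returns (beta, standard errors). Finite under complete separation,
    which standard maximum likelihood is not; used as the fallback for
    rare codes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = expit(eta)
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], cov, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        # step-halving to keep the update stable
        for _ in range(10):
            if np.all(np.abs(step) < 1e3):
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = expit(eta)
    w = p * (1 - p)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se


def _fit_one(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, str, bool]:
    """Fit one code's logistic model; Firth fallback when ML misbehaves.

    Returns (beta, intercept, p_value, method, converged).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            se = res.bse[1]
            if res.mle_retvals.get("converged", False) and np.isfinite(se) and se < 50:
                return (
                    float(res.params[1]),
                    float(res.params[0]),
                    float(res.pvalues[1]),
                    "ml",
                    True,
                )
        except Exception:
            pass
    beta, se = firth_logit(X, y)
    if se[1] <= 0 or not np.isfinite(se[1]):
        return float(beta[1]), float(beta[0]), 1.0, "firth", False
    z = beta[1] / se[1]
    p = float(2 * norm.sf(abs(z)))
    return float(beta[1]), float(beta[0]), max(p, np.finfo(float).tiny), "firth", True


def scan_phenotypes(
    histories: Mapping[str, PatientHistory],
    outcome_ids: Iterable[str],
    covariates: pd.DataFrame,
    codes: Iterable[str] | None = None,
    min_carriers_exclude: int = 1,
) -> pd.DataFrame:
    """Logistic phenome scan of every code against a binary outcome.

    ``outcome_ids`` are the individuals with the outcome (disease status
    for weighting; carrier status for the carrier-phenotype scans). Codes
    present in <= ``min_carriers_exclude`` individuals are flagged
    ``excluded`` and not fitted. Returns one row per code with columns
    ``code, n_with_code, beta, intercept, p_value, method, converged,
    excluded``.
    """
    ids = [eid for eid in sorted(histories) if eid in covariates.index]
    if len(ids) < len(histories):
        logger.warning(
            "%d individuals lack covariates and are omitted from the scan",
            len(histories) - len(ids),
        )
    outcome = set(outcome_ids)
    d = np.array([1.0 if eid in outcome else 0.0 for eid in ids])
    cov = covariates.loc[ids]
    X = np.column_stack(
        [
            np.ones(len(ids)),
            d,
            np.asarray(cov["age"], dtype=float),
            np.asarray(cov["sex"], dtype=float),
        ]
    )
    idx = {eid: i for i, eid in enumerate(ids)}
    members: dict[str, list[int]] = {}
    for eid in ids:
        for c in histories[eid].distinct_codes():
            members.setdefault(c, []).append(idx[eid])
    wanted = sorted(members) if codes is None else sorted(set(codes))
    rows = []
    for code in wanted:
        pos = members.get(code, [])
        n = len(pos)
        if n == 0:
            logger.info("code %s absent in everyone with covariates; skipped", code)
            continue
        if n <= min_carriers_exclude or n >= len(ids):
            rows.append(
                dict(
                    code=code,
                    n_with_code=n,
                    beta=np.nan,
                    intercept=np.nan,
                    p_value=np.nan,
                    method="none",
                    converged=False,
                    excluded=True,
                )
            )
            continue
        y = np.zeros(len(ids))
        y[pos] = 1.0
        beta, inter, p, method, conv = _fit_one(X, y)
        rows.append(
            dict(
                code=code,
                n_with_code=n,
                beta=beta,
                intercept=inter,
                p_value=min(max(p, np.finfo(float).tiny), 1.0),
                method=method,
                converged=conv,
                excluded=False,
            )
        )
    return pd.DataFrame(rows)


def information_content(r_k):
    """IC_k = -ln(r_k); higher for rarer phenotypes. Requires 0 < r_k <= 1."""
    r = np.asarray(r_k, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("frequencies must lie in (0, 1]")
    out = -np.log(r)
    return float(out) if np.isscalar(r_k) else out


def compute_weight(p_value, beta, ic, scheme: str = "pvalue_ic"):
    """Per-code weight under one of the five schemes (vectorized).

    primary ``pvalue_ic``: sigmoid(-ln p) * IC; ``effect_ic``:
    sigmoid(-ln|beta|) * IC; ``pvalue_only`` / ``effect_only``: the bare
    sigmoid factors; ``ic_only``: IC.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    p = np.asarray(p_value, dtype=float)
    b = np.asarray(beta, dtype=float)
    icv = np.asarray(ic, dtype=float)
    scalar = np.isscalar(p_value) or p.ndim == 0

    def sig_neglog(x):
        with np.errstate(divide="ignore"):
            return expit(-np.log(x))

    if scheme in ("pvalue_ic", "pvalue_only"):
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        factor = sig_neglog(p)
    elif scheme in ("effect_ic", "effect_only"):
        factor = sig_neglog(np.abs(b))  # |beta|=0 -> factor 1 (limit)
    else:  # ic_only
        factor = np.ones_like(icv)
    if scheme in ("pvalue_ic", "effect_ic", "ic_only"):
        if np.any(icv < 0):
            raise ValueError("IC must be non-negative")
        w = factor * icv
    else:
        w = factor * np.ones_like(icv)
    return float(w) if scalar else w


def build_weight_table(
    scan: pd.DataFrame,
    frequencies: CodeFrequencyTable,
    scheme: str = "pvalue_ic",
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Assemble the per-code weight table from a phenome scan.

    Codes flagged ``excluded`` (or non-converged) receive the neutral
    p = 1, beta = 0, so they keep the baseline weight 0.5*IC under the
    primary scheme rather than dropping out of embeddings entirely.
    Multiplicity adjustment (Bonferroni default, BH optional) is over the
    fitted codes only.
    """
    df = scan.copy()
    df["r_k"] = [frequencies.get(c, np.nan) for c in df["code"]]
    df = df.dropna(subset=["r_k"])
    df["ic"] = information_content(df["r_k"].to_numpy())
    fitted = (~df["excluded"]) & df["converged"] & df["p_value"].notna()
    p_eff = np.where(fitted, df["p_value"].fillna(1.0), 1.0)
    b_eff = np.where(fitted, df["beta"].fillna(0.0), 0.0)
    df["p_adjusted"] = np.nan
    if fitted.any():
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[adjust]
        df.loc[fitted, "p_adjusted"] = multipletests(
            df.loc[fitted, "p_value"].to_numpy(), method=method
        )[1]
    df["weight"] = compute_weight(p_eff, b_eff, df["ic"].to_numpy(), scheme)
    df["scheme"] = scheme
    cols = [
        "code",
        "n_with_code",
        "r_k",
        "ic",
        "beta",
        "p_value",
        "p_adjusted",
        "weight",
        "scheme",
    ]
    return df[cols].reset_index(drop=True)


def compare_schemes(weight_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlation between per-code weight vectors.

    All tables must cover the identical code set. A zero-variance weight
    vector yields NaN correlations (undefined), except on the diagonal.
    """
    names = list(weight_tables)
    if len(names) < 2:
        raise ValueError("need at least two schemes to compare")
    base = weight_tables[names[0]]["code"]
    mat = {}
    for name in names:
        tab = weight_tables[name].set_index("code")["weight"]
        if set(tab.index) != set(base):
            raise ValueError(f"scheme {name!r} covers a different code set")
        mat[name] = tab.loc[base].to_numpy()
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            va, vb = mat[a], mat[b]
            if va.std() == 0 or vb.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out
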