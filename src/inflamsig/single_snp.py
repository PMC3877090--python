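"""Single-SNP adjusted logistic regression (the comparator analysis).

Each SNP is tested in an unconditional logistic regression of case status on
its additive genotype code, adjusted for the environmental covariates.  The
per-allele coefficient gives the trend test (1 df Wald) and the rare- vs
common-homozygote odds ratio OR_aa/AA = exp(2 beta_snp); Bonferroni
correction multiplies p by the number of SNPs tested.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import CovariateTable, GenotypeMatrix, MISSING


@dataclasses.dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    converged: bool
    separated: bool
    n_iter: int


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence is declared at score (gradient) norm < tol; quasi-complete
    separation is flagged when fitted log-odds run away (|eta| > 30).
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        H = (X * np.maximum(w, 1e-12)[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # damped step to keep eta finite under near-separation
        if np.abs(step).max() > 10:
            step *= 10 / np.abs(step).max()
        beta = beta + step
    eta = X @ beta
    # fitted log-odds beyond +-15 put fitted probabilities within ~3e-7 of 0/1:
    # quasi-complete separation territory for case-control data
    separated = bool(np.abs(eta).max() > 15)
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return LogisticFit(beta, se, converged, separated, it)


def fit_snp_logistic(geno: np.ndarray, C: CovariateTable | None,
                     wald: bool = True) -> dict:
    """One SNP's adjusted logistic fit.

    Returns a dict with or_aa_aa = exp(2 beta_snp), p_trend (Wald by default,
    likelihood-ratio with ``wald=False``), the per-allele coefficient, and
    convergence/separation flags.  Non-convergent fits carry NaN estimates.
    """
    geno = np.asarray(geno, float)
    if (geno == MISSING).any() or np.isnan(geno).any():
        raise ValueError("genotype column must be imputed")
    if C is None:
        raise ValueError("a covariate table (at least labels) is required")
    from .io import prune_collinear
    W, _ = C.design_matrix(standardize_age=False)
    W = W[:, prune_collinear(W)]
    y = C.labels.astype(float)
    X = np.column_stack([W, geno])
    fit = _irls_logistic(X, y)
    if not fit.converged:
        return {"or_aa_aa": np.nan, "p_trend": np.nan, "beta": np.nan,
                "se": np.nan, "converged": False, "separated": fit.separated}
    b, se = fit.coef[-1], fit.se[-1]
    if wald:
        z = b / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        fit0 = _irls_logistic(X[:, :-1], y)
        ll = _loglik(X, y, fit.coef)
        ll0 = _loglik(X[:, :-1], y, fit0.coef)
        p = float(stats.chi2.sf(2.0 * (ll - ll0), df=1))
    return {"or_aa_aa": float(np.exp(2.0 * b)), "p_trend": float(p),
            "beta": float(b), "se": float(se),
            "converged": True, "separated": fit.separated}


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -700, 700)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_scan(G: GenotypeMatrix, C: CovariateTable) -> pd.DataFrame:
    """Per-SNP adjusted logistic table with Bonferroni-corrected p-values."""
    rows = []
    for j in range(G.p):
        res = fit_snp_logistic(G.codes[:, j].astype(float), C)
        rows.append({"rs": G.snps["rs"].iloc[j], **res})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = bonferroni(df["p_trend"].to_numpy(), m=G.p)
    return df


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = np.asarray(p, float)
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Probability-ordering definition: sums hypergeometric probabilities of all
    tables with the same margins no more probable than the observed one.  An
    empty margin returns p = 1 with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        import warnings
        warnings.warn("empty margin: Fisher p reported as 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table)[1])
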