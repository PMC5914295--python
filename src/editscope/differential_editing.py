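"""Per-site binomial logistic regression of editing on genotype, analysis of
deviance, and Benjamini-Hochberg FDR control across sites.

The model for each site is a binomial GLM on (edited, coverage - edited)
counts with an intercept and a two-level genotype factor, fitted by
iteratively reweighted least squares. Significance is the chi-squared
likelihood-ratio (analysis-of-deviance) test of the genotype term against
the intercept-only model; q-values are BH step-up adjusted p-values with a
5% FDR flag by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from editscope.editing_caller import CandidateSite
from editscope.io_formats import SampleDesign

__all__ = [
    "SiteGlmFit",
    "DifferentialResult",
    "fit_binomial_glm",
    "lrt_pvalue",
    "bh_fdr",
    "differential_editing_table",
    "write_differential_tsv",
]

MAX_ABS_COEF = 30.0  # separation cap on the log-odds scale
MAX_ITER = 50
TOL = 1e-8


@dataclass
class SiteGlmFit:
    site_id: str
    beta0: float
    beta1: float
    deviance_full: float
    deviance_null: float
    converged: bool
    separated: bool = False

    @property
    def lrt_statistic(self) -> float:
        return self.deviance_null - self.deviance_full


@dataclass
class DifferentialResult:
    site_id: str
    beta1: float
    lrt_stat: float
    pvalue: float
    qvalue: float = math.nan
    significant: bool = False


def _binomial_deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    """2 * sum of saturated-vs-fitted log-likelihood differences."""
    k = y
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / (n * mu)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / (n * (1 - mu))), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _irls(X: np.ndarray, k: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, bool, bool]:
    """IRLS for a binomial GLM with logit link on count data.

    Returns (beta, converged, separated); coefficients are capped at
    ``MAX_ABS_COEF`` so complete separation yields a finite deterministic fit.
    """
    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    for _ in range(MAX_ITER):
        eta = np.clip(X @ beta, -MAX_ABS_COEF, MAX_ABS_COEF)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (k - n * mu) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        beta_new = np.clip(beta_new, -MAX_ABS_COEF, MAX_ABS_COEF)
        if np.max(np.abs(beta_new - beta)) < TOL:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    separated = bool(np.any(np.abs(beta) >= MAX_ABS_COEF - 1e-6))
    return beta, converged, separated


def fit_binomial_glm(
    edited: Sequence[int],
    coverage: Sequence[int],
    genotype: Sequence[str],
    site_id: str = "",
) -> SiteGlmFit:
    """Fit editing ~ genotype as a binomial logistic regression.

    ``genotype`` must have exactly two levels with >= 2 samples each; the
    reference level is the lexicographically first label, so ``beta1`` is
    the log-odds difference of the second level relative to the first.
    """
    k = np.asarray(edited, dtype=float)
    n = np.asarray(coverage, dtype=float)
    if np.any(n <= 0):
        raise ValueError("coverage must be positive for all samples")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("edited counts must lie in [0, coverage]")
    levels = sorted(set(genotype))
    if len(levels) != 2:
        raise ValueError(f"exactly 2 genotype levels required, got {levels}")
    g = np.array([levels.index(x) for x in genotype], dtype=float)
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per genotype")

    X_full = np.column_stack([np.ones_like(g), g])
    beta, converged, separated = _irls(X_full, k, n)
    mu_full = 1.0 / (1.0 + np.exp(-np.clip(X_full @ beta, -MAX_ABS_COEF, MAX_ABS_COEF)))
    dev_full = _binomial_deviance(k, n, mu_full)

    X_null = np.ones((len(g), 1))
    beta_null, _, _ = _irls(X_null, k, n)
    mu_null = 1.0 / (1.0 + np.exp(-np.clip(X_null @ beta_null, -MAX_ABS_COEF, MAX_ABS_COEF)))
    dev_null = _binomial_deviance(k, n, mu_null)

    return SiteGlmFit(
        site_id=site_id,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        deviance_full=dev_full,
        deviance_null=dev_null,
        converged=converged,
        separated=separated,
    )


def lrt_pvalue(fit: SiteGlmFit) -> float:
    """Upper chi-squared (1 df) tail at the analysis-of-deviance statistic."""
    diff = fit.deviance_null - fit.deviance_full
    if diff < -1e-6:
        raise ValueError(
            f"site {fit.site_id!r}: null deviance below full deviance ({diff})"
        )
    return float(stats.chi2.sf(max(diff, 0.0), df=1))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q(i) = min over j >= i of m * p(j) / j on the sorted p-values, capped at
    1 and mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def differential_editing_table(
    candidates: Sequence[CandidateSite],
    design: Sequence[SampleDesign],
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """One analysis-of-deviance row per filtered site, BH-adjusted.

    Rows are sorted by (q, p). Masked or filter-failing candidates must be
    excluded upstream; sites are used as given here.
    """
    levels = sorted({d.genotype for d in design})
    if len(levels) != 2:
        raise ValueError(f"design must have exactly 2 genotype levels, got {levels}")
    for level in levels:
        if sum(d.genotype == level for d in design) < 2:
            raise ValueError(f"genotype {level!r} has fewer than 2 samples")
    if not candidates:
        return []

    geno_of = {d.sample_id: d.genotype for d in design}
    results: list[DifferentialResult] = []
    for site in candidates:
        sample_ids = [d.sample_id for d in design if d.sample_id in site.coverage]
        site_id = f"{site.chrom}:{site.position + 1}"
        fit = fit_binomial_glm(
            [site.edited[s] for s in sample_ids],
            [site.coverage[s] for s in sample_ids],
            [geno_of[s] for s in sample_ids],
            site_id=site_id,
        )
        results.append(
            DifferentialResult(
                site_id=site_id,
                beta1=fit.beta1,
                lrt_stat=fit.lrt_statistic,
                pvalue=lrt_pvalue(fit),
            )
        )
    qvals = bh_fdr([r.pvalue for r in results])
    for r, q in zip(results, qvals):
        r.qvalue = float(q)
        r.significant = bool(q <= alpha)
    results.sort(key=lambda r: (r.qvalue, r.pvalue, r.site_id))
    return results


def write_differential_tsv(
    results: Sequence[DifferentialResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("site\tbeta1\tlrt_stat\tpvalue\tqvalue\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.site_id}\t{r.beta1:.6g}\t{r.lrt_stat:.6g}\t"
                f"{r.pvalue:.6g}\t{r.qvalue:.6g}\t{int(r.significant)}\n"
            )
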