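"""Genome-wide FDR across phenotype-level adjusted P-values.

Implements the Storey-Tibshirani procedure: estimate pi0, the proportion
of phenotypes for which the null holds, from the flat right tail of the
P-value histogram, then compute q-values as pi0-scaled step-up FDR. With
pi0 = 1 the q-values reduce exactly to Benjamini-Hochberg; learning
pi0 < 1 from the data yields strictly more discoveries at the same level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = ["FdrResult", "estimate_pi0", "qvalue_transform", "call_significant", "fdr_analysis"]


@dataclass
class FdrResult:
    pi0: float
    qvalues: np.ndarray
    significant: np.ndarray
    threshold_p: float  # largest adjusted P called significant; NaN if none


def estimate_pi0(
    pvalues,
    lambda_grid=None,
    method: str = "smoother",
) -> float:
    """Estimate the null proportion pi0.

    For each lambda on the grid, pi0(lambda) = #{p > lambda} / (m (1 - lambda));
    these raw estimates are biased down for small lambda and noisy for
    large lambda. The "smoother" method fits a least-squares cubic
    smoothing spline to pi0(lambda) and evaluates it at the largest
    lambda (the qvalue-package convention); "fixed" returns the raw
    estimate at lambda = 0.5, which is more stable for small m. The
    result is clamped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m < 100:
        warnings.warn(f"pi0 estimated from only {m} P-values; expect instability")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lam = np.sort(np.asarray(lambda_grid, dtype=float))
    if method == "fixed":
        lam0 = lam[np.argmin(np.abs(lam - 0.5))]
        pi0 = np.mean(p > lam0) / (1.0 - lam0)
        return float(np.clip(pi0, 1.0 / m if m else 1e-8, 1.0))
    if lam.size < 4:
        raise ValueError("lambda grid degenerate: need >= 4 distinct values for the smoother")
    if np.any(lam <= 0) or np.any(lam >= 1) or np.any(np.diff(lam) <= 0):
        raise ValueError("lambda grid must be strictly increasing within (0, 1)")
    pi0_raw = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    spline = UnivariateSpline(lam, pi0_raw, k=3)
    pi0 = float(spline(lam[-1]))
    return float(np.clip(pi0, 1.0 / m if m else 1e-8, 1.0))


def qvalue_transform(pvalues, pi0: float = 1.0) -> np.ndarray:
    """q-values: q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted
    P-values, mapped back to input order. pi0 = 1 is exactly BH."""
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_significant(
    qvalues, fdr: float, pvalues=None
) -> tuple[np.ndarray, float]:
    """Boolean mask of calls at the target FDR plus the largest adjusted
    P-value among called phenotypes (NaN when nothing is called). The
    threshold is computed from ``pvalues`` when given, else from the
    q-values themselves."""
    q = np.asarray(qvalues, dtype=float)
    mask = q <= fdr
    if not mask.any():
        return mask, float("nan")
    basis = np.asarray(pvalues, dtype=float) if pvalues is not None else q
    return mask, float(basis[mask].max())


def fdr_analysis(pvalues, fdr: float = 0.05, lambda_grid=None, method: str = "smoother") -> FdrResult:
    """Full ST pipeline: pi0, q-values, significance calls, threshold."""
    pi0 = estimate_pi0(pvalues, lambda_grid=lambda_grid, method=method)
    q = qvalue_transform(pvalues, pi0)
    mask, thr = call_significant(q, fdr, pvalues=pvalues)
    return FdrResult(pi0=pi0, qvalues=q, significant=mask, threshold_p=thr)
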