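"""Permutation-based multiple-testing correction across cis variants.

Three schemes convert a phenotype's best nominal P-value into an adjusted
P-value accounting for the L correlated variants scanned in its window:

* direct  — R phenotype permutations; empirical p_d = (r + 1) / (R + 1),
  where r counts null best P-values at or below the nominal one.
* adaptive — permute until B exceedances are found or M permutations are
  spent; p_a = (min(r, B) + 1) / (min(R, M) + 1).
* beta — model the permutation-null minimum P-value as Beta(k, n): the
  minimum of n independent uniforms is Beta(1, n), and with LD the
  effective number of independent tests n drops below L, so (k, n) are
  fitted by maximum likelihood to R null minima and the adjusted P-value
  is the fitted CDF at the nominal P, I_{p_n}(k, n). This extrapolates
  the null tail far below the 1/(R+1) floor of resampling.

Permutations shuffle the phenotype and leave the genotype matrix intact,
preserving the LD structure among variants. Each phenotype gets its own
counter-based RNG substream keyed on (seed, hash(phenotype_id)), so
chunked runs and whole runs produce identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import betainc, betaln, psi

from .core import (
    correlation_to_pvalue,
    covariate_rank,
    nominal_pass,
    quantile_normalize,
    residualize,
    standardize_rows,
)
from .io_formats import CovariateMatrix, DosageMatrix, PhenotypeSet

__all__ = [
    "PermutationNull",
    "BetaFit",
    "PhenotypeResult",
    "phenotype_rng",
    "permute_and_scan",
    "direct_adjusted_p",
    "adaptive_adjusted_p",
    "fit_beta_mle",
    "beta_loglik",
    "beta_adjusted_p",
    "full_permutation_pass",
]

_CLAMP_LO = 1e-300
_CLAMP_HI = 1.0 - 1e-16


@dataclass
class PermutationNull:
    """Null distribution sample for one phenotype: best P-value per
    permutation, plus the exceedance count against the nominal P."""

    null_pvalues: np.ndarray
    r_exceed: int
    R: int


@dataclass
class BetaFit:
    """Maximum-likelihood Beta(k, n) fit to null minimum P-values.

    k is interpretable as the rank of the best variant (about 1), n as
    the effective number of independent tests (below L under LD).
    """

    k_hat: float
    n_hat: float
    loglik: float
    converged: bool


@dataclass
class PhenotypeResult:
    """Per-phenotype output record."""

    phenotype_id: str
    n_tested: int
    k_hat: float = np.nan
    n_hat: float = np.nan
    best_variant_id: str | None = None
    distance: int | None = None
    nominal_p: float = np.nan
    slope: float = np.nan
    perm_p: float = np.nan  # direct or adaptive empirical adjusted P
    beta_p: float = np.nan


def phenotype_rng(seed: int, phenotype_id: str) -> np.random.Generator:
    """Reproducible per-phenotype RNG substream, independent of the order
    in which phenotypes are processed or of chunk boundaries."""
    digest = hashlib.sha256(phenotype_id.encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *words]))


def _null_batch(
    ys: np.ndarray, Gs: np.ndarray, df: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Best P-value across variants for ``size`` phenotype permutations,
    computed as one matrix product against the standardized genotypes."""
    Y = np.tile(ys, (size, 1))
    Y = rng.permuted(Y, axis=1)
    r_best = np.max(np.abs(Gs @ Y.T), axis=0)
    return np.asarray(correlation_to_pvalue(r_best, df))


def permute_and_scan(
    phenotype,
    g_window,
    R: int,
    seed_or_rng,
    df: int | None = None,
    nominal_p: float | None = None,
    batch: int = 512,
) -> PermutationNull:
    """Sample the null distribution of the best cis P-value.

    ``phenotype`` must already be normalized/residualized exactly as in
    the nominal pass; ``g_window`` is the window's dosage (or already
    standardized) matrix. Ties between a null P and the nominal P count
    as exceedances (conservative).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    y = np.asarray(phenotype, dtype=float)
    G = g_window.dosages if isinstance(g_window, DosageMatrix) else np.asarray(g_window, float)
    Gs = standardize_rows(G)
    ys = standardize_rows(y[None, :])[0]
    if df is None:
        df = y.size - 2
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = np.empty(R)
    done = 0
    while done < R:
        b = min(batch, R - done)
        out[done : done + b] = _null_batch(ys, Gs, df, b, rng)
        done += b
    r_exceed = int(np.sum(out <= nominal_p)) if nominal_p is not None else 0
    return PermutationNull(null_pvalues=out, r_exceed=r_exceed, R=R)


def direct_adjusted_p(r_exceed: int, R: int) -> float:
    """Empirical adjusted P-value (r + 1) / (R + 1); its floor is 1/(R+1)."""
    if R < 1:
        raise ValueError("R must be >= 1")
    if not 0 <= r_exceed <= R:
        raise ValueError("need 0 <= r_exceed <= R")
    return (r_exceed + 1) / (R + 1)


def adaptive_adjusted_p(
    phenotype,
    g_window,
    nominal_p: float,
    B: int = 100,
    M: int = 100000,
    batch: int = 100,
    seed_or_rng=0,
    df: int | None = None,
) -> tuple[float, PermutationNull]:
    """Early-stopping permutation scheme.

    Permutes in batches until B null best P-values at or below the
    nominal one are seen, or M permutations are spent; returns
    (min(r, B) + 1) / (min(R, M) + 1). Cheap for weak associations,
    bounded at 1/(M+1) for strong ones.
    """
    if not 1 <= B <= M:
        raise ValueError("need 1 <= B <= M")
    y = np.asarray(phenotype, dtype=float)
    G = g_window.dosages if isinstance(g_window, DosageMatrix) else np.asarray(g_window, float)
    Gs = standardize_rows(G)
    ys = standardize_rows(y[None, :])[0]
    if df is None:
        df = y.size - 2
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    nulls: list[np.ndarray] = []
    r_exceed = 0
    R = 0
    while r_exceed < B and R < M:
        b = min(batch, M - R)
        p_null = _null_batch(ys, Gs, df, b, rng)
        hits = np.cumsum(p_null <= nominal_p)
        if hits[-1] >= B - r_exceed:
            # the B-th exceedance falls inside this batch: truncate at that
            # permutation so counts match exact one-at-a-time stopping
            stop = int(np.searchsorted(hits, B - r_exceed)) + 1
            p_null = p_null[:stop]
            nulls.append(p_null)
            r_exceed = B
            R += stop
            break
        nulls.append(p_null)
        r_exceed += int(hits[-1])
        R += b
    p_adj = (min(r_exceed, B) + 1) / (min(R, M) + 1)
    return p_adj, PermutationNull(
        null_pvalues=np.concatenate(nulls), r_exceed=r_exceed, R=R
    )


def beta_loglik(k: float, n: float, pvalues: np.ndarray) -> float:
    """Log-likelihood of Beta(k, n) for a sample of null P-values:
    (k-1) sum ln p + (n-1) sum ln(1-p) - R ln B(k, n)."""
    p = np.clip(np.asarray(pvalues, float), _CLAMP_LO, _CLAMP_HI)
    R = p.size
    return float(
        (k - 1.0) * np.sum(np.log(p))
        + (n - 1.0) * np.sum(np.log1p(-p))
        - R * betaln(k, n)
    )


def _mom_start(p: np.ndarray) -> tuple[float, float]:
    m, v = p.mean(), p.var()
    if v <= 0 or not 0 < m < 1:
        return 1.0, max(1.0 / max(p.mean(), 1e-12), 2.0)
    c = m * (1.0 - m) / v - 1.0
    if c <= 0:
        return 1.0, max(1.0 / m, 2.0)
    return max(m * c, 1e-3), max((1.0 - m) * c, 1e-3)


def fit_beta_mle(null_pvalues) -> BetaFit:
    """Maximum-likelihood Beta(k, n) fit by quasi-Newton optimization on
    (log k, log n), started from method-of-moments estimates.

    Values are clamped to [1e-300, 1 - 1e-16] before taking logs. Up to
    three deterministically jittered restarts; failure after restarts
    raises with the last iterate attached.
    """
    p = np.asarray(null_pvalues, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 null P-values for a stable fit")
    p = np.clip(p, _CLAMP_LO, _CLAMP_HI)
    S1 = np.sum(np.log(p))
    S2 = np.sum(np.log1p(-p))
    R = p.size

    def neg_ll_and_grad(theta):
        k, n = np.exp(theta)
        ll = (k - 1) * S1 + (n - 1) * S2 - R * betaln(k, n)
        dk = S1 - R * (psi(k) - psi(k + n))
        dn = S2 - R * (psi(n) - psi(k + n))
        # chain rule through the log-parameterization
        return -ll, -np.array([dk * k, dn * n])

    k0, n0 = _mom_start(p)
    start_ll = -neg_ll_and_grad(np.log([k0, n0]))[0]
    last = None
    for jitter in (1.0, 1.5, 0.5):
        x0 = np.log([k0 * jitter, n0 * jitter])
        res = optimize.minimize(
            neg_ll_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"ftol": 1e-8, "gtol": 1e-10, "maxiter": 500},
        )
        last = res
        if res.success and -res.fun >= start_ll - 1e-6:
            k_hat, n_hat = np.exp(res.x)
            return BetaFit(
                k_hat=float(k_hat),
                n_hat=float(n_hat),
                loglik=float(-res.fun),
                converged=True,
            )
    raise RuntimeError(
        f"beta MLE failed to converge after restarts; last iterate "
        f"(k, n) = {tuple(np.exp(last.x))}, message: {last.message}"
    )


def beta_adjusted_p(nominal_p: float, fit: BetaFit) -> float:
    """Adjusted P-value from the fitted null: P(U <= p_n) with
    U ~ Beta(k_hat, n_hat), i.e. the regularized incomplete beta function
    I_{p_n}(k, n). Strictly increasing in the nominal P.

    For extremely small nominal P, where the direct CDF underflows, the
    leading-order term x^k * Gamma(k+n) / (k Gamma(k) Gamma(n)) is
    evaluated in log space, keeping results down to ~1e-200 nonzero.
    """
    if not fit.converged:
        raise ValueError("beta fit did not converge")
    x = float(nominal_p)
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    val = float(betainc(fit.k_hat, fit.n_hat, x))
    if val == 0.0:
        log_val = (
            fit.k_hat * np.log(x)
            - np.log(fit.k_hat)
            - betaln(fit.k_hat, fit.n_hat)
        )
        val = float(np.exp(log_val))
    return min(val, 1.0)


def full_permutation_pass(
    p: PhenotypeSet,
    g: DosageMatrix,
    window: int,
    scheme: str = "beta",
    R: int = 1000,
    B: int = 100,
    M: int = 100000,
    seed: int = 0,
    cov: CovariateMatrix | None = None,
    normalize: bool = False,
    batch: int = 100,
    legacy_df: bool = False,
) -> list[PhenotypeResult]:
    """Nominal pass plus the chosen permutation scheme for every phenotype.

    The beta scheme also reports the direct empirical P from the same R
    permutations, so the two corrections can be compared phenotype by
    phenotype, and records the fitted (k, n) shapes.
    """
    if scheme not in ("direct", "adaptive", "beta"):
        raise ValueError(f"unknown scheme {scheme!r}")
    scans = nominal_pass(p, g, window, cov=cov, normalize=normalize, legacy_df=legacy_df)
    g_resid = residualize(g.dosages, cov) if cov is not None else g.dosages

    results: list[PhenotypeResult] = []
    for i, scan in enumerate(scans):
        pid = p.phenotype_ids[i]
        if scan.n_tested == 0:
            results.append(PhenotypeResult(phenotype_id=pid, n_tested=0))
            continue
        anchor = int(p.anchors[i])
        sub = g.window(anchor, window)
        lo = np.searchsorted(g.positions, anchor - window, side="left")
        G = g_resid[lo : lo + sub.n_variants]
        G = G[G.std(axis=1) > 0]
        y = p.values[i]
        if normalize:
            y = quantile_normalize(y)
        if cov is not None:
            y = residualize(y[None, :], cov)[0]
        rng = phenotype_rng(seed, pid)
        rec = PhenotypeResult(
            phenotype_id=pid,
            n_tested=scan.n_tested,
            best_variant_id=sub.variant_ids[scan.best_index],
            distance=int(sub.positions[scan.best_index] - anchor),
            nominal_p=scan.nominal_p,
            slope=scan.slope,
        )
        if scheme == "adaptive":
            p_adj, _ = adaptive_adjusted_p(
                y, G, scan.nominal_p, B=B, M=M, batch=batch,
                seed_or_rng=rng, df=scan.df,
            )
            rec.perm_p = p_adj
        else:
            null = permute_and_scan(
                y, G, R, rng, df=scan.df, nominal_p=scan.nominal_p
            )
            rec.perm_p = direct_adjusted_p(null.r_exceed, null.R)
            if scheme == "beta":
                fit = fit_beta_mle(null.null_pvalues)
                rec.k_hat, rec.n_hat = fit.k_hat, fit.n_hat
                rec.beta_p = beta_adjusted_p(scan.nominal_p, fit)
        results.append(rec)
    return results
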