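"""Nominal cis-association pass.

For each phenotype, scan all variants in the cis-window for the largest
absolute Pearson correlation; assess it with the standard t test for a
correlation coefficient, which is equivalent to testing beta != 0 in the
one-variant linear model P = beta * g + eps fitted by least squares.

Optional preprocessing mirrors common eQTL practice: a rank-based
inverse-normal transform of the phenotype (robust to outliers) and
residualization of both genotypes and phenotypes on covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.special import ndtri

from .io_formats import CovariateMatrix, DosageMatrix, PhenotypeSet

__all__ = [
    "ScanResult",
    "quantile_normalize",
    "residualize",
    "covariate_rank",
    "standardize_rows",
    "correlation_scan",
    "correlation_to_pvalue",
    "nominal_pass",
]

# floor on 1 - r^2 before the t transform, guards |r| -> 1
_R2_GUARD = 1e-16
_P_MIN = np.nextafter(0.0, 1.0)


@dataclass
class ScanResult:
    """Best cis association for one phenotype."""

    best_index: int
    best_r: float
    nominal_p: float
    slope: float
    df: int
    n_tested: int

    @classmethod
    def empty(cls) -> "ScanResult":
        return cls(best_index=-1, best_r=np.nan, nominal_p=np.nan,
                   slope=np.nan, df=0, n_tested=0)


def quantile_normalize(values, tie_policy: str = "average", rng=None) -> np.ndarray:
    """Rank-based inverse normal transform, rescaled to mean 0 and sd 1.

    Ranks use the offset rank/(n+1); ties get the average rank by default
    or, with ``tie_policy="random"``, are broken by a seeded jitter
    (pass ``rng``). Raises on a constant vector, where ranks are undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D vector of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: quantile normalization undefined")
    if tie_policy == "average":
        ranks = stats.rankdata(x, method="average")
    elif tie_policy == "random":
        rng = np.random.default_rng(rng)
        jitter = rng.uniform(-0.5, 0.5, size=x.size) * 1e-9 * max(np.ptp(x), 1.0)
        ranks = stats.rankdata(x + jitter, method="ordinal").astype(float)
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    q = ndtri(ranks / (x.size + 1))
    q = q - q.mean()
    sd = q.std(ddof=1)
    return q / sd


def _design(cov: CovariateMatrix | np.ndarray | None, n: int) -> np.ndarray:
    """Intercept + covariate design, collinear columns dropped (warns)."""
    if cov is None:
        return np.ones((n, 1))
    vals = cov.values if isinstance(cov, CovariateMatrix) else np.asarray(cov, float)
    if vals.ndim == 1:
        vals = vals[None, :]
    if vals.shape[1] != n:
        raise ValueError(f"covariates have {vals.shape[1]} samples, expected {n}")
    X = np.column_stack([np.ones(n), vals.T])
    # rank-revealing QR: keep a maximal independent subset of columns
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - rank} collinear covariate column(s)",
            stacklevel=2,
        )
        keep = np.sort(piv[:rank])
        X = X[:, keep]
    return X


def covariate_rank(cov: CovariateMatrix | np.ndarray | None, n: int) -> int:
    """Number of independent covariate dimensions beyond the intercept."""
    return _design(cov, n).shape[1] - 1


def residualize(matrix, cov: CovariateMatrix | np.ndarray | None) -> np.ndarray:
    """Project each row of ``matrix`` (rows x N) onto the orthogonal
    complement of the covariates and the intercept.

    The same projection is applied to genotypes and phenotypes, so the
    correlation of residuals equals the partial correlation given the
    covariates. Idempotent; rank-deficient covariate sets lose their
    collinear columns with a warning.
    """
    M = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = M.shape[1]
    X = _design(cov, n)
    beta, *_ = np.linalg.lstsq(X, M.T, rcond=None)
    return M - (X @ beta).T


def standardize_rows(matrix: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit Euclidean norm, so that
    correlations with a standardized vector are plain dot products."""
    M = np.atleast_2d(np.asarray(matrix, dtype=float))
    M = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance row cannot be standardized")
    return M / norms


def correlation_scan(phenotype, g) -> tuple[np.ndarray, int]:
    """Pearson correlations of one phenotype against every variant.

    ``g`` may be a DosageMatrix, a raw L x N matrix, or a matrix already
    standardized by :func:`standardize_rows` (repeated permuted scans then
    reduce to matrix-vector products). Returns the vector of correlations
    and the index of the largest ``|r|``; exact ties go to the lowest
    variant index, i.e. the lowest genomic position.
    """
    y = np.asarray(phenotype, dtype=float)
    G = g.dosages if isinstance(g, DosageMatrix) else np.asarray(g, dtype=float)
    if G.shape[0] < 1:
        raise ValueError("need at least one variant")
    if G.shape[1] != y.size:
        raise ValueError("phenotype length does not match sample count")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance phenotype")
    ys = standardize_rows(y[None, :])[0]
    Gs = standardize_rows(G)
    r = Gs @ ys
    r = np.clip(r, -1.0, 1.0)
    best = int(np.argmax(np.abs(r)))
    return r, best


def correlation_to_pvalue(r, df) -> np.ndarray | float:
    """Two-sided P-value for a Pearson correlation via the t transform
    ``t = r * sqrt(df / (1 - r^2))``.

    Monotone decreasing in |r|; |r| = 1 maps to the smallest positive
    float rather than 0.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("|r| must be <= 1")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    denom = np.maximum(1.0 - r_arr**2, _R2_GUARD)
    t = np.abs(r_arr) * np.sqrt(df / denom)
    p = np.minimum(2.0 * stats.t.sf(t, df), 1.0)
    p = np.maximum(p, _P_MIN)
    return float(p) if np.isscalar(r) or np.asarray(r).ndim == 0 else p


def _slope(r: float, y: np.ndarray, g: np.ndarray) -> float:
    sy, sg = y.std(), g.std()
    return float(r * sy / sg) if sg > 0 else np.nan


def nominal_pass(
    p: PhenotypeSet,
    g_full: DosageMatrix,
    window: int,
    cov: CovariateMatrix | None = None,
    normalize: bool = False,
    legacy_df: bool = False,
) -> list[ScanResult]:
    """Best nominal association for each phenotype.

    Variants are restricted to ``anchor +/- window``; the phenotype is
    optionally inverse-normal transformed, then genotypes and phenotype
    are residualized on the covariates. Degrees of freedom default to
    N - 2 - C for C residualized covariate dimensions (``legacy_df=True``
    uses N - 2). Phenotypes with no variant in the window yield an empty
    record with ``n_tested = 0``.
    """
    if p.sample_ids != g_full.sample_ids:
        raise ValueError("inputs are not sample-aligned; call intersect_samples first")
    n = len(p.sample_ids)
    c_rank = covariate_rank(cov, n) if cov is not None else 0
    df = n - 2 if legacy_df or cov is None else n - 2 - c_rank
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom (N={n}, C={c_rank})")

    g_resid = residualize(g_full.dosages, cov) if cov is not None else g_full.dosages

    results: list[ScanResult] = []
    for i in range(p.n_phenotypes):
        sub = g_full.window(int(p.anchors[i]), window)
        if sub.n_variants == 0:
            results.append(ScanResult.empty())
            continue
        lo = np.searchsorted(g_full.positions, p.anchors[i] - window, side="left")
        G = g_resid[lo : lo + sub.n_variants]
        y = p.values[i]
        if normalize:
            y = quantile_normalize(y)
        if cov is not None:
            y = residualize(y[None, :], cov)[0]
        keep = G.std(axis=1) > 0
        if not keep.all():
            G = G[keep]
        if G.shape[0] == 0 or np.ptp(y) == 0:
            results.append(ScanResult.empty())
            continue
        r, best_local = correlation_scan(y, G)
        best = int(np.flatnonzero(keep)[best_local]) if not keep.all() else best_local
        r_best = float(r[best_local])
        results.append(
            ScanResult(
                best_index=best,
                best_r=r_best,
                nominal_p=float(correlation_to_pvalue(r_best, df)),
                slope=_slope(r_best, y, G[best_local]),
                df=df,
                n_tested=int(G.shape[0]),
            )
        )
    return results
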