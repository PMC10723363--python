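"""Gradient latent space: derivation, projection, and covariance-based FC.

Gradients are principal components of a normative pool of region-by-time BOLD
timeseries: the R x K eigenvector matrix gives each region's weight on each
gradient ("spatial maps"), and projecting a subject's centered timeseries onto
the eigenvectors gives the T x K gradient timeseries ("temporal scores").  A
subject's region-level functional connectivity is then recovered from the K x K
gradient covariance by the quadratic form ``cov_R = E Sigma E^T`` followed by
normalization to Pearson correlations; at full rank (K = R) this equals the
direct pairwise correlation of the region timeseries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GradientPCA",
    "fit_gradient_basis",
    "project_timeseries",
    "gradient_covariance",
    "fc_from_gradient_covariance",
    "fc_direct",
    "global_signal_amplitude",
    "variance_partition",
]


def _as_matrix(ts) -> np.ndarray:
    arr = ts.to_numpy() if isinstance(ts, pd.DataFrame) else np.asarray(ts)
    arr = arr.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"expected a (T, R) timeseries matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("timeseries contains missing or non-finite values")
    return arr


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-|weight| entry positive (reproducible sign)."""
    anchor = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[anchor, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


class GradientPCA(BaseEstimator, TransformerMixin):
    """Derive a gradient basis by PCA of temporally concatenated timeseries.

    Parameters
    ----------
    n_components : int
        Number of gradients K to retain (the analysis convention is 6, with 12
        as a secondary choice).
    display_scale : {"sqrt", "eigenvalue"}
        Scaling of the display loadings: eigenvectors scaled by the square root
        of the eigenvalue (default, the conventional loading) or by the raw
        eigenvalue.  Projection always uses the orthonormal eigenvectors.

    Attributes
    ----------
    eigenvectors_ : (R, K) orthonormal columns used for projection.
    display_loadings_ : (R, K) scaled maps for visualization only.
    explained_variance_fraction_ : (K,) nonincreasing, each in [0, 1].
    region_ids_ : column labels when the pool was given as DataFrames.
    """

    def __init__(self, n_components: int = 6, display_scale: str = "sqrt"):
        self.n_components = n_components
        self.display_scale = display_scale

    def fit(self, X, y=None) -> "GradientPCA":
        pool = X if isinstance(X, (list, tuple)) else [X]
        region_ids = None
        mats = []
        for ts in pool:
            if isinstance(ts, pd.DataFrame):
                if region_ids is None:
                    region_ids = list(ts.columns)
                elif list(ts.columns) != region_ids:
                    raise ValueError("pool timeseries have mismatched region sets")
            mats.append(_as_matrix(ts))
        R = mats[0].shape[1]
        if any(m.shape[1] != R for m in mats):
            raise ValueError("pool timeseries have mismatched region counts")
        concat = np.vstack(mats)
        if concat.shape[0] <= R:
            raise ValueError(
                f"pool has {concat.shape[0]} timepoints for {R} regions; "
                "need more timepoints than regions"
            )
        if self.n_components > R:
            raise ValueError(f"n_components={self.n_components} exceeds R={R}")
        pca = PCA(n_components=self.n_components).fit(concat)
        vecs = _fix_signs(pca.components_.T)
        self.eigenvectors_ = vecs
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_fraction_ = pca.explained_variance_ratio_
        scale = {
            "sqrt": np.sqrt(pca.explained_variance_),
            "eigenvalue": pca.explained_variance_,
        }[self.display_scale]
        self.display_loadings_ = vecs * scale
        self.region_ids_ = region_ids
        return self

    def transform(self, X) -> np.ndarray:
        """Project a (T, R) timeseries: ``scores = centered values @ eigenvectors``."""
        check_is_fitted(self, "eigenvectors_")
        if isinstance(X, pd.DataFrame) and self.region_ids_ is not None:
            if list(X.columns) != self.region_ids_:
                raise ValueError("timeseries regions do not match the fitted basis")
        arr = _as_matrix(X)
        if arr.shape[1] != self.eigenvectors_.shape[0]:
            raise ValueError(
                f"timeseries has {arr.shape[1]} regions, basis expects "
                f"{self.eigenvectors_.shape[0]}"
            )
        return (arr - arr.mean(axis=0)) @ self.eigenvectors_


def fit_gradient_basis(pool, n_components: int = 6, **kwargs) -> GradientPCA:
    """Fit the gradient latent space from a pool of region timeseries."""
    return GradientPCA(n_components=n_components, **kwargs).fit(pool)


def project_timeseries(ts, basis: GradientPCA) -> np.ndarray:
    """Gradient timeseries of one subject in a fitted basis."""
    return basis.transform(ts)


def gradient_covariance(scores: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Unbiased sample covariance of the gradient score columns (K x K)."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 timepoints for a covariance")
    cov = np.cov(scores, rowvar=False, ddof=ddof)
    return np.atleast_2d(cov)


def _basis_array(basis) -> np.ndarray:
    if isinstance(basis, GradientPCA):
        return basis.eigenvectors_
    return np.asarray(basis, dtype=float)


def fc_from_gradient_covariance(basis, sigma: np.ndarray) -> np.ndarray:
    """Region FC implied by a gradient covariance: ``E Sigma E^T`` normalized.

    Uses the first ``dim(sigma)`` basis columns.  Regions whose implied variance
    is ~0 are flagged with a warning and their correlations set to NaN rather
    than silently zeroed.
    """
    E = _basis_array(basis)
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    k = sigma.shape[0]
    if k > E.shape[1]:
        raise ValueError(f"covariance dimension {k} exceeds basis K={E.shape[1]}")
    cov_r = E[:, :k] @ sigma @ E[:, :k].T
    var = np.diag(cov_r).copy()
    bad = var <= 1e-300
    if np.any(bad):
        warnings.warn(
            f"{bad.sum()} region(s) with zero implied variance; "
            "their correlations are undefined (NaN)",
            RuntimeWarning,
        )
        var[bad] = np.nan
    d = np.sqrt(var)
    fc = cov_r / np.outer(d, d)
    np.fill_diagonal(fc, 1.0)
    ok = np.isfinite(fc)
    fc[ok] = np.clip(fc[ok], -1.0, 1.0)
    return fc


def fc_direct(ts) -> np.ndarray:
    """Pairwise Pearson correlation of region timeseries columns (R x R)."""
    arr = _as_matrix(ts)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 timepoints for correlations")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} region(s) with zero variance; "
            "their correlations are undefined (NaN)",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    ok = np.isfinite(fc)
    fc[ok] = np.clip(fc[ok], -1.0, 1.0)
    return fc


def global_signal_amplitude(ts) -> float:
    """Standard deviation of the across-region mean BOLD timeseries."""
    arr = _as_matrix(ts)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    return float(arr.mean(axis=1).std(ddof=1))


def variance_partition(
    f_scores: np.ndarray,
    moments: np.ndarray,
    n_orderings: int = 200,
    seed: int | None = 0,
    min_subjects: int = 25,
) -> dict:
    """Partition variance in subject scores over gradient moment columns.

    Fits the multiple regression of ``f_scores`` on all moment columns and
    attributes variance to each term by LMG-style hierarchical partitioning:
    the average, over random predictor orderings, of each term's sequential
    R-squared increment.  Shares are nonnegative and sum to the full-model
    R-squared.  Also reports per-term t statistics from the full model.
    Collinear moments trigger a condition warning and a small ridge is added
    to the normal equations (recorded in the output).
    """
    y = np.asarray(f_scores, dtype=float).ravel()
    X = np.asarray(moments, dtype=float)
    n, p = X.shape
    if n < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects, got {n}")
    if y.shape[0] != n:
        raise ValueError("f_scores and moments have mismatched subject counts")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    yty = float(yc @ yc)
    if yty == 0:
        raise ValueError("f_scores are constant")
    gram = Xc.T @ Xc
    xty = Xc.T @ yc
    cond = np.linalg.cond(gram)
    ridge = 0.0
    if cond > 1e10:
        ridge = 1e-8 * np.trace(gram) / p
        warnings.warn(
            f"collinear moments (cond={cond:.3g}); ridge {ridge:.3g} added",
            RuntimeWarning,
        )
        gram = gram + ridge * np.eye(p)

    def r2(cols: list[int]) -> float:
        if not cols:
            return 0.0
        sub = np.ix_(cols, cols)
        b = np.linalg.solve(gram[sub], xty[cols])
        return float(b @ xty[cols]) / yty

    rng = np.random.default_rng(seed)
    shares = np.zeros(p)
    for _ in range(n_orderings):
        order = rng.permutation(p)
        cols: list[int] = []
        prev = 0.0
        for j in order:
            cols.append(int(j))
            cur = r2(cols)
            shares[j] += cur - prev
            prev = cur
    shares /= n_orderings
    shares = np.clip(shares, 0.0, None)

    # full-model t statistics
    beta = np.linalg.solve(gram, xty)
    resid = yc - Xc @ beta
    dof = n - p - 1
    sigma2 = float(resid @ resid) / max(dof, 1)
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(gram)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = beta / se
    return {
        "shares": shares,
        "total_r2": r2(list(range(p))),
        "t_statistics": tstats,
        "coefficients": beta,
        "condition_number": float(cond),
        "ridge": ridge,
    }
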