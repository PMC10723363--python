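"""Structure-function component analysis.

Regional gray-matter atrophy is quantified by W-scores: per-region normative
regressions of gray matter on covariates fitted in a reference cohort, with a
subject's deviation ``(predicted - actual) / residual_sd`` oriented so positive
means more atrophy than expected (values above 1.5 are conventionally read as
significant atrophy).  Partial least squares regression then decomposes the
subjects-by-regions atrophy matrix into components that maximally covary with
the subjects-by-edges functional connectivity matrix, yielding paired
structure (atrophy) and function (FC-edge) loadings with per-subject scores on
each side.  Out-of-fold ridge regression of atrophy-PCA scores on FC edges
provides function scores untouched by the PLSR coupling, suitable for
downstream brain-behavior models.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .edges import edge_matrix, n_edges

__all__ = [
    "WScoreModel",
    "fit_wscore_model",
    "apply_wscores",
    "PLSStructureFunction",
    "fit_plsr_components",
    "split_half_reliability",
    "atrophy_pca_scores",
    "RidgeFunctionScorer",
    "ridge_function_scores",
    "reconstruct_fc_from_components",
    "network_summary_map",
    "mds_embed",
    "typical_patients_lda",
]


def _table(x) -> np.ndarray:
    return x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)


class WScoreModel(BaseEstimator, TransformerMixin):
    """Normative per-region regression model producing atrophy W-scores.

    Fit on a reference cohort's regional gray-matter table and covariates
    (age, sex, scanner, ... as numeric columns); transform maps new subjects'
    gray matter to W-scores ``(predicted - actual) / residual_sd`` under the
    atrophy-positive convention (set ``atrophy_positive=False`` for the raw
    ``(actual - predicted)`` orientation).
    """

    def __init__(self, atrophy_positive: bool = True):
        self.atrophy_positive = atrophy_positive

    def fit(self, X, y=None, covariates=None) -> "WScoreModel":
        gm = _table(X)
        if covariates is None:
            raise ValueError("reference covariates are required")
        names = (list(covariates.columns)
                 if isinstance(covariates, pd.DataFrame) else None)
        cov = _table(covariates)
        if cov.ndim == 1:
            cov = cov[:, None]
        n, p = cov.shape
        if names is None:
            names = [f"cov_{j}" for j in range(p)]
        if gm.shape[0] != n:
            raise ValueError("gray matter and covariates differ in subject count")
        if n <= p + 2:
            raise ValueError(f"need more than {p + 2} reference subjects, got {n}")
        design = np.column_stack([np.ones(n), cov])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(
                f"rank-deficient covariates (rank {rank} < {design.shape[1]}); "
                f"check columns {names}"
            )
        beta, _, _, _ = np.linalg.lstsq(design, gm, rcond=None)
        resid = gm - design @ beta
        sd = resid.std(axis=0, ddof=design.shape[1])
        zero = sd <= 1e-12
        if np.any(zero):
            raise ValueError(
                f"{int(zero.sum())} region(s) with zero residual sd "
                f"(indices {np.flatnonzero(zero)[:10].tolist()}); the reference "
                "fit is exact there — add jitter or drop those regions"
            )
        self.coef_ = beta                  # (p+1, R), row 0 = intercept
        self.residual_sd_ = sd
        self.covariate_names_ = names
        self.n_regions_ = gm.shape[1]
        return self

    def predict(self, covariates) -> np.ndarray:
        """Expected gray matter for given covariate rows."""
        check_is_fitted(self, "coef_")
        cov = _table(covariates)
        if cov.ndim == 1:
            cov = cov[None, :]
        if cov.shape[1] != len(self.covariate_names_):
            raise ValueError(
                f"expected covariates {self.covariate_names_}, got "
                f"{cov.shape[1]} columns"
            )
        if not np.all(np.isfinite(cov)):
            raise ValueError("missing covariate values")
        return np.column_stack([np.ones(cov.shape[0]), cov]) @ self.coef_

    def transform(self, X, covariates=None) -> np.ndarray:
        """W-scores for one subject (R-vector) or a table of subjects."""
        check_is_fitted(self, "coef_")
        gm = _table(X)
        one = gm.ndim == 1
        if one:
            gm = gm[None, :]
        pred = self.predict(covariates)
        w = (pred - gm) / self.residual_sd_
        if not self.atrophy_positive:
            w = -w
        return w[0] if one else w


def fit_wscore_model(reference_gm, covariates) -> WScoreModel:
    """Per-region normative regression with residual sd from the reference."""
    return WScoreModel().fit(reference_gm, covariates=covariates)


def apply_wscores(gm, covariates, model: WScoreModel) -> np.ndarray:
    """W-scores for a subject's regional gray matter under a fitted model."""
    return model.transform(gm, covariates=covariates)


class PLSStructureFunction(BaseEstimator):
    """Paired structure-function components by partial least squares.

    Decomposes atrophy (X, the grounding side) into components maximally
    covarying with FC edges (Y) using NIPALS PLS2 with deflation; columns are
    centered but not variance-scaled by default (W-scores and FC edges are
    already on comparable scales).

    Attributes
    ----------
    structure_loadings_ : (R, C)
    function_loadings_ : (E, C)
    structure_scores_, function_scores_ : (S, C)
    score_correlations_ : (C,) per-component correlation of the two scores.
    atrophy_variance_explained_ : (C,) fraction of centered atrophy variance.
    """

    def __init__(self, n_components: int = 5, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, Y=None) -> "PLSStructureFunction":
        atrophy = _table(X)
        fc = _table(Y)
        S, R = atrophy.shape
        if fc.shape[0] != S:
            raise ValueError("atrophy and FC tables differ in subject count")
        if S <= self.n_components:
            raise ValueError(f"need more than {self.n_components} subjects")
        if self.n_components > min(S - 1, R):
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank bound "
                f"{min(S - 1, R)}"
            )
        pls = PLSRegression(n_components=self.n_components, scale=self.scale)
        pls.fit(atrophy, fc)
        self.structure_loadings_ = pls.x_loadings_
        self.function_loadings_ = pls.y_loadings_
        self.structure_scores_ = pls.x_scores_
        self.function_scores_ = pls.y_scores_
        self.score_correlations_ = np.array([
            np.corrcoef(pls.x_scores_[:, c], pls.y_scores_[:, c])[0, 1]
            for c in range(self.n_components)
        ])
        Xc = atrophy - atrophy.mean(axis=0)
        total = np.sum(Xc**2)
        self.atrophy_variance_explained_ = np.array([
            np.sum(pls.x_scores_[:, c] ** 2) * np.sum(pls.x_loadings_[:, c] ** 2)
            / total
            for c in range(self.n_components)
        ])
        self._pls = pls
        return self

    def transform(self, X) -> np.ndarray:
        """Structure scores of new atrophy maps in the fitted component space."""
        check_is_fitted(self, "structure_loadings_")
        return self._pls.transform(_table(X))


def fit_plsr_components(atrophy, fc_edges, n_components: int = 5,
                        **kwargs) -> PLSStructureFunction:
    return PLSStructureFunction(n_components=n_components, **kwargs).fit(
        atrophy, fc_edges
    )


def _balanced_split(labels: np.ndarray, rng: np.random.Generator):
    """Random half-split balancing each label's count across halves."""
    first = np.zeros(len(labels), dtype=bool)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 members")
        idx = rng.permutation(idx)
        first[idx[: len(idx) // 2]] = True
    return first


def split_half_reliability(
    atrophy,
    fc_edges,
    labels,
    n_splits: int = 1000,
    seed: int = 0,
    n_components: int = 5,
) -> dict:
    """Split-half reliability of PLSR structure loadings.

    Each split divides subjects into label-balanced halves, fits an
    independent PLSR per half, and correlates structure loadings across halves
    after matching components by maximum absolute correlation (components may
    swap order or sign between halves; the assignment used is recorded).
    Returns per-split per-component absolute correlations.
    """
    atrophy = _table(atrophy)
    fc = _table(fc_edges)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    corrs = np.empty((n_splits, n_components))
    orders = np.empty((n_splits, n_components), dtype=int)
    for s in range(n_splits):
        half = _balanced_split(labels, rng)
        m1 = PLSStructureFunction(n_components).fit(atrophy[half], fc[half])
        m2 = PLSStructureFunction(n_components).fit(atrophy[~half], fc[~half])
        L1 = m1.structure_loadings_
        L2 = m2.structure_loadings_
        cc = np.abs(np.corrcoef(L1.T, L2.T)[:n_components, n_components:])
        row, col = linear_sum_assignment(-cc)
        order = col[np.argsort(row)]
        corrs[s] = cc[np.arange(n_components), order]
        orders[s] = order
    return {
        "loading_correlations": corrs,
        "median_abs_r": np.median(corrs, axis=0),
        "component_assignment": orders,
    }


def atrophy_pca_scores(atrophy, n_components: int = 3):
    """PCA atrophy component scores and loadings (FC-independent scores).

    Returns ``(scores, loadings)`` with the sign of each loading fixed so its
    largest-|weight| region is positive.
    """
    X = _table(atrophy)
    pca = PCA(n_components=n_components).fit(X)
    loadings = pca.components_.T
    anchor = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[anchor, np.arange(n_components)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = (X - X.mean(axis=0)) @ loadings
    return scores, loadings


class RidgeFunctionScorer(BaseEstimator):
    """Out-of-fold ridge FC scores for atrophy components.

    For each component, ridge regression predicts the subject's atrophy score
    from FC edges; models are trained per fold of a label-stratified K-fold
    (several shuffled trials), each subject's function score is taken only
    from the fold where they were held out, and scores/coefficients are
    averaged over trials.  The default penalty follows the analysis convention
    (alpha = 1000 with 4 folds).

    Attributes
    ----------
    function_scores_ : (S, C) out-of-fold scores averaged over trials.
    coefficients_ : (E, C) ridge coefficients averaged over folds and trials.
    fold_correlations_ : (n_trials, n_folds, C) out-of-fold structure-function r.
    """

    def __init__(self, alpha: float = 1000.0, n_folds: int = 4,
                 n_trials: int = 10, seed: int = 0):
        self.alpha = alpha
        self.n_folds = n_folds
        self.n_trials = n_trials
        self.seed = seed

    def fit(self, X, y=None, labels=None) -> "RidgeFunctionScorer":
        fc = _table(X)
        scores = _table(y)
        if scores.ndim == 1:
            scores = scores[:, None]
        S, C = scores.shape
        if fc.shape[0] != S:
            raise ValueError("FC and score tables differ in subject count")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        labels = (np.zeros(S, dtype=int) if labels is None
                  else np.asarray(labels))
        counts = pd.Series(labels).value_counts()
        if (counts < self.n_folds).any():
            bad = counts[counts < self.n_folds].index.tolist()
            raise ValueError(
                f"labels {bad} have fewer members than n_folds={self.n_folds}; "
                "stratification impossible"
            )
        oof = np.zeros((self.n_trials, S, C))
        coefs = np.zeros((fc.shape[1], C))
        fold_r = np.full((self.n_trials, self.n_folds, C), np.nan)
        n_models = 0
        for t in range(self.n_trials):
            skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                  random_state=self.seed + t)
            for f, (tr, te) in enumerate(skf.split(fc, labels)):
                model = Ridge(alpha=self.alpha)
                model.fit(fc[tr], scores[tr])
                pred = model.predict(fc[te])
                oof[t, te] = pred
                coefs += model.coef_.T
                n_models += 1
                for c in range(C):
                    if pred[:, c].std() > 0 and scores[te, c].std() > 0:
                        fold_r[t, f, c] = np.corrcoef(
                            pred[:, c], scores[te, c]
                        )[0, 1]
        self.function_scores_ = oof.mean(axis=0)
        self.coefficients_ = coefs / n_models
        self.fold_correlations_ = fold_r
        return self


def ridge_function_scores(
    atrophy_scores,
    fc_edges,
    alpha: float = 1000.0,
    n_folds: int = 4,
    n_trials: int = 10,
    labels=None,
    seed: int = 0,
):
    """Out-of-fold ridge function scores, averaged coefficients, per-fold r."""
    est = RidgeFunctionScorer(alpha=alpha, n_folds=n_folds,
                              n_trials=n_trials, seed=seed)
    est.fit(fc_edges, atrophy_scores, labels=labels)
    return est.function_scores_, est.coefficients_, est.fold_correlations_


def reconstruct_fc_from_components(function_scores, function_loadings) -> np.ndarray:
    """Linear FC-edge reconstruction ``sum_c score_c * loading_c``.

    ``function_scores`` may be one subject's (C,) vector or an (S, C) table.
    """
    scores = np.asarray(function_scores, dtype=float)
    loadings = np.asarray(function_loadings, dtype=float)
    if scores.ndim == 1:
        return loadings @ scores
    return scores @ loadings.T


def network_summary_map(edge_weights: np.ndarray) -> np.ndarray:
    """Per-region sum of incident edge weights (spatial summary of an edge map)."""
    vec = np.asarray(edge_weights, dtype=float).ravel()
    R = int(round((1 + np.sqrt(1 + 8 * len(vec))) / 2))
    if n_edges(R) != len(vec):
        raise ValueError(f"edge vector length {len(vec)} is not R(R-1)/2 for any R")
    return edge_matrix(vec, R).sum(axis=1)


def mds_embed(structure_scores, n_dims: int = 2) -> dict:
    """Classical (Torgerson) MDS of subjects' component scores.

    Double-centers the squared Euclidean distance matrix and embeds on the top
    eigenvectors.  Returns the embedding plus the Pearson correlation between
    embedded and input pairwise distances.
    """
    X = _table(structure_scores)
    S = X.shape[0]
    if S < 3:
        raise ValueError("need at least 3 subjects")
    D2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    if np.allclose(D2, 0):
        raise ValueError("degenerate input: all subjects identical")
    J = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_dims]
    emb = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    iu = np.triu_indices(S, k=1)
    d_in = np.sqrt(D2[iu])
    d_emb = np.sqrt(np.sum((emb[:, None, :] - emb[None, :, :]) ** 2, axis=2))[iu]
    r = float(np.corrcoef(d_in, d_emb)[0, 1]) if d_in.std() > 0 else np.nan
    return {"embedding": emb, "distance_correlation": r,
            "eigenvalues": vals[np.argsort(vals)[::-1]]}


def typical_patients_lda(structure_scores, labels) -> dict:
    """Flag subjects whose atrophy components classify to their own syndrome.

    Linear discriminant analysis on the component scores with syndrome label
    as the response; a subject is "typical" when the predicted label equals
    the true label.  Deterministic given the input.
    """
    X = _table(structure_scores)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels")
    if (counts <= 3).any():
        raise ValueError(
            f"labels {uniq[counts <= 3].tolist()} have 3 or fewer members"
        )
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        pred = lda.fit(X, labels).predict(X)
    collinear = any("collinear" in str(w.message).lower() for w in caught)
    typical = pred == labels
    per_label = {
        str(lab): {
            "typical": int(np.sum(typical & (labels == lab))),
            "total": int(np.sum(labels == lab)),
        }
        for lab in uniq
    }
    return {
        "typical": typical,
        "predicted": pred,
        "counts": per_label,
        "collinearity_flagged": collinear,
    }
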