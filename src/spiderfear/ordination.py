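"""Redundancy analysis (RDA) with sequential permutation tests.

RDA is constrained ordination: a principal component analysis of the fitted
values of a multivariate linear regression of the responses Y (here,
per-stimulus fear ratings) on the explanatory variables X (SFI,
questionnaire scores, BAT, group, age).  With column-centered Y and X and
B = (X'X)^- X'Y, the constrained axes are the principal axes of
Yhat = XB; the k-th eigenvalue is the variance of Yhat along axis k, and
the proportion of explained variance is tr(Yhat'Yhat) / tr(Y'Y).

Axis scores follow the two standard triplot scalings: scaling 1 preserves
distances among sites (site scores Yhat*V, unit response loadings), scaling
2 preserves correlations among responses (response loadings scaled by the
square-rooted eigenvalues).

Term significance uses the sequential ("Type I") pseudo-F: each term is
added in the user's order, its added constrained variance is divided by its
df and compared with the full-model residual variance.  The permutation
null distribution permutes the residuals of the reduced model (the terms
before the one under test), an approximation to the common
permutation-of-residuals scheme; free permutation of Y rows is available as
an option.  p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["RDA", "RDAResult", "rda_fit", "rda_sequential_test"]


@dataclass
class RDAResult:
    constrained_axes: np.ndarray  # (n_responses, n_axes) loadings (V)
    eigenvalues: np.ndarray  # (n_axes,), non-increasing
    prop_explained: float
    site_scores: np.ndarray  # (n, n_axes), scaling-1 site coordinates (Yhat V)
    response_scores: np.ndarray  # (n_responses, n_axes), scaling-2 loadings
    biplot_scores: np.ndarray  # (n_predictors, n_axes) correlations of X with axes
    term_tests: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        assert -1e-9 <= self.prop_explained <= 1 + 1e-9
        assert np.all(np.diff(self.eigenvalues) <= 1e-9)


def _as_matrix(A) -> tuple[np.ndarray, list[str]]:
    if isinstance(A, pd.DataFrame):
        return A.to_numpy(dtype=float), list(A.columns)
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    return A, [f"x{j}" for j in range(A.shape[1])]


def _collinear_keep(X: np.ndarray, names: list[str], tol: float = 1e-9) -> list[int]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear predictor {names[j]!r}")
    return keep


def _hat(X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], X.shape[0]))
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


class RDA(BaseEstimator):
    """Redundancy analysis as a scikit-learn style estimator.

    Parameters
    ----------
    scale : bool
        Standardize response columns to unit variance before analysis
        (correlation-based RDA).  Centering is always applied.
    scale_predictors : bool
        Standardize predictor columns (affects biplot arrow lengths only;
        the explained variance is invariant to affine predictor rescaling).
    """

    def __init__(self, scale: bool = False, scale_predictors: bool = True):
        self.scale = scale
        self.scale_predictors = scale_predictors

    def fit(self, X, Y) -> "RDA":
        Xm, xnames = _as_matrix(X)
        Ym, ynames = _as_matrix(Y)
        n = Ym.shape[0]
        if Xm.shape[0] != n:
            raise ValueError("X and Y must have the same number of rows")
        if np.isnan(Xm).any() or np.isnan(Ym).any():
            raise ValueError("missing values are not supported")
        if n <= Xm.shape[1]:
            raise ValueError("need more observations than predictors")
        Xc = Xm - Xm.mean(axis=0)
        x_scale = np.ones(Xc.shape[1])
        if self.scale_predictors:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            x_scale = sd
            Xc = Xc / sd
        keep = _collinear_keep(Xc, xnames)
        Xc, xnames = Xc[:, keep], [xnames[j] for j in keep]
        Yc = Ym - Ym.mean(axis=0)
        if self.scale:
            sd = Yc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Yc = Yc / sd

        B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        Yhat = Xc @ B
        n_axes = min(np.linalg.matrix_rank(Xc), Yc.shape[1], n - 1)
        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
        eig = s**2 / (n - 1)
        total = float(np.sum(Yc**2)) / (n - 1)
        prop = float(eig.sum() / total) if total > 0 else 0.0

        V = Vt.T
        site1 = Yhat @ V  # scaling 1 (= U * s)
        with np.errstate(invalid="ignore", divide="ignore"):
            resp2 = V * np.sqrt(np.where(eig > 0, eig / eig.sum() if eig.sum() > 0 else 1.0, 0.0))
        # biplot scores: correlation of (processed) predictors with the axes
        biplot = np.zeros((Xc.shape[1], n_axes))
        for j in range(Xc.shape[1]):
            xj = Xc[:, j]
            for k in range(n_axes):
                ax = site1[:, k]
                denom = xj.std(ddof=1) * ax.std(ddof=1)
                biplot[j, k] = 0.0 if denom == 0 else float(np.corrcoef(xj, ax)[0, 1])

        self.n_features_in_ = Xm.shape[1]
        self.predictor_names_ = xnames
        self.response_names_ = ynames
        self.keep_idx_ = keep
        self.x_scale_ = x_scale
        self.x_mean_, self.y_mean_ = Xm.mean(axis=0), Ym.mean(axis=0)
        self.coef_ = B
        self.loadings_ = V
        self.eigenvalues_ = eig
        self.prop_explained_ = min(prop, 1.0)
        self.site_scores_ = site1
        self.response_scores_ = resp2
        self.biplot_scores_ = biplot
        self._Xc, self._Yc = Xc, Yc
        return self

    def transform(self, X=None) -> np.ndarray:
        """Site scores; new X rows are projected through the fitted axes."""
        if X is None:
            return self.site_scores_
        Xm, _ = _as_matrix(X)
        Xc = (Xm - self.x_mean_) / self.x_scale_
        return (Xc[:, self.keep_idx_] @ self.coef_) @ self.loadings_

    def scores(self, scaling: int = 1) -> dict[str, np.ndarray]:
        """Triplot coordinates under scaling 1 (distance) or 2 (correlation)."""
        if scaling == 1:
            return {"sites": self.site_scores_, "responses": self.loadings_,
                    "biplot": self.biplot_scores_}
        if scaling == 2:
            lam = np.sqrt(np.maximum(self.eigenvalues_, 0.0))
            lam[lam == 0] = 1.0
            return {"sites": self.site_scores_ / lam, "responses": self.loadings_ * lam,
                    "biplot": self.biplot_scores_}
        raise ValueError("scaling must be 1 or 2")

    def result(self, term_tests: pd.DataFrame | None = None) -> RDAResult:
        return RDAResult(
            constrained_axes=self.loadings_,
            eigenvalues=self.eigenvalues_,
            prop_explained=self.prop_explained_,
            site_scores=self.site_scores_,
            response_scores=self.response_scores_,
            biplot_scores=self.biplot_scores_,
            term_tests=term_tests,
        )


def rda_fit(Y, X, scale: bool = False) -> RDAResult:
    """Fit an RDA of responses Y on predictors X and return its summary."""
    return RDA(scale=scale).fit(X, Y).result()


def rda_sequential_test(Y, X, term_order: list[str] | None = None,
                        n_perm: int = 1999, seed: int = 0,
                        scheme: str = "reduced_residuals") -> pd.DataFrame:
    """Sequential (Type I) permutation tests of RDA terms.

    Each predictor column of X is a term with one df, tested in
    ``term_order`` after the terms before it.  Returns a DataFrame with
    columns (term, df, ss, F, p); df_res = n - 1 - n_terms.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if scheme not in ("reduced_residuals", "free"):
        raise ValueError("scheme must be 'reduced_residuals' or 'free'")
    Xm, xnames = _as_matrix(X)
    Ym, _ = _as_matrix(Y)
    n = Ym.shape[0]
    if term_order is None:
        term_order = list(xnames)
    unknown = set(term_order) - set(xnames)
    if unknown:
        raise ValueError(f"unknown terms in term_order: {sorted(unknown)}")
    cols = [xnames.index(t) for t in term_order]
    Xc = Xm[:, cols] - Xm[:, cols].mean(axis=0)
    Yc = Ym - Ym.mean(axis=0)
    m = len(cols)
    if n <= m + 1:
        raise ValueError("too few observations for the requested terms")

    # cumulative hat matrices H_0 (empty), H_1, ..., H_m
    hats = [_hat(Xc[:, :j]) for j in range(m + 1)]
    total_ss = float(np.sum(Yc**2))

    def seq_stats(Ymat: np.ndarray) -> tuple[np.ndarray, float]:
        fits = np.array([float(np.sum((hats[j] @ Ymat) ** 2)) for j in range(m + 1)])
        added = np.diff(fits)
        resid = float(np.sum(Ymat**2)) - fits[-1]
        return added, resid

    added_obs, resid_obs = seq_stats(Yc)
    df_res = n - 1 - m
    f_obs = (added_obs / 1.0) / (resid_obs / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(m)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        for j in range(m):
            if scheme == "free":
                Yp = Yc[perm]
            else:
                fitted_red = hats[j] @ Yc
                resid_red = Yc - fitted_red
                Yp = fitted_red + resid_red[perm]
            Hj, Hj1, Hm = hats[j], hats[j + 1], hats[m]
            fit_j = float(np.sum((Hj @ Yp) ** 2))
            fit_j1 = float(np.sum((Hj1 @ Yp) ** 2))
            fit_full = float(np.sum((Hm @ Yp) ** 2))
            resid_p = float(np.sum(Yp**2)) - fit_full
            f_p = (fit_j1 - fit_j) / (resid_p / df_res)
            if f_p >= f_obs[j]:
                exceed[j] += 1
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({
        "term": term_order,
        "df": 1,
        "ss": added_obs,
        "F": f_obs,
        "p": pvals,
        "df_res": df_res,
    })
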