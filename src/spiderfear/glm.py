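"""Voxelwise GLM, contrast t-maps, and the group one-sample t-test.

First-level analysis is mass-univariate ordinary least squares: each voxel's
time series is regressed on the shared design matrix, and a contrast t-map
is formed as

    t_v = c' beta_v / sqrt(sigma2_v * c' (X'X)^-1 c).

The group-level map is a one-sample t-test of per-subject contrast values
(estimates by default, first-level t-values optionally) against zero.

Zero-residual-variance voxels with a non-zero effect receive a signed
infinite sentinel; they are finite-masked out of ROI candidacy downstream.
No AR pre-whitening is applied at first level (documented limitation); the
temporal autocorrelation of the simulated noise therefore inflates
first-level dfs slightly, which cancels out of rank-based group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .bold import VolumeSeries
from .design import DesignMatrix


@dataclass
class GLMFit:
    """Per-voxel OLS results on a 3-D grid."""

    betas: np.ndarray  # (n_voxels, n_regressors)
    sigma2: np.ndarray  # (n_voxels,)
    df: int
    design: DesignMatrix
    grid_dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("non-positive residual degrees of freedom")
        if np.any(self.sigma2 < -1e-12):
            raise ValueError("negative residual variance")


@dataclass
class StatMap:
    """3-D map of t-values with its degrees of freedom."""

    tvalues: np.ndarray
    df: int
    contrast_name: str = ""

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.tvalues.shape

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.tvalues)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.tvalues.astype(np.float32), affine=np.eye(4)), path)


class VoxelGLM(BaseEstimator):
    """Mass-univariate OLS estimator.

    fit(design, series) computes per-voxel betas and residual variances;
    ``contrast`` then returns a t-map.  Follows the scikit-learn estimator
    protocol (params at construction, fitted attributes with trailing
    underscores) so it composes with sklearn tooling, although X here is a
    design matrix shared by all voxels rather than a feature matrix.
    """

    def fit(self, design: DesignMatrix, series: VolumeSeries) -> "VoxelGLM":
        X = design.matrix
        Y = series.flat()  # (n_voxels, time)
        if Y.shape[1] != X.shape[0]:
            raise ValueError(
                f"time dimension mismatch: series has {Y.shape[1]} volumes, design {X.shape[0]}"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        df = X.shape[0] - rank
        pinv = np.linalg.pinv(X)
        betas = Y @ pinv.T
        resid = Y - betas @ X.T
        sigma2 = np.einsum("ij,ij->i", resid, resid) / df
        self.design_ = design
        self.betas_ = betas
        self.sigma2_ = np.maximum(sigma2, 0.0)
        self.df_ = df
        self.xtx_inv_ = np.linalg.inv(X.T @ X)
        self.grid_dims_ = series.data.shape[:3]
        return self

    def to_fit(self) -> GLMFit:
        return GLMFit(betas=self.betas_, sigma2=self.sigma2_, df=self.df_,
                      design=self.design_, grid_dims=self.grid_dims_)

    def contrast(self, contrast: np.ndarray, name: str = "") -> StatMap:
        return contrast_tmap(self.to_fit(), contrast, name=name, xtx_inv=self.xtx_inv_)

    def contrast_estimates(self, contrast: np.ndarray) -> np.ndarray:
        """Per-voxel contrast of parameter estimates c'beta, as a 3-D map."""
        c = np.asarray(contrast, dtype=float)
        return (self.betas_ @ c).reshape(self.grid_dims_)


def fit_glm(series: VolumeSeries, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares per voxel: beta = (X'X)^-1 X' y."""
    return VoxelGLM().fit(design, series).to_fit()


def contrast_tmap(fit: GLMFit, contrast: np.ndarray, name: str = "",
                  xtx_inv: np.ndarray | None = None) -> StatMap:
    """t-map for a contrast of regression coefficients.

    Voxels with zero residual variance map to t = 0 when the contrast effect
    is also zero, and to a signed infinity sentinel otherwise.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.betas.shape[1],):
        raise ValueError("contrast length must equal the number of regressors")
    if np.all(c == 0):
        raise ValueError("all-zero contrast vector")
    if xtx_inv is None:
        X = fit.design.matrix
        xtx_inv = np.linalg.inv(X.T @ X)
    effect = fit.betas @ c
    var_scale = float(c @ xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_scale)
    t = np.full_like(effect, 0.0)
    ok = se > 0
    t[ok] = effect[ok] / se[ok]
    degenerate = (~ok) & (effect != 0)
    t[degenerate] = np.sign(effect[degenerate]) * np.inf
    return StatMap(tvalues=t.reshape(fit.grid_dims), df=fit.df, contrast_name=name)


def group_onesample_tmap(maps: list[np.ndarray] | list[StatMap],
                         contrast_name: str = "") -> StatMap:
    """One-sample t-test across subjects at each voxel, against zero.

    Accepts per-subject 3-D effect maps (contrast estimates, the default
    group pathway) or StatMaps (t-value pathway).  df = n_subjects - 1.
    """
    arrays = [m.tvalues if isinstance(m, StatMap) else np.asarray(m, dtype=float) for m in maps]
    if len(arrays) < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all subject maps must share the same grid")
    stack = np.stack(arrays)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    t = np.zeros(shape)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    degenerate = (~ok) & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    return StatMap(tvalues=t, df=n - 1, contrast_name=contrast_name)


def onesided_pvalues(stat_map: StatMap) -> np.ndarray:
    """Per-voxel one-sided (activation-increase) p-values."""
    return stats.t.sf(stat_map.tvalues, df=stat_map.df)
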