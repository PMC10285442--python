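"""Per-subject 4-D BOLD simulation with a planted spider-responsive region.

The signal model is the GLM's own generative form: voxel v at volume t is

    y[v, t] = sum_c beta[v, c] * X[t, c] + AR(1) Gaussian noise,

where X holds the HRF-convolved condition regressors.  Inside the planted
region (``BrainSpec.true_roi``) the tarantula-condition amplitude is

    beta = baseline + activation_gain * spider_trait,

so phobic subjects (high trait) carry a stronger spider response; all other
condition amplitudes sit at baseline.  Noise is temporally AR(1) per voxel
and independent across voxels; optional Gaussian spatial smoothing emulates
the usual preprocessing step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .config import BrainSpec, EffectConfig
from .cohort import Subject
from .design import DesignMatrix, SessionDesign, build_design_matrix

SPIDER_CONDITION = "tarantula"


@dataclass
class VolumeSeries:
    """4-D (x, y, z, time) signal array for one subject and session."""

    data: np.ndarray
    tr_s: float
    subject_id: str
    session_kind: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, time)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in volume series")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def flat(self) -> np.ndarray:
        """(n_voxels, time) view for vectorized per-voxel fits."""
        return self.data.reshape(-1, self.data.shape[3])

    def to_nifti(self, path) -> None:
        """Optional NIfTI-1 export (requires nibabel)."""
        import nibabel as nib

        img = nib.Nifti1Image(self.data.astype(np.float32), affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, self.tr_s))
        nib.save(img, path)


def _ar1_noise(shape: tuple[int, int], coef: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) rows: x_t = coef*x_{t-1} + e_t, marginal SD = sd."""
    innov_sd = sd * np.sqrt(1.0 - coef**2)
    e = rng.normal(0.0, innov_sd, size=shape)
    e[:, 0] = rng.normal(0.0, sd, size=shape[0])  # stationary start
    if coef == 0.0:
        return e
    return lfilter([1.0], [1.0, -coef], e, axis=1)


def planted_betas(subject: Subject, design: DesignMatrix, spec: BrainSpec,
                  config: EffectConfig) -> np.ndarray:
    """(n_voxels, n_regressors) ground-truth amplitude map for one subject."""
    n_vox = spec.n_voxels
    betas = np.zeros((n_vox, design.n_regressors))
    cond_idx = {name: j for j, name in enumerate(design.regressor_names)}
    roi_flat = np.flatnonzero(spec.roi_mask_array().ravel())
    for name, j in cond_idx.items():
        if name == "intercept" or name.startswith("drift"):
            continue
        betas[roi_flat, j] = spec.baseline_amplitude
    if SPIDER_CONDITION in cond_idx:
        j = cond_idx[SPIDER_CONDITION]
        betas[roi_flat, j] = spec.baseline_amplitude + config.activation_gain * subject.spider_trait
    return betas


def simulate_bold(subject: Subject, session: SessionDesign, spec: BrainSpec,
                  config: EffectConfig, seed: int,
                  design: DesignMatrix | None = None) -> VolumeSeries:
    """Simulate one session of 4-D BOLD data for one subject.

    Deterministic under a fixed seed.  ``design`` may be passed to reuse a
    precomputed design matrix (identical across subjects sharing a session).
    """
    if design is None:
        design = build_design_matrix(session)
    if design.n_volumes != session.n_volumes:
        raise ValueError("design/session volume mismatch")
    rng = np.random.default_rng(seed)
    betas = planted_betas(subject, design, spec, config)
    signal = betas @ design.matrix.T  # (n_voxels, time)
    if spec.noise_sd > 0:
        signal = signal + _ar1_noise(signal.shape, spec.ar1_coef, spec.noise_sd, rng)
    data = signal.reshape(*spec.grid_dims, session.n_volumes)
    series = VolumeSeries(data=data, tr_s=session.tr_s, subject_id=subject.id,
                          session_kind=session.session_kind)
    if spec.smooth_fwhm_mm > 0:
        series = smooth_volumes(series, spec.smooth_fwhm_mm, voxel_size_mm=spec.voxel_size_mm)
    return series


def smooth_volumes(series: VolumeSeries, fwhm_mm: float,
                   voxel_size_mm: float = 3.0) -> VolumeSeries:
    """Per-volume 3-D Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2)).

    ``fwhm_mm = 0`` is the identity.  Reflective boundaries are used, so the
    total signal mass is conserved exactly for interior impulses and to
    boundary-reflection accuracy near edges.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return VolumeSeries(data=series.data.copy(), tr_s=series.tr_s,
                            subject_id=series.subject_id, session_kind=series.session_kind)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    out = gaussian_filter(series.data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0),
                          mode="reflect")
    return VolumeSeries(data=out, tr_s=series.tr_s, subject_id=series.subject_id,
                        session_kind=series.session_kind)
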