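"""Spider Fear Index: data-driven ROI definition and per-subject scoring.

The SFI summarizes a subject's neurophysiological spider response in one
number.  The ROI is defined from the *fear* session only: voxels whose
group-level spider>beetle activation (one-sample t over the phobic group)
survives family-wise-error correction at alpha = 0.05.  Each subject's SFI
is then the arithmetic mean of her *spider*-session first-level t-values
inside that ROI.  Because the two sessions have independent noise, the ROI
selection does not bias the SFI: under a null spider session the SFI is
centered at zero.

Two FWE procedures are provided: Bonferroni over valid voxels (default,
exactly reproducible) and the sign-flipping max-t permutation test, the
closer analogue of common neuroimaging practice.  Testing is one-sided
(activation increases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bold import simulate_bold
from .cohort import Subject
from .config import BrainSpec, EffectConfig
from .design import build_design_matrix, build_session
from .glm import StatMap, VoxelGLM, group_onesample_tmap


class EmptyROIError(ValueError):
    """No voxel survived FWE correction; the SFI is undefined without a mask."""


@dataclass
class ROIMask:
    mask: np.ndarray  # boolean 3-D
    alpha: float
    method: str
    source_contrast: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine=np.eye(4)), path)


@dataclass
class SFIRecord:
    subject_id: str
    sfi: float
    n_roi_voxels: int
    session: str = "spider"


def define_roi(group_map: StatMap, alpha: float = 0.05, method: str = "bonferroni",
               subject_maps: list[np.ndarray] | None = None,
               n_perm: int = 1999, seed: int = 0) -> ROIMask:
    """FWE-significant voxels of the group-level activation map.

    bonferroni: include voxel v iff its one-sided p-value < alpha / n_valid
    (n_valid = finite-t voxels; infinite sentinels are excluded from
    candidacy).  max_t_permutation: include iff t_v exceeds the (1 - alpha)
    quantile of the sign-flipping max-t null distribution, which requires the
    per-subject effect maps the group map was built from.
    """
    t = group_map.tvalues
    valid = np.isfinite(t)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid voxels in group map")
    if method == "bonferroni":
        p = stats.t.sf(t[valid], df=group_map.df)
        sel = np.zeros_like(t, dtype=bool)
        sel[valid] = p < alpha / n_valid
    elif method == "max_t_permutation":
        if subject_maps is None:
            raise ValueError("max_t_permutation requires the per-subject maps")
        stack = np.stack([np.asarray(m, dtype=float) for m in subject_maps])
        n = stack.shape[0]
        rng = np.random.default_rng(seed)
        max_null = np.empty(n_perm)
        flat = stack.reshape(n, -1)[:, valid.ravel()]
        for b in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)[:, None]
            perm = flat * signs
            mean = perm.mean(axis=0)
            sd = perm.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tp = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
            max_null[b] = tp.max()
        thr = np.quantile(max_null, 1.0 - alpha)
        sel = np.zeros_like(t, dtype=bool)
        sel[valid] = t[valid] > thr
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    return ROIMask(mask=sel, alpha=alpha, method=method,
                   source_contrast=group_map.contrast_name)


def compute_sfi(subject_tmap: StatMap, roi: ROIMask, session: str = "spider") -> SFIRecord:
    """Mean subject-level t-statistic over the ROI voxels."""
    if roi.n_voxels == 0:
        raise EmptyROIError("ROI is empty: the fear-session contrast found no significant voxels")
    if subject_tmap.grid_dims != roi.mask.shape:
        raise ValueError("t-map and ROI are on different grids")
    vals = subject_tmap.tvalues[roi.mask]
    return SFIRecord(subject_id="", sfi=float(vals.mean()), n_roi_voxels=roi.n_voxels,
                     session=session)


@dataclass
class SFIPipelineResult:
    table: pd.DataFrame  # subject_id, group, sfi, n_roi_voxels
    roi: ROIMask
    group_map: StatMap
    excluded: tuple[str, ...] = ()
    subject_tmaps: dict = field(default_factory=dict)


def sfi_pipeline(cohort: list[Subject], spec: BrainSpec, config: EffectConfig,
                 seed: int = 0, alpha: float = 0.05, method: str = "bonferroni",
                 blocks_per_condition: int = 8, phobics_only_roi: bool = True,
                 group_pathway: str = "estimate",
                 exclude_ids: tuple[str, ...] = ()) -> SFIPipelineResult:
    """Full two-session SFI computation for a cohort.

    The ROI comes from the phobic group's fear-session spider>beetle group
    map (``phobics_only_roi=False`` pools all subjects); the SFI comes from
    each subject's independent spider-session first-level t-map.
    ``group_pathway`` selects whether the group one-sample t-test runs on
    contrast estimates (default) or first-level t-values.  ``exclude_ids``
    drops subjects before any analysis (e.g. low-quality acquisitions).
    """
    if group_pathway not in ("estimate", "tvalue"):
        raise ValueError("group_pathway must be 'estimate' or 'tvalue'")
    cohort = [s for s in cohort if s.id not in set(exclude_ids)]
    ss = np.random.SeedSequence(seed)
    fear_session = build_session("fear", blocks_per_condition, seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
    spider_session = build_session("spider", blocks_per_condition, seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
    fear_design = build_design_matrix(fear_session)
    spider_design = build_design_matrix(spider_session)
    c_fear = fear_design.contrast_vector("tarantula", "beetle")
    c_spider = spider_design.contrast_vector("tarantula", "beetle")

    child_seeds = ss.spawn(len(cohort))
    fear_maps_for_roi: list[np.ndarray] = []
    records = []
    tmaps = {}
    for subj, child in zip(cohort, child_seeds):
        s_fear, s_spider = (int(x % 2**31) for x in child.generate_state(2))
        fear_series = simulate_bold(subj, fear_session, spec, config, seed=s_fear,
                                    design=fear_design)
        fit_fear = VoxelGLM().fit(fear_design, fear_series)
        if subj.group == "phobic" or not phobics_only_roi:
            if group_pathway == "estimate":
                fear_maps_for_roi.append(fit_fear.contrast_estimates(c_fear))
            else:
                fear_maps_for_roi.append(fit_fear.contrast(c_fear, "spider>beetle").tvalues)
        spider_series = simulate_bold(subj, spider_session, spec, config, seed=s_spider,
                                      design=spider_design)
        tmap = VoxelGLM().fit(spider_design, spider_series).contrast(c_spider, "spider>beetle")
        tmaps[subj.id] = tmap
        records.append(subj)

    if not fear_maps_for_roi:
        raise ValueError("no subjects available to define the ROI")
    group_map = group_onesample_tmap(fear_maps_for_roi, contrast_name="spider>beetle")
    roi = define_roi(group_map, alpha=alpha, method=method,
                     subject_maps=fear_maps_for_roi if method == "max_t_permutation" else None,
                     seed=seed)
    if roi.n_voxels == 0:
        raise EmptyROIError("ROI is empty: the fear-session contrast found no significant voxels")

    rows = []
    for subj in records:
        rec = compute_sfi(tmaps[subj.id], roi)
        rows.append({"subject_id": subj.id, "group": subj.group, "sfi": rec.sfi,
                     "n_roi_voxels": rec.n_roi_voxels})
    return SFIPipelineResult(table=pd.DataFrame(rows), roi=roi, group_map=group_map,
                             excluded=tuple(exclude_ids), subject_tmaps=tmaps)
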