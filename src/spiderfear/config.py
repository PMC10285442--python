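"""Study configuration objects.

`EffectConfig` fixes the generative model of the cohort: how far apart the
phobic and control groups sit on the latent spider-fear trait, how strongly
that trait leaks into each observable (questionnaire items, approach
behavior, picture ratings, BOLD amplitude), and how correlated the snake-fear
and disgust-propensity traits are with it.  `BrainSpec` fixes the simulated
brain: grid size, the planted spider-responsive region, and the noise model.

Defaults emulate an extreme-groups design: ~30 phobic and ~32 control women
selected by a clinical interview, with group means chosen so that simulated
questionnaire and behavioral summaries fall in the realistically separated
range reported for such cohorts (phobic SPQ ~ low twenties vs control ~ low
single digits; BAT ~ 4-5 vs ~ 7 completed steps; low snake fear throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Mapping

RATING_CATEGORIES = ("tarantula", "daddy_long_legs", "beetle", "leaves", "snake", "lizard")

#: per-category Likert base level (the rating a trait-neutral subject gives on average)
DEFAULT_RATING_MU: Mapping[str, float] = {
    "tarantula": 1.6,
    "daddy_long_legs": 1.4,
    "beetle": 1.8,
    "leaves": 1.1,
    "snake": 2.6,
    "lizard": 1.8,
}

#: loading of the latent spider-fear trait on each category's rating
DEFAULT_SPIDER_WEIGHTS: Mapping[str, float] = {
    "tarantula": 1.5,
    "daddy_long_legs": 1.0,
    "beetle": 0.1,
    "leaves": 0.0,
    "snake": 0.0,
    "lizard": 0.0,
}

#: loading of the latent snake-fear trait
DEFAULT_SNAKE_WEIGHTS: Mapping[str, float] = {
    "tarantula": 0.0,
    "daddy_long_legs": 0.0,
    "beetle": 0.0,
    "leaves": 0.0,
    "snake": 1.2,
    "lizard": 0.5,
}


@dataclass(frozen=True)
class EffectConfig:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_phobic, n_control : int
        Group sizes (each >= 2).
    trait_means : (float, float)
        Mean latent spider-fear trait of (phobic, control) subjects, in
        standardized units.  The default separation of 3 SD reflects an
        extreme-groups design where phobics are selected by clinical
        interview.
    trait_sd : float
        Within-group SD of every latent trait.
    snake_trait_corr, disgust_trait_corr : float
        Correlation of the snake-fear / disgust-propensity trait with the
        *full* spider-fear trait (including the group shift), in [-1, 1].
    rating_weights : mapping
        Per-category loading of the spider trait on fear ratings.
    snake_rating_weights : mapping
        Per-category loading of the snake trait.
    rating_mu : mapping
        Per-category base rating on the 1-7 Likert scale.
    rating_noise_sd : float
        SD of the per-picture rating residual.
    activation_gain : float
        BOLD amplitude (% signal change) planted in the spider-responsive
        region per unit of spider trait.
    snake_trait_cap : float
        Phobic snake traits are truncated here so that simulated SNAQ totals
        respect the study's inclusion cutoff (score <= 17).
    trait_truncation : (float, float) or None
        Recruitment truncation of the spider trait: phobic draws below the
        first value and control draws above the second are rejected and
        redrawn, emulating the interview/questionnaire screening that made
        the recruited groups non-overlapping (their published SPQ ranges,
        13-31 vs 0-4, are disjoint).  None disables the truncation,
        yielding a continuous-trait cohort.
    age_range : (float, float)
        Uniform age range in years (women only are emulated).
    seed : int
        Base seed; every random draw derives from it.
    """

    n_phobic: int = 30
    n_control: int = 32
    trait_means: tuple[float, float] = (3.0, 0.0)
    trait_sd: float = 1.0
    snake_trait_corr: float = 0.3
    disgust_trait_corr: float = 0.3
    rating_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SPIDER_WEIGHTS))
    snake_rating_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SNAKE_WEIGHTS))
    rating_mu: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATING_MU))
    rating_noise_sd: float = 0.8
    pictures_per_category: int = 40
    activation_gain: float = 0.5
    snake_trait_cap: float = 1.8
    trait_truncation: tuple[float, float] | None = (1.8, 0.8)
    age_range: tuple[float, float] = (18.0, 66.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.n_phobic < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        for name in ("snake_trait_corr", "disgust_trait_corr"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {r}")
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be non-negative")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max)")

    def to_json(self) -> str:
        d = asdict(self)
        d["rating_weights"] = dict(d["rating_weights"])
        d["snake_rating_weights"] = dict(d["snake_rating_weights"])
        d["rating_mu"] = dict(d["rating_mu"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EffectConfig":
        d = json.loads(text)
        for key in ("trait_means", "age_range", "trait_truncation"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class BrainSpec:
    """Simulated brain geometry and noise model.

    The grid is deliberately small (12x12x12 voxels at 3 mm) so that a full
    two-session cohort simulation runs in seconds; GLM t-statistics are
    invariant to the overall signal scale, so the small grid changes power,
    not validity.  ``true_roi`` is the planted ground-truth spider-responsive
    region against which ROI recovery is evaluated.
    """

    grid_dims: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    true_roi: tuple[tuple[int, int, int], ...] = tuple(
        (x, y, z) for x in range(4, 7) for y in range(4, 7) for z in range(4, 7)
    )
    baseline_amplitude: float = 0.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    smooth_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.true_roi:
            raise ValueError("true_roi must be non-empty")
        nx, ny, nz = self.grid_dims
        for (x, y, z) in self.true_roi:
            if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
                raise ValueError(f"true_roi voxel {(x, y, z)} outside grid {self.grid_dims}")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.grid_dims
        return nx * ny * nz

    def roi_mask_array(self):
        import numpy as np

        mask = np.zeros(self.grid_dims, dtype=bool)
        for idx in self.true_roi:
            mask[idx] = True
        return mask
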