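"""Synthetic cohort generator with planted MD structure.

The generator emulates the statistical structure the downstream analyses
assume, with known ground truth, so the whole pipeline is testable without
any imaging data:

* **Task betas** — per-subject per-parcel contrast effect sizes
  ``beta[s,a,c] = mu[a,c] + u_s + e_{s,a,c}`` with a shared between-subject
  offset ``u_s ~ N(0, sigma_subject^2)`` and residual
  ``e ~ N(0, sigma_noise^2)``.  The default effect table plants positive
  means in all three contrasts exactly for the 27 extended-MD areas, with
  elevated means for the 10 core areas (three of them elevated in only two
  contrasts, exercising the two-of-three core rule).
* **Rest time series** — a K-factor model
  ``x_a(t) = sum_k lambda_{a,k} f_k(t) + eps_a(t)`` with unit-variance
  independent Gaussian factors and noise.  Default loadings (K=4: core,
  penumbra, two background factors) produce tiered population FC:
  core-core > core-penumbra > penumbra-penumbra > anything involving
  background parcels.
* **Border segments** — a 20-segment posterior→anterior profile across the
  SCEF/8BM border: flat zero over posterior SCEF, a ramp over its anterior
  two segments, a peak at the border, and a sustained plateau through 8BM.
* **Subcortical voxels** — 19 labelled structures; planted MD voxels
  (caudate-head and cerebellar-crus analogues) carry positive task effects
  in all three contrasts and time series loading on the core factor.

All outputs are deterministic functions of (config, seed); independent
substreams per product keep them invariant to call order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import (
    Atlas,
    CORE_AREAS,
    CORE_FULL_AREAS,
    CORE_PARTIAL_AREAS,
    CORE_PARTIAL_CONTRASTS,
    EXTENDED_MD_AREAS,
    PENUMBRA_AREAS,
    SUBCORTICAL_STRUCTURES,
    default_atlas,
)
from .containers import (
    BetaTable,
    ParcelTimeSeries,
    SegmentBetaTable,
    ValidationError,
    VoxelTable,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "make_default_config",
    "make_null_config",
    "generate_task_betas",
    "generate_rest_timeseries",
    "iter_rest_timeseries",
    "generate_segment_betas",
    "generate_subcortical",
    "population_fc",
    "DEFAULT_CONTRASTS",
]

DEFAULT_CONTRASTS = ("WM2bk_gt_0bk", "Relational_H_gt_E", "Math_gt_Story")

# Planted population means (in residual-noise SD units).  At n=449 the
# per-area noncentral-t power at the Bonferroni threshold is >0.999 for
# every planted decision, mirroring the near-ceiling split-half
# replication of the original analysis.
EXTENDED_EFFECT = 0.4
CORE_EFFECT = 0.8
PREFERENCE_DELTA = 0.1  # penumbra task-preference heterogeneity

# SCEF as a whole area: positive but sub-threshold in two contrasts and
# absent in the third, so it never joins the area-level conjunction even
# though its anterior segments do.
SCEF_AREA_EFFECT = (0.135, 0.135, 0.0)

# 20-segment posterior→anterior profile (SCEF 1-10 then 8BM 1-10): build-up
# over anterior SCEF, peak at the border, sustained plateau through 8BM.
SEGMENT_PROFILE = (0.0,) * 8 + (0.45, 0.9) + (0.9,) + (0.7,) * 9

# Factor loadings (K=4: core, penumbra, background A, background B).
CORE_LOADING = (0.8, 0.3, 0.0, 0.0)
PENUMBRA_LOADING = (0.35, 0.45, 0.0, 0.0)
BACKGROUND_LOADING = 0.4
VOXEL_CORE_LOADING = 0.6

# Subcortical layout.
VOXELS_PER_STRUCTURE = 30
PLANTED_VOXELS_PER_STRUCTURE = 10
PLANTED_STRUCTURES = (
    "Left_Caudate", "Right_Caudate", "Left_Cerebellum", "Right_Cerebellum",
)
VOXEL_TASK_EFFECT = 0.8

_STREAM = {"task": 1, "rest": 2, "segments": 3, "subcortex": 4}


@dataclass
class GroundTruth:
    """Planted membership recovered by the downstream analyses."""

    extended_set: frozenset
    core_full_set: frozenset
    core_partial_set: frozenset
    segment_truth: np.ndarray  # (segments, contrasts) bool: positive mean
    md_voxel_set: dict         # structure -> frozenset of voxel ids

    def __post_init__(self):
        if not (self.core_full_set | self.core_partial_set) <= self.extended_set:
            raise ValidationError("core sets must be subsets of the extended set")
        if self.core_full_set & self.core_partial_set:
            raise ValidationError("full and partial core sets must be disjoint")

    @property
    def core_set(self) -> frozenset:
        return self.core_full_set | self.core_partial_set

    @property
    def penumbra_set(self) -> frozenset:
        return self.extended_set - self.core_set


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, plus the seed."""

    n_subjects: int = 449
    n_parcels_per_hemi: int = 180
    contrasts: tuple = DEFAULT_CONTRASTS
    effect_table: np.ndarray = None          # (areas_per_hemi, contrasts)
    sigma_subject: float = 0.25
    sigma_noise: float = 1.0
    n_timepoints: int = 1200
    fc_loading_table: np.ndarray = None      # (2 * areas_per_hemi, K)
    ts_noise_sd: float = 1.0
    segment_profile: tuple = SEGMENT_PROFILE
    voxels_per_structure: int = VOXELS_PER_STRUCTURE
    planted_voxels_per_structure: int = PLANTED_VOXELS_PER_STRUCTURE
    voxel_task_effect: float = VOXEL_TASK_EFFECT
    voxel_core_loading: float = VOXEL_CORE_LOADING
    seed: int = 0
    atlas: Atlas = field(default_factory=default_atlas)
    ground_truth: GroundTruth = None

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if self.sigma_subject < 0 or self.sigma_noise <= 0 or self.ts_noise_sd <= 0:
            raise ValidationError("noise SDs must be positive")
        n_c = len(self.contrasts)
        if self.effect_table is None:
            self.effect_table = np.zeros((self.n_parcels_per_hemi, n_c))
        self.effect_table = np.asarray(self.effect_table, dtype=float)
        if self.effect_table.shape != (self.n_parcels_per_hemi, n_c):
            raise ValidationError(
                f"effect_table must be (n_parcels_per_hemi={self.n_parcels_per_hemi}, "
                f"n_contrasts={n_c}); got {self.effect_table.shape}"
            )
        if self.fc_loading_table is None:
            self.fc_loading_table = default_loading_table(self.atlas)
        self.fc_loading_table = np.asarray(self.fc_loading_table, dtype=float)
        if (
            self.fc_loading_table.ndim != 2
            or self.fc_loading_table.shape[0] != 2 * self.n_parcels_per_hemi
        ):
            raise ValidationError(
                "fc_loading_table must have one row per parcel "
                f"(2 x {self.n_parcels_per_hemi}); got {self.fc_loading_table.shape}"
            )
        if self.n_timepoints < 3:
            raise ValidationError("n_timepoints must be >= 3 for correlations")
        if self.n_timepoints < 2 * 2 * self.n_parcels_per_hemi:
            warnings.warn(
                "n_timepoints below 2x the parcel count; FC estimates will be noisy",
                stacklevel=2,
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed) % (2**31),
                                   spawn_key=(_STREAM[stream],))
        )


def default_loading_table(atlas: Atlas) -> np.ndarray:
    """Per-parcel loadings on the 4 latent factors.

    Core parcels load on the core factor (with a small shared component on
    the penumbra factor); penumbra parcels on the penumbra factor;
    background parcels split alternately over two background factors.
    Resulting population tiers (unit noise): core-core r = 0.42,
    core-penumbra 0.27, penumbra-penumbra 0.25, within-background-network
    0.14, everything else 0.
    """
    partition = atlas.parcel_partition(scef_as_penumbra=True)
    loadings = np.zeros((2 * atlas.n_areas, 4))
    bg = 0
    for i, pid in enumerate(atlas.parcel_ids):
        cls = partition[pid]
        if cls == "core":
            loadings[i] = CORE_LOADING
        elif cls == "penumbra":
            loadings[i] = PENUMBRA_LOADING
        else:
            loadings[i, 2 + bg % 2] = BACKGROUND_LOADING
            bg += 1
    return loadings


def population_fc(loadings: np.ndarray, noise_sd: float = 1.0) -> np.ndarray:
    """Population parcel-parcel correlation implied by a loading table."""
    loadings = np.asarray(loadings, dtype=float)
    cov = loadings @ loadings.T + (noise_sd**2) * np.eye(loadings.shape[0])
    d = 1.0 / np.sqrt(np.diag(cov))
    return cov * d[:, None] * d[None, :]


def _default_effect_table(atlas: Atlas, n_contrasts: int = 3) -> np.ndarray:
    table = np.zeros((atlas.n_areas, n_contrasts))
    idx = {a: i for i, a in enumerate(atlas.area_names)}
    for a in EXTENDED_MD_AREAS:
        table[idx[a]] = EXTENDED_EFFECT
    for a in CORE_FULL_AREAS:
        table[idx[a]] = CORE_EFFECT
    for a in CORE_PARTIAL_AREAS:
        table[idx[a]] = EXTENDED_EFFECT
        for c in CORE_PARTIAL_CONTRASTS[a]:
            table[idx[a], c] = CORE_EFFECT
    # Mild task-preference heterogeneity over the penumbra: cycling
    # zero-sum patterns keep each contrast's extended-set mean (almost)
    # unchanged while planting area-by-contrast structure, so split-half
    # profile correlations are diagonally dominant.
    patterns = ((1, 0, -1), (-1, 1, 0), (0, -1, 1))
    for j, a in enumerate(PENUMBRA_AREAS):
        table[idx[a]] += PREFERENCE_DELTA * np.asarray(patterns[j % 3])
    table[idx["SCEF"]] = SCEF_AREA_EFFECT
    # A few background areas active in one or two contrasts only — these
    # must be rejected by the three-way conjunction.
    table[idx["FPNx1"], 0] = 0.5
    table[idx["FPNx2"], :2] = 0.5
    table[idx["P001"], 2] = 0.6
    return table


def _default_ground_truth(config: GeneratorConfig) -> GroundTruth:
    n_seg = len(config.segment_profile)
    seg = np.repeat(
        (np.asarray(config.segment_profile) > 0)[:, None], len(config.contrasts), axis=1
    )
    md_voxels = {}
    for s in SUBCORTICAL_STRUCTURES:
        if s in PLANTED_STRUCTURES:
            md_voxels[s] = frozenset(
                f"{s}_v{i + 1:03d}" for i in range(config.planted_voxels_per_structure)
            )
        else:
            md_voxels[s] = frozenset()
    assert n_seg == 20
    return GroundTruth(
        extended_set=frozenset(EXTENDED_MD_AREAS),
        core_full_set=frozenset(CORE_FULL_AREAS),
        core_partial_set=frozenset(CORE_PARTIAL_AREAS),
        segment_truth=seg,
        md_voxel_set=md_voxels,
    )


def make_default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default synthetic cohort: 449 subjects, planted 27/10 (7+3) MD sets."""
    atlas = overrides.pop("atlas", default_atlas())
    contrasts = overrides.pop("contrasts", DEFAULT_CONTRASTS)
    config = GeneratorConfig(
        contrasts=contrasts,
        effect_table=overrides.pop(
            "effect_table", _default_effect_table(atlas, len(contrasts))
        ),
        seed=seed,
        atlas=atlas,
        **overrides,
    )
    config.ground_truth = _default_ground_truth(config)
    return config


def make_null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """All planted effects zero; used for familywise-error calibration."""
    atlas = overrides.pop("atlas", default_atlas())
    config = GeneratorConfig(seed=seed, atlas=atlas, **overrides)
    config.ground_truth = GroundTruth(
        extended_set=frozenset(),
        core_full_set=frozenset(),
        core_partial_set=frozenset(),
        segment_truth=np.zeros((20, len(config.contrasts)), dtype=bool),
        md_voxel_set={s: frozenset() for s in SUBCORTICAL_STRUCTURES},
    )
    config.effect_table = np.zeros_like(config.effect_table)
    config.fc_loading_table = np.zeros_like(config.fc_loading_table)
    config.voxel_task_effect = 0.0
    config.voxel_core_loading = 0.0
    return config


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_task_betas(config: GeneratorConfig) -> BetaTable:
    """Per-subject per-parcel contrast betas for the full 360-parcel atlas.

    The same per-area population mean applies to both hemispheres; the
    subject offset ``u_s`` is shared across parcels and contrasts, residual
    noise is independent per subject x parcel x contrast.
    """
    rng = config.rng("task")
    atlas = config.atlas
    n_s, n_c = config.n_subjects, len(config.contrasts)
    n_p = 2 * config.n_parcels_per_hemi
    mu = np.concatenate([config.effect_table, config.effect_table], axis=0)
    u = rng.normal(0.0, config.sigma_subject, size=n_s)
    e = rng.normal(0.0, config.sigma_noise, size=(n_s, n_p, n_c))
    beta = mu[None, :, :] + u[:, None, None] + e
    return BetaTable(
        beta=beta,
        subject_ids=tuple(f"sub{i + 1:04d}" for i in range(n_s)),
        area_ids=atlas.parcel_area_names,
        contrast_ids=config.contrasts,
        hemispheres=atlas.parcel_hemispheres,
    )


def _rest_session(config: GeneratorConfig, rng: np.random.Generator) -> ParcelTimeSeries:
    lam = config.fc_loading_table
    t, k = config.n_timepoints, lam.shape[1]
    factors = rng.standard_normal((t, k))
    noise = rng.normal(0.0, config.ts_noise_sd, size=(t, lam.shape[0]))
    data = factors @ lam.T + noise
    return ParcelTimeSeries(
        data=data,
        parcel_ids=config.atlas.parcel_ids,
        hemispheres=config.atlas.parcel_hemispheres,
    )


def iter_rest_timeseries(config: GeneratorConfig, n_subjects: int | None = None):
    """Yield one :class:`ParcelTimeSeries` per subject (memory-friendly)."""
    rng = config.rng("rest")
    n = config.n_subjects if n_subjects is None else n_subjects
    for _ in range(n):
        yield _rest_session(config, rng)


def generate_rest_timeseries(config: GeneratorConfig, n_subjects: int | None = None):
    """All subjects' rest sessions as a list (use the iterator for big runs)."""
    return list(iter_rest_timeseries(config, n_subjects))


def generate_segment_betas(config: GeneratorConfig) -> SegmentBetaTable:
    """Betas for the 20 ordered SCEF/8BM border segments, all contrasts.

    Same noise model as :func:`generate_task_betas` (shared subject offset
    plus independent residuals); the planted profile is identical across
    the three contrasts.
    """
    rng = config.rng("segments")
    profile = np.asarray(config.segment_profile, dtype=float)
    n_s, n_seg, n_c = config.n_subjects, profile.size, len(config.contrasts)
    u = rng.normal(0.0, config.sigma_subject, size=n_s)
    e = rng.normal(0.0, config.sigma_noise, size=(n_s, n_seg, n_c))
    beta = profile[None, :, None] + u[:, None, None] + e
    half = n_seg // 2
    return SegmentBetaTable(
        beta=beta,
        subject_ids=tuple(f"sub{i + 1:04d}" for i in range(n_s)),
        segment_areas=("SCEF",) * half + ("8BM",) * half,
        segment_numbers=tuple(range(1, half + 1)) * 2,
        contrast_ids=config.contrasts,
        border_index=half,
    )


def generate_subcortical(config: GeneratorConfig) -> VoxelTable:
    """Subcortical voxel table: task betas per subject plus one rest session.

    The rest session shares its latent factors with a matching cortical
    parcel session (returned as ``table.cortex``), so voxel-to-parcel FC is
    meaningful: planted voxels load on the core factor, null voxels are
    pure noise.
    """
    rng = config.rng("subcortex")
    n_per = config.voxels_per_structure
    n_planted = config.planted_voxels_per_structure
    if n_planted > n_per:
        raise ValidationError("planted voxel count exceeds voxels per structure")
    voxel_ids, structures, planted = [], [], []
    for s in SUBCORTICAL_STRUCTURES:
        for i in range(n_per):
            voxel_ids.append(f"{s}_v{i + 1:03d}")
            structures.append(s)
            planted.append(s in PLANTED_STRUCTURES and i < n_planted)
    planted = np.asarray(planted)
    n_v, n_s, n_c = len(voxel_ids), config.n_subjects, len(config.contrasts)

    mu = np.where(planted[:, None], config.voxel_task_effect, 0.0) * np.ones((1, n_c))
    u = rng.normal(0.0, config.sigma_subject, size=n_s)
    e = rng.normal(0.0, config.sigma_noise, size=(n_s, n_v, n_c))
    betas = mu[None, :, :] + u[:, None, None] + e

    # one rest session with factors shared between cortex and voxels
    lam = config.fc_loading_table
    t, k = config.n_timepoints, lam.shape[1]
    factors = rng.standard_normal((t, k))
    cortex_data = factors @ lam.T + rng.normal(
        0.0, config.ts_noise_sd, size=(t, lam.shape[0])
    )
    vox_loading = np.where(planted, config.voxel_core_loading, 0.0)
    vox_data = factors[:, [0]] * vox_loading[None, :] + rng.normal(
        0.0, config.ts_noise_sd, size=(t, n_v)
    )
    cortex = ParcelTimeSeries(
        data=cortex_data,
        parcel_ids=config.atlas.parcel_ids,
        hemispheres=config.atlas.parcel_hemispheres,
    )
    return VoxelTable(
        voxel_ids=tuple(voxel_ids),
        structures=tuple(structures),
        betas=betas,
        subject_ids=tuple(f"sub{i + 1:04d}" for i in range(n_s)),
        contrast_ids=config.contrasts,
        timeseries=vox_data,
        cortex=cortex,
        known_structures=SUBCORTICAL_STRUCTURES,
    )
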