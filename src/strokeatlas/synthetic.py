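"""Synthetic cohorts with the spatial structure the atlas assumes.

Each outcome parameter gets a smooth ground-truth field over the atlas
grid; a case's outcome is the field mean over its lesion plus noise,
rounded and clipped to the parameter's scale.  Lesions are random
ellipsoidal blobs inside a brain mask with log-normally distributed
volumes; the native frame is the atlas frame perturbed by a random rigid
(optionally scaled) transform whose exact landmark images are emitted,
so normalization is exactly invertible.  All randomness flows from one
master seed through spawned substreams; the noise level sigma scales a
fixed noise draw, so cohorts at different sigma share lesions and
fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    AtlasSpace,
    CaseRecord,
    ContourFile,
    MRS_DAYS,
    BI_DAYS,
    OUTCOME_PARAMETERS,
)
from .normalization import LandmarkSet, default_atlas_landmarks_mm

__all__ = [
    "GroundTruthField",
    "SyntheticCase",
    "Cohort",
    "parameter_range",
    "make_field",
    "brain_mask",
    "sample_case",
    "make_cohort",
]

_DEFAULT_MISSINGNESS = {
    "mRS7": 2 / 128, "mRS30": 3 / 128, "mRS90": 6 / 128,
    "mRS180": 10 / 128, "mRS360": 12 / 128,
    "BI30": 9 / 128, "BI90": 17 / 128, "BI180": 25 / 128, "BI360": 29 / 128,
}


def parameter_range(parameter: str) -> tuple[float, float]:
    if parameter.startswith("mRS"):
        return (0.0, 6.0)
    if parameter.startswith("BI"):
        return (0.0, 100.0)
    if parameter.startswith("NIHSS"):
        return (0.0, 42.0)
    raise KeyError(f"unknown parameter {parameter!r}")


@dataclass
class GroundTruthField:
    """A smooth per-parameter outcome field over the atlas grid."""

    parameter: str
    values: np.ndarray
    smoothness_mm: float
    seed: int

    def mean_over(self, mask: np.ndarray) -> float:
        return float(self.values[mask].mean())


def make_field(
    parameter: str,
    space: AtlasSpace,
    smoothness_mm: float = 40.0,
    seed: int = 0,
    hemi_asymmetry: float = 0.0,
) -> GroundTruthField:
    """Band-limited random field rescaled into the parameter's range.

    White noise is Gaussian-smoothed at ``smoothness_mm`` and rescaled by
    the theoretical post-filter standard deviation, so the field has
    roughly unit variance at any smoothness; it is then centered on the
    parameter's mid-range and clipped to its bounds.  As smoothness grows
    past the grid extent the field becomes spatially constant.
    ``hemi_asymmetry`` adds a left/right offset (in normalized units).
    """
    if smoothness_mm <= 0:
        raise ValueError("smoothness_mm must be > 0")
    lo, hi = parameter_range(parameter)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(space.dims)
    sigma_vox = np.asarray([smoothness_mm / v for v in space.voxel_size])
    g = gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    # theoretical std of gaussian_filter applied to unit white noise
    std_theory = float(np.prod(2.0 * np.sqrt(np.pi) * sigma_vox) ** -0.5)
    z = g / std_theory
    if hemi_asymmetry:
        x = np.arange(space.dims[0]) - (space.dims[0] - 1) / 2.0
        z = z + hemi_asymmetry * np.sign(x)[:, None, None]
    center, halfspan = (lo + hi) / 2.0, (hi - lo) / 2.0
    values = np.clip(center + halfspan * z / 2.5, lo, hi)
    return GroundTruthField(parameter, values, smoothness_mm, seed)


def brain_mask(space: AtlasSpace) -> np.ndarray:
    """Ellipsoid inscribed in the grid (95% of the half-extents)."""
    half = np.asarray(space.dims) / 2.0
    axes = 0.95 * half
    grids = np.meshgrid(*[np.arange(d) for d in space.dims], indexing="ij")
    q = sum(((g - c + 0.5) / a) ** 2 for g, c, a in zip(grids, half, axes))
    return q <= 1.0


@dataclass(frozen=True)
class JitterParams:
    """Native-frame perturbation: rigid by default (volume preserving)."""

    max_rotation_deg: float = 10.0
    max_translation_mm: float = 15.0
    max_log_scale: float = 0.0


@dataclass
class SyntheticCase:
    record: CaseRecord
    native_contour: ContourFile
    atlas_contour: ContourFile
    landmarks: LandmarkSet
    true_means: dict
    noise_draws: dict


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    cx, cy, cz = np.cos(angles_rad)
    sx, sy, sz = np.sin(angles_rad)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _sample_lesion(
    rng: np.random.Generator,
    space: AtlasSpace,
    brain: np.ndarray,
    volume_log_mean: float,
    volume_log_sd: float,
    volume_range_cm3: tuple[float, float],
    max_retries: int = 20,
) -> np.ndarray:
    vox_cm3 = space.voxel_volume_cm3
    brain_idx = np.argwhere(brain)
    grids = np.meshgrid(*[np.arange(d) for d in space.dims], indexing="ij")
    vs = np.asarray(space.voxel_size)
    for _ in range(max_retries):
        target = float(
            np.clip(rng.lognormal(volume_log_mean, volume_log_sd), *volume_range_cm3)
        )
        center = brain_idx[rng.integers(len(brain_idx))]
        ratios = rng.uniform(0.6, 1.6, size=3)
        # semi-axes (mm) such that the ellipsoid volume matches the target
        r0 = (target * 1000.0 * 3.0 / (4.0 * math.pi * np.prod(ratios))) ** (1 / 3)
        axes_mm = r0 * ratios
        q = sum(
            (((g - c) * v) / a) ** 2
            for g, c, v, a in zip(grids, center, vs, axes_mm)
        )
        lesion = (q <= 1.0) & brain
        if lesion.sum() >= 2:
            return lesion
    raise RuntimeError("failed to generate a lesion after max retries")


def sample_case(
    fields: Mapping[str, GroundTruthField],
    space: AtlasSpace,
    seed: int,
    case_id: Optional[str] = None,
    sigma: float = 0.5,
    volume_log_mean: float = math.log(12.0),
    volume_log_sd: float = 1.2,
    volume_range_cm3: tuple[float, float] = (1.0, 251.0),
    jitter: Optional[JitterParams] = None,
    missingness: Optional[Mapping[str, float]] = None,
    atlas_landmarks: Optional[Mapping] = None,
) -> SyntheticCase:
    """Draw one synthetic case: lesion, native frame, outcomes, landmarks.

    Substreams for lesion, jitter, noise and missingness are spawned
    independently, and sigma only scales the (fixed) noise draws, so the
    same seed yields identical geometry across noise levels.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    jitter = jitter if jitter is not None else JitterParams()
    missingness = dict(_DEFAULT_MISSINGNESS) if missingness is None else dict(missingness)
    ss = np.random.SeedSequence(seed)
    lesion_rng, jitter_rng, noise_rng, miss_rng = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    case_id = case_id if case_id is not None else f"case{seed:06d}"

    brain = brain_mask(space)
    lesion = _sample_lesion(
        lesion_rng, space, brain, volume_log_mean, volume_log_sd, volume_range_cm3
    )
    atlas_contour = ContourFile(case_id=case_id, mask=lesion, space=space, frame="atlas")
    volume_cm3 = atlas_contour.volume_cm3

    # native frame: atlas mm -> native mm
    ang = np.deg2rad(
        jitter_rng.uniform(-jitter.max_rotation_deg, jitter.max_rotation_deg, 3)
    )
    rot = _rotation_matrix(ang)
    scale = math.exp(jitter_rng.uniform(-jitter.max_log_scale, jitter.max_log_scale))
    trans = jitter_rng.uniform(-jitter.max_translation_mm, jitter.max_translation_mm, 3)
    amat = np.eye(4)
    amat[:3, :3] = scale * rot
    amat[:3, 3] = trans
    native_affine = amat @ space.affine()
    native_contour = ContourFile(
        case_id=case_id, mask=lesion.copy(), space=space,
        frame="native", affine=native_affine,
    )

    atl = atlas_landmarks or default_atlas_landmarks_mm(space)
    lm_native = {
        k: (amat[:3, :3] @ np.asarray(v) + amat[:3, 3]) for k, v in atl.items()
    }
    msp = amat[:3, :3] @ np.array([1.0, 0.0, 0.0])
    landmarks = LandmarkSet(
        ac=lm_native["AC"], pc=lm_native["PC"],
        l=lm_native["L"], r=lm_native["R"],
        a=lm_native["A"], p=lm_native["P"],
        s=lm_native["S"], i=lm_native["I"],
        msp_normal=msp / np.linalg.norm(msp),
    )

    eps = noise_rng.standard_normal(len(OUTCOME_PARAMETERS) + 2)
    true_means, noise_draws = {}, {}
    mrs: dict[int, Optional[int]] = {}
    bi: dict[int, Optional[int]] = {}
    for pi, parameter in enumerate(OUTCOME_PARAMETERS):
        fld = fields.get(parameter)
        if fld is None:
            continue
        lo, hi = parameter_range(parameter)
        noise_scale = sigma * (hi - lo) / 6.0  # sigma is in mRS grades
        mu = fld.mean_over(lesion)
        val = int(np.clip(round(mu + noise_scale * eps[pi]), lo, hi))
        true_means[parameter] = mu
        noise_draws[parameter] = noise_scale * eps[pi]
        if miss_rng.random() < missingness.get(parameter, 0.0):
            val = None
        if parameter.startswith("mRS"):
            mrs[int(parameter[3:])] = val
        else:
            bi[int(parameter[2:])] = val

    nihssa = int(np.clip(round(4.5 * math.log(volume_cm3) + 2.0
                                + 2.0 * sigma * eps[-2]), 0, 42))
    nihss7 = int(np.clip(round(0.85 * nihssa + 2.0 * sigma * eps[-1]), 0, 42))

    record = CaseRecord(
        case_id=case_id,
        infarct_volume_cm3=volume_cm3,
        nihss_admission=nihssa,
        nihss_day7=nihss7,
        mrs=mrs,
        bi=bi,
    )
    return SyntheticCase(
        record=record,
        native_contour=native_contour,
        atlas_contour=atlas_contour,
        landmarks=landmarks,
        true_means=true_means,
        noise_draws=noise_draws,
    )


@dataclass
class Cohort:
    """An in-memory synthetic dataset: records, contours, landmarks, truth."""

    space: AtlasSpace
    seed: int
    sigma: float
    cases: list = dc_field(default_factory=list)
    fields: dict = dc_field(default_factory=dict)

    @property
    def records(self) -> list[CaseRecord]:
        return [c.record for c in self.cases]

    @property
    def atlas_contours(self) -> dict[str, ContourFile]:
        return {c.record.case_id: c.atlas_contour for c in self.cases}

    @property
    def native_contours(self) -> dict[str, ContourFile]:
        return {c.record.case_id: c.native_contour for c in self.cases}

    @property
    def landmarks(self) -> dict[str, LandmarkSet]:
        return {c.record.case_id: c.landmarks for c in self.cases}


def make_cohort(
    n: int,
    seed: int = 0,
    space: Optional[AtlasSpace] = None,
    sigma: float = 0.5,
    smoothness_mm: float = 40.0,
    parameters: Sequence[str] = OUTCOME_PARAMETERS,
    jitter: Optional[JitterParams] = None,
    missingness: Optional[Mapping[str, float]] = None,
) -> Cohort:
    """Generate ``n`` independent cases plus their ground-truth fields.

    Per-case seeds are derived from the master seed by counter; two runs
    with the same arguments produce identical cohorts.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    space = space or AtlasSpace.reduced()
    master = np.random.SeedSequence(seed)
    field_ss, case_ss = master.spawn(2)
    field_seeds = field_ss.generate_state(len(parameters))
    fields = {
        p: make_field(p, space, smoothness_mm=smoothness_mm, seed=int(s),
                      hemi_asymmetry=0.15 if p.startswith("NIHSS") else 0.0)
        for p, s in zip(parameters, field_seeds)
    }
    case_seeds = case_ss.generate_state(max(n, 1))
    cohort = Cohort(space=space, seed=seed, sigma=sigma, fields=fields)
    for i in range(n):
        cohort.cases.append(
            sample_case(
                fields, space, seed=int(case_seeds[i]),
                case_id=f"case{i:04d}", sigma=sigma,
                jitter=jitter, missingness=missingness,
            )
        )
    return cohort
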