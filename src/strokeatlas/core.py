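"""Domain types and geometric primitives.

The atlas lives on a fixed stereotactic (Talairach-style) grid.  All
volumes are voxel-count based: a voxel belongs to a mask iff its flag is
set, and no partial-volume geometry is applied.  World coordinates are in
mm, with the center of voxel (0, 0, 0) at the world origin.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AtlasSpace",
    "ContourFile",
    "CaseRecord",
    "SelectionSpec",
    "StrokeMap",
    "WeightContext",
    "GridMismatchError",
    "EmptyMaskError",
    "mask_volume_cm3",
    "overlap_volume",
    "centroid_distance",
    "MRS_DAYS",
    "BI_DAYS",
    "OUTCOME_PARAMETERS",
]

#: follow-up days at which outcomes are recorded
MRS_DAYS = (7, 30, 90, 180, 360)
BI_DAYS = (30, 90, 180, 360)

#: the nine predictable outcome parameters
OUTCOME_PARAMETERS = tuple(f"mRS{d}" for d in MRS_DAYS) + tuple(
    f"BI{d}" for d in BI_DAYS
)


class GridMismatchError(ValueError):
    """Two volumes do not live on the same voxel grid."""


class EmptyMaskError(ValueError):
    """An operation requires at least one foreground voxel."""


@dataclass(frozen=True)
class AtlasSpace:
    """A regular voxel grid with fixed physical resolution.

    The default grid is 512 x 512 x 64 voxels at
    0.320119 x 0.320119 x 2 mm, spanning roughly 163.9 x 163.9 x 128 mm.
    ``reduced()`` returns a coarser grid covering the same physical
    extent, convenient for tests and simulation.
    """

    dims: tuple[int, int, int] = (512, 512, 64)
    voxel_size: tuple[float, float, float] = (0.320119, 0.320119, 2.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(
                f"voxel_size must be three positive reals, got {self.voxel_size}"
            )
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(d * v for d, v in zip(self.dims, self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal scaling)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    @classmethod
    def reduced(cls, factor: int = 8) -> "AtlasSpace":
        """Grid downsampled in-plane by ``factor`` and 4x along z, same extent."""
        zf = max(factor // 2, 1)
        return cls(
            dims=(512 // factor, 512 // factor, 64 // zf),
            voxel_size=(0.320119 * factor, 0.320119 * factor, 2.0 * zf),
        )


def _as_bool_mask(mask: np.ndarray, space: AtlasSpace, name: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != tuple(space.dims):
        raise GridMismatchError(
            f"{name} has shape {mask.shape}, expected {tuple(space.dims)}"
        )
    return mask.astype(bool, copy=False)


def mask_volume_cm3(mask: np.ndarray, space: AtlasSpace) -> float:
    """Volume of the foreground in cm^3 (voxel count times voxel volume)."""
    m = _as_bool_mask(mask, space)
    return int(m.sum()) * space.voxel_volume_cm3


def overlap_volume(a: np.ndarray, b: np.ndarray, space: AtlasSpace) -> float:
    """Volume (cm^3) of the voxel-wise AND of two masks on the same grid."""
    ma = _as_bool_mask(a, space, "a")
    mb = _as_bool_mask(b, space, "b")
    return int(np.count_nonzero(ma & mb)) * space.voxel_volume_cm3


def mask_centroid_mm(mask: np.ndarray, space: AtlasSpace) -> np.ndarray:
    """Unweighted mean of foreground voxel centers, in world mm."""
    m = _as_bool_mask(mask, space)
    idx = np.argwhere(m)
    if idx.shape[0] == 0:
        raise EmptyMaskError("centroid of an empty mask is undefined")
    return idx.mean(axis=0) * np.asarray(space.voxel_size)


def centroid_distance(a: np.ndarray, b: np.ndarray, space: AtlasSpace) -> float:
    """Euclidean distance (mm) between the centroids of two masks."""
    ca = mask_centroid_mm(a, space)
    cb = mask_centroid_mm(b, space)
    return float(np.linalg.norm(ca - cb))


@dataclass
class ContourFile:
    """The complete delineation of one patient's lesion as a binary mask.

    ``frame`` records whether the mask lives in the patient's native
    scanner frame or in the atlas grid.  ``affine`` maps voxel indices to
    world mm; when omitted it defaults to the diagonal affine of
    ``space``.  Native-frame masks may sit on an arbitrary grid, in which
    case ``space`` describes that grid (dims + voxel size) and ``affine``
    carries the scanner pose.
    """

    case_id: str
    mask: np.ndarray
    space: AtlasSpace
    frame: str = "atlas"
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.frame not in ("native", "atlas"):
            raise ValueError(f"frame must be 'native' or 'atlas', got {self.frame!r}")
        self.mask = _as_bool_mask(self.mask, self.space, f"contour {self.case_id}")
        if self.mask.sum() == 0:
            raise EmptyMaskError(f"contour {self.case_id} has no foreground voxels")
        if self.affine is None:
            self.affine = self.space.affine()
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be a 4x4 matrix")

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        # atlas-frame masks live on the grid: use the exact voxel volume
        if self.frame == "atlas":
            return self.volume_voxels * self.space.voxel_volume_cm3
        det = abs(np.linalg.det(self.affine[:3, :3]))
        return self.volume_voxels * det / 1000.0

    def flat_indices(self) -> np.ndarray:
        """Indices of foreground voxels in the flattened (C-order) grid."""
        return np.flatnonzero(self.mask.reshape(-1))

    def centroid_mm(self) -> np.ndarray:
        return mask_centroid_mm(self.mask, self.space)


_MISSING = None


def _check_int_range(value, lo, hi, what):
    if value is _MISSING:
        return None
    v = int(value)
    if not lo <= v <= hi:
        raise ValueError(f"{what} must lie in [{lo}, {hi}], got {value}")
    return v


@dataclass
class CaseRecord:
    """Clinical parameters and outcomes of one patient.

    Missing values are ``None`` and are first-class: a case with a
    missing value is excluded only from computations that need it.
    """

    case_id: str
    infarct_volume_cm3: float
    nihss_admission: Optional[int] = None
    nihss_day7: Optional[int] = None
    mrs: Mapping[int, Optional[int]] = field(default_factory=dict)
    bi: Mapping[int, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.infarct_volume_cm3 > 0):
            raise ValueError(
                f"case {self.case_id}: infarct_volume_cm3 must be > 0, "
                f"got {self.infarct_volume_cm3}"
            )
        self.nihss_admission = _check_int_range(
            self.nihss_admission, 0, 42, f"case {self.case_id}: nihss_admission"
        )
        self.nihss_day7 = _check_int_range(
            self.nihss_day7, 0, 42, f"case {self.case_id}: nihss_day7"
        )
        mrs = {}
        for day in MRS_DAYS:
            mrs[day] = _check_int_range(
                self.mrs.get(day), 0, 6, f"case {self.case_id}: mRS{day}"
            )
        self.mrs = mrs
        bi = {}
        for day in BI_DAYS:
            bi[day] = _check_int_range(
                self.bi.get(day), 0, 100, f"case {self.case_id}: BI{day}"
            )
        self.bi = bi

    def value(self, parameter: str) -> Optional[float]:
        """Value of a named predictable parameter, or None if missing."""
        if parameter.startswith("mRS"):
            day = int(parameter[3:])
            if day not in self.mrs:
                raise KeyError(f"unknown parameter {parameter!r}")
            v = self.mrs[day]
        elif parameter.startswith("BI"):
            day = int(parameter[2:])
            if day not in self.bi:
                raise KeyError(f"unknown parameter {parameter!r}")
            v = self.bi[day]
        elif parameter == "NIHSSa":
            v = self.nihss_admission
        elif parameter == "NIHSS7":
            v = self.nihss_day7
        elif parameter == "volume":
            v = self.infarct_volume_cm3
        else:
            raise KeyError(f"unknown parameter {parameter!r}")
        return None if v is None else float(v)

    def has_any_outcome(self) -> bool:
        return any(v is not None for v in self.mrs.values()) or any(
            v is not None for v in self.bi.values()
        )


_FULL_NIHSS = (0, 42)


@dataclass(frozen=True)
class SelectionSpec:
    """Closed-interval constraints on the case-selection variables.

    A variable whose range equals its full range is unconstrained; cases
    missing that variable are then still admitted.  The all-cases spec is
    ``SelectionSpec()``.
    """

    volume_range: tuple[float, float] = (0.0, math.inf)
    nihssa_range: tuple[int, int] = _FULL_NIHSS
    nihss7_range: tuple[int, int] = _FULL_NIHSS

    def __post_init__(self) -> None:
        vl, vh = self.volume_range
        if not vl <= vh:
            raise ValueError(f"volume_range lower > upper: {self.volume_range}")
        for name, (lo, hi) in (
            ("nihssa_range", self.nihssa_range),
            ("nihss7_range", self.nihss7_range),
        ):
            if not (0 <= lo <= hi <= 42):
                raise ValueError(f"{name} must be a sub-interval of [0, 42]: {(lo, hi)}")
        object.__setattr__(self, "volume_range", (float(vl), float(vh)))
        object.__setattr__(
            self, "nihssa_range", (int(self.nihssa_range[0]), int(self.nihssa_range[1]))
        )
        object.__setattr__(
            self, "nihss7_range", (int(self.nihss7_range[0]), int(self.nihss7_range[1]))
        )

    @classmethod
    def all_cases(cls) -> "SelectionSpec":
        return cls()

    @property
    def constrains_volume(self) -> bool:
        return self.volume_range != (0.0, math.inf)

    @property
    def constrains_nihssa(self) -> bool:
        return self.nihssa_range != _FULL_NIHSS

    @property
    def constrains_nihss7(self) -> bool:
        return self.nihss7_range != _FULL_NIHSS

    def admits(self, case: CaseRecord) -> bool:
        if self.constrains_volume:
            v = case.infarct_volume_cm3
            if v is None or not self.volume_range[0] <= v <= self.volume_range[1]:
                return False
        if self.constrains_nihssa:
            v = case.nihss_admission
            if v is None or not self.nihssa_range[0] <= v <= self.nihssa_range[1]:
                return False
        if self.constrains_nihss7:
            v = case.nihss_day7
            if v is None or not self.nihss7_range[0] <= v <= self.nihss7_range[1]:
                return False
        return True


@dataclass(frozen=True)
class WeightContext:
    """Geometric quantities a weight variant may consume.

    v_psa: volume (cm^3) of the atlas-side contour file; v_p: volume of
    the contour under prediction; v_o: their overlap volume; d: distance
    (mm) between their centroids.  v_p, v_o and d may be absent for the
    variants that do not depend on the predicted case.
    """

    v_psa: float
    v_p: Optional[float] = None
    v_o: Optional[float] = None
    d: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.v_psa > 0:
            raise ValueError(f"v_psa must be > 0, got {self.v_psa}")
        if self.v_p is not None and not self.v_p > 0:
            raise ValueError(f"v_p must be > 0 when present, got {self.v_p}")
        if self.v_o is not None:
            lim = min(
                self.v_psa, self.v_p if self.v_p is not None else math.inf
            )
            if not -1e-9 <= self.v_o <= lim + 1e-9:
                raise ValueError(
                    f"v_o must lie in [0, min(v_psa, v_p)], got {self.v_o}"
                )
        if self.d is not None and self.d < 0:
            raise ValueError(f"d must be >= 0, got {self.d}")


@dataclass
class StrokeMap:
    """Per-voxel weighted accumulators of one parameter, one weight variant.

    Stores the raw accumulators (weighted sum, summed weight, contributor
    count) rather than the ratio, so maps over disjoint cohorts can be
    merged exactly and updated incrementally.  ``values()`` returns the
    per-voxel weighted mean, NaN where no weight has accumulated.
    """

    parameter: str
    weight_id: int
    sum_map: np.ndarray
    weight_map: np.ndarray
    count_map: np.ndarray
    n_cases: int
    selection: SelectionSpec
    space: AtlasSpace
    case_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("sum_map", "weight_map", "count_map"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != tuple(self.space.dims):
                raise GridMismatchError(
                    f"{name} has shape {arr.shape}, expected {tuple(self.space.dims)}"
                )
        self.sum_map = np.asarray(self.sum_map, dtype=np.float64)
        self.weight_map = np.asarray(self.weight_map, dtype=np.float64)
        self.count_map = np.asarray(self.count_map, dtype=np.int32)
        self.case_ids = tuple(self.case_ids)

    @property
    def covered(self) -> np.ndarray:
        """Boolean volume: voxels where the map value is defined."""
        return self.weight_map > 0

    def values(self) -> np.ndarray:
        """Per-voxel weighted mean; NaN where undefined."""
        out = np.full(self.space.dims, np.nan)
        cov = self.covered
        out[cov] = self.sum_map[cov] / self.weight_map[cov]
        return out

    def value_at(self, voxel: Sequence[int]) -> float:
        v = tuple(int(i) for i in voxel)
        w = self.weight_map[v]
        if w <= 0:
            raise ValueError(f"map value undefined at voxel {v}")
        return float(self.sum_map[v] / w)

    def copy(self) -> "StrokeMap":
        return dataclasses.replace(
            self,
            sum_map=self.sum_map.copy(),
            weight_map=self.weight_map.copy(),
            count_map=self.count_map.copy(),
        )
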