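import numpy as np
import pytest

from strokeatlas.core import AtlasSpace, CaseRecord, ContourFile


@pytest.fixture
def small_space():
    """A tiny isotropic grid for micro-cohort tests."""
    return AtlasSpace(dims=(12, 12, 6), voxel_size=(1.0, 1.0, 1.0))


@pytest.fixture
def cube_space():
    """16^3 grid at 1 mm for oracle-equivalence tests."""
    return AtlasSpace(dims=(16, 16, 16), voxel_size=(1.0, 1.0, 1.0))


def random_mask(rng, space, density=0.25):
    """Random nonempty boolean mask on the grid."""
    while True:
        m = rng.random(space.dims) < density
        if m.any():
            return m


def blob_mask(space, center, radius_vox):
    grids = np.meshgrid(*[np.arange(d) for d in space.dims], indexing="ij")
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    m = q <= radius_vox**2
    assert m.any()
    return m


def micro_cohort(rng, n, space, parameter="mRS90", density=0.25):
    """n cases with random masks and random integer outcomes."""
    cases, contours = [], {}
    for i in range(n):
        cid = f"c{i}"
        contour = ContourFile(cid, random_mask(rng, space, density), space)
        day = int(parameter[3:]) if parameter.startswith("mRS") else None
        cases.append(
            CaseRecord(
                case_id=cid,
                infarct_volume_cm3=contour.volume_cm3,
                nihss_admission=int(rng.integers(0, 43)),
                nihss_day7=int(rng.integers(0, 43)),
                mrs={day: int(rng.integers(0, 7))} if day else {},
            )
        )
        contours[cid] = contour
    return cases, contours


def brute_force_mean_map(cases, contours, parameter, space):
    """Independent per-voxel mean oracle: loops cases x voxels."""
    out = np.full(space.dims, np.nan)
    for v in np.ndindex(*space.dims):
        total, count = 0.0, 0
        for case in cases:
            value = case.value(parameter)
            if value is not None and contours[case.case_id].mask[v]:
                total += value
                count += 1
        if count:
            out[v] = total / count
    return out
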