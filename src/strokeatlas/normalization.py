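"""Landmark-driven piecewise-affine normalization into the atlas grid.

The transform is the classic 12-cell proportional-grid scheme: an
orthonormal frame is anchored at the anterior commissure (AC), with one
axis along the midsagittal-plane normal, one along the PC->AC direction
and the third perpendicular to both.  In that frame the mapping is
separable and piecewise linear, with breakpoints at the MSP (x), at AC
and PC (y) and at the AC-PC plane (z); the cortical extremes L/R, A/P,
S/I pin the outer segments.  This yields 2 x 3 x 2 = 12 affine blocks
that agree on shared boundary planes and are each invertible.

Landmark detection is not performed here; landmarks are inputs.  The
atlas-side landmark coordinates are package conventions (configurable),
not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .core import AtlasSpace, ContourFile

__all__ = [
    "LandmarkSet",
    "TalairachTransform",
    "LandmarkError",
    "LesionOutsideGridError",
    "default_atlas_landmarks_mm",
    "fit_transform",
    "normalize_contour",
]


class LandmarkError(ValueError):
    """Degenerate or mis-ordered landmark geometry."""


class LesionOutsideGridError(ValueError):
    """A lesion maps entirely outside the atlas grid."""


@dataclass
class LandmarkSet:
    """Talairach-style landmarks of one case, in native scanner mm.

    ac/pc: anterior/posterior commissure; l/r/a/p/s/i: cortical extremes
    (left, right, anterior, posterior, superior, inferior); msp_normal:
    unit normal of the midsagittal plane, pointing toward the right
    cortical extreme.
    """

    ac: np.ndarray
    pc: np.ndarray
    l: np.ndarray
    r: np.ndarray
    a: np.ndarray
    p: np.ndarray
    s: np.ndarray
    i: np.ndarray
    msp_normal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ac", "pc", "l", "r", "a", "p", "s", "i", "msp_normal"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            setattr(self, name, v)
        n = np.linalg.norm(self.msp_normal)
        if n == 0:
            raise LandmarkError("msp_normal must be a nonzero vector")
        self.msp_normal = self.msp_normal / n

    def as_dict(self) -> dict:
        return {
            "AC": self.ac.tolist(),
            "PC": self.pc.tolist(),
            "L": self.l.tolist(),
            "R": self.r.tolist(),
            "A": self.a.tolist(),
            "P": self.p.tolist(),
            "S": self.s.tolist(),
            "I": self.i.tolist(),
            "msp_normal": self.msp_normal.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandmarkSet":
        return cls(
            ac=d["AC"], pc=d["PC"], l=d["L"], r=d["R"],
            a=d["A"], p=d["P"], s=d["S"], i=d["I"],
            msp_normal=d["msp_normal"],
        )


def default_atlas_landmarks_mm(space: Optional[AtlasSpace] = None) -> dict:
    """Conventional atlas-side landmark positions, in atlas world mm.

    AC sits on the grid midline (x) at a documented anchor; the other
    landmarks use classic proportional-grid distances trimmed to the
    grid's physical extent.  These are package conventions, configurable
    per deployment; they are NOT anatomical measurements.
    """
    space = space or AtlasSpace()
    ex, ey, ez = space.extent_mm
    cx = ex / 2.0
    ac_y, ac_z = 0.58 * ey, 42.0
    return {
        "AC": [cx, ac_y, ac_z],
        "PC": [cx, ac_y - 23.0, ac_z],
        "L": [cx - 68.0, ac_y, ac_z],
        "R": [cx + 68.0, ac_y, ac_z],
        "A": [cx, ac_y + 68.0, ac_z],
        "P": [cx, ac_y - 94.0, ac_z],
        "S": [cx, ac_y, ac_z + 74.0],
        "I": [cx, ac_y, ac_z - 42.0],
    }


def _pwl(x: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Piecewise-linear map through (xs, ys), linearly extrapolated."""
    x = np.asarray(x, dtype=float)
    j = np.clip(np.searchsorted(xs, x, side="right"), 1, len(xs) - 1)
    x0, x1 = xs[j - 1], xs[j]
    y0, y1 = ys[j - 1], ys[j]
    return y0 + (x - x0) * (y1 - y0) / (x1 - x0)


@dataclass
class TalairachTransform:
    """Piecewise-affine map: native world mm -> atlas world mm.

    ``rotation`` rows are the native frame axes (lateral, AP, SI) so that
    frame coordinates are ``rotation @ (p - ac_native)``.  Knot arrays
    hold the per-axis breakpoints in native frame coordinates and their
    atlas-side images (relative to the atlas AC).
    """

    rotation: np.ndarray
    ac_native: np.ndarray
    native_knots: tuple[np.ndarray, np.ndarray, np.ndarray]
    atlas_knots: tuple[np.ndarray, np.ndarray, np.ndarray]
    atlas_ac: np.ndarray

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        u = (pts - self.ac_native) @ self.rotation.T
        out = np.empty_like(u)
        for axis in range(3):
            out[:, axis] = _pwl(
                u[:, axis], self.native_knots[axis], self.atlas_knots[axis]
            )
        return out + self.atlas_ac

    def apply_inverse(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        x = pts - self.atlas_ac
        u = np.empty_like(x)
        for axis in range(3):
            u[:, axis] = _pwl(
                x[:, axis], self.atlas_knots[axis], self.native_knots[axis]
            )
        return u @ self.rotation + self.ac_native

    def block_determinants(self) -> np.ndarray:
        """Determinants of the linear parts of the 12 affine blocks.

        Order: x-segment (2) x y-segment (3) x z-segment (2), C-order.
        """
        slopes = []
        for axis in range(3):
            nk, ak = self.native_knots[axis], self.atlas_knots[axis]
            slopes.append(np.diff(ak) / np.diff(nk))
        dets = []
        det_r = np.linalg.det(self.rotation)
        for sx in slopes[0]:
            for sy in slopes[1]:
                for sz in slopes[2]:
                    dets.append(sx * sy * sz * det_r)
        return np.asarray(dets)


def _frame_from_landmarks(lm: LandmarkSet) -> np.ndarray:
    ey = lm.ac - lm.pc
    ny = np.linalg.norm(ey)
    if ny < 1e-9:
        raise LandmarkError("AC and PC coincide")
    ey = ey / ny
    ex = lm.msp_normal - (lm.msp_normal @ ey) * ey
    nx = np.linalg.norm(ex)
    if nx < 1e-6:
        raise LandmarkError("msp_normal is parallel to the AC-PC axis")
    ex = ex / nx
    if (lm.r - lm.ac) @ ex < 0:
        ex = -ex
    ez = np.cross(ex, ey)
    return np.vstack([ex, ey, ez])


def fit_transform(
    landmarks: LandmarkSet,
    space: Optional[AtlasSpace] = None,
    atlas_landmarks: Optional[Mapping] = None,
) -> TalairachTransform:
    """Fit the 12-block proportional-grid transform from one case's landmarks.

    The transform maps each native landmark exactly onto its atlas
    counterpart and is piecewise linear in between.  Raises
    LandmarkError for coincident or mis-ordered landmarks.
    """
    space = space or AtlasSpace()
    atl = atlas_landmarks or default_atlas_landmarks_mm(space)
    rot = _frame_from_landmarks(landmarks)

    def u(pt: np.ndarray) -> np.ndarray:
        return rot @ (pt - landmarks.ac)

    ux_l, ux_r = u(landmarks.l)[0], u(landmarks.r)[0]
    uy_p, uy_pc, uy_a = u(landmarks.p)[1], u(landmarks.pc)[1], u(landmarks.a)[1]
    uz_i, uz_s = u(landmarks.i)[2], u(landmarks.s)[2]
    if not ux_l < 0 < ux_r:
        raise LandmarkError("L and R must lie on opposite sides of the MSP")
    if not uy_p < uy_pc < 0 < uy_a:
        raise LandmarkError(
            "A must be anterior to AC and P posterior to PC along the AC-PC axis"
        )
    if not uz_i < 0 < uz_s:
        raise LandmarkError("S must be above and I below the AC-PC plane")

    atl = {k: np.asarray(v, dtype=float) for k, v in atl.items()}
    ac_a = atl["AC"]
    ax = np.array([atl["L"][0] - ac_a[0], 0.0, atl["R"][0] - ac_a[0]])
    ay = np.array(
        [atl["P"][1] - ac_a[1], atl["PC"][1] - ac_a[1], 0.0, atl["A"][1] - ac_a[1]]
    )
    az = np.array([atl["I"][2] - ac_a[2], 0.0, atl["S"][2] - ac_a[2]])

    native_knots = (
        np.array([ux_l, 0.0, ux_r]),
        np.array([uy_p, uy_pc, 0.0, uy_a]),
        np.array([uz_i, 0.0, uz_s]),
    )
    for nk, ak in zip(native_knots, (ax, ay, az)):
        if not (np.all(np.diff(nk) > 0) and np.all(np.diff(ak) > 0)):
            raise LandmarkError("landmark knots are not strictly ordered")
    return TalairachTransform(
        rotation=rot,
        ac_native=landmarks.ac.copy(),
        native_knots=native_knots,
        atlas_knots=(ax, ay, az),
        atlas_ac=ac_a,
    )


def normalize_contour(
    contour: ContourFile,
    transform: TalairachTransform,
    space: Optional[AtlasSpace] = None,
) -> ContourFile:
    """Resample a native-frame mask onto the atlas grid by pull-back.

    An atlas voxel is foreground iff its center, mapped back through the
    inverse transform, falls inside a foreground native voxel (nearest
    neighbor).  Raises LesionOutsideGridError when nothing survives.
    """
    space = space or AtlasSpace()
    if contour.frame != "native":
        raise ValueError("normalize_contour expects a native-frame contour")
    native_aff = contour.affine
    native_inv = np.linalg.inv(native_aff)
    vs = np.asarray(space.voxel_size)

    # forward-map foreground voxel centers to bound the atlas-side region
    idx = np.argwhere(contour.mask).astype(float)
    native_mm = idx @ native_aff[:3, :3].T + native_aff[:3, 3]
    atlas_vox = transform.apply(native_mm) / vs
    native_extent = np.abs(native_aff[:3, :3]).sum(axis=1).max()
    pad = int(np.ceil(native_extent / vs.min())) + 2
    lo = np.maximum(np.floor(atlas_vox.min(axis=0)).astype(int) - pad, 0)
    hi = np.minimum(
        np.ceil(atlas_vox.max(axis=0)).astype(int) + pad + 1, np.asarray(space.dims)
    )
    if np.any(lo >= hi):
        raise LesionOutsideGridError(
            f"contour {contour.case_id} maps entirely outside the atlas grid"
        )

    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    box = np.stack([g.reshape(-1) for g in grids], axis=1)
    back_mm = transform.apply_inverse(box * vs)
    nvox = np.rint(back_mm @ native_inv[:3, :3].T + native_inv[:3, 3]).astype(int)
    inside = np.all((nvox >= 0) & (nvox < np.asarray(contour.mask.shape)), axis=1)
    fg = np.zeros(box.shape[0], dtype=bool)
    fg[inside] = contour.mask[tuple(nvox[inside].T)]
    if not fg.any():
        raise LesionOutsideGridError(
            f"contour {contour.case_id} maps entirely outside the atlas grid"
        )
    out = np.zeros(space.dims, dtype=bool)
    out[tuple(box[fg].T)] = True
    return ContourFile(case_id=contour.case_id, mask=out, space=space, frame="atlas")
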