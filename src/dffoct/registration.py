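"""Rigid landmark-based registration between imaging modalities.

The correlative procedure re-implemented here aligns the dynamic-OCT frame
with fluorescence frames using only rotation and translation — no scaling,
shear or reflection — so that shapes are never warped.  A least-squares
rigid fit (Kabsch/Procrustes without scaling) recovers the transform from
paired landmarks; transforms compose and invert as a group, so a cascade of
pairwise fits (e.g. high-magnification → overview → OCT) can be collapsed
into a single mapping.  Coarse alignment of a small field inside a larger
overview is provided by normalized cross-correlation template matching.

All transforms are computed and stored in micrometres, using the pixel-size
metadata of the images involved; conversion to pixel space happens only at
resampling time.  Coordinates are (y, x[, z]) with 0-based voxel indices and
physical coordinate = index × pixel_size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import match_template

__all__ = [
    "RigidTransform",
    "LandmarkSet",
    "FitReport",
    "fit_rigid",
    "compose",
    "invert",
    "template_locate",
    "resample_stack",
    "max_intensity_projection",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation in 2 or 3 dimensions; maps x → R x + t (µm).

    The rotation must be orthonormal with determinant +1 (proper rotation:
    no scaling, shear or reflection).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] not in (2, 3):
            raise ValueError("rotation must be a 2x2 or 3x3 matrix")
        if t.shape != (R.shape[0],):
            raise ValueError("translation length must match dimensionality")
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflection detected (det(R) < 0); only proper "
                             "rotations are allowed")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def dim(self) -> int:
        return self.rotation.shape[0]

    @classmethod
    def identity(cls, dim: int = 2) -> "RigidTransform":
        return cls(np.eye(dim), np.zeros(dim))

    @classmethod
    def from_angle(
        cls, angle_rad: float, translation=(0.0, 0.0)
    ) -> "RigidTransform":
        """2-D transform from an in-plane rotation angle (about the origin)."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        return cls(np.array([[c, -s], [s, c]]), np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, dim) array of points in µm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.dim:
            raise ValueError(f"points must be (n, {self.dim})")
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Cascade: returns the transform x → other(self(x))."""
        if other.dim != self.dim:
            raise ValueError("dimensionality mismatch in compose")
        return RigidTransform(
            other.rotation @ self.rotation,
            other.rotation @ self.translation + other.translation,
        )

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # --- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dimensionality": self.dim,
            "rotation_row_major": self.rotation.ravel().tolist(),
            "translation_um": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        dim = int(d["dimensionality"])
        R = np.asarray(d["rotation_row_major"], dtype=float).reshape(dim, dim)
        return cls(R, np.asarray(d["translation_um"], dtype=float))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LandmarkSet:
    """Paired points (µm) in frames A and B with per-pair identifiers."""

    points_a: np.ndarray  # (n, dim)
    points_b: np.ndarray  # (n, dim)
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points_a = np.atleast_2d(np.asarray(self.points_a, dtype=float))
        self.points_b = np.atleast_2d(np.asarray(self.points_b, dtype=float))
        if self.points_a.shape != self.points_b.shape:
            raise ValueError("landmark counts/dimensions differ between frames")
        if self.points_a.shape[1] not in (2, 3):
            raise ValueError("landmarks must be 2-D or 3-D")
        if len(self.points_a) < 3:
            raise ValueError("need at least 3 landmark pairs")
        if not self.ids:
            self.ids = list(range(1, len(self.points_a) + 1))

    @property
    def dim(self) -> int:
        return self.points_a.shape[1]

    def __len__(self) -> int:
        return len(self.points_a)


@dataclass
class FitReport:
    """Residual diagnostics of a rigid fit."""

    residuals_um: np.ndarray  # per-landmark Euclidean residual
    rms_um: float
    condition_number: float


def fit_rigid(landmarks: LandmarkSet) -> tuple[RigidTransform, FitReport]:
    """Least-squares rigid transform A → B (Kabsch/Procrustes, no scaling).

    Solves min_{R,t} Σ ||R a_i + t − b_i||² with det(R) = +1 enforced via the
    sign-corrected SVD.  Degenerate (collinear/coincident) configurations are
    rejected with the observed condition number in the message.
    """
    A, B = landmarks.points_a, landmarks.points_b
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinearity check on the centred source cloud
    sv = np.linalg.svd(A0, compute_uv=False)
    # the rotation is unidentifiable when the cloud is (near-)collinear:
    # require a healthy second singular value
    cond = float(sv[0] / sv[1]) if sv[1] > 0 else np.inf
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError(
            f"degenerate landmark configuration (condition number {cond:.3g}): "
            "points are collinear or coincident"
        )
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(landmarks.dim)
    D[-1, -1] = d
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t)
    resid = np.linalg.norm(transform.apply(A) - B, axis=1)
    report = FitReport(resid, float(np.sqrt(np.mean(resid**2))), cond)
    return transform, report


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Cascaded transform x → t2(t1(x))."""
    return t1.compose(t2)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def template_locate(
    template: np.ndarray,
    reference: np.ndarray,
    *,
    min_score: float | None = None,
) -> tuple[tuple[int, int], float]:
    """Locate a small field inside a larger one by normalized cross-correlation.

    Returns the (row, col) offset of the template's top-left corner in the
    reference and the peak correlation score in [-1, 1].  If ``min_score`` is
    given and the peak falls below it, the match is flagged by raising
    ``ValueError`` (caller decides how to proceed).
    """
    template = np.asarray(template, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if template.ndim != 2 or reference.ndim != 2:
        raise ValueError("template_locate expects 2-D images")
    if any(ts > rs for ts, rs in zip(template.shape, reference.shape)):
        raise ValueError("template must not be larger than the reference")
    if template.std() == 0:
        raise ValueError("flat template (zero variance) cannot be localized")
    ncc = match_template(reference, template, pad_input=False)
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    score = float(ncc[peak])
    if min_score is not None and score < min_score:
        raise ValueError(
            f"template match score {score:.3f} below acceptance threshold "
            f"{min_score:.3f}"
        )
    return (int(peak[0]), int(peak[1])), score


def resample_stack(
    stack: np.ndarray,
    transform: RigidTransform,
    *,
    pixel_size: float = 1.0,
    output_shape: tuple[int, ...] | None = None,
    order: int = 1,
    cval: float = np.nan,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an image (2-D) or stack (leading non-spatial axis) under a
    rigid transform.

    The transform maps source coordinates (µm) to target coordinates (µm);
    the output grid samples the target frame.  Returns ``(resampled, valid)``
    where ``valid`` is False wherever the source voxel fell outside the
    field (those voxels hold ``cval``).
    """
    if transform.dim != 2:
        raise ValueError("resample_stack currently supports 2-D transforms")
    data = np.asarray(stack, dtype=float)
    single = data.ndim == 2
    if single:
        data = data[None]
    if output_shape is None:
        output_shape = data.shape[1:]
    inv = transform.invert()
    matrix = inv.rotation
    offset = inv.translation / pixel_size
    out = np.stack(
        [
            ndi.affine_transform(
                frame, matrix, offset=offset, output_shape=output_shape,
                order=order, cval=np.nan, mode="constant",
            )
            for frame in data
        ]
    )
    valid = ~np.isnan(out).any(axis=0)
    out = np.where(np.isnan(out), cval, out)
    if single:
        out = out[0]
    return out, valid


def max_intensity_projection(stack: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-pixel maximum along the z axis (identity for single-plane input)."""
    data = np.asarray(stack)
    if data.ndim == 2:
        return data.copy()
    return data.max(axis=axis)
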