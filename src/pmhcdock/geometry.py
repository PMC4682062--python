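"""Rigid-body superposition (Kabsch) and RMSD.

This is the numeric core shared by consensus pose selection, the cleft
check and cross-docking evaluation. Superposition uses
:func:`scipy.spatial.transform.Rotation.align_vectors`, which solves the
orthogonal Procrustes problem with the reflection excluded, i.e. the Kabsch
solution with a guaranteed proper rotation (det = +1). RMSD is plain
unweighted atomic RMSD in Angstrom.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError
from .structure_io import Selection, Structure, select_atoms

ORTHONORMALITY_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation (Angstrom)."""
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rigid transform needs a 3x3 rotation and 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise GeometryError(f"rotation determinant {np.linalg.det(R):.8f} != +1")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-6:
            raise GeometryError("rotation matrix is not orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclasses.dataclass(frozen=True)
class RmsdValue:
    value: float
    n_atoms: int

    def __post_init__(self):
        if self.n_atoms < 1:
            raise GeometryError("RMSD over zero atoms is undefined")
        if not np.isfinite(self.value) or self.value < 0:
            raise GeometryError(f"invalid RMSD value {self.value}")

    def __float__(self) -> float:
        return self.value


def _as_coords(x, label: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError(f"{label}: expected an (n, 3) coordinate array, "
                            f"got shape {arr.shape}")
    return arr


def rmsd(coords_a, coords_b) -> RmsdValue:
    """Root-mean-square deviation between corresponding atoms; no fitting."""
    a = _as_coords(coords_a, "coords_a")
    b = _as_coords(coords_b, "coords_b")
    if a.shape[0] != b.shape[0]:
        raise GeometryError(
            f"coordinate sets differ in length: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise GeometryError("empty coordinate sets")
    value = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    return RmsdValue(value=value, n_atoms=a.shape[0])


def kabsch_superpose(mobile, reference) -> tuple[RigidTransform, RmsdValue]:
    """Least-squares optimal proper rigid superposition of mobile onto reference.

    Returns the transform and the post-fit RMSD. Requires at least 3
    corresponding atoms that are not all collinear.
    """
    mob = _as_coords(mobile, "mobile")
    ref = _as_coords(reference, "reference")
    if mob.shape[0] != ref.shape[0]:
        raise GeometryError(
            f"coordinate sets differ in length: {mob.shape[0]} vs {ref.shape[0]}")
    n = mob.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs >= 3 atoms, got {n}")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    A = mob - mob_c
    if np.linalg.matrix_rank(A, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) mobile coordinates")
    rot, _ = Rotation.align_vectors(ref - ref_c, A)
    R = rot.as_matrix()
    transform = RigidTransform(R, ref_c - R @ mob_c)
    return transform, rmsd(transform.apply(mob), ref)


def fit_then_rmsd(mobile_struct: Structure, reference_struct: Structure,
                  fit_selector: Selection | str,
                  measure_selector: Selection | str) -> RmsdValue:
    """Superpose on one atom set, measure RMSD on another.

    The rigid transform is computed from ``fit_selector`` atoms of both
    structures and applied to the whole mobile structure before measuring the
    RMSD over ``measure_selector`` atoms — e.g. fit on MHC Calpha, measure on
    the peptide.
    """
    fit_mob = select_atoms(mobile_struct, fit_selector)
    fit_ref = select_atoms(reference_struct, fit_selector)
    transform, _ = kabsch_superpose(fit_mob, fit_ref)
    meas_mob = select_atoms(mobile_struct, measure_selector)
    meas_ref = select_atoms(reference_struct, measure_selector)
    return rmsd(transform.apply(meas_mob), meas_ref)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an (unnormalized) axis through the origin."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise GeometryError("rotation axis has zero length")
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm).as_matrix()


def rotate_points_about_axis(points: np.ndarray, origin: np.ndarray,
                             axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis``."""
    R = rotation_about_axis(axis, angle_deg)
    pts = np.asarray(points, dtype=float)
    origin = np.asarray(origin, dtype=float)
    return (pts - origin) @ R.T + origin
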