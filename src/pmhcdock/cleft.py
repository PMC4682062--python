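"""Docking search box over the alpha1/alpha2 cleft and pose position checks.

The grid box is anchored on the template's epitope pattern: centred on the
pattern peptide's heavy-atom centroid and sized to its extent plus padding.
After docking, each pose is screened for the two failure modes a groove-bound
peptide can exhibit — leaving the cleft, and lying inverted (N/C termini
swapped or protruding). The thresholds quantifying the check are explicit
config knobs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import StructureError
from .geometry import RigidTransform
from .registry import TemplateEntry
from .structure_io import Structure, select_atoms

DEFAULT_PADDING = 8.0  # Angstrom added on each side of the pattern extent


@dataclasses.dataclass(frozen=True)
class GridBox:
    """Search box: centre, edge lengths and an orthonormal frame (Angstrom).

    ``axes`` rows are the box's edge directions; the identity frame gives the
    common axis-aligned docking-engine box convention.
    """
    center: np.ndarray
    dimensions: np.ndarray
    axes: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        d = np.asarray(self.dimensions, dtype=float)
        A = np.asarray(self.axes, dtype=float)
        if c.shape != (3,) or d.shape != (3,) or A.shape != (3, 3):
            raise StructureError("grid box needs 3-vector center/dimensions "
                                 "and a 3x3 frame")
        if np.any(d <= 0):
            raise StructureError(f"box dimensions must be positive, got {d}")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "dimensions", d)
        object.__setattr__(self, "axes", A)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (closed) box."""
        local = (np.atleast_2d(points) - self.center) @ self.axes.T
        half = self.dimensions / 2.0
        return np.all(np.abs(local) <= half + 1e-9, axis=1)

    def transformed(self, transform: RigidTransform) -> "GridBox":
        return GridBox(center=transform.apply(self.center[None, :])[0],
                       dimensions=self.dimensions.copy(),
                       axes=self.axes @ transform.rotation.T)

    def to_dict(self) -> dict:
        return {"center": [round(float(v), 3) for v in self.center],
                "dimensions": [round(float(v), 3) for v in self.dimensions]}


@dataclasses.dataclass(frozen=True)
class CleftCheckParams:
    min_fraction_inside: float = 0.9
    max_anchor_distance: float = 6.0  # Angstrom, each terminal Calpha
    min_orientation_dot: float = 0.0  # N->C vector alignment with template


@dataclasses.dataclass(frozen=True)
class CleftCheckReport:
    passed: bool
    fraction_inside: float
    n_term_anchor_distance: float
    c_term_anchor_distance: float
    orientation_dot: float
    failure_reasons: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "fraction_inside": round(self.fraction_inside, 4),
            "n_term_anchor_distance": round(self.n_term_anchor_distance, 3),
            "c_term_anchor_distance": round(self.c_term_anchor_distance, 3),
            "orientation_dot": round(self.orientation_dot, 4),
            "failure_reasons": list(self.failure_reasons),
        }


def compute_grid_box(template: TemplateEntry,
                     padding: float = DEFAULT_PADDING) -> GridBox:
    """Box centred on the pattern peptide, extent + 2 x padding per axis."""
    if template.pattern_backbone is None:
        raise StructureError(
            f"template {template.allotype} has no pattern peptide")
    if padding < 0:
        raise StructureError(f"padding must be >= 0, got {padding}")
    coords = select_atoms(template.pattern_backbone, "heavy")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    # bounding-box midpoint, not centroid: guarantees containment of the
    # whole pattern for every padding, including the tight padding-0 box
    center = (lo + hi) / 2.0
    return GridBox(center=center, dimensions=(hi - lo) + 2.0 * padding)


def _terminal_ca(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    ca = select_atoms(structure, "CA")
    return ca[0], ca[-1]


def check_pose_in_cleft(pose: Structure, template: TemplateEntry,
                        box: GridBox,
                        params: CleftCheckParams = CleftCheckParams()
                        ) -> CleftCheckReport:
    """Screen a docked peptide pose for position/orientation errors.

    Passing requires (a) at least ``min_fraction_inside`` of the pose's heavy
    atoms inside the box, (b) both terminal Calpha atoms within
    ``max_anchor_distance`` of the template pattern's corresponding termini
    (catches inversion and protruding termini), and (c) a positive projection
    of the pose's N->C axis on the template's.
    """
    pattern = template.pattern_backbone
    if pattern is None:
        raise StructureError(
            f"template {template.allotype} has no pattern peptide")
    pose_residues = sum(len(v) for v in pose.chains().values())
    if pose_residues != template.epitope_length:
        raise StructureError(
            f"pose has {pose_residues} residues, template expects "
            f"{template.epitope_length}")

    heavy = select_atoms(pose, "heavy")
    fraction = float(np.mean(box.contains(heavy)))

    pose_n, pose_c = _terminal_ca(pose)
    pat_n, pat_c = _terminal_ca(pattern)
    n_dist = float(np.linalg.norm(pose_n - pat_n))
    c_dist = float(np.linalg.norm(pose_c - pat_c))

    v_pose = pose_c - pose_n
    v_pat = pat_c - pat_n
    denom = np.linalg.norm(v_pose) * np.linalg.norm(v_pat)
    dot = float(np.dot(v_pose, v_pat) / denom) if denom > 1e-9 else 0.0

    reasons: list[str] = []
    if fraction < params.min_fraction_inside:
        reasons.append("outside_cleft")
    if dot <= params.min_orientation_dot:
        reasons.append("inverted")
    if n_dist > params.max_anchor_distance or c_dist > params.max_anchor_distance:
        reasons.append("protruding_terminus")

    return CleftCheckReport(
        passed=not reasons,
        fraction_inside=fraction,
        n_term_anchor_distance=n_dist,
        c_term_anchor_distance=c_dist,
        orientation_dot=dot,
        failure_reasons=tuple(reasons),
    )
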