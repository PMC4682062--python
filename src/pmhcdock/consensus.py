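"""Consensus best-pose selection from a docking ensemble.

A docking stage yields up to 20 peptide conformations, each scored with a
binding energy (BE, kcal/mol, lower = stronger predicted binding). The best
pose is chosen in three steps:

1. cut-off filter: keep poses whose BE is at or below the ensemble's mean BE
   (the cut-off ``Co``); the minimum is never above the mean, so at least one
   pose always survives;
2. all-pairs RMSD: superpose every retained pair on peptide heavy atoms
   (Kabsch) and record the post-fit RMSD;
3. average-structure selection: pick the retained pose with the lowest mean
   RMSD to the other retained poses — the conformation most representative
   of the ensemble — breaking exact ties by lower BE, then lower run index.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .errors import ConsensusError
from .geometry import kabsch_superpose
from .structure_io import Structure, select_atoms

_TIE_TOL = 1e-9


@dataclasses.dataclass
class DockedPose:
    coords: Structure  # peptide only
    binding_energy: float  # kcal/mol
    run_index: int

    def __post_init__(self):
        if not np.isfinite(self.binding_energy):
            raise ConsensusError(
                f"pose {self.run_index}: non-finite binding energy")


@dataclasses.dataclass
class PoseEnsemble:
    poses: list[DockedPose]

    def __post_init__(self):
        if not self.poses:
            raise ConsensusError("empty pose ensemble")
        counts = {sum(len(v) for v in p.coords.chains().values())
                  for p in self.poses}
        if len(counts) > 1:
            raise ConsensusError(
                f"poses disagree on residue count: {sorted(counts)}")

    def __len__(self) -> int:
        return len(self.poses)

    def binding_energies(self) -> np.ndarray:
        return np.array([p.binding_energy for p in self.poses], dtype=float)


@dataclasses.dataclass
class ConsensusResult:
    cutoff: float  # Co, kcal/mol
    retained_indices: list[int]  # 0-based positions into ensemble.poses
    rmsd_matrix: np.ndarray  # pairwise, over retained poses only, Angstrom
    row_means: np.ndarray  # mean RMSD of each retained pose to the others
    selected_index: int  # 0-based position into ensemble.poses

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "retained_indices": list(self.retained_indices),
            "rmsd_matrix": np.round(self.rmsd_matrix, 6).tolist(),
            "row_means": np.round(self.row_means, 6).tolist(),
            "selected_index": self.selected_index,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compute_cutoff(ensemble: PoseEnsemble) -> float:
    """Cut-off Co = arithmetic mean of all pose binding energies."""
    return float(np.mean(ensemble.binding_energies()))


def filter_poses(ensemble: PoseEnsemble, cutoff: float) -> list[int]:
    """Indices of poses with BE <= cutoff (non-strict, so the all-equal
    ensemble keeps everything; the minimum-BE pose always survives)."""
    bes = ensemble.binding_energies()
    return [int(i) for i in np.flatnonzero(bes <= cutoff)]


def _pose_heavy_coords(pose: DockedPose) -> np.ndarray:
    return select_atoms(pose.coords, "heavy")


def pairwise_rmsd_matrix(ensemble: PoseEnsemble,
                         retained: list[int]) -> np.ndarray:
    """Symmetric fit-then-RMSD matrix over the retained poses.

    Each pair is superposed on peptide heavy atoms and the post-fit RMSD over
    the same atoms recorded; the diagonal is zero.
    """
    if not retained:
        raise ConsensusError("no retained poses to compare")
    coords = [_pose_heavy_coords(ensemble.poses[i]) for i in retained]
    m = len(retained)
    matrix = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            _, fit = kabsch_superpose(coords[i], coords[j])
            matrix[i, j] = matrix[j, i] = fit.value
    return matrix


def select_from_matrix(matrix: np.ndarray, binding_energies: np.ndarray,
                       run_indices: np.ndarray) -> tuple[int, np.ndarray]:
    """Lowest-row-mean selection with BE then run-index tie-breaks.

    Returns the winning row position and the row means (mean over the other
    rows; 0 for a singleton).
    """
    matrix = np.asarray(matrix, dtype=float)
    m = matrix.shape[0]
    if m == 1:
        return 0, np.zeros(1)
    row_means = matrix.sum(axis=1) / (m - 1)
    best_mean = row_means.min()
    tied = np.flatnonzero(row_means <= best_mean + _TIE_TOL)
    order = sorted(tied, key=lambda k: (binding_energies[k], run_indices[k]))
    return int(order[0]), row_means


def select_best(ensemble: PoseEnsemble, retained: list[int],
                matrix: np.ndarray, cutoff: float) -> ConsensusResult:
    """Complete the consensus: pick the average structure among retained."""
    bes = ensemble.binding_energies()[retained]
    runs = np.array([ensemble.poses[i].run_index for i in retained])
    pos, row_means = select_from_matrix(matrix, bes, runs)
    return ConsensusResult(
        cutoff=cutoff,
        retained_indices=list(retained),
        rmsd_matrix=matrix,
        row_means=row_means,
        selected_index=int(retained[pos]),
    )


def run_consensus(ensemble: PoseEnsemble) -> ConsensusResult:
    """Full cut-off -> pairwise-RMSD -> average-structure procedure."""
    cutoff = compute_cutoff(ensemble)
    retained = filter_poses(ensemble, cutoff)
    matrix = pairwise_rmsd_matrix(ensemble, retained)
    return select_best(ensemble, retained, matrix, cutoff)


def selected_pose(ensemble: PoseEnsemble, result: ConsensusResult) -> DockedPose:
    return ensemble.poses[result.selected_index]


def load_ensemble(poses_dir, energies_csv) -> PoseEnsemble:
    """Read an ensemble from a directory of pose PDBs plus a BE table.

    The CSV needs columns ``run_index`` and ``binding_energy``; an optional
    ``pose_file`` column names each pose file, defaulting to
    ``pose_<run_index>.pdb`` inside ``poses_dir``.
    """
    import pandas as pd

    from .structure_io import read_pdb

    from pathlib import Path
    poses_dir = Path(poses_dir)
    table = pd.read_csv(energies_csv)
    for col in ("run_index", "binding_energy"):
        if col not in table.columns:
            raise ConsensusError(f"{energies_csv}: missing column {col!r}")
    poses = []
    for row in table.itertuples(index=False):
        fname = getattr(row, "pose_file", None) or f"pose_{int(row.run_index)}.pdb"
        poses.append(DockedPose(
            coords=read_pdb(poses_dir / fname),
            binding_energy=float(row.binding_energy),
            run_index=int(row.run_index),
        ))
    return PoseEnsemble(poses)
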