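"""Synthetic test inputs: toy pMHC-like complexes, ensembles, benchmarks.

Every contract exercised by the test suite is geometric or statistical, so
the toy structures only need to be geometrically sane, not energetically
realistic: an ideal-geometry extended poly-alanine peptide lying in a cleft
formed by two straight chain segments (standing in for the alpha1/alpha2
walls) over a floor segment, plus an optional beta-2-microglobulin-sized
chain. All generators are pure functions of their spec — the same spec gives
bit-identical output.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np

from . import topology
from .backends import perturb_side_chains
from .consensus import DockedPose, PoseEnsemble, run_consensus
from .epitope_builder import thread_peptide
from .errors import FixtureError
from .registry import TemplateEntry
from .structure_io import AtomRecord, Structure, write_pdb

RESIDUE_SPACING = 3.5  # Angstrom between consecutive Calpha along a strand


@dataclasses.dataclass(frozen=True)
class ToyComplexSpec:
    peptide_length: int = 9
    heavy_chain_length: int = 180
    include_b2m: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 8 <= self.peptide_length <= 10:
            raise FixtureError(
                f"toy peptide length must be 8-10, got {self.peptide_length}")
        if self.heavy_chain_length < 16:
            raise FixtureError("toy heavy chain needs >= 16 residues")


@dataclasses.dataclass(frozen=True)
class EnsembleSpec:
    n_poses: int = 20
    be_values: tuple[float, ...] | None = None
    be_mean: float = -8.0
    be_sd: float = 1.0
    chi_sigma_deg: float = 0.0
    rigid_trans_sigma: float = 0.0
    rigid_rot_sigma_deg: float = 0.0
    planted_consensus: int | None = None  # 0-based pose position
    seed: int = 0

    def __post_init__(self):
        if self.n_poses < 1:
            raise FixtureError("ensemble needs >= 1 pose")
        if self.be_values is not None and len(self.be_values) != self.n_poses:
            raise FixtureError(
                f"{len(self.be_values)} BE values for {self.n_poses} poses")
        if self.planted_consensus is not None and not (
                0 <= self.planted_consensus < self.n_poses):
            raise FixtureError("planted_consensus out of range")


def _extended_backbone(length: int, origin: np.ndarray,
                       direction: np.ndarray = np.array([1.0, 0.0, 0.0])
                       ) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry extended (beta-strand-like) backbone coordinates."""
    phi, psi, omega = -139.0, 135.0, 180.0
    coords: list[dict[str, np.ndarray]] = []
    # seed triad along the requested direction
    d = direction / np.linalg.norm(direction)
    up = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    side = np.cross(up, d)
    n0 = origin
    ca0 = origin + 1.458 * d
    c0 = ca0 + 1.525 * (0.423 * d + 0.906 * side)
    res = {"N": n0, "CA": ca0, "C": c0}
    coords.append(res)
    for _ in range(1, length):
        prev = coords[-1]
        n = topology.place_atom(prev["N"], prev["CA"], prev["C"],
                                1.329, 116.2, psi)
        ca = topology.place_atom(prev["CA"], prev["C"], n, 1.458, 121.7, omega)
        c = topology.place_atom(prev["C"], n, ca, 1.525, 111.2, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    for i, res in enumerate(coords):
        if i + 1 < length:
            nxt = coords[i + 1]["N"]
            res["O"] = topology.place_atom(nxt, res["CA"], res["C"],
                                           1.231, 120.5, 180.0)
        else:
            res["O"] = topology.place_atom(res["N"], res["CA"], res["C"],
                                           1.231, 120.5, -45.0)
            res["OXT"] = topology.place_atom(res["N"], res["CA"], res["C"],
                                             1.231, 120.5, 135.0)
    return coords


def _strand_atoms(chain_id: str, start_resnum: int, length: int,
                  origin: np.ndarray, direction: np.ndarray,
                  residue_name: str = "GLY") -> list[AtomRecord]:
    backbone = _extended_backbone(length, origin, direction)
    atoms = []
    for i, res in enumerate(backbone):
        names = list(topology.BACKBONE_ATOMS)
        for name in names:
            atoms.append(AtomRecord(
                serial=0, name=name,
                element="N" if name == "N" else ("O" if name == "O" else "C"),
                residue_name=residue_name, chain_id=chain_id,
                residue_number=start_resnum + i, coords=res[name].copy()))
    return atoms


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, TemplateEntry]:
    """Toy pMHC-I-like complex and a registry entry describing it.

    Chain A: heavy-chain stand-in — two parallel wall strands flanking the
    peptide groove at y = +/-7 A plus floor strands at z = -6 A below it.
    Chain B (optional): a 99-residue beta-2-microglobulin-sized strand well
    away from the groove. Chain C: the peptide, an ideal extended
    poly-alanine strand lying along x between the walls. The returned
    template registers the complex as a test allotype whose epitope pattern
    is the toy peptide's own backbone.
    """
    L = spec.peptide_length
    atoms: list[AtomRecord] = []

    # heavy chain: walls and floor, split into 4 segments of equal length
    seg = spec.heavy_chain_length // 4
    rest = spec.heavy_chain_length - 3 * seg
    span = (L - 1) * RESIDUE_SPACING
    x0 = -(seg * RESIDUE_SPACING - span) / 2.0  # roughly centre walls on peptide
    layout = [
        (seg, np.array([x0, 7.0, 0.0]), np.array([1.0, 0.0, 0.0])),
        (seg, np.array([x0, -7.0, 0.0]), np.array([1.0, 0.0, 0.0])),
        (seg, np.array([x0, 3.0, -6.0]), np.array([1.0, 0.0, 0.0])),
        (rest, np.array([x0, -3.0, -6.0]), np.array([1.0, 0.0, 0.0])),
    ]
    resnum = 1
    for n_res, origin, direction in layout:
        atoms.extend(_strand_atoms("A", resnum, n_res, origin, direction))
        resnum += n_res

    if spec.include_b2m:
        atoms.extend(_strand_atoms("B", 1, 99,
                                   np.array([0.0, 0.0, -15.0]),
                                   np.array([1.0, 0.0, 0.0])))

    # peptide: extended poly-ALA with CB, plus terminal OXT
    backbone = _extended_backbone(L, np.array([0.0, 0.0, 0.0]))
    pep_atoms: list[AtomRecord] = []
    for i, res in enumerate(backbone):
        placed = dict(res)
        name_order = list(topology.BACKBONE_ATOMS)
        cb_entry = topology.SIDE_CHAIN_ICS["ALA"][0]
        _, refs, r, theta, tau = cb_entry
        placed["CB"] = topology.place_atom(*(placed[x] for x in refs),
                                           r, theta, tau)
        name_order.append("CB")
        if i == L - 1:
            name_order.append("OXT")
        for name in name_order:
            pep_atoms.append(AtomRecord(
                serial=0, name=name,
                element="N" if name == "N" else
                        ("O" if name in ("O", "OXT") else "C"),
                residue_name="ALA", chain_id="C",
                residue_number=i + 1, coords=placed[name].copy()))
    atoms.extend(pep_atoms)
    for serial, atom in enumerate(atoms, start=1):
        atom.serial = serial
    complex_structure = Structure(atoms)

    pattern_atoms = [a.copy() for a in pep_atoms
                     if a.name in topology.BACKBONE_ATOMS
                     or a.name == topology.TERMINAL_OXYGEN]
    template = TemplateEntry(
        allotype=f"TOY-{L}",
        epitope_length=L,
        mhc_donor_id=f"toy-donor-{L}",
        pattern_id=f"toy-pattern-{L}",
        pattern_sequence="A" * L,
        mhc_donor=complex_structure.copy(),
        pattern_backbone=Structure(pattern_atoms),
    )
    return complex_structure, template


def make_ensemble(template: TemplateEntry, spec: EnsembleSpec) -> PoseEnsemble:
    """Pose ensemble derived from the template's (threaded) peptide.

    Per-pose side-chain and rigid-body jitter follow the requested sigmas.
    With ``planted_consensus`` set, that pose stays at the threaded base
    conformation while every other pose receives its own large, distinct
    side-chain displacement; the planted pose is then strictly the ensemble's
    average structure, which is verified before returning.
    """
    rng = np.random.default_rng(abs(int(spec.seed)))
    base = thread_peptide(template.pattern_sequence, template)
    if spec.planted_consensus is not None and \
            spec.n_poses - 1 > template.epitope_length:
        raise FixtureError(
            f"planted-consensus scatter supports at most epitope_length + 1 "
            f"poses ({template.epitope_length + 1}), got {spec.n_poses}")
    poses = []
    scatter_count = 0
    for k in range(spec.n_poses):
        if spec.planted_consensus is not None:
            if k == spec.planted_consensus:
                pose = base.copy()
            else:
                # each non-planted pose flips one distinct residue's side
                # chain: mutual pose distances are sqrt(2) x the distance to
                # the planted base, so the base is strictly the average
                # structure (verified below before returning)
                pose = _rotate_residue_side_chain(base, scatter_count, 180.0)
                scatter_count += 1
        else:
            pose = perturb_side_chains(base, rng, spec.chi_sigma_deg)
            xyz = pose.coords_array()
            if spec.rigid_rot_sigma_deg > 0:
                from scipy.spatial.transform import Rotation
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = rng.normal(0, np.deg2rad(spec.rigid_rot_sigma_deg))
                c = xyz.mean(axis=0)
                xyz = Rotation.from_rotvec(ang * axis).apply(xyz - c) + c
            if spec.rigid_trans_sigma > 0:
                xyz = xyz + rng.normal(0, spec.rigid_trans_sigma, size=3)
            pose.set_coords(xyz)
        if spec.be_values is not None:
            be = float(spec.be_values[k])
        elif spec.planted_consensus is not None:
            # equal energies keep every pose past the cut-off filter
            be = float(spec.be_mean)
        else:
            be = float(rng.normal(spec.be_mean, spec.be_sd))
        poses.append(DockedPose(coords=pose, binding_energy=be,
                                run_index=k + 1))
    ensemble = PoseEnsemble(poses)
    if spec.planted_consensus is not None:
        result = run_consensus(ensemble)
        others = [m for i, m in zip(result.retained_indices, result.row_means)
                  if i != spec.planted_consensus]
        planted_pos = [p for p, i in enumerate(result.retained_indices)
                       if i == spec.planted_consensus]
        if not planted_pos or (
                others and result.row_means[planted_pos[0]] >= min(others)):
            raise FixtureError(
                "planted pose is not strictly the row-mean minimum; "
                "adjust BE values so it survives the cut-off filter")
    return ensemble


def _rotate_residue_side_chain(pose: Structure, residue_index: int,
                               angle_deg: float) -> Structure:
    """Copy of ``pose`` with one residue's side chain rotated about N-CA."""
    from scipy.spatial.transform import Rotation
    out = pose.copy()
    (residues,) = out.chains().values()
    res = residues[residue_index]
    n, ca = res.atom("N"), res.atom("CA")
    side = [a for a in res.atoms
            if a.name not in topology.BACKBONE_ATOMS
            and a.name != topology.TERMINAL_OXYGEN]
    axis = ca.coords - n.coords
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    for a in side:
        a.coords = rot.apply(a.coords - ca.coords) + ca.coords
    return out


def make_benchmark_set(template: TemplateEntry, displacements: list[float],
                       out_dir: str | Path, seed: int = 0) -> Path:
    """Write target/model PDB pairs with exactly known epitope RMSD.

    For each displacement d the target is the template's toy complex and the
    model is the same complex with the peptide chain rigidly translated by d
    along the groove axis; since the MHC chains are identical, the MHC fit
    is the identity and the evaluated Calpha (and all-atom) RMSD equals d
    exactly. Returns the path of the manifest CSV referencing the pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if any(d < 0 for d in displacements):
        raise FixtureError("displacements must be >= 0")
    # snap the target onto the PDB's 3-decimal grid so that writing and
    # re-reading the shifted model keeps the displacement exact
    target = template.mhc_donor.copy()
    target.set_coords(np.round(target.coords_array(), 3))
    rows = []
    target_path = out_dir / "target.pdb"
    write_pdb(target, target_path)
    from .structure_io import assign_chain_roles
    peptide_chain = assign_chain_roles(target).peptide
    for k, d in enumerate(displacements):
        model = target.copy()
        shift = np.array([0.0, 0.0, 1.0]) * float(d)
        for atom in model.atoms:
            if atom.chain_id == peptide_chain:
                atom.coords = atom.coords + shift
        model_path = out_dir / f"model_{k}.pdb"
        write_pdb(model, model_path)
        rows.append({"model_path": model_path.name,
                     "target_path": target_path.name,
                     "allotype": template.allotype,
                     "epitope_length": template.epitope_length})
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["model_path", "target_path",
                                                "allotype", "epitope_length"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
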