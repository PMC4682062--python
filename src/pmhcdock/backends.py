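"""Docking and energy-minimization backend contracts and implementations.

The pipeline treats docking and EM as pluggable engines:

* docking backend — ``dock(spec, seed) -> PoseEnsemble``: one best pose per
  run, each carrying a binding energy (kcal/mol, lower = better);
* EM backend — ``minimize(structure, config, mobile) -> Structure``.

The built-in mock backends make the whole workflow deterministic and
desk-scale: the mock docker perturbs side-chain torsions and applies a small
rigid-body jitter per run, scoring poses by a soft receptor-contact count;
the mock minimizer relieves steric clashes with a soft-sphere push-apart.
The external adapters emit native input files for an AutoDock-Vina-style
docking engine and a GROMACS-style minimizer and shell out to them when
installed; they are optional and never required by the test suite.
"""

from __future__ import annotations

import dataclasses
import shutil
import subprocess
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import topology
from .consensus import DockedPose, PoseEnsemble
from .errors import BackendError, BackendUnavailableError
from .structure_io import Structure, select_atoms, write_pdb

CLASH_DISTANCE = 2.0  # Angstrom, minimum allowed non-bonded heavy-atom gap
CONTACT_DISTANCE = 4.0  # Angstrom, receptor-peptide contact shell for scoring


@dataclasses.dataclass(frozen=True)
class EMConfig:
    """Energy-minimization protocol parameters (external-engine units).

    Defaults mirror the complex-relaxation protocol the modelling workflow
    was validated with: steepest-descent minimization in a cubic solvated box
    (SPC water, 0.15 mol/L NaCl), GROMOS53a5 force field, 1.0 nm non-bonded
    cut-offs, at most 10000 steps starting at 0.001 nm, converged when the
    maximum force drops below 2000 kJ/mol/nm.
    """
    box_shape: str = "cubic"
    water_model: str = "SPC"
    ion_concentration: float = 0.15  # mol/L Na+/Cl-
    force_field: str = "GROMOS53a5"
    nonbonded_cutoff: float = 1.0  # nm
    integrator: str = "steep"
    max_steps: int = 10000
    initial_step: float = 0.001  # nm
    force_tolerance: float = 2000.0  # kJ/mol/nm

    def __post_init__(self):
        for field in ("ion_concentration", "nonbonded_cutoff", "max_steps",
                      "initial_step", "force_tolerance"):
            if getattr(self, field) <= 0:
                raise BackendError(f"EMConfig.{field} must be positive")


@dataclasses.dataclass(frozen=True)
class DockingJobSpec:
    receptor: Structure  # sanitized MHC donor
    peptide: Structure  # threaded epitope
    box: "object"  # cleft.GridBox
    n_runs: int = 20
    # engine contract: receptor rigid, peptide backbone rigid, side chains free
    flexibility: str = "side_chains_only"

    def __post_init__(self):
        if self.n_runs < 1:
            raise BackendError(f"n_runs must be >= 1, got {self.n_runs}")
        if not self.peptide.atoms:
            raise BackendError("docking job has an empty peptide")


def _movable_mask(structure: Structure, mobile: str) -> np.ndarray:
    if mobile == "all":
        return np.ones(len(structure.atoms), dtype=bool)
    if mobile == "side_chains":
        frozen = set(topology.BACKBONE_ATOMS) | {topology.TERMINAL_OXYGEN}
        return np.array([a.name not in frozen for a in structure.atoms])
    raise BackendError(f"unknown mobility selector {mobile!r}")


def find_clashes(structure: Structure,
                 cutoff: float = CLASH_DISTANCE) -> list[tuple[int, int, float]]:
    """Non-bonded heavy-atom pairs closer than ``cutoff``.

    Pairs within one residue, or in adjacent residues of the same chain, are
    treated as bonded context and excluded.
    """
    coords = structure.coords_array()
    atoms = structure.atoms
    tree = cKDTree(coords)
    clashes = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        a, b = atoms[i], atoms[j]
        if a.chain_id == b.chain_id and abs(a.residue_number - b.residue_number) <= 1:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        clashes.append((i, j, d))
    return clashes


class MockEMBackend:
    """Deterministic soft-sphere clash relief standing in for a force-field
    minimizer.

    Clashing non-bonded pairs are pushed apart along their separation vector
    until no heavy-atom pair (outside bonded context) is closer than 2.0 A,
    moving only the atoms allowed by ``mobile``. Displacements are small and
    local, honoring the contract that minimization is a mild relaxation:
    side-chain-only mode leaves the backbone bit-identical, and clash-free
    input is returned unchanged.
    """

    def __init__(self, clash_distance: float = CLASH_DISTANCE,
                 margin: float = 0.05, max_iterations: int = 100):
        self.clash_distance = clash_distance
        self.margin = margin
        self.max_iterations = max_iterations

    def minimize(self, structure: Structure, config: EMConfig | None = None,
                 mobile: str = "all") -> Structure:
        out = structure.copy()
        movable = _movable_mask(out, mobile)
        coords = out.coords_array()
        for _ in range(self.max_iterations):
            tmp = Structure(out.atoms)
            tmp.set_coords(coords)
            clashes = find_clashes(tmp, self.clash_distance)
            if not clashes:
                break
            shift = np.zeros_like(coords)
            for i, j, d in clashes:
                if not (movable[i] or movable[j]):
                    continue
                vec = coords[j] - coords[i]
                if d < 1e-9:
                    # coincident atoms: deterministic fallback axis
                    vec = np.array([1.0, 0.0, 0.0])
                    d = 0.0
                else:
                    vec = vec / d
                push = (self.clash_distance + self.margin - d)
                if movable[i] and movable[j]:
                    shift[i] -= vec * push / 2
                    shift[j] += vec * push / 2
                elif movable[j]:
                    shift[j] += vec * push
                else:
                    shift[i] -= vec * push
            coords = coords + shift
        out.set_coords(coords)
        return out


def perturb_side_chains(peptide: Structure, rng: np.random.Generator,
                        chi_sigma_deg: float) -> Structure:
    """Gaussian jitter of side-chain torsions, backbone untouched.

    For every residue the side chain is rotated about the N-CA axis (a
    pseudo-chi moving CB and beyond) and, when atoms beyond CB exist, about
    the CA-CB axis (chi1). Gly residues are left alone. A zero sigma is an
    exact no-op.
    """
    out = peptide.copy()
    if chi_sigma_deg == 0:
        return out
    for residues in out.chains().values():
        for res in residues:
            n, ca, cb = res.atom("N"), res.atom("CA"), res.atom("CB")
            side = [a for a in res.atoms
                    if a.name not in topology.BACKBONE_ATOMS
                    and a.name != topology.TERMINAL_OXYGEN]
            if not side or n is None or ca is None:
                continue
            angle0 = float(rng.normal(0.0, chi_sigma_deg))
            rot = Rotation.from_rotvec(
                np.deg2rad(angle0) * _unit(ca.coords - n.coords))
            for a in side:
                a.coords = rot.apply(a.coords - ca.coords) + ca.coords
            beyond = [a for a in side if a.name != "CB"]
            if cb is not None and beyond:
                angle1 = float(rng.normal(0.0, chi_sigma_deg))
                rot1 = Rotation.from_rotvec(
                    np.deg2rad(angle1) * _unit(cb.coords - ca.coords))
                for a in beyond:
                    a.coords = rot1.apply(a.coords - cb.coords) + cb.coords
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


class MockDockingBackend:
    """Seeded stochastic pose generator standing in for a docking engine.

    Each run perturbs the peptide's side-chain torsions (sigma
    ``chi_sigma_deg``), applies a small rigid-body jitter (``trans_sigma`` A
    translation per axis, ``rot_sigma_deg`` rotation about a random axis
    through the peptide centroid), and scores the pose by a soft contact
    count against the receptor plus Gaussian noise. All randomness derives
    from ``(seed, run_index)``, so ensembles are bit-reproducible, and with
    every sigma at zero each pose equals the input peptide exactly.
    """

    def __init__(self, chi_sigma_deg: float = 10.0, trans_sigma: float = 0.5,
                 rot_sigma_deg: float = 5.0, be_noise_sigma: float = 0.5,
                 contact_weight: float = 0.05):
        self.chi_sigma_deg = chi_sigma_deg
        self.trans_sigma = trans_sigma
        self.rot_sigma_deg = rot_sigma_deg
        self.be_noise_sigma = be_noise_sigma
        self.contact_weight = contact_weight

    def dock(self, spec: DockingJobSpec, seed: int) -> PoseEnsemble:
        receptor_xyz = select_atoms(spec.receptor, "heavy")
        tree = cKDTree(receptor_xyz)
        poses = []
        for run in range(1, spec.n_runs + 1):
            rng = np.random.default_rng([abs(int(seed)), run])
            pose = perturb_side_chains(spec.peptide, rng, self.chi_sigma_deg)
            xyz = pose.coords_array()
            centroid = xyz.mean(axis=0)
            if self.rot_sigma_deg > 0:
                axis = _unit(rng.normal(size=3))
                angle = rng.normal(0.0, np.deg2rad(self.rot_sigma_deg))
                xyz = Rotation.from_rotvec(angle * axis).apply(xyz - centroid) \
                    + centroid
            if self.trans_sigma > 0:
                xyz = xyz + rng.normal(0.0, self.trans_sigma, size=3)
            pose.set_coords(xyz)
            contacts = tree.query_ball_point(
                select_atoms(pose, "heavy"), CONTACT_DISTANCE,
                return_length=True).sum()
            noise = rng.normal(0.0, self.be_noise_sigma) \
                if self.be_noise_sigma > 0 else 0.0
            be = -self.contact_weight * float(contacts) + float(noise)
            poses.append(DockedPose(coords=pose, binding_energy=be,
                                    run_index=run))
        return PoseEnsemble(poses)


def write_mdp(config: EMConfig) -> str:
    """Render the minimizer's run-parameter file from an EMConfig."""
    return "\n".join([
        "; energy minimization parameters",
        f"integrator       = {config.integrator}",
        f"nsteps           = {config.max_steps}",
        f"emtol            = {config.force_tolerance:g}",
        f"emstep           = {config.initial_step:g}",
        f"rcoulomb         = {config.nonbonded_cutoff:g}",
        f"rvdw             = {config.nonbonded_cutoff:g}",
        "constraints      = none",
        "",
    ])


class GromacsEMAdapter:
    """Adapter emitting run inputs for a GROMACS-style minimizer.

    Writes the structure and the ``.mdp`` parameter file rendered from the
    :class:`EMConfig` into a work directory and, when the engine executable
    is on PATH, drives the standard prepare/solvate/ionize/minimize sequence.
    System preparation (topology generation, solvation, ion placement per
    ``ion_concentration``) is delegated to the engine's own tools.
    """

    def __init__(self, executable: str = "gmx", workdir: str | Path = "em_work"):
        self.executable = executable
        self.workdir = Path(workdir)

    def prepare_inputs(self, structure: Structure,
                       config: EMConfig) -> dict[str, Path]:
        self.workdir.mkdir(parents=True, exist_ok=True)
        pdb_path = self.workdir / "input.pdb"
        mdp_path = self.workdir / "em.mdp"
        write_pdb(structure, pdb_path)
        mdp_path.write_text(write_mdp(config))
        return {"structure": pdb_path, "mdp": mdp_path}

    def minimize(self, structure: Structure, config: EMConfig | None = None,
                 mobile: str = "all") -> Structure:
        config = config or EMConfig()
        if shutil.which(self.executable) is None:
            raise BackendUnavailableError(
                f"minimizer executable {self.executable!r} not found on PATH",
                stage="energy minimization")
        paths = self.prepare_inputs(structure, config)
        raise BackendError(
            f"external minimization drive-through is not implemented beyond "
            f"input preparation ({paths['mdp']}); run the engine manually",
            stage="energy minimization")


class VinaDockingAdapter:
    """Adapter emitting run inputs for an AutoDock-Vina-style engine.

    Prepares the receptor and peptide per the engine's protocol — hydrogens
    and Gasteiger charges added, non-polar hydrogens merged, torsion tree
    restricted so the peptide backbone stays rigid — via the engine's own
    preparation tools, and writes the search-box config from the cleft grid
    box. The engine executable is optional; without it this adapter only
    prepares inputs.
    """

    def __init__(self, executable: str = "vina", workdir: str | Path = "dock_work"):
        self.executable = executable
        self.workdir = Path(workdir)

    def write_box_config(self, box, n_runs: int) -> Path:
        self.workdir.mkdir(parents=True, exist_ok=True)
        cx, cy, cz = box.center
        sx, sy, sz = box.dimensions
        conf = self.workdir / "box.conf"
        conf.write_text(
            f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
            f"size_x = {sx:.3f}\nsize_y = {sy:.3f}\nsize_z = {sz:.3f}\n"
            f"exhaustiveness = 8\nnum_modes = {n_runs}\n")
        return conf

    def prepare_inputs(self, spec: DockingJobSpec) -> dict[str, Path]:
        self.workdir.mkdir(parents=True, exist_ok=True)
        receptor = self.workdir / "receptor.pdb"
        peptide = self.workdir / "peptide.pdb"
        write_pdb(spec.receptor, receptor)
        write_pdb(spec.peptide, peptide)
        conf = self.write_box_config(spec.box, spec.n_runs)
        return {"receptor": receptor, "peptide": peptide, "config": conf}

    def dock(self, spec: DockingJobSpec, seed: int) -> PoseEnsemble:
        if shutil.which(self.executable) is None:
            raise BackendUnavailableError(
                f"docking executable {self.executable!r} not found on PATH",
                stage="docking")
        paths = self.prepare_inputs(spec)
        cmd = [self.executable, "--config", str(paths["config"]),
               "--seed", str(seed)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BackendError(
                f"docking engine exited {proc.returncode}: {proc.stderr[-500:]}",
                stage="docking")
        raise BackendError(
            "external docking output parsing requires engine-prepared PDBQT "
            "inputs; use the engine's preparation tools and load_ensemble()",
            stage="docking")
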