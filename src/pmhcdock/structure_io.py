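"""PDB structure reading, writing, sanitization, chain roles, atom selection.

Parsing is delegated to :mod:`gemmi`; the in-memory representation is a flat
list of :class:`AtomRecord` grouped on demand into chains and residues, which
is all the downstream geometry needs. Only the first model of multi-model
files is read. Writing emits fixed-column PDB v3.3 ``ATOM``/``TER`` records
with coordinates at the format's native 3-decimal precision.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from . import topology
from .errors import (
    AmbiguousPeptideError,
    EmptySelectionError,
    PdbFormatError,
    RoleAssignmentError,
    StructureError,
)

PEPTIDE_MIN, PEPTIDE_MAX = 8, 12
B2M_MIN, B2M_MAX = 90, 110

ATOM_CLASSES = ("CA", "backbone", "heavy", "side-chain")


@dataclasses.dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    coords: np.ndarray
    insertion_code: str = ""
    alt_loc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def copy(self) -> "AtomRecord":
        return dataclasses.replace(self, coords=self.coords.copy())

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclasses.dataclass
class Residue:
    name: str
    number: int
    insertion_code: str
    chain_id: str
    atoms: list[AtomRecord]

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_protein(self) -> bool:
        return self.name in topology.STANDARD_RESIDUES


class Structure:
    """Ordered collection of atom records with chain/residue grouping."""

    def __init__(self, atoms: Iterable[AtomRecord], meta: dict | None = None):
        self.atoms: list[AtomRecord] = list(atoms)
        self.meta: dict = dict(meta or {})

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], meta=dict(self.meta))

    def coords_array(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms")
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz.copy()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        xyz = out.coords_array()
        out.set_coords(xyz @ np.asarray(rotation, float).T + np.asarray(translation, float))
        return out

    def chains(self) -> dict[str, list[Residue]]:
        """Group atoms into residues per chain, preserving file order."""
        chains: dict[str, list[Residue]] = {}
        current: Residue | None = None
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_number, atom.insertion_code,
                   atom.residue_name)
            if current is None or (current.chain_id, current.number,
                                   current.insertion_code, current.name) != key:
                current = Residue(atom.residue_name, atom.residue_number,
                                  atom.insertion_code, atom.chain_id, [])
                chains.setdefault(atom.chain_id, []).append(current)
            current.atoms.append(atom)
        return chains

    def chain_residues(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains()[chain_id]
        except KeyError:
            raise StructureError(f"no chain {chain_id!r} in structure") from None

    def protein_residue_count(self, chain_id: str) -> int:
        return sum(1 for r in self.chain_residues(chain_id) if r.is_protein)

    def sequence(self, chain_id: str) -> str:
        return "".join(topology.THREE_TO_ONE.get(r.name, "X")
                       for r in self.chain_residues(chain_id))

    def subset(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = set(chain_ids)
        return Structure([a.copy() for a in self.atoms if a.chain_id in wanted])


@dataclasses.dataclass(frozen=True)
class ChainRoles:
    heavy_chain: str
    peptide: str
    beta2m: str | None = None


def read_pdb(path: str | Path) -> Structure:
    """Read all ATOM/HETATM records of the first model of a PDB file."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read PDB file: {path} does not exist")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PdbFormatError(f"{path}: not parseable as PDB ({exc})") from exc
    atoms: list[AtomRecord] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for res in chain:
                for atom in res:
                    alt = atom.altloc if atom.altloc not in ("\0", " ") else ""
                    icode = res.seqid.icode.strip()
                    atoms.append(AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        insertion_code=icode,
                        alt_loc=alt,
                        occupancy=atom.occ,
                        is_hetero=(res.het_flag == "H"),
                    ))
    if not atoms:
        first = ""
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    first = line.rstrip("\n")
                    break
        raise PdbFormatError(
            f"{path}: no ATOM/HETATM records found (first line: {first!r})")
    return Structure(atoms)


def _format_atom_line(atom: AtomRecord, serial: int) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM"
    name = atom.name
    # PDB convention: 1-letter elements with short names start in column 14
    if len(name) < 4 and len(atom.element) < 2:
        name = " " + name
    x, y, z = atom.coords
    return (f"{record:<6}{serial:>5} {name:<4}{atom.alt_loc or ' ':1}"
            f"{atom.residue_name:>3} {atom.chain_id:1}"
            f"{atom.residue_number:>4}{atom.insertion_code or ' ':1}   "
            f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{atom.occupancy:>6.2f}{0.0:>6.2f}"
            f"          {atom.element:>2}")


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column PDB v3.3 with TER records between chains."""
    if not structure.atoms:
        raise StructureError("refusing to write an empty structure")
    path = Path(path)
    lines: list[str] = []
    serial = 0
    prev: AtomRecord | None = None
    for atom in structure.atoms:
        if prev is not None and atom.chain_id != prev.chain_id:
            serial += 1
            lines.append(f"{'TER':<6}{serial:>5}      {prev.residue_name:>3} "
                         f"{prev.chain_id:1}{prev.residue_number:>4}")
        serial += 1
        lines.append(_format_atom_line(atom, serial))
        prev = atom
    if prev is not None:
        serial += 1
        lines.append(f"{'TER':<6}{serial:>5}      {prev.residue_name:>3} "
                     f"{prev.chain_id:1}{prev.residue_number:>4}")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc


def sanitize_structure(structure: Structure,
                       drop_chains: Sequence[str] = (),
                       drop_short_chains: bool = False) -> Structure:
    """Strip waters, ligands, hydrogens and alternate locations.

    Non-standard residues with a known standard parent (e.g. selenomethionine)
    are renamed to that parent; unknown polymer residues raise. One alternate
    location per atom is kept: blank preferred, then 'A', then highest
    occupancy. Chains listed in ``drop_chains`` (e.g. TCR chains in a ternary
    complex) are removed; with ``drop_short_chains`` protein chains shorter
    than 8 residues are also removed. The result's ``meta['sanitization']``
    records what was stripped; an empty result is allowed and flagged there.
    """
    counts = {"waters": 0, "hydrogens": 0, "hetero": 0, "alt_locs": 0,
              "chains_dropped": 0, "renamed": 0}
    dropped = set(drop_chains)
    kept: list[AtomRecord] = []
    for atom in structure.atoms:
        if atom.chain_id in dropped:
            continue
        name = atom.residue_name
        if name in topology.WATER_NAMES:
            counts["waters"] += 1
            continue
        if name in topology.NONSTANDARD_PARENT:
            atom = atom.copy()
            atom.residue_name = topology.NONSTANDARD_PARENT[name]
            atom.is_hetero = False
            counts["renamed"] += 1
        elif name not in topology.STANDARD_RESIDUES:
            if atom.is_hetero:
                counts["hetero"] += 1
                continue
            raise StructureError(
                f"unknown polymer residue {name!r} at {atom.chain_id}"
                f"{atom.residue_number} (no standard parent mapping)")
        if atom.is_hydrogen:
            counts["hydrogens"] += 1
            continue
        kept.append(atom.copy())

    # alternate-location resolution: blank > 'A' > highest occupancy
    best: dict[tuple, tuple[tuple, int]] = {}
    order: list[int] = []
    for i, atom in enumerate(kept):
        key = (atom.chain_id, atom.residue_number, atom.insertion_code,
               atom.residue_name, atom.name)
        rank = (atom.alt_loc == "", atom.alt_loc == "A", atom.occupancy)
        if key not in best:
            best[key] = (rank, i)
            order.append(i)
        else:
            counts["alt_locs"] += 1
            if rank > best[key][0]:
                order[order.index(best[key][1])] = i
                best[key] = (rank, i)
    deduped = []
    for i in sorted(order):
        atom = kept[i]
        atom.alt_loc = ""
        deduped.append(atom)

    result = Structure(deduped)
    if drop_short_chains:
        chains = result.chains()
        short = {cid for cid, residues in chains.items()
                 if sum(1 for r in residues if r.is_protein) < PEPTIDE_MIN}
        if short:
            counts["chains_dropped"] = len(short)
            result = Structure([a for a in result.atoms
                                if a.chain_id not in short])
    counts["empty_result"] = not result.atoms
    result.meta["sanitization"] = counts
    return result


def assign_chain_roles(structure: Structure) -> ChainRoles:
    """Identify peptide, MHC heavy chain and beta-2-microglobulin.

    The peptide is the protein chain with 8-12 residues (the shortest when
    several lengths qualify); the heavy chain is the longest protein chain;
    beta-2-microglobulin is a remaining chain of 90-110 residues, if any.
    """
    sizes = {cid: sum(1 for r in residues if r.is_protein)
             for cid, residues in structure.chains().items()}
    sizes = {cid: n for cid, n in sizes.items() if n > 0}
    if len(sizes) < 2:
        raise RoleAssignmentError(
            f"need at least two protein chains, found {len(sizes)}")
    candidates = {cid: n for cid, n in sizes.items()
                  if PEPTIDE_MIN <= n <= PEPTIDE_MAX}
    if not candidates:
        shortest = min(sizes.values())
        raise RoleAssignmentError(
            f"no chain with {PEPTIDE_MIN}-{PEPTIDE_MAX} residues "
            f"(shortest chain has {shortest})")
    min_len = min(candidates.values())
    shortest_ids = sorted(cid for cid, n in candidates.items() if n == min_len)
    if len(shortest_ids) > 1:
        raise AmbiguousPeptideError(
            f"ambiguous peptide chain: {shortest_ids} all have {min_len} residues")
    peptide = shortest_ids[0]
    heavy = max((cid for cid in sizes if cid != peptide),
                key=lambda cid: (sizes[cid], cid))
    beta2m = None
    for cid in sorted(sizes):
        if cid in (peptide, heavy):
            continue
        if B2M_MIN <= sizes[cid] <= B2M_MAX:
            beta2m = cid
            break
    return ChainRoles(heavy_chain=heavy, peptide=peptide, beta2m=beta2m)


@dataclasses.dataclass(frozen=True)
class Selection:
    """Parsed atom-selection specification.

    ``target`` is a chain role name (``peptide``, ``heavy_chain``, ``beta2m``)
    or a literal chain id; ``atom_class`` one of CA | backbone | heavy |
    side-chain; ``residue_range`` an optional inclusive (first, last) pair.
    """
    atom_class: str
    target: str | None = None
    residue_range: tuple[int, int] | None = None


_RANGE_RE = re.compile(r"^(-?\d+)-(-?\d+)$")


def parse_selection(spec: str) -> Selection:
    """Parse strings like ``"peptide:CA"`` or ``"heavy_chain:1-180:CA"``."""
    parts = [p.strip() for p in spec.split(":")]
    if not parts or not parts[-1]:
        raise ValueError(f"empty selection spec: {spec!r}")
    atom_class = parts[-1]
    if atom_class not in ATOM_CLASSES:
        raise ValueError(f"unknown atom class {atom_class!r}; "
                         f"expected one of {ATOM_CLASSES}")
    target = None
    residue_range = None
    for part in parts[:-1]:
        m = _RANGE_RE.match(part)
        if m:
            residue_range = (int(m.group(1)), int(m.group(2)))
        elif part:
            target = part
    return Selection(atom_class=atom_class, target=target,
                     residue_range=residue_range)


def _resolve_chain(structure: Structure, target: str | None,
                   roles: ChainRoles | None) -> str | None:
    if target is None:
        return None
    if target in ("peptide", "heavy_chain", "beta2m"):
        if roles is None:
            roles = assign_chain_roles(structure)
        chain = getattr(roles, target)
        if chain is None:
            raise EmptySelectionError(f"structure has no {target} chain")
        return chain
    return target


def _atom_matches(atom: AtomRecord, atom_class: str) -> bool:
    if atom.is_hydrogen:
        return False
    if atom_class == "CA":
        return atom.name == "CA"
    if atom_class == "backbone":
        return atom.name in topology.BACKBONE_ATOMS
    if atom_class == "heavy":
        return True
    if atom_class == "side-chain":
        return atom.name not in topology.BACKBONE_ATOMS and \
            atom.name != topology.TERMINAL_OXYGEN
    raise ValueError(f"unknown atom class {atom_class!r}")


def select_atom_records(structure: Structure,
                        selection: Selection | str,
                        roles: ChainRoles | None = None) -> list[AtomRecord]:
    """Return matching atoms in canonical order.

    Canonical order is residue file order, then the fixed per-residue
    heavy-atom name order, so equal-sequence structures give positionally
    corresponding lists.
    """
    if isinstance(selection, str):
        selection = parse_selection(selection) if ":" in selection else \
            Selection(atom_class=selection)
    chain = _resolve_chain(structure, selection.target, roles)
    out: list[AtomRecord] = []
    for cid, residues in structure.chains().items():
        if chain is not None and cid != chain:
            continue
        for res in residues:
            if selection.residue_range is not None:
                lo, hi = selection.residue_range
                if not (lo <= res.number <= hi):
                    continue
            matched = [a for a in res.atoms
                       if _atom_matches(a, selection.atom_class)]
            matched.sort(key=lambda a: topology.atom_sort_key(res.name, a.name))
            out.extend(matched)
    if not out:
        raise EmptySelectionError(f"selection {selection} matched no atoms")
    return out


def select_atoms(structure: Structure,
                 selection: Selection | str,
                 roles: ChainRoles | None = None) -> np.ndarray:
    """Coordinates (n, 3) of the selection, in canonical order."""
    records = select_atom_records(structure, selection, roles)
    return np.array([a.coords for a in records], dtype=float)
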