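"""Build a 3-D epitope from its linear sequence.

The query sequence is validated against the allotype registry, then threaded
onto the allotype's crystallographic epitope-pattern backbone: backbone atoms
(N, CA, C, O, terminal OXT) are copied verbatim from the pattern, CB is copied
when the pattern provides one (never for Gly) or constructed at ideal
tetrahedral geometry, and the remaining side-chain heavy atoms are built from
the ideal-geometry single-rotamer table in :mod:`pmhcdock.topology`.
Threading is exact and deterministic — the modelled backbone *is* the pattern
backbone. A short mock-relaxation step can then relieve side-chain clashes
before docking.
"""

from __future__ import annotations

import numpy as np

from . import topology
from .errors import BackendError, SequenceError
from .registry import AllotypeRegistry, TemplateEntry
from .structure_io import AtomRecord, Structure

_VALID_LETTERS = frozenset(topology.ONE_TO_THREE)


def validate_sequence(sequence: str,
                      registry: AllotypeRegistry) -> list[TemplateEntry]:
    """Check the alphabet and return registry entries matching the length.

    The sequence is upper-cased; letters outside the 20-residue alphabet
    (including B, J, O, U, X, Z) raise with the 1-based offending position.
    An empty compatibility list is returned when no allotype supports the
    length.
    """
    if not sequence:
        raise SequenceError("empty epitope sequence")
    seq = sequence.strip().upper()
    for pos, letter in enumerate(seq, start=1):
        if letter not in _VALID_LETTERS:
            raise SequenceError(
                f"invalid amino-acid letter {letter!r} at position {pos} "
                f"of {seq!r}")
    return registry.by_length(len(seq))


_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME.get(atom_name[0], "C")


def thread_peptide(sequence: str, template: TemplateEntry,
                   chain_id: str = "P") -> Structure:
    """Thread a sequence onto the template's epitope-pattern backbone.

    Returns a complete heavy-atom peptide whose backbone coordinates equal
    the pattern backbone exactly (RMSD 0 by construction, no fitting).
    """
    seq = sequence.strip().upper()
    if len(seq) != template.epitope_length:
        raise SequenceError(
            f"sequence length {len(seq)} does not match template "
            f"{template.allotype} epitope length {template.epitope_length}")
    if template.pattern_backbone is None:
        raise SequenceError(
            f"template {template.allotype} has no pattern backbone structure")
    pattern_residues = template.pattern_residues()

    atoms: list[AtomRecord] = []
    serial = 0
    n_res = len(seq)
    for i, letter in enumerate(seq):
        res3 = topology.ONE_TO_THREE[letter]
        pres = pattern_residues[i]
        placed: dict[str, np.ndarray] = {}
        for name in topology.BACKBONE_ATOMS:
            src = pres.atom(name)
            if src is None:
                raise SequenceError(
                    f"pattern residue {pres.number} lacks backbone atom {name}")
            placed[name] = src.coords.copy()
        for name, refs, r, theta, tau in topology.SIDE_CHAIN_ICS[res3]:
            src = pres.atom(name) if name == "CB" else None
            if src is not None and res3 != "GLY":
                placed[name] = src.coords.copy()
            else:
                a, b, c = (placed[x] for x in refs)
                placed[name] = topology.place_atom(a, b, c, r, theta, tau)
        order = list(topology.HEAVY_ATOMS[res3])
        if i == n_res - 1:
            oxt = pres.atom(topology.TERMINAL_OXYGEN)
            if oxt is not None:
                placed[topology.TERMINAL_OXYGEN] = oxt.coords.copy()
                order.append(topology.TERMINAL_OXYGEN)
        for name in order:
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=name, element=_element_of(name),
                residue_name=res3, chain_id=chain_id,
                residue_number=i + 1, coords=placed[name]))
    return Structure(atoms, meta={"threaded_from": template.pattern_id,
                                  "allotype": template.allotype})


def audit_topology(peptide: Structure) -> list[str]:
    """List heavy-atom completeness violations; empty list means complete.

    Every residue must carry exactly the standard heavy atoms for its type;
    the C-terminal residue may additionally carry OXT.
    """
    problems: list[str] = []
    for cid, residues in peptide.chains().items():
        for k, res in enumerate(residues):
            expected = set(topology.HEAVY_ATOMS[res.name])
            allowed = set(expected)
            if k == len(residues) - 1:
                allowed.add(topology.TERMINAL_OXYGEN)
            names = [a.name for a in res.atoms if not a.is_hydrogen]
            seen = set(names)
            if len(names) != len(seen):
                problems.append(f"{cid}{res.number} {res.name}: duplicate atoms")
            missing = expected - seen
            extra = seen - allowed
            if missing:
                problems.append(
                    f"{cid}{res.number} {res.name}: missing {sorted(missing)}")
            if extra:
                problems.append(
                    f"{cid}{res.number} {res.name}: unexpected {sorted(extra)}")
    return problems


def relax_epitope(peptide: Structure, backend, em_config=None) -> Structure:
    """Mild relaxation of the lone threaded epitope via the EM backend.

    Only side chains move; the backbone is frozen, so the pattern backbone
    survives relaxation unchanged. Backend failures are re-raised with the
    stage label ``"epitope relaxation"``.
    """
    try:
        return backend.minimize(peptide, config=em_config, mobile="side_chains")
    except BackendError as exc:
        raise BackendError(f"epitope relaxation failed: {exc}",
                           stage="epitope relaxation") from exc
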