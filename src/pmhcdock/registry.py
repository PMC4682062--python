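"""Allotype registry: template entries keyed by (allotype, epitope length).

A :class:`TemplateEntry` bundles everything the modelling pipeline needs for
one allotype/length combination: the MHC donor structure (receptor), the
epitope-pattern backbone (threading template) and the pattern's sequence.
The default registry carries the metadata of the supported allotypes without
coordinates; structures are attached from user-supplied PDB files through a
YAML config, and the test suite uses synthetic toy templates throughout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from . import refdata, structure_io, topology
from .errors import PmhcdockError, StructureError
from .structure_io import Structure


@dataclasses.dataclass
class TemplateEntry:
    allotype: str
    epitope_length: int
    mhc_donor_id: str
    pattern_id: str
    pattern_sequence: str
    mhc_donor: Structure | None = None
    pattern_backbone: Structure | None = None

    def __post_init__(self):
        if len(self.pattern_sequence) != self.epitope_length:
            raise PmhcdockError(
                f"{self.allotype}: pattern sequence "
                f"{self.pattern_sequence!r} does not match epitope length "
                f"{self.epitope_length}")
        if self.pattern_backbone is not None:
            _check_backbone(self.pattern_backbone, self.epitope_length,
                            self.allotype)

    @property
    def has_structures(self) -> bool:
        return self.mhc_donor is not None and self.pattern_backbone is not None

    def pattern_residues(self) -> list[structure_io.Residue]:
        chains = self.pattern_backbone.chains()
        (residues,) = chains.values()
        return residues


def _check_backbone(backbone: Structure, length: int, label: str) -> None:
    chains = backbone.chains()
    if len(chains) != 1:
        raise StructureError(
            f"{label}: pattern backbone must be a single peptide chain, "
            f"found {len(chains)}")
    (residues,) = chains.values()
    if len(residues) != length:
        raise StructureError(
            f"{label}: pattern backbone has {len(residues)} residues, "
            f"expected {length}")
    for res in residues:
        for name in topology.BACKBONE_ATOMS:
            if res.atom(name) is None:
                raise StructureError(
                    f"{label}: pattern residue {res.number} is missing "
                    f"backbone atom {name}")


class AllotypeRegistry:
    """Mapping (allotype, epitope_length) -> TemplateEntry."""

    def __init__(self, entries: list[TemplateEntry] | None = None):
        self._entries: dict[tuple[str, int], TemplateEntry] = {}
        for entry in entries or []:
            self.add(entry)

    def add(self, entry: TemplateEntry) -> None:
        self._entries[(entry.allotype, entry.epitope_length)] = entry

    def get(self, allotype: str, epitope_length: int) -> TemplateEntry:
        try:
            return self._entries[(allotype, epitope_length)]
        except KeyError:
            raise PmhcdockError(
                f"no template for allotype {allotype!r} with "
                f"{epitope_length}-mer epitopes; available: "
                f"{sorted(self._entries)}") from None

    def by_length(self, epitope_length: int) -> list[TemplateEntry]:
        return [e for (_, n), e in sorted(self._entries.items())
                if n == epitope_length]

    def allotypes(self) -> list[str]:
        return sorted({a for a, _ in self._entries})

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())


def default_registry() -> AllotypeRegistry:
    """Registry with the supported allotypes' metadata, no coordinates."""
    return AllotypeRegistry([
        TemplateEntry(allotype=a, epitope_length=n, mhc_donor_id=d,
                      pattern_id=p, pattern_sequence=s)
        for a, n, d, p, s in refdata.TEMPLATE_CATALOGUE
    ])


def _extract_pattern_backbone(structure: Structure) -> Structure:
    """Peptide-chain backbone (N, CA, C, O, OXT) of a sanitized complex.

    Accepts either a lone peptide chain or a full pMHC-I complex.
    """
    chains = structure.chains()
    if len(chains) == 1:
        peptide_id = next(iter(chains))
    else:
        peptide_id = structure_io.assign_chain_roles(structure).peptide
    keep = topology.BACKBONE_ATOMS + (topology.TERMINAL_OXYGEN,)
    atoms = [a.copy() for a in structure.atoms
             if a.chain_id == peptide_id and a.name in keep]
    return Structure(atoms)


def load_registry(config_path: str | Path) -> AllotypeRegistry:
    """Build a registry from a YAML config.

    Schema (paths are resolved relative to the config file)::

        templates:
          - allotype: HLA-A*02:01
            epitope_length: 9
            mhc_donor: 2v2w.pdb
            pattern: 1t1z.pdb
            pattern_sequence: ALYNTAAAL
    """
    config_path = Path(config_path)
    data = yaml.safe_load(config_path.read_text())
    if not isinstance(data, dict) or "templates" not in data:
        raise PmhcdockError(f"{config_path}: expected a 'templates' list")
    base = config_path.parent
    entries = []
    for item in data["templates"]:
        donor = structure_io.sanitize_structure(
            structure_io.read_pdb(base / item["mhc_donor"]))
        pattern_full = structure_io.sanitize_structure(
            structure_io.read_pdb(base / item["pattern"]))
        entries.append(TemplateEntry(
            allotype=str(item["allotype"]),
            epitope_length=int(item["epitope_length"]),
            mhc_donor_id=str(item.get("mhc_donor_id", item["mhc_donor"])),
            pattern_id=str(item.get("pattern_id", item["pattern"])),
            pattern_sequence=str(item["pattern_sequence"]).upper(),
            mhc_donor=donor,
            pattern_backbone=_extract_pattern_backbone(pattern_full),
        ))
    return AllotypeRegistry(entries)
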