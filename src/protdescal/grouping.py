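"""Residue groups: the subsets over which index values are aggregated.

Three families are provided — type-based (one group per amino acid),
property-based (physicochemical classes), and structure-based (buried/
exposed at a relative-SASA cutoff, plus secondary-structure classes).
The whole protein (PRT) is always available.
"""

from __future__ import annotations

from dataclasses import dataclass

from .protein_io import ProteinModel
from .scales import AA3, PROPERTY_CLASSES, THREE_TO_ONE

__all__ = [
    "ResidueGroup",
    "type_groups",
    "property_groups",
    "structure_groups",
    "prt_group",
    "DEFAULT_SASA_CUTOFF",
    "STRUCTURE_GROUP_NAMES",
]

DEFAULT_SASA_CUTOFF = 0.25
STRUCTURE_GROUP_NAMES = ("INT", "SUP", "HEX", "SHT", "TRN", "RCL", "PRT")


@dataclass(frozen=True)
class ResidueGroup:
    """Named subset of residue positions (1-based, strictly increasing)."""

    name: str
    members: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.members) != sorted(set(self.members)):
            raise ValueError(f"group {self.name!r}: members must be strictly increasing")

    def __len__(self) -> int:
        return len(self.members)


def prt_group(model: ProteinModel) -> ResidueGroup:
    """The whole protein as a special group (PRT)."""
    return ResidueGroup("PRT", tuple(range(1, len(model) + 1)))


def type_groups(model: ProteinModel) -> list[ResidueGroup]:
    """Exactly 20 groups, one per standard amino-acid type (empty kept).

    The groups partition the protein: disjoint, union = all residues.
    """
    by_type: dict[str, list[int]] = {aa: [] for aa in AA3}
    for res in model.residues:
        by_type[res.aa_type].append(res.position)
    return [ResidueGroup(aa, tuple(by_type[aa])) for aa in AA3]


def property_groups(model: ProteinModel) -> list[ResidueGroup]:
    """Physicochemical classes (polar, basic, acidic, aromatic, …).

    Classes may overlap (HIS is both basic and aromatic); charged is the
    union of basic and acidic by construction.
    """
    groups = []
    for name in PROPERTY_CLASSES:
        letters = PROPERTY_CLASSES[name]
        members = tuple(
            r.position for r in model.residues if THREE_TO_ONE[r.aa_type] in letters
        )
        groups.append(ResidueGroup(name, members))
    return groups


def structure_groups(
    model: ProteinModel,
    sasa_cutoff: float = DEFAULT_SASA_CUTOFF,
) -> list[ResidueGroup]:
    """Structure-based groups: INT/SUP burial partition and SS classes.

    INT holds residues with relative SASA below ``sasa_cutoff``; SUP is its
    complement. HEX/SHT/TRN come from the explicit HELIX/SHEET/TURN records;
    RCL holds everything neither helix nor sheet (so RCL ⊇ TRN). PRT is the
    whole protein. Requires a structure with relative SASA annotated (run
    :func:`protdescal.protein_io.compute_sasa` first).
    """
    if not model.has_structure:
        raise ValueError(
            "structure-based groups require a 3D structure; only PRT is "
            "available for sequence-only models"
        )
    if any(r.rel_sasa is None for r in model.residues):
        raise ValueError("relative SASA not computed; run compute_sasa first")

    int_members, sup_members = [], []
    ss: dict[str, list[int]] = {"HEX": [], "SHT": [], "TRN": [], "RCL": []}
    label_map = {"HELIX": "HEX", "SHEET": "SHT", "TURN": "TRN"}
    for res in model.residues:
        (int_members if res.rel_sasa < sasa_cutoff else sup_members).append(res.position)
        tag = label_map.get(res.ss_label or "COIL")
        if tag is not None:
            ss[tag].append(res.position)
        if res.ss_label not in ("HELIX", "SHEET"):
            ss["RCL"].append(res.position)

    return [
        ResidueGroup("INT", tuple(int_members)),
        ResidueGroup("SUP", tuple(sup_members)),
        ResidueGroup("HEX", tuple(ss["HEX"])),
        ResidueGroup("SHT", tuple(ss["SHT"])),
        ResidueGroup("TRN", tuple(ss["TRN"])),
        ResidueGroup("RCL", tuple(ss["RCL"])),
        prt_group(model),
    ]
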