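"""Protein input: PDB and FASTA parsing into :class:`ProteinModel`, plus
solvent-accessible surface area annotation.

Residue positions are 1-based consecutive model positions; the PDB ``resSeq``
is kept as metadata. Secondary structure comes only from explicit
HELIX/SHEET/TURN records — no geometric reassignment is attempted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .scales import MAX_SASA, ONE_TO_THREE, THREE_TO_ONE

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueRecord",
    "ProteinModel",
    "read_pdb",
    "read_fasta",
    "write_pdb",
    "compute_sasa",
    "shrake_rupley",
]

#: three-letter codes of nonstandard residues mapped onto standard types
NONSTANDARD_MAP = {"MSE": "MET", "SEC": "CYS", "MLE": "LEU", "CSO": "CYS"}

#: van der Waals radii (Å) by element symbol
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70


@dataclass
class ResidueRecord:
    """One residue: position, type, and optional structural annotations."""

    position: int                      # 1-based model position
    aa_type: str                       # three-letter code, one of the 20
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    ss_label: str | None = None        # HELIX / SHEET / TURN / COIL
    rel_sasa: float | None = None      # fraction of the type's max area
    resseq: int | None = None          # original PDB residue number

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.aa_type]

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")


@dataclass
class ProteinModel:
    """Ordered residues of a single-chain protein, with or without structure."""

    id: str
    residues: list[ResidueRecord]
    has_structure: bool
    source_format: str  # "PDB" or "FASTA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r} has no residues")
        for pos, res in enumerate(self.residues, start=1):
            if res.position != pos:
                raise ValueError(
                    f"protein {self.id!r}: residue positions must be 1..N "
                    f"contiguous (found {res.position} at slot {pos})"
                )
        if not self.has_structure:
            for res in self.residues:
                if res.atoms or res.ss_label is not None or res.rel_sasa is not None:
                    raise ValueError(
                        "sequence-only model must carry no coordinates, "
                        "secondary structure or SASA"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) Cα coordinates; rows of NaN where Cα is missing."""
        out = np.full((len(self), 3), np.nan)
        for i, res in enumerate(self.residues):
            if res.ca is not None:
                out[i] = res.ca
        return out


def _scan_ss_records(path: Path) -> dict[str, list[tuple[str, int, int]]]:
    """Collect (chain, start_resseq, end_resseq) from HELIX/SHEET/TURN records."""
    spans: dict[str, list[tuple[str, int, int]]] = {
        "HELIX": [], "SHEET": [], "TURN": []
    }
    # fixed columns per the PDB format: (init chain, init seq, end seq)
    cols = {
        "HELIX": (19, slice(21, 25), slice(33, 37)),
        "SHEET": (21, slice(22, 26), slice(33, 37)),
        "TURN": (19, slice(20, 24), slice(32, 36)),
    }
    with open(path) as handle:
        for line in handle:
            rec = line[:6].strip()
            if rec not in spans:
                continue
            chain_col, start_sl, end_sl = cols[rec]
            try:
                chain = line[chain_col].strip()
                start = int(line[start_sl])
                end = int(line[end_sl])
            except (ValueError, IndexError):
                logger.warning("unparseable %s record skipped: %s", rec, line.rstrip())
                continue
            spans[rec].append((chain, start, end))
    return spans


def read_pdb(path: str | Path, chain: str | None = None) -> ProteinModel:
    """Parse a PDB file into a structure-bearing :class:`ProteinModel`.

    Uses the first model and, by default, the first chain. ANISOU, REMARK and
    hetero records are ignored, except for mappable nonstandard residues
    (e.g. MSE→MET). Residues lacking a Cα atom are dropped with a warning.

    Parameters
    ----------
    path : path to the PDB file
    chain : chain identifier; default is the first chain in the file.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no ATOM records found")
    chains = {c.id: c for c in models[0]}
    if not chains:
        raise ValueError(f"{path}: no ATOM records found")
    if chain is None:
        chain_id = next(iter(chains))
    else:
        if chain not in chains:
            raise KeyError(
                f"{path}: chain {chain!r} not found (available: {sorted(chains)})"
            )
        chain_id = chain

    residues: list[ResidueRecord] = []
    resseq_to_pos: dict[int, int] = {}
    for bio_res in chains[chain_id]:
        resname = bio_res.get_resname().strip()
        aa_type = resname if resname in THREE_TO_ONE else NONSTANDARD_MAP.get(resname)
        if aa_type is None:
            if bio_res.id[0] == " ":
                logger.warning(
                    "%s: dropping unmappable residue %s %s", path.name,
                    resname, bio_res.id[1],
                )
            continue
        atoms = {a.get_name(): np.asarray(a.get_coord(), dtype=float)
                 for a in bio_res.get_atoms()}
        if "CA" not in atoms:
            logger.warning(
                "%s: dropping residue %s %s without Cα", path.name,
                resname, bio_res.id[1],
            )
            continue
        pos = len(residues) + 1
        residues.append(ResidueRecord(
            position=pos, aa_type=aa_type, atoms=atoms, ss_label="COIL",
            resseq=bio_res.id[1],
        ))
        resseq_to_pos[bio_res.id[1]] = pos

    if not residues:
        raise ValueError(f"{path}: no standard amino-acid residues in chain {chain_id!r}")

    spans = _scan_ss_records(path)
    for label in ("TURN", "SHEET", "HELIX"):  # HELIX takes precedence on overlap
        for span_chain, start, end in spans[label]:
            if span_chain and span_chain != chain_id:
                continue
            for resseq in range(start, end + 1):
                pos = resseq_to_pos.get(resseq)
                if pos is not None:
                    residues[pos - 1].ss_label = label

    return ProteinModel(
        id=path.stem, residues=residues, has_structure=True, source_format="PDB"
    )


def read_fasta(path: str | Path) -> list[ProteinModel]:
    """Parse a FASTA/multi-FASTA file into sequence-only models.

    Letters outside the 20 standard residues (X, B, Z, U, O, …) are dropped
    with a warning; case is normalised.
    """
    path = Path(path)
    models: list[ProteinModel] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        residues: list[ResidueRecord] = []
        for letter in seq:
            if letter not in ONE_TO_THREE:
                logger.warning(
                    "%s: dropping unknown residue letter %r in %s",
                    path.name, letter, record.id,
                )
                continue
            residues.append(ResidueRecord(
                position=len(residues) + 1, aa_type=ONE_TO_THREE[letter]
            ))
        if not residues:
            raise ValueError(f"{path}: record {record.id!r} has no usable residues")
        models.append(ProteinModel(
            id=record.id, residues=residues, has_structure=False,
            source_format="FASTA",
        ))
    if not models:
        raise ValueError(f"{path}: no FASTA records found")
    return models


def write_pdb(model: ProteinModel, path: str | Path) -> Path:
    """Write a minimal PDB file (ATOM + HELIX/SHEET/TURN records, chain A)."""
    if not model.has_structure:
        raise ValueError("cannot write a PDB file for a sequence-only model")
    path = Path(path)
    lines: list[str] = []

    def runs(label: str) -> list[tuple[int, int]]:
        out, start = [], None
        for res in model.residues:
            if res.ss_label == label:
                if start is None:
                    start = res.position
            elif start is not None:
                out.append((start, res.position - 1))
                start = None
        if start is not None:
            out.append((start, model.residues[-1].position))
        return out

    for n, (start, end) in enumerate(runs("HELIX"), start=1):
        lines.append(
            f"HELIX  {n:>3} {n:>3} {model.residues[start - 1].aa_type} A {start:>4} "
            f"{model.residues[end - 1].aa_type} A {end:>4}  1{'':>30}{end - start + 1:>6}"
        )
    for n, (start, end) in enumerate(runs("SHEET"), start=1):
        lines.append(
            f"SHEET  {n:>3}   A 1 {model.residues[start - 1].aa_type} A{start:>4} "
            f"{model.residues[end - 1].aa_type} A{end:>4}  0"
        )
    for n, (start, end) in enumerate(runs("TURN"), start=1):
        lines.append(
            f"TURN   {n:>3} T{n:<2} {model.residues[start - 1].aa_type} A{start:>4} "
            f"{model.residues[end - 1].aa_type} A{end:>4}"
        )

    serial = 1
    for res in model.residues:
        for name, xyz in res.atoms.items():
            element = name.lstrip("0123456789")[:1]
            lines.append(
                f"ATOM  {serial:>5} {name:^4} {res.aa_type} A{res.position:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"{'':>10}{element:>2}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def _sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-spiral lattice)."""
    idx = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / n)
    theta = math.pi * (1.0 + 5.0 ** 0.5) * idx
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def atom_radius(atom_name: str) -> float:
    element = atom_name.strip().lstrip("0123456789")[:1].upper()
    return VDW_RADII.get(element, DEFAULT_RADIUS)


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible surface areas (Å²) by the Shrake–Rupley method.

    Each atom's probe-inflated sphere is sampled at ``n_points`` quasi-uniform
    points; a point counts as accessible when it lies outside every other
    atom's inflated sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n_atoms = len(coords)
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.empty(n_atoms)
    max_reach = radii.max()
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + max_reach)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= radii[j] ** 2
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return areas


def compute_sasa(
    model: ProteinModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> ProteinModel:
    """Annotate every residue with its relative solvent accessibility.

    Relative SASA is the residue's summed accessible atom area divided by a
    per-type reference maximum, clipped to [0, 1]. For full-atom models the
    reference is the Tien-style theoretical maximum; for Cα-only models
    (synthetic traces) it is the isolated single-sphere area
    4π(r_C + probe)², since the full-atom maxima presuppose side chains.
    Returns the same model with ``rel_sasa`` set.
    """
    if not model.has_structure:
        raise ValueError("SASA requires a 3D structure (sequence-only model)")
    coords, radii, owner = [], [], []
    for i, res in enumerate(model.residues):
        for name, xyz in res.atoms.items():
            coords.append(xyz)
            radii.append(atom_radius(name))
            owner.append(i)
    coords_arr = np.asarray(coords)
    areas = shrake_rupley(coords_arr, np.asarray(radii), probe_radius, n_points)

    per_res = np.zeros(len(model))
    np.add.at(per_res, owner, areas)

    ca_only = all(set(res.atoms) <= {"CA"} for res in model.residues)
    sphere_ref = 4.0 * math.pi * (VDW_RADII["C"] + probe_radius) ** 2
    for i, res in enumerate(model.residues):
        ref = sphere_ref if ca_only else MAX_SASA[res.one_letter]
        res.rel_sasa = float(np.clip(per_res[i] / ref, 0.0, 1.0))
    return model
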