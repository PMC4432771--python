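"""Amino-acid property scales and classification tables.

All built-in scales are keyed by one-letter code and sourced from the original
publications: Kyte & Doolittle (1982) hydropathy, the Hellberg/Wold principal
property z-scales (1987), Levitt (1978) conformational preferences, plus the
isoelectric point and the average residue mass. User tables loaded from
tab-delimited files are registered alongside the built-ins.
"""

from __future__ import annotations

from pathlib import Path

__all__ = [
    "AA1",
    "AA3",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "PROPERTY_CLASSES",
    "MAX_SASA",
    "get_scale",
    "list_scales",
    "register_scale",
    "load_property_table",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
AA3 = sorted(THREE_TO_ONE)

# Kyte & Doolittle hydropathy
_HP = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Hellberg z-scales: z1 hydrophilicity, z2 steric bulk, z3 polarity
_Z = {
    "A": (0.07, -1.73, 0.09), "V": (-2.69, -2.53, -1.29),
    "L": (-4.19, -1.03, -0.98), "I": (-4.44, -1.68, -1.03),
    "P": (-1.22, 0.88, 2.23), "F": (-4.92, 1.30, 0.45),
    "W": (-4.75, 3.65, 0.85), "M": (-2.49, -0.27, -0.41),
    "K": (2.84, 1.41, -3.14), "R": (2.88, 2.52, -3.44),
    "H": (2.41, 1.74, 1.11), "G": (2.23, -5.36, 0.30),
    "S": (1.96, -1.63, 0.57), "T": (0.92, -2.09, -1.40),
    "C": (0.71, -0.97, 4.13), "Y": (1.39, 2.32, 0.01),
    "N": (3.22, 1.45, 0.84), "Q": (2.18, 0.53, -1.14),
    "D": (3.64, 1.13, 2.36), "E": (3.08, 0.39, -0.07),
}

# Levitt conformational preferences: P(alpha), P(beta), P(turn)
_LEVITT = {
    "A": (1.29, 0.90, 0.78), "R": (0.96, 0.99, 0.88),
    "N": (0.90, 0.76, 1.28), "D": (1.04, 0.72, 1.41),
    "C": (1.11, 0.74, 0.80), "Q": (1.27, 0.80, 0.97),
    "E": (1.44, 0.75, 1.00), "G": (0.56, 0.92, 1.64),
    "H": (1.22, 1.08, 0.69), "I": (0.97, 1.45, 0.51),
    "L": (1.30, 1.02, 0.59), "K": (1.23, 0.77, 0.96),
    "M": (1.47, 0.97, 0.39), "F": (1.07, 1.32, 0.58),
    "P": (0.52, 0.64, 1.91), "S": (0.82, 0.95, 1.33),
    "T": (0.82, 1.21, 1.03), "W": (0.99, 1.14, 0.75),
    "Y": (0.72, 1.25, 1.05), "V": (0.91, 1.49, 0.47),
}

_PI = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.60, "W": 5.89, "Y": 5.66, "V": 5.96,
}

# average residue (monomer minus water) masses, Da
_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

_REGISTRY: dict[str, dict[str, float]] = {
    "HP": dict(_HP),
    "z1": {a: v[0] for a, v in _Z.items()},
    "z2": {a: v[1] for a, v in _Z.items()},
    "z3": {a: v[2] for a, v in _Z.items()},
    "Pa": {a: v[0] for a, v in _LEVITT.items()},
    "Pb": {a: v[1] for a, v in _LEVITT.items()},
    "Pt": {a: v[2] for a, v in _LEVITT.items()},
    "IP": dict(_PI),
    "Mw": dict(_MASS),
}

# Physicochemical residue classes (IUPAC-conventional; HIS is deliberately
# both basic and aromatic). Group tags follow the descriptor-name grammar.
PROPERTY_CLASSES: dict[str, frozenset[str]] = {
    "POL": frozenset("RNDQEHKSTY"),       # polar
    "NPL": frozenset("ACGILMFPWV"),       # nonpolar
    "BSC": frozenset("KRH"),              # basic
    "ACD": frozenset("DE"),               # acidic
    "ARM": frozenset("FWYH"),             # aromatic
    "ALF": frozenset("AGILPV"),           # aliphatic
    "CHG": frozenset("DEKRH"),            # charged = basic ∪ acidic
    "TNY": frozenset("ACGS"),             # tiny
    "SML": frozenset("ACDGNPSTV"),        # small
}

# Theoretical maximum accessible surface areas (Å²), Tien et al. style,
# used as denominators for relative SASA of full-atom residues.
MAX_SASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# side-chain formal charges at neutral pH (HIS half-protonated)
CHARGE: dict[str, float] = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}


def list_scales() -> list[str]:
    """Names of all registered per-residue property scales."""
    return sorted(_REGISTRY)


def get_scale(name: str) -> dict[str, float]:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown property scale {name!r}; registered scales: {list_scales()}"
        ) from None


def register_scale(name: str, table: dict[str, float]) -> None:
    """Register a user scale. Keys may be one- or three-letter codes."""
    norm: dict[str, float] = {}
    for key, val in table.items():
        key = key.strip().upper()
        if len(key) == 3:
            key = THREE_TO_ONE.get(key, "")
        if key not in ONE_TO_THREE:
            continue
        norm[key] = float(val)
    missing = set(AA1) - set(norm)
    if missing:
        raise ValueError(f"scale {name!r} missing values for: {sorted(missing)}")
    _REGISTRY[name] = norm


def load_property_table(path: str | Path) -> list[str]:
    """Load a tab-delimited property table and register one scale per column.

    First row is a header of scale names; first column holds one- or
    three-letter residue codes. Returns the registered scale names.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty property table: {path}")
    header = lines[0].split("\t")
    names = [h.strip() for h in header[1:]]
    columns: dict[str, dict[str, float]] = {n: {} for n in names}
    for line in lines[1:]:
        fields = line.split("\t")
        code = fields[0].strip()
        for name, field in zip(names, fields[1:]):
            columns[name][code] = float(field)
    for name in names:
        register_scale(name, columns[name])
    return names
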