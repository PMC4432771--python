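"""Per-residue index vectors: topographic contact-based indices, amino-acid
property scales, and thermodynamic-style energy indices.

Topographic indices follow the residue-level redefinition pattern of the
weighted contact order wCO_i = (1/(2·N·N_c)) Σ_j ω_ij δ_ij: each whole-protein
index is split into per-residue contributions such that, without weighting,
summing the contributions recovers the original whole-protein quantity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .protein_io import ProteinModel
from .scales import CHARGE, get_scale
from . import scales as _scales

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "IndexVector",
    "build_contact_map",
    "weighted_contact_order",
    "topographic_index",
    "property_index",
    "thermodynamic_index",
    "TOPOGRAPHIC_INDICES",
    "THERMODYNAMIC_INDICES",
]

DEFAULT_D_CUT = 8.0   # Å spatial contact threshold
DEFAULT_T_CUT = 4     # minimum sequence separation (exclusive)


@dataclass
class IndexVector:
    """One real value per residue for a named index (the L_i array)."""

    protein_id: str
    index_name: str
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("index values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"index {self.index_name!r} on {self.protein_id!r} "
                "contains non-finite values"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ContactMap:
    """Pairwise residue contacts δ_ij with their weighting coefficients ω_ij.

    δ_ij is true iff the Cα spatial distance is below ``d_cut`` and the
    sequence separation |i−j| exceeds ``t_cut``. ω_ij is 1 (no weighting),
    the sequence separation ΔN_ij, or a per-residue property product ω_i·ω_j.
    """

    n: int
    d_cut: float
    t_cut: int
    delta: np.ndarray       # (n, n) bool, symmetric, zero diagonal
    omega: np.ndarray       # (n, n) float, symmetric
    weight_scheme: str = "none"

    @property
    def n_contacts(self) -> int:
        return int(self.delta.sum()) // 2

    @property
    def seq_separation(self) -> np.ndarray:
        idx = np.arange(self.n)
        return np.abs(idx[:, None] - idx[None, :]).astype(float)


def build_contact_map(
    model: ProteinModel,
    d_cut: float = DEFAULT_D_CUT,
    t_cut: int = DEFAULT_T_CUT,
    weight_scheme: str = "none",
) -> ContactMap:
    """Build the Cα contact map of a structure.

    Parameters
    ----------
    d_cut : spatial cutoff in Å; residues closer than this may contact.
    t_cut : topological cutoff; a contact requires |i−j| strictly greater.
    weight_scheme : "none" (ω≡1), "seq_separation" (ω_ij = |i−j|), or
        "property:<scale>" (ω_ij = ω_i·ω_j from the named property scale).
    """
    if not model.has_structure:
        raise ValueError("contact map requires a 3D structure")
    if d_cut <= 0 or t_cut < 0:
        raise ValueError("d_cut must be positive and t_cut non-negative")
    n = len(model)
    coords = model.ca_coords()
    missing = np.isnan(coords).any(axis=1)
    if missing.any():
        logger.warning(
            "%s: %d residues lack Cα and participate in no contacts",
            model.id, int(missing.sum()),
        )
    with np.errstate(invalid="ignore"):
        dist = squareform(pdist(np.nan_to_num(coords, nan=1e9)))
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    delta = (dist < d_cut) & (sep > t_cut)
    delta[missing, :] = False
    delta[:, missing] = False
    np.fill_diagonal(delta, False)

    if weight_scheme == "none":
        omega = np.ones((n, n))
    elif weight_scheme == "seq_separation":
        omega = sep.astype(float)
    elif weight_scheme.startswith("property:"):
        scale = get_scale(weight_scheme.split(":", 1)[1])
        w = np.array([scale[r.one_letter] for r in model.residues])
        omega = np.outer(w, w)
    else:
        raise ValueError(
            f"unknown weight scheme {weight_scheme!r}; use 'none', "
            "'seq_separation' or 'property:<scale>'"
        )
    return ContactMap(n=n, d_cut=d_cut, t_cut=t_cut, delta=delta,
                      omega=omega, weight_scheme=weight_scheme)


class DegenerateStructureError(ValueError):
    """Raised when a contact-normalised index is undefined (no contacts)."""


def weighted_contact_order(
    cm: ContactMap,
    protein_id: str = "",
    zero_on_degenerate: bool = False,
) -> IndexVector:
    """Residue-level weighted contact order wCO_i = (1/(2·N·N_c)) Σ_j ω_ij δ_ij.

    Summed over residues with ω = sequence separation this recovers the
    classic whole-protein contact order of Plaxco.
    """
    nc = cm.n_contacts
    if nc == 0:
        if zero_on_degenerate:
            return IndexVector(protein_id, "wCO", np.zeros(cm.n),
                               {"d": cm.d_cut, "t": cm.t_cut})
        raise DegenerateStructureError(
            "contact map has no contacts; wCO is undefined "
            "(pass zero_on_degenerate=True for an all-zero vector)"
        )
    values = (cm.omega * cm.delta).sum(axis=1) / (2.0 * cm.n * nc)
    return IndexVector(protein_id, "wCO", values, {"d": cm.d_cut, "t": cm.t_cut})


def _clq(cm: ContactMap) -> np.ndarray:
    """ω-weighted clustering coefficient (cliquishness) per residue."""
    values = np.zeros(cm.n)
    wdelta = cm.omega * cm.delta
    for i in range(cm.n):
        nbrs = np.flatnonzero(cm.delta[i])
        deg = len(nbrs)
        if deg < 2:
            continue
        sub = wdelta[np.ix_(nbrs, nbrs)]
        values[i] = sub.sum() / 2.0 / (deg * (deg - 1) / 2.0)
    return values


def _backbone_dihedrals(model: ProteinModel) -> list[list[float]]:
    """Available backbone dihedral angles (radians) per residue.

    Uses (φ, ψ) when N/CA/C atoms are present; falls back to the Cα
    pseudo-dihedral over four consecutive Cα atoms otherwise.
    """

    def dihedral(p0, p1, p2, p3) -> float | None:
        b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
        n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
        m1 = np.cross(n1, b1 / np.linalg.norm(b1))
        x, y = n1 @ n2, m1 @ n2
        if x == 0 and y == 0:
            return None
        return math.atan2(y, x)

    res = model.residues
    full = all({"N", "CA", "C"} <= set(r.atoms) for r in res)
    out: list[list[float]] = [[] for _ in res]
    if full:
        for i in range(len(res)):
            if i > 0:
                phi = dihedral(res[i - 1].atoms["C"], res[i].atoms["N"],
                               res[i].atoms["CA"], res[i].atoms["C"])
                if phi is not None:
                    out[i].append(phi)
            if i < len(res) - 1:
                psi = dihedral(res[i].atoms["N"], res[i].atoms["CA"],
                               res[i].atoms["C"], res[i + 1].atoms["N"])
                if psi is not None:
                    out[i].append(psi)
    else:
        coords = model.ca_coords()
        for i in range(1, len(res) - 2):
            quad = coords[i - 1:i + 3]
            if np.isnan(quad).any():
                continue
            tau = dihedral(*quad)
            if tau is not None:
                out[i].append(tau)
    return out


def _lnfd(model: ProteinModel, eps: float) -> np.ndarray:
    """Per-residue folding-degree contribution, log scale.

    The folding degree of a residue is the mean of (1 + cos θ)/2 over its
    available backbone dihedrals θ — near 1 for extended/planar geometry,
    near 0 for tightly folded-back geometry. The log is floored at ``eps``.
    """
    dihedrals = _backbone_dihedrals(model)
    values = np.empty(len(model))
    for i, angles in enumerate(dihedrals):
        if angles:
            f = float(np.mean([(1.0 + math.cos(a)) / 2.0 for a in angles]))
        else:
            f = eps
        values[i] = math.log(max(f, eps))
    return values


TOPOGRAPHIC_INDICES = ("wCO", "wLRO", "wTCD", "wNc", "wCLQ", "lnFD")


def topographic_index(
    model: ProteinModel,
    cm: ContactMap | None,
    name: str,
    zero_on_degenerate: bool = False,
    eps: float = 1e-6,
) -> IndexVector:
    """Compute one residue-level topographic index.

    wNc_i = Σ_j ω_ij δ_ij;  wLRO_i = (1/(2N)) Σ_j ω_ij δ_ij;
    wTCD_i = (1/(2N²)) Σ_j ΔN_ij ω_ij δ_ij;  wCO_i as in
    :func:`weighted_contact_order`;  wCLQ_i = weighted clustering
    coefficient of the contact graph;  lnFD_i = log folding degree from
    backbone dihedrals (contact map unused).
    """
    if not model.has_structure:
        raise ValueError("topographic indices require a 3D structure")
    if name == "lnFD":
        return IndexVector(model.id, "lnFD", _lnfd(model, eps), {"eps": eps})
    if cm is None:
        raise ValueError(f"index {name!r} requires a contact map")
    if cm.n != len(model):
        raise ValueError("contact map size does not match the model")
    params = {"d": cm.d_cut, "t": cm.t_cut, "omega": cm.weight_scheme}
    if name == "wCO":
        vec = weighted_contact_order(cm, model.id, zero_on_degenerate)
        vec.params = params
        return vec
    if name == "wNc":
        values = (cm.omega * cm.delta).sum(axis=1)
    elif name == "wLRO":
        values = (cm.omega * cm.delta).sum(axis=1) / (2.0 * cm.n)
    elif name == "wTCD":
        values = (cm.seq_separation * cm.omega * cm.delta).sum(axis=1) / (2.0 * cm.n ** 2)
    elif name == "wCLQ":
        values = _clq(cm)
    else:
        raise ValueError(
            f"unknown topographic index {name!r}; supported: {TOPOGRAPHIC_INDICES}"
        )
    return IndexVector(model.id, name, values, params)


def property_index(model: ProteinModel, scale: str) -> IndexVector:
    """Per-residue lookup of a registered amino-acid property scale."""
    table = get_scale(scale)
    values = np.array([table[r.one_letter] for r in model.residues])
    return IndexVector(model.id, scale, values, {"scale": scale})


# --- thermodynamic-style energy indices -----------------------------------
# Surrogate functional forms (the field's standard shapes); each is
# registry-pluggable so alternative parameterisations can be swapped in
# without API changes. Favourable contributions are negative.

_COULOMB = 332.0   # kcal·Å/(mol·e²)
_DIELECTRIC = 40.0
_SCREENING = 10.0  # Å Debye-like screening length
_LJ_EPS = 0.1      # kcal/mol well depth
_HB_ENERGY = -1.0  # kcal/mol per backbone hydrogen bond
_HB_CUTOFF = 3.5   # Å O···N distance


def _charges(model: ProteinModel) -> np.ndarray:
    return np.array([CHARGE.get(r.one_letter, 0.0) for r in model.residues])


def _electrostatic(model: ProteinModel) -> np.ndarray:
    q = _charges(model)
    coords = model.ca_coords()
    values = np.zeros(len(model))
    charged = np.flatnonzero(q != 0)
    for a, i in enumerate(charged):
        for j in charged[a + 1:]:
            if np.isnan(coords[i]).any() or np.isnan(coords[j]).any():
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r < 1e-6:
                continue
            e = _COULOMB * q[i] * q[j] * math.exp(-r / _SCREENING) / (_DIELECTRIC * r)
            values[i] += e / 2.0
            values[j] += e / 2.0
    return values


def _vdw_radius(aa1: str) -> float:
    # effective residue radius from the average residue mass
    return 0.8 * _scales.get_scale("Mw")[aa1] ** (1.0 / 3.0)


def _van_der_waals(model: ProteinModel) -> np.ndarray:
    coords = model.ca_coords()
    radii = np.array([_vdw_radius(r.one_letter) for r in model.residues])
    n = len(model)
    values = np.zeros(n)
    for i in range(n):
        for j in range(i + 3, n):  # skip bonded/adjacent pairs
            if np.isnan(coords[i]).any() or np.isnan(coords[j]).any():
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r < 1e-6 or r > 12.0:
                continue
            sigma = radii[i] + radii[j]
            x6 = (sigma / r) ** 6
            e = _LJ_EPS * (x6 * x6 - 2.0 * x6)
            values[i] += e / 2.0
            values[j] += e / 2.0
    return values


def _hbond(model: ProteinModel) -> np.ndarray:
    values = np.zeros(len(model))
    res = model.residues
    for i, ri in enumerate(res):
        o = ri.atoms.get("O")
        if o is None:
            continue
        for j, rj in enumerate(res):
            if abs(i - j) < 3:
                continue
            nn = rj.atoms.get("N")
            if nn is None:
                continue
            if float(np.linalg.norm(o - nn)) < _HB_CUTOFF:
                values[i] += _HB_ENERGY / 2.0
                values[j] += _HB_ENERGY / 2.0
    return values


def _torsion(model: ProteinModel) -> np.ndarray:
    # threefold dihedral potential, minimum 0 at staggered geometry,
    # shifted so every term is ≤ 0
    dihedrals = _backbone_dihedrals(model)
    values = np.zeros(len(model))
    for i, angles in enumerate(dihedrals):
        for a in angles:
            values[i] += 0.5 * (1.0 + math.cos(3.0 * a)) - 1.0
    return values


def _hydrophobic(model: ProteinModel) -> np.ndarray:
    from .protein_io import compute_sasa

    if any(r.rel_sasa is None for r in model.residues):
        compute_sasa(model)
    hp = get_scale("HP")
    return np.array([
        hp[r.one_letter] * (1.0 - r.rel_sasa) for r in model.residues
    ])


def _electrostatic_seq(model: ProteinModel) -> np.ndarray:
    q = _charges(model)
    n = len(model)
    values = np.zeros(n)
    for i in range(n):
        for j in range(max(0, i - 4), min(n, i + 5)):
            if j == i:
                continue
            values[i] += 0.5 * q[i] * q[j] / abs(i - j)
    return values


def _hydrophobic_seq(model: ProteinModel) -> np.ndarray:
    hp = get_scale("HP")
    return np.array([-hp[r.one_letter] for r in model.residues])


def _torsion_seq(model: ProteinModel) -> np.ndarray:
    # conformational-entropy proxy from Levitt preferences
    pa, pb, pt = get_scale("Pa"), get_scale("Pb"), get_scale("Pt")
    return np.array([
        -math.log(max(pa[r.one_letter], pb[r.one_letter], pt[r.one_letter]))
        for r in model.residues
    ])


#: name → (function, requires 3D structure)
THERMO_REGISTRY: dict[str, tuple] = {
    "Gc": (_electrostatic, True),
    "Gw": (_van_der_waals, True),
    "Ghb": (_hbond, True),
    "Gtor": (_torsion, True),
    "Ghp": (_hydrophobic, True),
    "Gc(U)": (_electrostatic_seq, False),
    "Ghp(U)": (_hydrophobic_seq, False),
    "Gtor(U)": (_torsion_seq, False),
}

THERMODYNAMIC_INDICES = tuple(THERMO_REGISTRY)


def thermodynamic_index(model: ProteinModel, name: str) -> IndexVector:
    """Per-residue energy-like contribution for a named thermodynamic index.

    Structure-based members (Gc, Gw, Ghb, Gtor, Ghp) require coordinates;
    the (U) members are sequence-based unfolded-state analogues built from
    scale lookups only.
    """
    try:
        func, needs_structure = THERMO_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown thermodynamic index {name!r}; "
            f"supported: {THERMODYNAMIC_INDICES}"
        ) from None
    if needs_structure and not model.has_structure:
        raise ValueError(
            f"thermodynamic index {name!r} requires a 3D structure "
            "(sequence-only model given)"
        )
    return IndexVector(model.id, name, func(model))
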