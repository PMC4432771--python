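"""Descriptor-generation engine.

Orchestrates the four-level combinatorial pipeline — index × weighting ×
group × aggregation — over a set of proteins, names each descriptor
``<index>[_<weightop><k>]_<group>_<aggregator>`` (e.g. ``HP_PRT_Q2``), and
writes tab-delimited residue-level (``*_AA.txt``) and protein-level
(``*_Prot.txt``) tables.

The engine is exposed as two scikit-learn estimators:

- :class:`DescriptorCalculator` — a transformer mapping a list of
  :class:`~protdescal.protein_io.ProteinModel` to the proteins × descriptors
  matrix;
- :class:`ShannonRelevanceFilter` — a feature selector ranking descriptors
  by the Shannon entropy of their histogram across proteins (Godden-style
  variability test) and keeping those above a threshold.

Module-level functions (:func:`generate_descriptors`,
:func:`shannon_relevance`, :func:`distance_matrix`, :func:`run_project`)
are thin wrappers over these estimators.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin

from . import grouping as _grouping
from .aggregation import AGGREGATORS, AggregatorSpec, DEFAULT_IC_PRECISION, aggregate
from .grouping import DEFAULT_SASA_CUTOFF, STRUCTURE_GROUP_NAMES
from .indices import (
    DEFAULT_D_CUT,
    DEFAULT_T_CUT,
    THERMO_REGISTRY,
    TOPOGRAPHIC_INDICES,
    build_contact_map,
    property_index,
    thermodynamic_index,
    topographic_index,
)
from .protein_io import ProteinModel, compute_sasa, read_fasta, read_pdb
from .scales import AA3, PROPERTY_CLASSES, list_scales
from .weighting import WeightingSpec, apply_weighting

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorTable",
    "ProjectConfig",
    "DescriptorCalculator",
    "ShannonRelevanceFilter",
    "generate_descriptors",
    "write_outputs",
    "read_descriptor_table",
    "shannon_relevance",
    "distance_matrix",
    "run_project",
    "run_multi",
]

DEFAULT_SENTINEL = "NA"
DEFAULT_N_BINS = 20
_NUM_FMT = "%.5E"  # six significant digits, scientific


@dataclass
class DescriptorTable:
    """Rectangular proteins × descriptors matrix; NaN is the missing sentinel."""

    protein_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.descriptor_names)):
            raise ValueError("values shape does not match ids × descriptors")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids,
                            columns=self.descriptor_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorTable":
        return cls(list(frame.index.astype(str)), list(frame.columns),
                   frame.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# selection parsing

_GROUP_FAMILIES = {
    "type": list(AA3),
    "property": list(PROPERTY_CLASSES),
    "structure": list(STRUCTURE_GROUP_NAMES),
}


def _expand_groups(names: list[str]) -> list[str]:
    out: list[str] = []
    for name in names:
        expansion = _GROUP_FAMILIES.get(name.lower(), [name])
        for g in expansion:
            if g not in out:
                out.append(g)
    return out


def _parse_weighting(item) -> WeightingSpec:
    if isinstance(item, WeightingSpec):
        return item
    if isinstance(item, dict):
        return WeightingSpec(item.get("op", "NONE"), int(item.get("k", 1)))
    text = str(item).strip().upper()
    match = re.fullmatch(r"(NONE|AC|KH|ES|IB|GR)(\d+)?", text)
    if not match:
        raise ValueError(f"cannot parse weighting spec {item!r} (e.g. 'AC2', 'ES', 'none')")
    return WeightingSpec(match.group(1), int(match.group(2) or 1))


def _index_kind(name: str) -> tuple[str, bool]:
    """Classify an index name → (family, requires_structure)."""
    if name in TOPOGRAPHIC_INDICES:
        return "topographic", True
    if name in THERMO_REGISTRY:
        return "thermodynamic", THERMO_REGISTRY[name][1]
    if name in list_scales():
        return "property", False
    raise ValueError(
        f"unknown index {name!r}; supported: property scales {list_scales()}, "
        f"topographic {TOPOGRAPHIC_INDICES}, thermodynamic {tuple(THERMO_REGISTRY)}"
    )


# ---------------------------------------------------------------------------
# estimators


class DescriptorCalculator(BaseEstimator, TransformerMixin):
    """Transform proteins into a descriptor matrix.

    The descriptor set is the full cross product of the selected indices,
    weighting operators, residue groups and aggregation operators, so the
    output always has ``|I|·|W|·|G|·|A|`` columns.

    Parameters
    ----------
    indices : index names — property scales (``HP``, ``z1`` …), topographic
        (``wCO``, ``wLRO``, ``wTCD``, ``wNc``, ``wCLQ``, ``lnFD``) or
        thermodynamic (``Gc``, ``Gw``, ``Ghb``, ``Gtor``, ``Ghp`` and their
        sequence-based ``(U)`` analogues).
    weightings : neighbourhood operators, e.g. ``["none", "AC2", "ES"]``.
    groups : group names or family shortcuts ``type``/``property``/``structure``.
    aggregators : aggregation operator names (``Q2``, ``AM``, ``TIC`` …).
    d_cut, t_cut : contact-map thresholds (Å / sequence separation).
    contact_weight : ω scheme for contacts — ``none``, ``seq_separation``
        or ``property:<scale>``.
    sasa_cutoff : relative-SASA threshold for the INT/SUP partition.
    probe_radius : solvent probe radius in Å.
    ic_precision : rounding precision for information-content classes.
    strict : raise instead of emitting sentinel columns when a selection is
        incompatible with an input (e.g. a structure index on FASTA input).
    zero_on_degenerate : emit zeros instead of raising when a contact-
        normalised index is undefined (structure with no contacts).
    """

    def __init__(
        self,
        indices=("HP",),
        weightings=("none",),
        groups=("PRT",),
        aggregators=("Q2",),
        d_cut=DEFAULT_D_CUT,
        t_cut=DEFAULT_T_CUT,
        contact_weight="none",
        sasa_cutoff=DEFAULT_SASA_CUTOFF,
        probe_radius=1.4,
        ic_precision=DEFAULT_IC_PRECISION,
        strict=False,
        zero_on_degenerate=False,
    ):
        self.indices = indices
        self.weightings = weightings
        self.groups = groups
        self.aggregators = aggregators
        self.d_cut = d_cut
        self.t_cut = t_cut
        self.contact_weight = contact_weight
        self.sasa_cutoff = sasa_cutoff
        self.probe_radius = probe_radius
        self.ic_precision = ic_precision
        self.strict = strict
        self.zero_on_degenerate = zero_on_degenerate

    # -- sklearn plumbing ---------------------------------------------------

    def fit(self, X=None, y=None):
        """Validate the selection and freeze the descriptor-name grammar."""
        if not self.indices:
            raise ValueError("at least one index must be selected")
        for name in self.indices:
            _index_kind(name)
        self.weighting_specs_ = [_parse_weighting(w) for w in self.weightings]
        if not self.weighting_specs_:
            raise ValueError("at least one weighting (possibly 'none') is required")
        self.group_names_ = _expand_groups(list(self.groups))
        if not self.group_names_:
            raise ValueError("at least one residue group is required")
        known = set(AA3) | set(PROPERTY_CLASSES) | set(STRUCTURE_GROUP_NAMES)
        for g in self.group_names_:
            if g not in known:
                raise ValueError(f"unknown residue group {g!r}")
        self.aggregator_specs_ = [
            AggregatorSpec(a, {"precision": self.ic_precision}) for a in self.aggregators
        ]
        if not self.aggregator_specs_:
            raise ValueError("at least one aggregation operator is required")
        self.descriptor_names_ = [
            "_".join(filter(None, [idx, spec.tag, grp, agg.name]))
            for idx in self.indices
            for spec in self.weighting_specs_
            for grp in self.group_names_
            for agg in self.aggregator_specs_
        ]
        if len(set(self.descriptor_names_)) != len(self.descriptor_names_):
            raise ValueError("duplicate selections produce non-unique descriptor names")
        return self

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.descriptor_names_, dtype=object)

    def transform(self, X) -> np.ndarray:
        """Proteins × descriptors matrix (NaN = missing sentinel)."""
        return self.compute(X)[1].values

    # -- computation --------------------------------------------------------

    def _groups_for(self, model: ProteinModel) -> dict[str, tuple[int, ...] | None]:
        """Resolve selected group names to member tuples (None = unavailable)."""
        lookup: dict[str, tuple[int, ...] | None] = {}
        wanted = set(self.group_names_)
        if wanted & set(AA3):
            for grp in _grouping.type_groups(model):
                lookup[grp.name] = grp.members
        if wanted & set(PROPERTY_CLASSES):
            for grp in _grouping.property_groups(model):
                lookup[grp.name] = grp.members
        structural = wanted & set(STRUCTURE_GROUP_NAMES) - {"PRT"}
        if structural:
            if model.has_structure:
                if {"INT", "SUP"} & structural and any(
                    r.rel_sasa is None for r in model.residues
                ):
                    compute_sasa(model, probe_radius=self.probe_radius)
                for grp in _grouping.structure_groups(model, self.sasa_cutoff):
                    lookup[grp.name] = grp.members
            else:
                message = (
                    f"protein {model.id!r}: structure-based groups "
                    f"{sorted(structural)} unavailable on sequence-only input"
                )
                if self.strict:
                    raise ValueError(message)
                logger.warning("%s; emitting sentinel", message)
                for name in structural:
                    lookup[name] = None
        lookup["PRT"] = tuple(range(1, len(model) + 1))
        return lookup

    def _index_vectors(self, model: ProteinModel) -> dict[str, np.ndarray | None]:
        """Raw (pre-weighting) index vectors; None where unavailable."""
        out: dict[str, np.ndarray | None] = {}
        cm = None
        needs_cm = any(
            _index_kind(i)[0] == "topographic" and i != "lnFD" for i in self.indices
        )
        if needs_cm and model.has_structure:
            cm = build_contact_map(model, self.d_cut, self.t_cut, self.contact_weight)
        for name in self.indices:
            family, needs_structure = _index_kind(name)
            if needs_structure and not model.has_structure:
                message = (
                    f"protein {model.id!r}: structure-based index {name!r} "
                    "unavailable on sequence-only input"
                )
                if self.strict:
                    raise ValueError(message)
                logger.warning("%s; emitting sentinel", message)
                out[name] = None
                continue
            if family == "property":
                out[name] = property_index(model, name).values
            elif family == "thermodynamic":
                out[name] = thermodynamic_index(model, name).values
            else:
                out[name] = topographic_index(
                    model, cm, name, zero_on_degenerate=self.zero_on_degenerate
                ).values
        return out

    def compute(self, models: list[ProteinModel]) -> tuple[pd.DataFrame, DescriptorTable]:
        """Run the full pipeline.

        Returns the residue-level table (rows ``<id>_aa<pos>_<TYPE>``,
        columns = post-weighting index vectors) and the protein-level
        :class:`DescriptorTable`.
        """
        if not models:
            raise ValueError("no input proteins")
        if not hasattr(self, "descriptor_names_"):
            self.fit()
        residue_rows: list[pd.DataFrame] = []
        matrix = np.full((len(models), len(self.descriptor_names_)), np.nan)
        from .indices import IndexVector

        for p, model in enumerate(models):
            raw = self._index_vectors(model)
            group_lookup = self._groups_for(model)
            labels = [
                f"{model.id}_aa{r.position}_{r.aa_type}" for r in model.residues
            ]
            residue_cols: dict[str, np.ndarray] = {}
            col = 0
            for idx_name in self.indices:
                base = raw[idx_name]
                for spec in self.weighting_specs_:
                    col_tag = "_".join(filter(None, [idx_name, spec.tag]))
                    if base is None:
                        weighted = None
                        residue_cols[col_tag] = np.full(len(model), np.nan)
                    else:
                        vec = IndexVector(model.id, idx_name, base)
                        weighted = apply_weighting(vec, spec).values
                        residue_cols[col_tag] = weighted
                    for grp in self.group_names_:
                        members = group_lookup[grp]
                        for agg in self.aggregator_specs_:
                            if weighted is None or members is None:
                                value = None
                            else:
                                value = aggregate(
                                    [weighted[m - 1] for m in members], agg
                                )
                            matrix[p, col] = np.nan if value is None else value
                            col += 1
            residue_rows.append(pd.DataFrame(residue_cols, index=labels))

        residue_table = pd.concat(residue_rows, axis=0)
        table = DescriptorTable(
            [m.id for m in models], list(self.descriptor_names_), matrix
        )
        return residue_table, table


class ShannonRelevanceFilter(SelectorMixin, BaseEstimator):
    """Rank descriptors by histogram Shannon entropy across proteins.

    Each descriptor's values are binned into ``n_bins`` equal-width bins over
    [min, max]; the entropy H = −Σ p·log₂p measures how well the descriptor
    differentiates proteins. Constant (and all-missing) descriptors get H = 0
    and are dropped at the default threshold.

    Attributes
    ----------
    entropies_ : entropy in bits per input descriptor.
    """

    def __init__(self, n_bins: int = DEFAULT_N_BINS, min_entropy: float = 0.0):
        self.n_bins = n_bins
        self.min_entropy = min_entropy

    @staticmethod
    def _column_entropy(values: np.ndarray, n_bins: int) -> float:
        v = values[np.isfinite(values)]
        if len(v) == 0:
            return 0.0
        lo, hi = float(v.min()), float(v.max())
        # a span below float resolution for the bin edges counts as constant
        if hi - lo <= n_bins * np.spacing(max(abs(lo), abs(hi), 1e-300)):
            return 0.0
        counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
        p = counts[counts > 0] / len(v)
        return float(-(p * np.log2(p)).sum())

    def fit(self, X, y=None):
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if isinstance(X, DescriptorTable):
            X = X.to_frame()
        frame = pd.DataFrame(X)
        if len(frame) < 2:
            raise ValueError("relevance ranking needs at least two proteins")
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        values = frame.to_numpy(dtype=float)
        self.entropies_ = np.array([
            self._column_entropy(values[:, j], self.n_bins)
            for j in range(values.shape[1])
        ])
        return self

    def _get_support_mask(self):
        return self.entropies_ > self.min_entropy

    def ranking(self) -> list[tuple[str, float]]:
        """Descriptors sorted by decreasing entropy; ties broken by name."""
        pairs = list(zip(self.feature_names_in_, self.entropies_))
        return sorted(pairs, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# functional wrappers and file I/O


def generate_descriptors(
    models: list[ProteinModel], cfg: "ProjectConfig"
) -> tuple[pd.DataFrame, DescriptorTable]:
    """Run the pipeline described by a project configuration."""
    calc = cfg.calculator().fit()
    return calc.compute(models)


def write_outputs(
    residue_table: pd.DataFrame,
    table: DescriptorTable,
    prefix: str | Path,
    sentinel: str = DEFAULT_SENTINEL,
) -> tuple[Path, Path]:
    """Write ``<prefix>_AA.txt`` and ``<prefix>_Prot.txt`` (tab-delimited)."""
    if residue_table.empty or not table.protein_ids:
        raise ValueError("cannot write empty tables")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aa_path = prefix.parent / (prefix.name + "_AA.txt")
    prot_path = prefix.parent / (prefix.name + "_Prot.txt")
    residue_table.to_csv(
        aa_path, sep="\t", float_format=_NUM_FMT, na_rep=sentinel,
        index_label="Residue",
    )
    table.to_frame().to_csv(
        prot_path, sep="\t", float_format=_NUM_FMT, na_rep=sentinel,
        index_label="Protein",
    )
    return aa_path, prot_path


def read_descriptor_table(
    path: str | Path, sentinel: str = DEFAULT_SENTINEL
) -> DescriptorTable:
    """Read a ``*_Prot.txt`` file back into a :class:`DescriptorTable`."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[sentinel])
    return DescriptorTable.from_frame(frame)


def shannon_relevance(
    table: DescriptorTable | pd.DataFrame, n_bins: int = DEFAULT_N_BINS
) -> list[tuple[str, float]]:
    """Descriptors ranked by histogram Shannon entropy (descending).

    All-missing descriptors are excluded with a warning.
    """
    frame = table.to_frame() if isinstance(table, DescriptorTable) else pd.DataFrame(table)
    dead = [c for c in frame.columns if frame[c].isna().all()]
    if dead:
        logger.warning("excluding %d all-missing descriptors from ranking", len(dead))
        frame = frame.drop(columns=dead)
    selector = ShannonRelevanceFilter(n_bins=n_bins).fit(frame)
    return selector.ranking()


def distance_matrix(
    table: DescriptorTable | pd.DataFrame, metric: str = "euclidean"
) -> pd.DataFrame:
    """Inter-protein distance matrix over sentinel-free descriptors.

    Columns containing missing values are excluded (logged). Supported
    metrics: ``euclidean``, ``manhattan``.
    """
    metrics = {"euclidean": "euclidean", "manhattan": "cityblock"}
    if metric not in metrics:
        raise ValueError(f"unsupported metric {metric!r}; use {sorted(metrics)}")
    frame = table.to_frame() if isinstance(table, DescriptorTable) else pd.DataFrame(table)
    if len(frame) < 2:
        raise ValueError("distance matrix needs at least two proteins")
    usable = frame.dropna(axis=1)
    dropped = frame.shape[1] - usable.shape[1]
    if dropped:
        logger.warning("excluding %d sentinel-bearing descriptors", dropped)
    if usable.shape[1] == 0:
        raise ValueError("no sentinel-free descriptors available")
    values = usable.to_numpy(dtype=float)
    dist = cdist(values, values, metric=metrics[metric])
    return pd.DataFrame(dist, index=frame.index, columns=frame.index)


# ---------------------------------------------------------------------------
# project configuration / batch mode


@dataclass
class ProjectConfig:
    """Declarative description of one descriptor-generation run."""

    inputs: list[str] = field(default_factory=list)
    format: str = "auto"             # pdb | fasta | auto (by extension)
    chain: str | None = None
    indices: list[str] = field(default_factory=lambda: ["HP"])
    weightings: list[str] = field(default_factory=lambda: ["none"])
    groups: list[str] = field(default_factory=lambda: ["PRT"])
    aggregators: list[str] = field(default_factory=lambda: ["Q2"])
    d_cut: float = DEFAULT_D_CUT
    t_cut: int = DEFAULT_T_CUT
    contact_weight: str = "none"
    sasa_cutoff: float = DEFAULT_SASA_CUTOFF
    probe_radius: float = 1.4
    ic_precision: int = DEFAULT_IC_PRECISION
    sentinel: str = DEFAULT_SENTINEL
    strict: bool = False
    zero_on_degenerate: bool = False
    output_prefix: str = "protdescal"
    seed: int = 0
    schema_version: int = 1

    def calculator(self) -> DescriptorCalculator:
        return DescriptorCalculator(
            indices=list(self.indices),
            weightings=list(self.weightings),
            groups=list(self.groups),
            aggregators=list(self.aggregators),
            d_cut=self.d_cut,
            t_cut=self.t_cut,
            contact_weight=self.contact_weight,
            sasa_cutoff=self.sasa_cutoff,
            probe_radius=self.probe_radius,
            ic_precision=self.ic_precision,
            strict=self.strict,
            zero_on_degenerate=self.zero_on_degenerate,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProjectConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: project file must be a key/value mapping")
        valid = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"{path}: unknown project fields {sorted(unknown)}")
        return cls(**data)


def _load_inputs(cfg: ProjectConfig) -> list[ProteinModel]:
    models: list[ProteinModel] = []
    for item in cfg.inputs:
        path = Path(item)
        if not path.exists():
            raise FileNotFoundError(f"input not found: {path}")
        fmt = cfg.format
        if fmt == "auto":
            fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "fasta"
        if fmt == "pdb":
            models.append(read_pdb(path, chain=cfg.chain))
        elif fmt == "fasta":
            models.extend(read_fasta(path))
        else:
            raise ValueError(f"unknown input format {cfg.format!r}")
    if not models:
        raise ValueError("project has no inputs")
    return models


def run_project(cfg_path: str | Path) -> tuple[Path, Path]:
    """Load a project file, run the pipeline, write outputs and a log."""
    cfg = ProjectConfig.load(cfg_path)
    prefix = Path(cfg.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    log_path = prefix.parent / (prefix.name + ".log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.WARNING)
    root = logging.getLogger("protdescal")
    root.addHandler(handler)
    try:
        models = _load_inputs(cfg)
        residue_table, table = generate_descriptors(models, cfg)
        paths = write_outputs(residue_table, table, prefix, cfg.sentinel)
    finally:
        root.removeHandler(handler)
        handler.close()
    return paths


def run_multi(cfg_paths: list[str | Path]) -> list[dict]:
    """Run several project files sequentially; failures are isolated.

    Returns one summary record per project with ``status`` ``ok``/``error``.
    """
    summaries = []
    for cfg_path in cfg_paths:
        record: dict = {"project": str(cfg_path)}
        try:
            aa, prot = run_project(cfg_path)
            record.update(status="ok", aa_file=str(aa), prot_file=str(prot))
        except Exception as exc:  # noqa: BLE001 — batch isolation by contract
            logger.error("project %s failed: %s", cfg_path, exc)
            record.update(status="error", error=str(exc))
        summaries.append(record)
    return summaries
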