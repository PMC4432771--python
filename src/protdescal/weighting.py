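"""Neighbourhood weighting operators over sequence topology.

Each operator transforms an index vector L according to the residue's
neighbourhood on the chain, with topological distance d_ij = |j − i|:

- AC (autocorrelation):  AC_i^k = Σ_j L_i·L_j·δ(d_ij − k)
- ES (electrotopological-state-like):  L_i + Σ_{j≠i} (L_i − L_j)/(d_ij + 1)²
- GR (gravitational-like):  Σ_{j≠i, d_ij ≤ k} L_i·L_j / d_ij²
- KH (Kier–Hall-like):  Σ_{d_ij = k} sign(L_i·L_j)·|L_i·L_j|^(−1/2)
- IB (Ivanciuc–Balaban-like): as KH at d_ij = 1 on distance sums
  S_i = Σ_j d_ij·L_j

Chain ends are truncated (no reflection): a residue with no neighbour at the
required distance simply accumulates fewer terms. Inverse-square-root terms
with |product| < ε are dropped rather than raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .indices import IndexVector

logger = logging.getLogger(__name__)

__all__ = ["WeightingSpec", "autocorrelation", "apply_weighting", "OPERATORS"]

OPERATORS = ("NONE", "AC", "KH", "ES", "IB", "GR")
_NEEDS_K = {"AC", "KH", "GR"}
EPS = 1e-12


@dataclass(frozen=True)
class WeightingSpec:
    """Operator choice plus its topological cut-off k."""

    operator: str = "NONE"
    k: int = 1

    def __post_init__(self) -> None:
        op = self.operator.upper()
        object.__setattr__(self, "operator", op)
        if op not in OPERATORS:
            raise ValueError(f"unknown weighting operator {op!r}; use one of {OPERATORS}")
        if op in _NEEDS_K and self.k < 1:
            raise ValueError(f"operator {op} requires k >= 1 (got {self.k})")

    @property
    def tag(self) -> str:
        """Descriptor-name fragment, e.g. 'AC2'; empty for NONE."""
        if self.operator == "NONE":
            return ""
        if self.operator in _NEEDS_K:
            return f"{self.operator}{self.k}"
        return self.operator


def _check_k(values: np.ndarray, k: int) -> bool:
    if k >= len(values):
        logger.warning(
            "weighting cut-off k=%d >= chain length %d: no pair exists, "
            "result is all zeros", k, len(values),
        )
        return False
    return True


def autocorrelation(L: IndexVector, k: int) -> IndexVector:
    """Autocorrelation weighting AC_i^k = Σ_j L_i·L_j·δ(|j−i| − k).

    Interior residues sum two products (neighbours at i−k and i+k);
    residues within k of a chain end sum one; if k ≥ N the result is an
    all-zero vector (with a warning).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1 (got {k})")
    v = L.values
    out = np.zeros_like(v)
    if _check_k(v, k):
        out[k:] += v[k:] * v[:-k]
        out[:-k] += v[:-k] * v[k:]
    return IndexVector(L.protein_id, f"{L.index_name}_AC{k}", out,
                       {**L.params, "weighting": "AC", "k": k})


def _inv_sqrt_sum(products: np.ndarray) -> float:
    """Σ sign(p)·|p|^(−1/2) with near-zero products dropped."""
    total = 0.0
    for p in products:
        if abs(p) < EPS:
            continue
        total += math.copysign(1.0, p) / math.sqrt(abs(p))
    return total


def apply_weighting(L: IndexVector, spec: WeightingSpec) -> IndexVector:
    """Apply one of the five neighbourhood operators (or the identity)."""
    op, k = spec.operator, spec.k
    if op == "NONE":
        return IndexVector(L.protein_id, L.index_name, L.values.copy(), dict(L.params))
    if op == "AC":
        return autocorrelation(L, k)

    v = L.values
    n = len(v)
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    out = np.zeros(n)

    if op == "ES":
        denom = (dist + 1.0) ** 2
        np.fill_diagonal(denom, np.inf)
        out = v + ((v[:, None] - v[None, :]) / denom).sum(axis=1)
    elif op == "GR":
        mask = (dist >= 1) & (dist <= k)
        with np.errstate(divide="ignore"):
            inv2 = np.where(mask, 1.0 / np.where(dist == 0, np.inf, dist) ** 2, 0.0)
        out = v * (inv2 @ v)
    elif op == "KH":
        if _check_k(v, k):
            for i in range(n):
                nbrs = [j for j in (i - k, i + k) if 0 <= j < n]
                out[i] = _inv_sqrt_sum(v[i] * v[nbrs])
    elif op == "IB":
        s = dist @ v
        for i in range(n):
            nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
            out[i] = _inv_sqrt_sum(s[i] * s[nbrs])

    name = f"{L.index_name}_{spec.tag}"
    params = {**L.params, "weighting": op}
    if op in _NEEDS_K:
        params["k"] = k
    return IndexVector(L.protein_id, name, out, params)
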