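"""Aggregation operators: collapse a group's index values to one descriptor.

Twenty operators in four families — Minkowski norms (N1, N2, N3), central
tendency (AM, GM, HM, Q1, Q2, Q3, MX, MN), dispersion (V, SD, CV, SK, RG,
IQ), and information content over rounding-based equivalence classes (TIC,
MIC, SIC). Degenerate cases (empty group, zero mean for CV, single class for
SIC, …) yield the missing-value sentinel ``None`` rather than raising.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AggregatorSpec", "aggregate", "AGGREGATORS", "DEFAULT_IC_PRECISION"]

AGGREGATORS = (
    "N1", "N2", "N3", "AM", "GM", "HM", "Q1", "Q2", "Q3", "MX", "MN",
    "V", "SD", "CV", "SK", "RG", "IQ", "TIC", "MIC", "SIC",
)
_INFORMATION = {"TIC", "MIC", "SIC"}
DEFAULT_IC_PRECISION = 6


@dataclass(frozen=True)
class AggregatorSpec:
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in AGGREGATORS:
            raise ValueError(
                f"unknown aggregation operator {self.name!r}; "
                f"supported: {AGGREGATORS}"
            )
        if self.name in _INFORMATION:
            precision = self.params.get("precision", DEFAULT_IC_PRECISION)
            if not (isinstance(precision, int) and precision > 0):
                raise ValueError("information measures need a positive integer precision")


def _class_counts(v: np.ndarray, precision: int) -> list[int]:
    return list(Counter(np.round(v, precision)).values())


def aggregate(values, spec: AggregatorSpec | str) -> float | None:
    """Aggregate a list of index values per the named operator.

    Returns ``None`` (the missing-value sentinel) for every operator on
    empty input and for operator-specific degeneracies; never raises on
    numeric content.
    """
    if isinstance(spec, str):
        spec = AggregatorSpec(spec)
    v = np.sort(np.asarray(list(values), dtype=float))  # canonical order:
    # every operator is symmetric, and sorting makes results bit-identical
    # under input permutation despite float non-associativity
    n = len(v)
    if n == 0:
        return None
    with np.errstate(all="ignore"):
        result = _aggregate(v, spec)
    # overflow/underflow degeneracies (e.g. sd³ underflowing in SK) map to
    # the sentinel like every other degenerate case
    if result is not None and not math.isfinite(result):
        return None
    return result


def _aggregate(v: np.ndarray, spec: AggregatorSpec) -> float | None:
    n = len(v)
    name = spec.name

    if name == "N1":
        return float(np.abs(v).sum())
    if name == "N2":
        return float(np.sqrt((v ** 2).sum()))
    if name == "N3":
        return float((np.abs(v) ** 3).sum() ** (1.0 / 3.0))
    if name == "AM":
        return float(v.mean())
    if name == "GM":
        # signs dropped; any zero propagates to zero
        if np.any(v == 0):
            return 0.0
        return float(np.exp(np.log(np.abs(v)).mean()))
    if name == "HM":
        if np.any(v == 0):
            return None
        return float(n / (1.0 / v).sum())
    if name in ("Q1", "Q2", "Q3"):
        q = {"Q1": 25, "Q2": 50, "Q3": 75}[name]
        return float(np.percentile(v, q))
    if name == "MX":
        return float(v.max())
    if name == "MN":
        return float(v.min())
    if name == "V":
        return float(v.var())
    if name == "SD":
        return float(v.std())
    if name == "CV":
        mean = v.mean()
        if mean == 0:
            return None
        return float(v.std() / abs(mean))
    if name == "SK":
        sd = v.std()
        if sd == 0:
            return None
        return float(((v - v.mean()) ** 3).mean() / sd ** 3)
    if name == "RG":
        return float(v.max() - v.min())
    if name == "IQ":
        return float(np.percentile(v, 75) - np.percentile(v, 25))

    precision = spec.params.get("precision", DEFAULT_IC_PRECISION)
    counts = _class_counts(v, precision)
    if name == "TIC":
        return float(n * math.log2(n) - sum(c * math.log2(c) for c in counts))
    if name == "MIC":
        return float(-sum((c / n) * math.log2(c / n) for c in counts))
    if name == "SIC":
        if n == 1:
            return None
        mic = -sum((c / n) * math.log2(c / n) for c in counts)
        return float(mic / math.log2(n))
    raise AssertionError(name)
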