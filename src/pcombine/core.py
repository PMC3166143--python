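"""Domain types, input validation, and the weighted log statistic.

A combined significance level for ``L`` independent p-values ``p_i`` with
positive weights ``w_i`` is the tail probability ``Pr(T >= t)`` of the
weighted sum of unit-exponential variables ``T = sum_i w_i E_i`` evaluated
at the observed statistic ``t = -sum_i w_i ln(p_i)``.  Everything downstream
(Fisher, Good, the grouped general case and the stable expansion) is an
evaluator of that survival probability; this module owns the shared input
contract and the statistic itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "InputDomainError",
    "WeightedPValueSet",
    "CombinationResult",
    "validate",
    "weighted_log_statistic",
]


class InputDomainError(ValueError):
    """Raised when p-values or weights violate the input contract."""


@dataclass(frozen=True)
class WeightedPValueSet:
    """An immutable list of p-values in ``(0, 1]`` with positive weights.

    Parameters
    ----------
    pvalues
        Probabilities, each strictly positive and at most 1.
    weights
        Strictly positive, finite trust multipliers, one per p-value.
    ids
        Optional record labels used in error messages and reports.
    """

    pvalues: tuple[float, ...]
    weights: tuple[float, ...]
    ids: Optional[tuple[str, ...]] = None

    def __init__(
        self,
        pvalues: Sequence[float],
        weights: Optional[Sequence[float]] = None,
        ids: Optional[Sequence[str]] = None,
    ):
        object.__setattr__(self, "pvalues", tuple(float(p) for p in pvalues))
        if weights is None:
            weights = [1.0] * len(self.pvalues)
        object.__setattr__(self, "weights", tuple(float(w) for w in weights))
        object.__setattr__(
            self, "ids", tuple(str(i) for i in ids) if ids is not None else None
        )

    def __len__(self) -> int:
        return len(self.pvalues)

    def label(self, i: int) -> str:
        return self.ids[i] if self.ids is not None else f"record {i + 1}"


@dataclass
class CombinationResult:
    """Outcome of a combination method plus numeric diagnostics.

    ``cancellation_index`` is the ratio of the sum of absolute term
    magnitudes to the absolute value of their sum; values far above 1 mean
    the result was produced by cancelling large terms and digits were lost.
    ``clipped`` is set iff the raw value fell outside ``[0, 1]`` (the raw
    value is preserved in ``raw_value``).  ``truncation_bound`` is present
    only for the series-expansion method.
    """

    pvalue: float
    method: str
    raw_value: float = field(default=float("nan"))
    order_used: Optional[int] = None
    truncation_bound: Optional[float] = None
    cancellation_index: float = 1.0
    clipped: bool = False

    def __post_init__(self) -> None:
        if math.isnan(self.raw_value):
            self.raw_value = self.pvalue


def validate(pset: WeightedPValueSet) -> WeightedPValueSet:
    """Check the invariants of a :class:`WeightedPValueSet`.

    Returns the set unchanged when valid; raises :class:`InputDomainError`
    naming the offending record otherwise.  A p-value of exactly 1 is legal
    (zero contribution to the statistic); a p-value of exactly 0 is a hard
    error because it would make the combined statistic infinite.
    """
    if len(pset.pvalues) == 0:
        raise InputDomainError("empty input: at least one p-value is required")
    if len(pset.pvalues) != len(pset.weights):
        raise InputDomainError(
            f"{len(pset.pvalues)} p-values but {len(pset.weights)} weights"
        )
    for i, p in enumerate(pset.pvalues):
        if not math.isfinite(p) or p <= 0.0 or p > 1.0:
            raise InputDomainError(
                f"{pset.label(i)}: p-value {p!r} outside (0, 1]"
            )
    for i, w in enumerate(pset.weights):
        if not math.isfinite(w) or w <= 0.0:
            raise InputDomainError(
                f"{pset.label(i)}: weight {w!r} is not a positive finite number"
            )
    return pset


def weighted_log_statistic(pset: WeightedPValueSet) -> float:
    """Observed statistic ``t = -sum_i w_i ln(p_i)``.

    Carried as a sum of logs; the product of p-values is never formed, so
    the statistic does not underflow for large ``L``.
    """
    validate(pset)
    return -math.fsum(w * math.log(p) for p, w in zip(pset.pvalues, pset.weights))
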