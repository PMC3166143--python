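"""Closed-form combination formulas: Fisher, Good, and the grouped general case.

The combined p-value is the survival function at ``t`` of a weighted sum of
unit exponentials.  With all weights equal this is an Erlang tail (Fisher);
with all weights distinct it is a pure hypoexponential tail (Good); with
``m`` groups of repeated inverse-weight rates ``lambda_j`` of multiplicity
``N_j`` it is the hypoexponential with repeated rates, evaluated here by
partial fractions:

    S(t) = prod_j lambda_j^{N_j}
           * sum_j sum_{k=1..N_j} a_{j,k} Gamma(k, lambda_j t)
                                   / ((k-1)! lambda_j^k)

where ``a_{j,k}`` is the coefficient of ``(lambda_j + s)^{-k}`` in the
partial-fraction decomposition of ``prod_j (lambda_j + s)^{-N_j}``.  The
pole coefficients are computed by a stable log-derivative recurrence, with
an independent constrained-index-sum route retained for cross-checking.

Good's formula cancels catastrophically when weights are nearly equal, so
the exact evaluators default to 50-digit arithmetic and always report a
cancellation index (sum of absolute term magnitudes over the absolute
result).  A double-precision path (``digits <= 16``) is kept for
demonstrating the instability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import mpmath as mp
from scipy.special import gammaincc

from .clustering import cluster_inverse_weights, normalize_inverse_weights
from .core import (
    CombinationResult,
    InputDomainError,
    WeightedPValueSet,
    validate,
)

__all__ = [
    "DegenerateWeightsError",
    "GCParameters",
    "PartialFractionCoefficients",
    "fisher_combine",
    "good_combine",
    "gc_combine",
    "partial_fraction_coefficients",
    "gc_parameters_from_set",
    "normalized_statistic",
    "CANCELLATION_WARN_THRESHOLD",
]

logger = logging.getLogger("pcombine")

#: cancellation indices above this trigger a "hold more decimal places" warning
CANCELLATION_WARN_THRESHOLD = 1e6

Real = Union[float, mp.mpf]


class DegenerateWeightsError(InputDomainError):
    """Good's formula was asked to handle exactly equal weights."""


@dataclass(frozen=True)
class GCParameters:
    """Distinct inverse-weight rates with multiplicities plus the observed statistic.

    ``rates`` must be strictly ascending and positive; ``multiplicities``
    are positive integers summing to the number of p-values combined;
    ``t >= 0`` is the observed weighted log statistic on the same scale as
    the rates.
    """

    rates: tuple[float, ...]
    multiplicities: tuple[int, ...]
    t: Real

    def __init__(self, rates: Sequence[float], multiplicities: Sequence[int], t: Real):
        object.__setattr__(self, "rates", tuple(float(r) for r in rates))
        object.__setattr__(self, "multiplicities", tuple(int(n) for n in multiplicities))
        object.__setattr__(self, "t", t)
        self._check()

    def _check(self) -> None:
        if len(self.rates) == 0 or sum(self.multiplicities) == 0:
            raise InputDomainError("at least one rate with positive multiplicity required")
        if len(self.rates) != len(self.multiplicities):
            raise InputDomainError("rates and multiplicities differ in length")
        for r in self.rates:
            if not (r > 0 and math.isfinite(r)):
                raise InputDomainError(f"rate {r!r} is not positive and finite")
        for a, b in zip(self.rates, self.rates[1:]):
            if not a < b:
                raise InputDomainError("rates must be strictly ascending (and distinct)")
        for n in self.multiplicities:
            if n < 1:
                raise InputDomainError("multiplicities must be positive integers")
        if not self.t >= 0:
            raise InputDomainError(f"statistic t must be nonnegative, got {self.t!r}")

    @property
    def n_values(self) -> int:
        return sum(self.multiplicities)


@dataclass(frozen=True)
class PartialFractionCoefficients:
    """Decomposition ``prod_j (lambda_j+s)^{-N_j} = sum_{j,k} a_{j,k} (lambda_j+s)^{-k}``.

    ``coefficients[j][k-1]`` holds ``a_{j,k}`` for ``1 <= k <= N_j`` as
    mpmath reals at the precision they were computed with.  ``prefactor``
    is the overall factor ``prod_j lambda_j^{N_j}``.
    """

    rates: tuple[float, ...]
    multiplicities: tuple[int, ...]
    coefficients: tuple[tuple[mp.mpf, ...], ...]
    prefactor: mp.mpf

    def reconstruct(self, s: Real) -> mp.mpf:
        """Evaluate ``sum_{j,k} a_{j,k}/(lambda_j+s)^k`` at a probe point."""
        acc = mp.mpf(0)
        for lam, coeffs in zip(self.rates, self.coefficients):
            for k, a in enumerate(coeffs, start=1):
                acc += a / (mp.mpf(lam) + s) ** k
        return acc

    def direct(self, s: Real) -> mp.mpf:
        """Evaluate ``prod_j (lambda_j+s)^{-N_j}`` at a probe point."""
        acc = mp.mpf(1)
        for lam, n in zip(self.rates, self.multiplicities):
            acc /= (mp.mpf(lam) + s) ** n
        return acc

    def survival_terms(self, t: Real, include_prefactor: bool = True) -> list[mp.mpf]:
        """Per-pole tail contributions at the ambient mpmath precision."""
        pre = self.prefactor if include_prefactor else mp.mpf(1)
        terms = []
        for lam, coeffs in zip(self.rates, self.coefficients):
            lam = mp.mpf(lam)
            for k, a in enumerate(coeffs, start=1):
                terms.append(
                    pre * a * mp.gammainc(k, lam * t) / (mp.factorial(k - 1) * lam**k)
                )
        return terms

    def survival(self, t: Real, include_prefactor: bool = True) -> mp.mpf:
        return mp.fsum(self.survival_terms(t, include_prefactor))


def _pf_recurrence(rates: Sequence[mp.mpf], mults: Sequence[int]) -> list[list[mp.mpf]]:
    # For pole j, expand g_j(s) = prod_{l!=j}(lambda_l+s)^{-N_l} around
    # s = -lambda_j.  With h_n = g^(n)/n! and phi = (log g)', the Taylor
    # coefficients follow h_{n+1} = (1/(n+1)) sum_i h_i phi_{n-i} where
    # phi_m = -sum_{l!=j} N_l (-1)^m / (lambda_l - lambda_j)^{m+1}.
    # Then a_{j,k} = h_{N_j - k}.
    out = []
    for j, (lam_j, n_j) in enumerate(zip(rates, mults)):
        others = [(lam, n) for l, (lam, n) in enumerate(zip(rates, mults)) if l != j]
        h = [mp.mpf(1)]
        for lam, n in others:
            h[0] /= (lam - lam_j) ** n
        if n_j > 1:
            phi = [
                -mp.fsum(
                    n * (-1) ** m / (lam - lam_j) ** (m + 1) for lam, n in others
                )
                for m in range(n_j - 1)
            ]
            for n in range(n_j - 1):
                h.append(mp.fsum(h[i] * phi[n - i] for i in range(n + 1)) / (n + 1))
        out.append([h[n_j - k] for k in range(1, n_j + 1)])
    return out


def _compositions(total: int, parts: int):
    if parts == 0:
        if total == 0:
            yield ()
        return
    for head in range(total + 1):
        for rest in _compositions(total - head, parts - 1):
            yield (head,) + rest


def _pf_constrained_sum(rates: Sequence[mp.mpf], mults: Sequence[int]) -> list[list[mp.mpf]]:
    # Independent route: expand each cross factor as a negative-binomial
    # series in u = s + lambda_j and sum over index patterns {k_l} with
    # sum k_l = N_j - k.  Exponential cost in the order; testing only.
    out = []
    for j, (lam_j, n_j) in enumerate(zip(rates, mults)):
        others = [(lam, n) for l, (lam, n) in enumerate(zip(rates, mults)) if l != j]
        coeffs = []
        for k in range(1, n_j + 1):
            order = n_j - k
            acc = mp.mpf(0)
            for pattern in _compositions(order, len(others)):
                term = mp.mpf(1)
                for (lam, n), kl in zip(others, pattern):
                    term *= (
                        (-1) ** kl
                        * mp.binomial(n + kl - 1, kl)
                        / (lam - lam_j) ** (n + kl)
                    )
                acc += term
            coeffs.append(acc)
        out.append(coeffs)
    return out


def partial_fraction_coefficients(
    params: GCParameters, digits: int = 50, method: str = "recurrence"
) -> PartialFractionCoefficients:
    """Pole coefficients of the grouped-rate survival formula.

    ``method`` selects the stable log-derivative recurrence (default) or the
    constrained-index-sum expansion; both satisfy the reconstruction
    identity and must agree, which the test suite exercises.
    """
    with mp.workdps(digits + 10):
        rates = [mp.mpf(r) for r in params.rates]
        mults = list(params.multiplicities)
        if method == "recurrence":
            table = _pf_recurrence(rates, mults)
        elif method == "constrained_sum":
            table = _pf_constrained_sum(rates, mults)
        else:
            raise ValueError(f"unknown method {method!r}")
        pre = mp.mpf(1)
        for lam, n in zip(rates, mults):
            pre *= lam**n
        return PartialFractionCoefficients(
            rates=params.rates,
            multiplicities=params.multiplicities,
            coefficients=tuple(tuple(row) for row in table),
            prefactor=pre,
        )


def _finalize(
    raw: float,
    method: str,
    cancellation_index: float = 1.0,
    order_used: Optional[int] = None,
    truncation_bound: Optional[float] = None,
    digits: int = 16,
) -> CombinationResult:
    # warn when cancellation ate into the digits the user asked for: the
    # fixed threshold applies to double precision, and extended-precision
    # runs only warn once fewer than ~12 significant digits survive
    clipped = not 0.0 <= raw <= 1.0
    if cancellation_index > max(CANCELLATION_WARN_THRESHOLD, 10.0 ** (digits - 12)):
        logger.warning(
            "%s: cancellation index %.3g exceeds %.1g — digits were lost, "
            "use gc/expansion or raise the working precision",
            method,
            cancellation_index,
            CANCELLATION_WARN_THRESHOLD,
        )
    if clipped:
        logger.warning("%s: raw value %.6g outside [0, 1]; clipped", method, raw)
    return CombinationResult(
        pvalue=min(1.0, max(0.0, raw)),
        method=method,
        raw_value=raw,
        order_used=order_used,
        truncation_bound=truncation_bound,
        cancellation_index=cancellation_index,
        clipped=clipped,
    )


def _adaptive_survival(params: GCParameters, digits: int) -> tuple[mp.mpf, float]:
    """Survival value carrying >= ``digits`` correct digits, plus cancellation.

    The partial-fraction sum cancels by a factor that grows like the inverse
    pairwise rate gaps to the (N-1)th power; the working precision is raised
    until the requested digits survive the observed cancellation.
    """
    work = digits
    total, cancel = mp.mpf(0), math.inf
    for _ in range(8):
        with mp.workdps(work + 10):
            pfc = partial_fraction_coefficients(params, digits=work)
            terms = pfc.survival_terms(mp.mpf(params.t))
            total = mp.fsum(terms)
            mag = mp.fsum(abs(x) for x in terms)
            if total == 0:
                return total, math.inf
            cancel = float(mag / abs(total))
            lost = math.ceil(max(0.0, math.log10(cancel)))
            if work - lost >= digits:
                break
            work = lost + digits
    return total, cancel


def fisher_combine(pset: WeightedPValueSet) -> CombinationResult:
    """Equal-weight combination: ``P = Q(L, t0)`` with ``t0 = -sum ln p_i``.

    Weights are ignored — the equal-weight tail probability does not depend
    on the common weight value.
    """
    validate(pset)
    t0 = -math.fsum(math.log(p) for p in pset.pvalues)
    return _finalize(float(gammaincc(len(pset), t0)), "fisher")


def good_combine(pset: WeightedPValueSet, digits: int = 50) -> CombinationResult:
    """All-distinct-weight combination, ``P = sum_i c_i V^{1/w_i}``.

    ``V = prod p_k^{w_k}`` is carried in log space and
    ``c_i = prod_{k!=i} (1 - w_k/w_i)^{-1}``, computed as
    ``w_i/(w_i - w_k)`` so each pairwise difference is formed directly.
    Defaults to 50-digit arithmetic; ``digits <= 16`` evaluates in ordinary
    double precision, which loses all significant figures when weights are
    nearly degenerate (the raw value can even go negative — it is then
    clipped and flagged).  Exactly equal weights are refused: use
    :func:`gc_combine` or the expansion instead.
    """
    validate(pset)
    lams = normalize_inverse_weights(pset)
    if len(set(lams)) != len(lams):
        raise DegenerateWeightsError(
            "weights are exactly equal for some records; Good's prefactor is "
            "ill-defined — use gc_combine or expansion_combine"
        )
    w = pset.weights
    if len(w) == 1:
        return _finalize(float(pset.pvalues[0]), "good")
    if digits <= 16:
        # plain IEEE double arithmetic throughout, including naive sequential
        # accumulation — this is the evaluation whose instability the
        # expansion exists to fix, so no compensated summation here
        lnV = 0.0
        for p, wi in zip(pset.pvalues, w):
            lnV += wi * math.log(p)
        total = 0.0
        mag = 0.0
        for i, wi in enumerate(w):
            c = 1.0
            for k, wk in enumerate(w):
                if k != i:
                    c *= wi / (wi - wk)
            term = c * math.exp(lnV / wi)
            total += term
            mag += abs(term)
        cancel = mag / abs(total) if total else math.inf
        return _finalize(total, "good", cancellation_index=cancel, digits=digits)
    work = digits
    total, cancel = mp.mpf(0), math.inf
    for _ in range(8):  # raise precision until `digits` survive cancellation
        with mp.workdps(work + 10):
            wm = [mp.mpf(x) for x in w]
            lnVm = mp.fsum(wi * mp.log(mp.mpf(p)) for p, wi in zip(pset.pvalues, wm))
            terms = []
            for i, wi in enumerate(wm):
                c = mp.mpf(1)
                for k, wk in enumerate(wm):
                    if k != i:
                        c *= wi / (wi - wk)
                terms.append(c * mp.exp(lnVm / wi))
            total = mp.fsum(terms)
            mag = mp.fsum(abs(x) for x in terms)
            if total == 0:
                break
            cancel = float(mag / abs(total))
            lost = math.ceil(max(0.0, math.log10(cancel)))
            if work - lost >= digits:
                break
            work = lost + digits
    return _finalize(float(total), "good", cancellation_index=cancel, digits=digits)


def gc_combine(params: GCParameters, digits: int = 50) -> CombinationResult:
    """Exact general-case survival probability for grouped inverse weights.

    Evaluated from the partial-fraction form with at least ``digits``
    correct decimal digits (default 50): the working precision is raised
    adaptively to absorb the formula's intrinsic cancellation when rates
    are close.
    """
    total, cancel = _adaptive_survival(params, digits)
    return _finalize(float(total), "gc", cancellation_index=cancel, digits=digits)


def normalized_statistic(pset: WeightedPValueSet) -> float:
    """Observed statistic on the normalized inverse-weight scale.

    Equals ``weighted_log_statistic(pset) * sum_k(1/w_k) / L``; computed
    directly as ``-sum_i ln(p_i)/lam_i`` from the normalized inverse
    weights ``lam_i``.
    """
    lams = normalize_inverse_weights(pset)
    return -math.fsum(math.log(p) / lam for p, lam in zip(pset.pvalues, lams))


def gc_parameters_from_set(pset: WeightedPValueSet) -> GCParameters:
    """Group exactly equal normalized inverse weights into GC parameters.

    Scale invariance guarantees the combined p-value computed from the
    normalized rates and rescaled statistic equals the one for the raw
    weights.
    """
    validate(pset)
    lams = normalize_inverse_weights(pset)
    cs = cluster_inverse_weights(lams, radius=0.0)
    return GCParameters(
        rates=cs.centers,
        multiplicities=cs.multiplicities,
        t=normalized_statistic(pset),
    )
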