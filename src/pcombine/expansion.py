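"""Numerically stable series expansion in powers of inverse-weight deviations.

Writing each normalized inverse weight as its cluster center plus a small
deviation, ``lam_{j,i} = lam_bar_j + delta_{j,i}``, the Laplace-domain
product splits into a well-conditioned grouped-rate base times a correction
factor::

    prod_{j,i} (lam_{j,i}+s)^{-1}
        = prod_j (lam_bar_j+s)^{-N_j}
          * exp( sum_j sum_{k>=2} (-1)^k D_{j,k} z_j^k / k ),

with ``z_j = 1/(lam_bar_j + s)`` and moment sums ``D_{j,k} = sum_i
delta_{j,i}^k`` (``D_{j,1} = 0`` by centering).  Taylor-expanding the
exponential and collecting powers of delta turns every monomial
``prod_j z_j^{k_j}`` into the grouped-rate base function with multiplicities
shifted ``N_j -> N_j + k_j``.  The combined p-value is then

    P = Lam * sum over shift patterns of coeff({k_j}) * S~({N_j + k_j}, t),

where ``Lam = prod_{j,i} lam_{j,i}`` is the exact (well-conditioned)
prefactor and ``S~`` the unnormalized partial-fraction tail.  No pairwise
differences of nearly equal rates ever appear, so the evaluation is stable
in ordinary double precision; truncation at a chosen total order carries an
explicit error bound driven by ``rho = max |delta| / lam_bar``.

The bound multiplies the zeroth-order term by the tail of the majorant
series ``prod_j (1-u_j)^{-N_j} exp(-N_j u_j)`` with ``u_j = rho_j * G``,
where ``G`` estimates the growth of the base function per unit multiplicity
shift (measured from an actual shifted evaluation).  It requires
``max u_j < 1`` and is verified empirically against higher-order partial
sums in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import mpmath as mp

from .classic import GCParameters, _finalize, normalized_statistic, partial_fraction_coefficients
from .clustering import (
    ClusterMoments,
    ClusterSet,
    cluster_inverse_weights,
    cluster_moments,
    normalize_inverse_weights,
)
from .core import InputDomainError, WeightedPValueSet, CombinationResult, validate

__all__ = [
    "ExpansionTerm",
    "ExpansionConfig",
    "BoundUnavailableError",
    "expansion_combine",
    "correction_terms",
    "truncation_bound",
    "AUTO_RADIUS_CANDIDATES",
]

SUPPORTED_ORDERS = (0, 2, 3, 4, 5, 6)
AUTO_RADIUS_CANDIDATES = (0.0, 0.01, 0.02, 0.05, 0.1)


class BoundUnavailableError(RuntimeError):
    """The truncation bound diverges (``rho`` too large); use a smaller radius."""


@dataclass(frozen=True)
class ExpansionTerm:
    """One correction term: a moment coefficient times a shifted base function.

    ``order`` is the total power of delta carried (``sum_j k_j``); there are
    no order-1 terms (centering) and orders 2 and 3 involve exactly one
    cluster each.
    """

    order: int
    coefficient: float
    multiplicity_shift: tuple[int, ...]
    value: float


@dataclass(frozen=True)
class ExpansionConfig:
    """Knobs of the stable expansion.

    ``radius`` may be a nonnegative float or ``"auto"``, which picks the
    largest candidate radius whose estimated truncation bound at
    ``max_order`` stays below ``accuracy_goal`` relative to the zeroth-order
    term.
    """

    max_order: int = 4
    radius: Union[float, str] = 0.05
    precision_digits: int = 50
    accuracy_goal: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_order not in SUPPORTED_ORDERS:
            raise InputDomainError(
                f"max_order must be one of {SUPPORTED_ORDERS}, got {self.max_order}"
            )
        if self.radius != "auto" and float(self.radius) < 0:
            raise InputDomainError(f"radius must be nonnegative, got {self.radius}")


def _exp_series(coeffs_a: Sequence[mp.mpf], max_order: int) -> list[mp.mpf]:
    # exp of a power series with a_0 = a_1 = 0; coeffs_a[k] holds a_k.
    e = [mp.mpf(1)] + [mp.mpf(0)] * max_order
    for n in range(1, max_order + 1):
        e[n] = (
            mp.fsum(k * coeffs_a[k] * e[n - k] for k in range(2, n + 1)) / n
            if n >= 2
            else mp.mpf(0)
        )
    return e


def _cluster_series(moments: ClusterMoments, j: int, max_order: int) -> list[mp.mpf]:
    a = [mp.mpf(0)] * (max_order + 1)
    for k in range(2, max_order + 1):
        a[k] = (-1) ** k * mp.mpf(moments.D(j, k)) / k
    return _exp_series(a, max_order)


def _shift_patterns(n_clusters: int, max_order: int):
    # per-cluster shifts in {0, 2, 3, ..., max_order}; total order <= max_order
    def rec(j: int, budget: int):
        if j == n_clusters:
            yield ()
            return
        for k in [0] + list(range(2, budget + 1)):
            for rest in rec(j + 1, budget - k):
                yield (k,) + rest

    for pat in rec(0, max_order):
        if 0 < sum(pat):
            yield pat


def _base_survival(cs: ClusterSet, shift: Sequence[int], t) -> mp.mpf:
    # unnormalized tail S~ of prod_j (lam_bar_j + s)^(-(N_j + k_j))
    mults = [n + k for n, k in zip(cs.multiplicities, shift)]
    params = GCParameters(rates=cs.centers, multiplicities=mults, t=t)
    pfc = partial_fraction_coefficients(params, digits=mp.mp.dps)
    return pfc.survival(t, include_prefactor=False)


def _exact_prefactor(cs: ClusterSet) -> mp.mpf:
    pre = mp.mpf(1)
    for mem in cs.members:
        for lam in mem:
            pre *= mp.mpf(lam)
    return pre


def correction_terms(
    cs: ClusterSet,
    moments: ClusterMoments,
    t: float,
    max_order: int,
    digits: int = 50,
) -> list[ExpansionTerm]:
    """All correction terms of total order ``2..max_order``, sorted.

    Each term's value is its full contribution to the combined p-value,
    i.e. ``Lam * prod_j g_{j,k_j} * S~({N_j + k_j}, t)`` where ``g_{j,k}``
    are the Taylor coefficients of the per-cluster exponential of moment
    sums.  Terms whose moment coefficient vanishes (e.g. the order-3 term of
    a perfectly symmetric cluster) are still listed, with value 0.
    """
    if moments.max_order < max_order:
        raise ValueError("moments were not computed to the requested order")
    with mp.workdps(digits + 10):
        m = len(cs.centers)
        series = [_cluster_series(moments, j, max_order) for j in range(m)]
        pre = _exact_prefactor(cs)
        terms = []
        for pat in sorted(_shift_patterns(m, max_order), key=lambda p: (sum(p), p)):
            coeff = mp.mpf(1)
            for j, k in enumerate(pat):
                coeff *= series[j][k]
            value = coeff * pre * _base_survival(cs, pat, mp.mpf(t)) if coeff != 0 else mp.mpf(0)
            terms.append(
                ExpansionTerm(
                    order=sum(pat),
                    coefficient=float(coeff),
                    multiplicity_shift=pat,
                    value=float(value),
                )
            )
        return terms


def truncation_bound(
    cs: ClusterSet,
    moments: ClusterMoments,
    t: float,
    order: int,
    digits: int = 50,
) -> float:
    """Upper estimate of the error from truncating the expansion at ``order``.

    Computed as ``|P_0| * (M(u) - partial_order(u))`` where ``M`` is the
    majorant described in the module docstring.  Raises
    :class:`BoundUnavailableError` when ``rho >= 1`` or the growth-corrected
    ratio reaches 1 (the majorant diverges); cluster at a smaller radius in
    that case.
    """
    with mp.workdps(digits + 10):
        rhos = [
            max((abs(d) for d in devs), default=0.0) / c
            for c, devs in zip(cs.centers, cs.deviations)
        ]
        rho = max(rhos)
        if rho == 0.0:
            return 0.0
        if rho >= 1.0:
            raise BoundUnavailableError(
                f"rho = {rho:.3g} >= 1: deviations exceed cluster centers; "
                "re-cluster with a smaller radius"
            )
        t_mp = mp.mpf(t)
        base0 = _base_survival(cs, [0] * len(cs.centers), t_mp)
        p0 = abs(_exact_prefactor(cs) * base0)
        # per-unit-shift growth of the base function, probed at depth order+2
        depth = order + 2
        growth = mp.mpf(1)
        for j in range(len(cs.centers)):
            if rhos[j] == 0.0:
                continue
            shift = [0] * len(cs.centers)
            shift[j] = depth
            gj = (_base_survival(cs, shift, t_mp) / base0) ** (mp.mpf(1) / depth)
            growth = max(growth, gj)
        us = [mp.mpf(r) * growth for r in rhos]
        if max(us) >= 1:
            raise BoundUnavailableError(
                "growth-corrected expansion ratio reaches 1; "
                "re-cluster with a smaller radius"
            )
        full = mp.mpf(1)
        for u, n in zip(us, cs.multiplicities):
            if u > 0:
                full *= (1 - u) ** (-n) * mp.exp(-n * u)
        series = [
            _exp_series(
                [mp.mpf(0)] * 2 + [n * u**k / k for k in range(2, order + 1)],
                order,
            )
            for u, n in zip(us, cs.multiplicities)
        ]
        # convolve the per-cluster majorant series and sum through `order`
        conv = [mp.mpf(1)] + [mp.mpf(0)] * order
        for s in series:
            conv = [
                mp.fsum(conv[i] * s[n - i] for i in range(n + 1))
                for n in range(order + 1)
            ]
        partial = mp.fsum(conv)
        return float(p0 * max(mp.mpf(0), full - partial))


def _pipeline(pset: WeightedPValueSet, radius: float, max_order: int):
    lams = normalize_inverse_weights(pset)
    cs = cluster_inverse_weights(lams, radius)
    t = normalized_statistic(pset)
    moments = cluster_moments(cs, max(max_order, 1))
    return cs, moments, t


def _evaluate(cs, moments, t, max_order: int, digits: int):
    """Zeroth-order value, correction terms and the mp-precision total."""
    with mp.workdps(digits + 10):
        t_mp = mp.mpf(t)
        zeroth = _exact_prefactor(cs) * _base_survival(cs, [0] * len(cs.centers), t_mp)
        terms = correction_terms(cs, moments, t, max_order, digits=digits)
        total = zeroth + mp.fsum(mp.mpf(x.value) for x in terms)
        mag = abs(zeroth) + mp.fsum(abs(mp.mpf(x.value)) for x in terms)
        cancel = float(mag / abs(total)) if total != 0 else math.inf
        return float(zeroth), terms, total, cancel


def expansion_combine(
    pset: WeightedPValueSet, config: Optional[ExpansionConfig] = None
) -> CombinationResult:
    """Combine weighted p-values via the stable clustered expansion.

    Pipeline: normalize inverse weights, cluster at the configured radius,
    evaluate the grouped-rate base term at the cluster centers and add
    moment-weighted corrections up to ``config.max_order``.  With radius 0
    only exactly identical weights cluster, all deviations vanish and the
    exact grouped-rate result is recovered; with all weights equal the
    result equals Fisher's formula.
    """
    validate(pset)
    config = config or ExpansionConfig()
    digits = config.precision_digits
    if config.radius == "auto":
        radius = _choose_radius(pset, config)
    else:
        radius = float(config.radius)
    cs, moments, t = _pipeline(pset, radius, config.max_order)
    _, terms, total, cancel = _evaluate(cs, moments, t, config.max_order, digits)
    try:
        bound = truncation_bound(cs, moments, t, config.max_order, digits=digits)
    except BoundUnavailableError:
        bound = math.inf
    return _finalize(
        float(total),
        "expansion",
        cancellation_index=cancel,
        order_used=config.max_order,
        truncation_bound=bound,
        digits=digits,
    )


def _choose_radius(pset: WeightedPValueSet, config: ExpansionConfig) -> float:
    """Largest candidate radius whose relative truncation bound meets the goal."""
    best = 0.0
    for r in AUTO_RADIUS_CANDIDATES:
        cs, moments, t = _pipeline(pset, r, config.max_order)
        try:
            bound = truncation_bound(
                cs, moments, t, config.max_order, digits=config.precision_digits
            )
        except BoundUnavailableError:
            continue
        with mp.workdps(config.precision_digits + 10):
            p0 = abs(
                _exact_prefactor(cs)
                * _base_survival(cs, [0] * len(cs.centers), mp.mpf(t))
            )
        if p0 > 0 and bound <= config.accuracy_goal * float(p0):
            best = max(best, r)
    return best
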