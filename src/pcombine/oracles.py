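"""Independent ground-truth engines and a deterministic fixture generator.

Two oracles estimate the same tail probability by means unrelated to the
partial-fraction algebra used by the analytic methods:

* a seeded Monte-Carlo sampler of ``T = sum_i w_i E_i`` with unit
  exponentials ``E_i = -ln U_i``;
* numeric inversion of the Laplace-domain survival transform
  ``(1 - prod_j (lambda_j/(lambda_j+s))^{N_j})/s`` along a deformed
  (Talbot) contour at extended precision, cross-checked against the
  high-precision partial-fraction route — the two must agree to half the
  working digits or an internal-consistency error is raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import mpmath as mp
import numpy as np

from .classic import GCParameters
from .core import WeightedPValueSet

__all__ = [
    "OracleConfig",
    "OracleEstimate",
    "OracleInconsistencyError",
    "monte_carlo_pvalue",
    "quadrature_pvalue",
    "generate_fixture",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("well_separated", "near_degenerate", "grouped", "symmetric_clusters")


class OracleInconsistencyError(RuntimeError):
    """The two quadrature routes disagree beyond tolerance."""


@dataclass(frozen=True)
class OracleConfig:
    mc_samples: int = 10**6
    seed: Optional[int] = None
    quad_digits: int = 50
    quad_method: str = "partial_fraction_hp"  # or "contour_quadrature"

    def __post_init__(self) -> None:
        if self.mc_samples < 10**3:
            raise ValueError("mc_samples must be at least 1000")
        if self.quad_digits < 20:
            raise ValueError("quad_digits must be at least 20")


@dataclass(frozen=True)
class OracleEstimate:
    estimate: float
    standard_error: float
    method: str


def monte_carlo_pvalue(
    weights: Sequence[float], t: float, config: Optional[OracleConfig] = None
) -> OracleEstimate:
    """Seeded Monte-Carlo estimate of ``Pr(sum_i w_i E_i >= t)``.

    Returns the sample fraction and its binomial standard error.
    """
    config = config or OracleConfig()
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if t < 0:
        raise ValueError("t must be nonnegative")
    rng = np.random.default_rng(config.seed)
    n = config.mc_samples
    # block the draws to keep memory flat for large n
    hits = 0
    block = max(1, min(n, 10**7 // max(1, len(w))))
    done = 0
    while done < n:
        b = min(block, n - done)
        samples = rng.standard_exponential((b, len(w))) @ w
        hits += int(np.count_nonzero(samples >= t))
        done += b
    p = hits / n
    se = math.sqrt(p * (1.0 - p) / n)
    return OracleEstimate(estimate=p, standard_error=se, method="monte_carlo")


def _survival_partial_fraction(params: GCParameters, digits: int) -> mp.mpf:
    from .classic import _adaptive_survival

    return _adaptive_survival(params, digits)[0]


def _survival_contour(params: GCParameters, digits: int) -> mp.mpf:
    # Talbot-deformed inversion of the survival transform (1 - F(s))/s;
    # the deformed contour wraps around the poles on the negative real axis.
    with mp.workdps(digits + 10):
        rates = [mp.mpf(r) for r in params.rates]
        mults = params.multiplicities

        def transform(s):
            F = mp.mpc(1)
            for r, n in zip(rates, mults):
                F *= (r / (r + s)) ** n
            return (1 - F) / s

        return mp.invertlaplace(transform, mp.mpf(params.t), method="talbot")


def quadrature_pvalue(
    params: GCParameters, config: Optional[OracleConfig] = None
) -> OracleEstimate:
    """Extended-precision tail probability with a two-route consistency check.

    Route (a) evaluates the partial-fraction survival form at
    ``quad_digits`` digits; route (b) numerically inverts the survival
    transform along a deformed contour.  The requested route's value is
    returned, after verifying the routes agree to ``quad_digits/2``
    significant digits.
    """
    config = config or OracleConfig()
    d = config.quad_digits
    if params.t == 0:
        return OracleEstimate(1.0, 0.0, config.quad_method)
    a = _survival_partial_fraction(params, d)
    b = _survival_contour(params, d)
    with mp.workdps(d + 10):
        scale = max(abs(a), abs(b))
        if scale > 0 and abs(a - b) / scale > mp.mpf(10) ** (-(d // 2)):
            raise OracleInconsistencyError(
                f"partial-fraction and contour routes disagree: {a} vs {b}"
            )
    value = a if config.quad_method == "partial_fraction_hp" else b
    return OracleEstimate(estimate=float(value), standard_error=0.0, method=config.quad_method)


def _dyadic(rng: np.random.Generator, lo: float, hi: float, grid: int = 1024) -> float:
    """A random dyadic rational in [lo, hi] (exactly representable)."""
    return int(rng.integers(round(lo * grid), round(hi * grid) + 1)) / grid


def generate_fixture(
    kind: str,
    L: int,
    seed: int,
    alternative: bool = False,
) -> WeightedPValueSet:
    """Deterministic synthetic inputs exercising the weight regimes.

    ``well_separated``: pairwise gaps of normalized inverse weights large.
    ``near_degenerate``: inverse weights within 1e-5 of 1.
    ``grouped``: 2-4 well-separated cluster centers, intra-cluster spread
    below 0.05.  ``symmetric_clusters``: members placed in exact
    plus/minus pairs around dyadic centers summing exactly to ``L``, so
    odd deviation moments vanish identically after clustering.
    P-values are uniform under the null, or beta-skewed toward zero when
    ``alternative`` is set.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    rng = np.random.default_rng(
        np.random.SeedSequence([FIXTURE_KINDS.index(kind), L, int(seed), int(alternative)])
    )

    if kind == "well_separated":
        # evenly spread with jitter; min gap >= 0.3 of the mean spacing
        base = np.linspace(0.5, 1.5, L)
        gap = (base[1] - base[0]) if L > 1 else 1.0
        lams = base + rng.uniform(-0.3, 0.3, size=L) * gap / 2
    elif kind == "near_degenerate":
        lams = 1.0 + rng.uniform(-1e-5, 1e-5, size=L)
    elif kind == "grouped":
        m = int(rng.integers(2, min(4, max(2, L)) + 1))
        centers = np.sort(0.55 + 0.9 * rng.random(m))
        while np.any(np.diff(centers) < 0.25):
            centers = np.sort(0.55 + 0.9 * rng.random(m))
        assign = np.sort(rng.integers(0, m, size=L))
        assign[: min(m, L)] = np.arange(min(m, L))  # no empty cluster
        lams = centers[assign] + rng.uniform(-0.02, 0.02, size=L)
    else:  # symmetric_clusters
        n_pairs = L // 2
        m = int(rng.integers(1, min(3, n_pairs) + 1)) if n_pairs else 0
        counts = np.full(m, n_pairs // m) if m else np.array([], dtype=int)
        counts[: n_pairs % m if m else 0] += 1
        # dyadic centers with gaps well above twice the intra-cluster spread
        while True:
            centers = sorted(_dyadic(rng, 0.55, 1.45) for _ in range(m + 1))
            if all(b - a >= 0.25 for a, b in zip(centers, centers[1:])):
                break
        lams_list: list[float] = []
        for c, npair in zip(centers, counts):
            for _ in range(int(npair)):
                d = _dyadic(rng, 1 / 1024, 0.02)
                lams_list.extend([c - d, c + d])
        if len(lams_list) < L:  # pad odd L with a singleton cluster
            lams_list.append(centers[m])
        lams = np.array(lams_list)
    lams = np.maximum(lams, 1e-3)
    weights = 1.0 / lams

    if alternative:
        pvals = rng.beta(0.15, 1.0, size=L)
    else:
        pvals = rng.random(size=L)
    pvals = np.clip(pvals, 1e-300, 1.0)
    return WeightedPValueSet(pvalues=pvals.tolist(), weights=weights.tolist())
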