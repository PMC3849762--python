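"""Poisson-Tweedie (PT) count distributions.

The PT family is a three-parameter family of discrete distributions on the
non-negative integers that unifies the count models most often used for
over-dispersed data: it contains the Poisson (shape a = 1), the negative
binomial (a = 0), the Poisson-inverse-Gaussian (a = 1/2), the Polya-Aeppli
(a = -1) and, in the limit a -> -inf, the Neyman type A distribution.

Two parameterizations are exposed:

* canonical ``(a, b, c)`` with domain ``a <= 1``, ``b > 0``, ``0 <= c < 1``,
  in which the probability generating function and the pmf recursion are
  written, and
* an interpretable ``(mu, phi, a)`` with ``mu`` the mean, ``phi = var/mean``
  the dispersion index (``phi = 1`` is Poisson equidispersion) and ``a`` the
  shape selecting the family member.

The pmf has no closed form for general ``a``; it is evaluated by a forward
recursion on the probabilities with auxiliary coefficients, run in a scaled
linear space so that profiles with very large means do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

__all__ = [
    "PTCanonicalParams",
    "PTMeanParams",
    "PMFVector",
    "PTDomainError",
    "PTNumericError",
    "PTTailCapError",
    "to_canonical",
    "to_mean_params",
    "pt_pgf",
    "pt_pmf",
    "pt_cdf",
    "pt_quantile",
    "pt_sample",
    "pt_mean_variance",
]

# Numerical policy for the whole package.
POISSON_PHI_TOL = 1e-8  # phi <= 1 + tol is dispatched to Poisson
POISSON_A_TOL = 1e-8  # a >= 1 - tol is dispatched to Poisson
NEG_CLIP = 1e-12  # pmf entries in [-NEG_CLIP, 0) are clipped to 0
TAIL_BLOCK = 256  # support is extended in blocks of this size
TAIL_TARGET = 1.0 - 1e-12  # cumulative mass required before stopping
TAIL_CAP = 1_000_000  # hard cap on tabulated support points
LOG_FLOOR = math.log(1e-300)  # per-cell floor for log-pmf values


class PTDomainError(ValueError):
    """Parameters outside the Poisson-Tweedie domain."""


class PTNumericError(RuntimeError):
    """The pmf recursion produced numerically invalid values."""


class PTTailCapError(RuntimeError):
    """Tail extension exceeded the hard support cap."""


@dataclass(frozen=True)
class PTCanonicalParams:
    """Canonical PT parameters ``(a, b, c)``.

    ``a`` is the shape (a <= 1), ``b`` a positive rate-like scalar and
    ``c`` a probability-like scalar in [0, 1).
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= 1.0):
            raise PTDomainError(f"shape a must be <= 1, got {self.a}")
        if not (self.b > 0.0):
            raise PTDomainError(f"b must be > 0, got {self.b}")
        if not (0.0 <= self.c < 1.0):
            raise PTDomainError(f"c must lie in [0, 1), got {self.c}")


@dataclass(frozen=True)
class PTMeanParams:
    """Interpretable PT parameters ``(mu, phi, a)``.

    ``mu`` is the mean, ``phi = variance / mean`` the dispersion index and
    ``a`` the shape.  ``phi = 1`` denotes the Poisson member regardless of
    the nominal shape value.
    """

    mu: float
    phi: float
    a: float

    def __post_init__(self) -> None:
        if not (self.mu > 0.0):
            raise PTDomainError(f"mean mu must be > 0, got {self.mu}")
        if not (self.phi >= 1.0):
            raise PTDomainError(f"dispersion index phi must be >= 1, got {self.phi}")
        if not (self.a <= 1.0):
            raise PTDomainError(f"shape a must be <= 1, got {self.a}")

    @property
    def is_poisson(self) -> bool:
        return self.phi <= 1.0 + POISSON_PHI_TOL or self.a >= 1.0 - POISSON_A_TOL


@dataclass(frozen=True)
class PMFVector:
    """Probabilities ``p_0 .. p_m`` plus the untabulated tail mass."""

    probs: np.ndarray
    truncation_mass: float


def to_canonical(p: PTMeanParams) -> PTCanonicalParams:
    """Map ``(mu, phi, a)`` to the canonical ``(a, b, c)`` parameterization.

    ``c = (phi - 1) / (phi - a)`` and ``b = mu (1 - c)^(1 - a) / c``, the
    unique ``b`` for which the pgf has derivative ``mu`` at 1.  The Poisson
    boundary ``phi = 1`` (where ``c = 0``) is not representable here and is
    rejected; callers route it to the Poisson closed forms.
    """
    if p.is_poisson:
        raise PTDomainError(
            "phi <= 1 (or a ~ 1) is the Poisson boundary; use the Poisson "
            "closed form instead of the canonical parameterization"
        )
    c = (p.phi - 1.0) / (p.phi - p.a)
    b = p.mu * (1.0 - c) ** (1.0 - p.a) / c
    return PTCanonicalParams(a=p.a, b=b, c=c)


def to_mean_params(p: PTCanonicalParams) -> PTMeanParams:
    """Map canonical ``(a, b, c)`` to ``(mu, phi, a)``.

    ``mu = b c (1 - c)^(a - 1)`` and ``phi = 1 + c (1 - a) / (1 - c)``,
    obtained from the first two derivatives of the pgf at 1.
    """
    if p.c == 0.0:
        raise PTDomainError(
            "c = 0 is a degenerate (Poisson-limit) case with no mean-form "
            "equivalent; handle it through the Poisson closed form"
        )
    mu = p.b * p.c * (1.0 - p.c) ** (p.a - 1.0)
    phi = 1.0 + p.c * (1.0 - p.a) / (1.0 - p.c)
    return PTMeanParams(mu=mu, phi=phi, a=p.a)


def pt_pgf(y, p: PTCanonicalParams):
    """Probability generating function G(y) for y in [0, 1].

    ``G(y) = exp{(b/a)[(1-c)^a - (1-cy)^a]}`` for a != 0 and the negative
    binomial form ``[(1-c)/(1-cy)]^b`` in the a -> 0 limit.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0.0) or np.any(y > 1.0):
        raise PTDomainError("pgf argument must lie in [0, 1]")
    if p.a == 0.0:
        out = ((1.0 - p.c) / (1.0 - p.c * y)) ** p.b
    else:
        # expm1 keeps the expression smooth through a -> 0
        out = np.exp(
            (p.b / p.a)
            * (np.expm1(p.a * np.log(1.0 - p.c)) - np.expm1(p.a * np.log(1.0 - p.c * y)))
        )
    return out if out.ndim else float(out)


@njit(cache=False)
def _pmf_recursion(a, b, c, m):  # pragma: no cover - exercised via wrappers
    """Forward pmf recursion in a scaled linear space.

    Returns ``(q, shift, status)`` where the pmf is ``q * exp(shift)``;
    status 1 flags an entry below the negativity tolerance.
    The working values are renormalized by their running maximum whenever
    they overflow the double range, so profiles with log p0 < -700 remain
    computable.
    """
    q = np.zeros(m + 1)
    r = np.zeros(m + 1)  # r[j] holds the auxiliary coefficient r_j, j >= 1
    # log p0; expm1 keeps the a -> 0 limit smooth to machine precision
    if a != 0.0:
        shift = b * math.expm1(a * math.log(1.0 - c)) / a
    else:
        shift = b * math.log(1.0 - c)
    q[0] = 1.0
    if m == 0:
        return q, shift, 0
    q[1] = b * c  # p1 = b c p0
    if m >= 1:
        r[1] = (1.0 - a) * c
    for k in range(1, m):
        # p_{k+1} = [b c p_k + sum_{j=1}^{k} j r_{k+1-j} p_j] / (k+1)
        acc = b * c * q[k]
        for j in range(1, k + 1):
            acc += j * r[k + 1 - j] * q[j]
        q[k + 1] = acc / (k + 1.0)
        r[k + 1] = (k - 1.0 + a) / (k + 1.0) * c * r[k]
        if q[k + 1] > 1e250:
            f = q[k + 1]
            for i in range(k + 2):
                q[i] /= f
            shift += math.log(f)
    status = 0
    scale = 0.0
    for i in range(m + 1):
        if q[i] > scale:
            scale = q[i]
    for i in range(m + 1):
        if q[i] < 0.0:
            # tolerance is applied on the probability scale
            if q[i] * math.exp(min(shift, 0.0)) < -1e-12:
                status = 1
            q[i] = 0.0
    return q, shift, status


def _pmf_array(p: PTCanonicalParams, m: int) -> np.ndarray:
    """pmf values p_0..p_m, dispatching the closed-form special cases."""
    k = np.arange(m + 1)
    if p.a >= 1.0 - POISSON_A_TOL:
        # a = 1 reduces the pgf to exp{b c (y - 1)}: Poisson(b c)
        return stats.poisson.pmf(k, p.b * p.c)
    if p.a == 0.0:
        return stats.nbinom.pmf(k, p.b, 1.0 - p.c)
    q, shift, status = _pmf_recursion(p.a, p.b, p.c, m)
    if status != 0:
        raise PTNumericError(
            f"pmf recursion unstable for (a={p.a}, b={p.b}, c={p.c}): "
            "an entry fell below the negativity tolerance"
        )
    with np.errstate(over="ignore"):
        probs = q * math.exp(min(shift, 0.0)) if shift < 0 else q * math.exp(shift)
    probs[(probs < 0.0) & (probs >= -NEG_CLIP)] = 0.0
    if np.any(probs < -NEG_CLIP) or not np.all(np.isfinite(probs)):
        raise PTNumericError(
            f"pmf recursion produced invalid values for (a={p.a}, b={p.b}, c={p.c})"
        )
    if probs.sum() > 1.0 + 1e-8:
        raise PTNumericError(
            f"pmf recursion mass exceeds 1 for (a={p.a}, b={p.b}, c={p.c}): "
            "cancellation instability"
        )
    return probs


def pt_pmf(m: int, p: PTCanonicalParams) -> PMFVector:
    """Tabulate the pmf on 0..m.

    Closed forms serve the negative binomial (a = 0) and Poisson (a ~ 1)
    members; everything else runs the recursion.
    """
    if m < 0:
        raise PTDomainError("m must be >= 0")
    probs = _pmf_array(p, int(m))
    return PMFVector(probs=probs, truncation_mass=float(1.0 - probs.sum()))


def _extended_pmf(p: PTCanonicalParams, target: float = TAIL_TARGET,
                  start: int | None = None) -> np.ndarray:
    """Extend the pmf in blocks until cumulative mass reaches ``target``."""
    mu = to_mean_params(p).mu if p.c > 0.0 else p.b * p.c
    m = start if start is not None else max(TAIL_BLOCK, int(4 * mu))
    prev_mass = -1.0
    while True:
        m = min(m, TAIL_CAP)
        probs = _pmf_array(p, m)
        mass = probs.sum()
        if mass >= target:
            return probs
        # saturation: essentially all representable mass is tabulated and
        # further extension gains nothing beyond rounding noise
        if mass >= 1.0 - 1e-9 and mass - prev_mass < 1e-13:
            return probs
        if m >= TAIL_CAP:
            raise PTTailCapError(
                f"support cap of {TAIL_CAP} points reached at cumulative "
                f"mass {mass:.15f} < {target}"
            )
        prev_mass = mass
        m = m * 2 + TAIL_BLOCK


def pt_cdf(k: int, p: PTCanonicalParams) -> float:
    """P(Y <= k), from the tabulated pmf."""
    if k < 0:
        raise PTDomainError("k must be >= 0")
    return float(min(_pmf_array(p, int(k)).sum(), 1.0))


def pt_quantile(q: float, p: PTCanonicalParams) -> int:
    """Smallest k with cdf(k) >= q, for q in [0, 1)."""
    if not (0.0 <= q < 1.0):
        raise PTDomainError("quantile level must lie in [0, 1)")
    probs = _extended_pmf(p, target=max(TAIL_TARGET, q))
    cum = np.cumsum(probs)
    # tolerance absorbs accumulation error at exact cdf ties (e.g. the
    # median of a symmetric NB)
    return int(np.searchsorted(cum, q - 1e-12, side="left"))


def pt_sample(n: int, p: PTMeanParams, seed) -> np.ndarray:
    """Draw n i.i.d. counts.

    Poisson and negative-binomial members use their closed-form samplers;
    other shapes invert the tabulated cdf with one uniform per variate.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise PTDomainError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if p.is_poisson:
        return rng.poisson(p.mu, size=n).astype(np.int64)
    if p.a == 0.0:
        # NB with mean mu, variance mu*phi: n = mu/(phi-1), p = 1/phi
        return rng.negative_binomial(p.mu / (p.phi - 1.0), 1.0 / p.phi, size=n).astype(np.int64)
    probs = _extended_pmf(to_canonical(p))
    cum = np.cumsum(probs)
    u = rng.random(n)
    return np.searchsorted(cum, u, side="left").astype(np.int64)


def pt_mean_variance(p: PTCanonicalParams) -> tuple[float, float]:
    """Mean and variance computed from the tabulated pmf."""
    if p.a >= 1.0 - POISSON_A_TOL:
        lam = p.b * p.c
        return lam, lam
    probs = _extended_pmf(p)
    k = np.arange(probs.size, dtype=float)
    mean = float(k @ probs)
    var = float((k - mean) ** 2 @ probs)
    return mean, var
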