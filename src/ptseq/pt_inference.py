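"""Maximum-likelihood inference for Poisson-Tweedie expression profiles.

One expression profile (the counts of a gene across replicate samples) is
summarized as a frequency table and fitted by constrained quasi-Newton
maximum likelihood over the interpretable parameters ``(mu, phi, a)``.
Internally the optimizer works on the smooth unconstrained coordinates
``(log mu, log(phi - 1), a)`` with the single box constraint ``a <= 1``;
the parameter covariance is the negative inverse Hessian of the
log-likelihood at the optimum, mapped back by the delta method.

The module also provides the likelihood-ratio goodness-of-fit test of the
negative binomial (the a = 0 member, nested in the PT family): under the
null, twice the log likelihood ratio is asymptotically chi-squared with
one degree of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, stats

from .pt_core import (
    LOG_FLOOR,
    POISSON_PHI_TOL,
    PTDomainError,
    PTMeanParams,
    _pmf_recursion,
)

__all__ = [
    "FrequencyTable",
    "PTFit",
    "GOFResult",
    "PTFitError",
    "tabulate_counts",
    "log_likelihood",
    "moment_init",
    "fit_pt_mle",
    "estimate_variance",
    "nb_gof_test",
    "gof_zscore",
]

# Shape is boxed to keep the canonical map well-conditioned; a = -100 is
# already indistinguishable from the Neyman type A limit in double precision.
_A_MIN = -100.0
_A_MAX = 1.0
_PHI_FLOOR = 1.0 + 1e-6  # moment initialization clamp for phi
_T2_MIN = math.log(1e-9)  # lower bound on log(phi - 1); at bound => Poisson
_HESS_REL_STEP = 1e-4
_HESS_ABS_FLOOR = 1e-6
_MAX_RESTARTS = 3


class PTFitError(RuntimeError):
    """Raised when a fit (or a pair of fits) cannot be completed.

    Carries the partial fit objects, when available, in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class FrequencyTable:
    """Counts tabulated as frequencies y_0..y_m of each observed value."""

    y: np.ndarray
    n: int
    m: int


@dataclass
class PTFit:
    """Result of one maximum-likelihood fit."""

    params: PTMeanParams
    loglik: float
    converged: bool
    cov: np.ndarray
    var_mu: float
    fixed_a: float | None = None
    flags: list[str] = field(default_factory=list)
    n: int = 0


@dataclass(frozen=True)
class GOFResult:
    """Likelihood-ratio goodness-of-fit of the NB member against full PT."""

    statistic: float
    pvalue: float
    loglik_pt: float
    loglik_nb: float
    a_hat: float


def tabulate_counts(counts) -> FrequencyTable:
    """Tabulate integer counts into frequencies of 0, 1, ..., max(counts)."""
    arr = np.asarray(counts)
    if arr.size < 1:
        raise PTDomainError("need at least one observation")
    if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
        raise PTDomainError("counts must be non-negative integers")
    arr = arr.astype(np.int64)
    m = int(arr.max())
    y = np.bincount(arr, minlength=m + 1).astype(np.float64)
    return FrequencyTable(y=y, n=int(arr.size), m=m)


@njit(cache=False)
def _nll(t1, t2, a, y):  # pragma: no cover - exercised via wrappers
    """Negative log-likelihood in optimizer coordinates.

    t1 = log mu, t2 = log(phi - 1).  The Poisson boundary (phi - 1 below
    tolerance, or a at 1) is served by the Poisson closed form so the
    objective stays finite and smooth up to the boundary.
    """
    mu = math.exp(t1)
    d = math.exp(t2)  # phi - 1
    if d <= POISSON_PHI_TOL or a >= 1.0 - 1e-8:
        ll = 0.0
        for i in range(y.shape[0]):
            if y[i] > 0.0:
                lp = -mu + i * math.log(mu) - math.lgamma(i + 1.0)
                if lp < LOG_FLOOR:
                    lp = LOG_FLOOR
                ll += y[i] * lp
        return -ll
    phi = 1.0 + d
    c = d / (phi - a)
    logb = math.log(mu) + (1.0 - a) * math.log(1.0 - c) - math.log(c)
    if logb < -690.0 or logb > 690.0:
        return 1e30
    b = math.exp(logb)
    q, shift, status = _pmf_recursion(a, b, c, y.shape[0] - 1)
    if status != 0:
        return 1e30
    # cancellation for very negative shapes can yield garbage positive
    # entries; a partial pmf sum above 1 is a sure sign of instability
    total = 0.0
    for i in range(q.shape[0]):
        total += q[i]
    if shift + math.log(total) > 1e-6:
        return 1e30
    ll = 0.0
    for i in range(y.shape[0]):
        if y[i] > 0.0:
            if q[i] <= 0.0:
                lp = LOG_FLOOR
            else:
                lp = shift + math.log(q[i])
                if lp < LOG_FLOOR:
                    lp = LOG_FLOOR
            ll += y[i] * lp
    if not math.isfinite(ll):
        return 1e30
    return -ll


def log_likelihood(p: PTMeanParams, f: FrequencyTable) -> float:
    """Sum over cells of y_i * log p_i(theta), floored at log(1e-300)."""
    return -float(_nll(math.log(p.mu), math.log(max(p.phi - 1.0, 1e-300)), p.a, f.y))


def moment_init(counts) -> PTMeanParams:
    """Moment starting values: sample mean, dispersion index, and a = 0.

    The shape starts at the negative binomial, the natural cut-point of the
    PT parameter space; the dispersion index uses the unbiased (n-1)
    variance and is clamped at 1 + 1e-6 for underdispersed profiles.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size < 2:
        raise PTDomainError("need at least two observations for moment estimates")
    mu0 = float(arr.mean())
    if mu0 <= 0.0:
        raise PTDomainError("degenerate all-zero profile")
    phi0 = float(arr.var(ddof=1)) / mu0
    return PTMeanParams(mu=mu0, phi=max(phi0, _PHI_FLOOR), a=0.0)


def _objective(fixed_a: float | None, y: np.ndarray):
    if fixed_a is None:
        return lambda x: _nll(x[0], x[1], x[2], y)
    return lambda x: _nll(x[0], x[1], fixed_a, y)


def _hessian(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with relative steps."""
    k = x.size
    h = np.maximum(_HESS_REL_STEP * np.abs(x), _HESS_ABS_FLOOR)
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def estimate_variance(params: PTMeanParams, f: FrequencyTable,
                      fixed_a: float | None = None) -> tuple[np.ndarray, list[str]]:
    """Covariance of (mu, phi, a) at the optimum.

    Negative inverse central-difference Hessian of the log-likelihood,
    computed in the optimizer coordinates and mapped back to the natural
    scale by the delta method; singular Hessians fall back to the
    Moore-Penrose pseudo-inverse and flag the fit.
    """
    y = f.y
    x = np.array([math.log(params.mu), math.log(max(params.phi - 1.0, 1e-12)), params.a])
    flags: list[str] = []
    if fixed_a is not None:
        xt = x[:2]
        fun = _objective(fixed_a, y)
    else:
        xt = x
        fun = _objective(None, y)
    H = _hessian(fun, xt)  # Hessian of the NEGATIVE loglik
    H = 0.5 * (H + H.T)
    try:
        cov_t = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_t = np.linalg.pinv(H)
        flags.append("pseudo_inverse_cov")
    if not np.all(np.isfinite(cov_t)) or np.any(np.diag(cov_t) < 0):
        cov_t = np.linalg.pinv(H)
        flags.append("pseudo_inverse_cov")
    # delta method: d(mu)/d(log mu) = mu, d(phi)/d(log(phi-1)) = phi - 1
    if fixed_a is not None:
        J = np.diag([params.mu, params.phi - 1.0])
        cov = np.zeros((3, 3))
        cov[:2, :2] = J @ cov_t @ J
    else:
        J = np.diag([params.mu, params.phi - 1.0, 1.0])
        cov = J @ cov_t @ J
    cov = 0.5 * (cov + cov.T)
    return cov, flags


def _poisson_fit(arr: np.ndarray, flags: list[str], fixed_a: float | None) -> PTFit:
    mu = float(arr.mean())
    n = arr.size
    ll = float(np.sum(stats.poisson.logpmf(arr, mu)))
    cov = np.zeros((3, 3))
    cov[0, 0] = mu / n
    return PTFit(
        params=PTMeanParams(mu=mu, phi=1.0, a=1.0),
        loglik=ll, converged=True, cov=cov, var_mu=mu / n,
        fixed_a=fixed_a, flags=flags + ["poisson_boundary"], n=n,
    )


def fit_pt_mle(counts, fixed_a: float | None = None, options: dict | None = None) -> PTFit:
    """Constrained quasi-Newton maximum-likelihood fit of one profile.

    ``fixed_a`` pins the shape (``fixed_a=0`` gives the negative-binomial
    fit used by the goodness-of-fit test).  Profiles whose fitted
    dispersion collapses to the phi = 1 boundary are returned as Poisson
    fits with ``Var(mu) = mu / n``; all-equal profiles are flagged as
    degenerate rather than failing, so genome-wide loops survive.
    """
    arr = np.asarray(counts)
    if arr.size < 2:
        raise PTDomainError("need at least two observations")
    if np.all(arr == 0):
        raise PTDomainError("degenerate all-zero profile")
    if np.all(arr == arr.flat[0]):
        f = tabulate_counts(arr)
        return _poisson_fit(arr.astype(float), ["degenerate_profile"], fixed_a)
    f = tabulate_counts(arr)
    init = moment_init(arr)
    a0 = 0.0 if fixed_a is None else float(fixed_a)
    starts = [(init.mu, init.phi, a0)]
    for a_alt in (-0.5, 0.5):
        starts.append((init.mu, 1.0 + 1.5 * (init.phi - 1.0),
                       a_alt if fixed_a is None else a0))
    opts = {"maxiter": 500}
    if options:
        opts.update(options)

    fun = _objective(fixed_a, f.y)
    bounds = [(None, None), (_T2_MIN, None)]
    if fixed_a is None:
        bounds.append((_A_MIN, _A_MAX))
    best, best_ok = None, False
    n_tried = 0
    for mu_s, phi_s, a_s in starts[: 1 + _MAX_RESTARTS]:
        n_tried += 1
        x0 = [math.log(mu_s), math.log(max(phi_s - 1.0, 1e-6))]
        if fixed_a is None:
            x0.append(a_s)
        res = optimize.minimize(fun, np.array(x0), method="L-BFGS-B",
                                bounds=bounds, options=opts)
        if not res.success:
            # a quasi-Newton line-search stall near the optimum is common at
            # small n; polish with a simplex pass before declaring failure
            res2 = optimize.minimize(fun, res.x, method="Nelder-Mead",
                                     options={"xatol": 1e-6, "fatol": 1e-8,
                                              "maxiter": 2000})
            if res2.fun <= res.fun:
                res2.x = np.clip(res2.x, [b[0] if b[0] is not None else -np.inf
                                          for b in bounds],
                                 [b[1] if b[1] is not None else np.inf
                                  for b in bounds])
                res = res2
        ok = bool(res.success and res.fun < 1e29)
        if best is None or (ok and not best_ok) or (ok == best_ok and res.fun < best.fun):
            best, best_ok = res, ok
        if ok:
            break
    res = best
    flags: list[str] = []
    converged = best_ok and res.fun < 1e29
    if not converged:
        flags.append("no_convergence")

    t1, t2 = res.x[0], res.x[1]
    a_hat = float(res.x[2]) if fixed_a is None else float(fixed_a)
    mu_hat = math.exp(t1)
    d_hat = math.exp(t2)
    if d_hat <= 10.0 * math.exp(_T2_MIN) or a_hat >= 1.0 - 1e-8:
        # dispersion collapsed to the Poisson boundary
        return _poisson_fit(arr.astype(float), flags, fixed_a)
    params = PTMeanParams(mu=mu_hat, phi=1.0 + d_hat, a=a_hat)
    cov, cov_flags = estimate_variance(params, f, fixed_a=fixed_a)
    flags += cov_flags
    var_mu = float(cov[0, 0])
    if var_mu < 0.0:
        var_mu = float("nan")
        flags.append("invalid_var_mu")
    return PTFit(params=params, loglik=-float(res.fun), converged=converged,
                 cov=cov, var_mu=var_mu, fixed_a=fixed_a, flags=flags, n=f.n)


def nb_gof_test(counts) -> GOFResult:
    """Likelihood-ratio test of H0: a = 0 (negative binomial) within PT.

    The statistic 2 log T = 2 (l_PT - l_NB) is referred to chi-squared
    with 1 df; a = 0 is interior to the shape domain so no boundary
    correction applies.  Small negative statistics from optimizer noise
    are clipped to zero.
    """
    arr = np.asarray(counts)
    if arr.size < 15:
        warnings.warn(
            f"goodness-of-fit asymptotics are unreliable at n={arr.size} < 15",
            stacklevel=2,
        )
    fit_pt = fit_pt_mle(arr)
    fit_nb = fit_pt_mle(arr, fixed_a=0.0)
    if not (fit_pt.converged and fit_nb.converged):
        raise PTFitError(
            "PT and/or NB fit did not converge",
            diagnostics={"pt": fit_pt, "nb": fit_nb},
        )
    stat = 2.0 * (fit_pt.loglik - fit_nb.loglik)
    if stat < -1e-6:
        # both optima are approximate; anything worse than tolerance means
        # the full fit landed in a worse basin than its nested special case
        stat = 0.0
    stat = max(stat, 0.0)
    pvalue = float(stats.chi2.sf(stat, df=1))
    return GOFResult(statistic=stat, pvalue=pvalue,
                     loglik_pt=fit_pt.loglik, loglik_nb=fit_nb.loglik,
                     a_hat=fit_pt.params.a)


def gof_zscore(gof: GOFResult) -> float:
    """Map the goodness-of-fit result to a signed normal score.

    |z| is the upper-tail standard-normal quantile at pvalue/2, signed by
    the fitted shape so that heavy-tailed departures (a > 0) map right and
    zero-inflated ones (a < 0) map left.
    """
    z = float(stats.norm.ppf(1.0 - gof.pvalue / 2.0))
    return z * float(np.sign(gof.a_hat))
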