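"""Seed-survival curve fitting under controlled ageing.

Two models are fitted to germination time-courses by binomial maximum
likelihood:

* probit: viable fraction at time t is ``Phi(Ki - t/sigma)`` -- viability
  in normal equivalent deviates (NED) falls linearly with time from the
  initial value ``Ki`` with slope ``-1/sigma``;
* declining logistic: germination percent is ``(100 - alpha) /
  (1 + exp(beta * (t - c)))`` so the curve falls from ``100 - alpha``
  toward 0 with midpoint ``c``. (The rising-sign variant seen in print is
  treated as typographical: a survival curve must decrease.)

p50 is, by default, the time at which viability reaches 50 % of its
*initial* fitted value, not an absolute 50 % -- ``p50_of_initial``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from seedspan.errors import DegenerateFitError, InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

_PHI = special.ndtr  # standard normal CDF
_PHI_INV = special.ndtri

_EPS_P = 1e-12


@dataclass(frozen=True)
class GerminationTimeCourse:
    """One species' ageing schedule: (time, n tested, n germinated) triples."""

    species_id: str
    times: tuple[float, ...]
    n_tested: tuple[int, ...]
    n_germinated: tuple[int, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_tested)
        r = np.asarray(self.n_germinated)
        if not (len(t) == len(n) == len(r)):
            raise SchemaError(f"{self.species_id}: unequal column lengths")
        if len(t) == 0:
            raise SchemaError(f"{self.species_id}: empty time-course")
        if np.any(t < 0):
            raise SchemaError(f"{self.species_id}: negative withdrawal time")
        if np.any(np.diff(t) <= 0):
            raise SchemaError(f"{self.species_id}: withdrawal times must strictly increase")
        if np.any(n <= 0):
            raise SchemaError(f"{self.species_id}: n_tested must be positive")
        if np.any(r < 0) or np.any(r > n):
            raise SchemaError(f"{self.species_id}: need 0 <= n_germinated <= n_tested")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray(self.n_germinated) / np.asarray(self.n_tested)


@dataclass
class ViabilityFit:
    """Fitted survival-curve parameters plus p50 and diagnostics."""

    species_id: str
    model: Literal["probit", "logistic"]
    p50_days: float
    p50_se: float
    log_likelihood: float
    converged: bool
    censored: bool
    degenerate: bool = False
    n_withdrawals: int = 0
    # probit parameters
    Ki: Optional[float] = None
    sigma: Optional[float] = None
    cov_Ki_sigma: Optional[np.ndarray] = None
    # logistic parameters
    alpha: Optional[float] = None
    beta: Optional[float] = None
    c: Optional[float] = None
    c_se: Optional[float] = None

    @property
    def n_parameters(self) -> int:
        return 2 if self.model == "probit" else 3

    @property
    def aic(self) -> float:
        return 2 * self.n_parameters - 2 * self.log_likelihood


# ---------------------------------------------------------------------------
# p50 definitions (probit / viability-equation scale)
# ---------------------------------------------------------------------------

def p50_of_initial(Ki: float, sigma: float) -> float:
    """Time for viability to fall to half its *initial* value.

    Solves ``Phi(Ki - p/sigma) = Phi(Ki) / 2``; closed form
    ``sigma * (Ki - Phi^-1(Phi(Ki)/2))``. Defined for any real Ki; for
    large Ki it converges to the classical ``Ki * sigma``.
    """
    if not (sigma > 0):
        raise InvalidInputError(f"sigma must be positive, got {sigma}")
    return float(sigma * (Ki - _PHI_INV(_PHI(Ki) / 2.0)))


def p50_absolute(Ki: float, sigma: float) -> float:
    """Classical p50: time at which viability reaches an absolute 50 %."""
    if not (sigma > 0):
        raise InvalidInputError(f"sigma must be positive, got {sigma}")
    if Ki <= 0:
        raise InvalidInputError(
            f"absolute p50 undefined: initial viability already <= 50 % (Ki={Ki})"
        )
    return float(Ki * sigma)


def solve_sigma_for_p50(target_p50: float, Ki: float) -> float:
    """Invert p50_of_initial for sigma (p50 is linear in sigma at fixed Ki)."""
    if not (target_p50 > 0):
        raise InvalidInputError("target p50 must be positive")
    unit = p50_of_initial(Ki, 1.0)
    return target_p50 / unit


# ---------------------------------------------------------------------------
# Probit (viability equation) binomial ML fit
# ---------------------------------------------------------------------------

def _binom_loglik_probit(a: float, b: float, t: np.ndarray, n: np.ndarray, r: np.ndarray) -> float:
    p = np.clip(_PHI(a + b * t), _EPS_P, 1 - _EPS_P)
    return float(np.sum(stats.binom.logpmf(r, n, p)))


def _negloglik_grad(params: np.ndarray, t: np.ndarray, n: np.ndarray, r: np.ndarray):
    a, b = params
    eta = a + b * t
    p = np.clip(_PHI(eta), _EPS_P, 1 - _EPS_P)
    ll = np.sum(stats.binom.logpmf(r, n, p))
    phi = stats.norm.pdf(eta)
    w = phi * (r - n * p) / (p * (1 - p))
    grad = -np.array([np.sum(w), np.sum(w * t)])
    return -ll, grad


def _numeric_hessian(fun, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h * max(1.0, abs(x[i]))
            ej[j] = h * max(1.0, abs(x[j]))
            f = fun
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * ei[i] * ej[j])
    return H


def _moment_starts(tc: GerminationTimeCourse) -> tuple[float, float]:
    t = np.asarray(tc.times, dtype=float)
    frac = tc.fractions
    p0 = np.clip(frac[0], 0.02, 0.98)
    a0 = float(_PHI_INV(p0))
    drops = -np.diff(frac)
    if len(drops) and drops.max() > 0:
        i = int(np.argmax(drops))
        dt = t[i + 1] - t[i]
        # steepest drop spans roughly one NED per sigma days
        b0 = -max(drops.max(), 0.05) / dt
    else:
        b0 = -1.0 / max(t[-1], 1.0)
    return a0, float(b0)


def fit_probit(tc: GerminationTimeCourse, n_restarts: int = 5) -> ViabilityFit:
    """Binomial-ML probit fit of the viability decline curve.

    Equivalent to probit regression of germinated/tested on time with
    intercept Ki and slope -1/sigma. Standard errors come from the
    observed information (numeric Hessian at the optimum); p50 and its
    delta-method SE use the half-of-initial definition.
    """
    t = np.asarray(tc.times, dtype=float)
    n = np.asarray(tc.n_tested)
    r = np.asarray(tc.n_germinated)
    frac = tc.fractions

    if np.all(r == 0) or np.all(r == n):
        raise DegenerateFitError(f"{tc.species_id}: all withdrawals at 0 % or 100 %")
    if np.allclose(frac, frac[0]):
        raise DegenerateFitError(f"{tc.species_id}: no viability decline in data")

    degenerate = False
    informative = np.sum((r > 0) & (r < n))
    if len(tc) < 3 or informative < 3:
        degenerate = True
        logger.warning("%s: <3 informative withdrawals; SEs unreliable", tc.species_id)

    a0, b0 = _moment_starts(tc)
    rng = np.random.default_rng(0)  # fixed jitter seed for reproducible restarts
    best = None
    for k in range(1 + n_restarts):
        if k == 0:
            x0 = np.array([a0, b0])
        else:
            x0 = np.array([a0 + rng.normal(0, 0.5), b0 * np.exp(rng.normal(0, 0.7))])
        res = optimize.minimize(
            _negloglik_grad, x0, args=(t, n, r), jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if k == 0 and res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise DegenerateFitError(f"{tc.species_id}: probit fit did not converge: {best}")
    if not best.success:
        logger.warning("%s: optimizer reported non-convergence: %s", tc.species_id, best.message)

    a, b = best.x
    if b >= -1e-10:
        raise DegenerateFitError(
            f"{tc.species_id}: fitted slope is non-negative (no decline); probit p50 undefined"
        )
    Ki = float(a)
    sigma = float(-1.0 / b)
    loglik = -float(best.fun)

    nll = lambda x: _negloglik_grad(x, t, n, r)[0]
    H = _numeric_hessian(nll, best.x)
    try:
        cov_ab = np.linalg.inv(H)
        if not np.all(np.isfinite(cov_ab)) or cov_ab[0, 0] < 0 or cov_ab[1, 1] < 0:
            raise np.linalg.LinAlgError("non-PSD covariance")
    except np.linalg.LinAlgError:
        degenerate = True
        cov_ab = np.full((2, 2), np.inf)

    # delta method: p50(a,b) = -(a - q(a))/b with q = Phi^-1(Phi(a)/2)
    q = float(_PHI_INV(_PHI(a) / 2.0))
    qprime = float(stats.norm.pdf(a) / (2.0 * stats.norm.pdf(q)))
    dp_da = -(1.0 - qprime) / b
    dp_db = (a - q) / b**2
    g = np.array([dp_da, dp_db])
    var_p50 = float(g @ cov_ab @ g)
    p50 = p50_of_initial(Ki, sigma)
    p50_se = float(np.sqrt(var_p50)) if np.isfinite(var_p50) and var_p50 >= 0 else np.inf
    if not np.isfinite(p50_se):
        degenerate = True

    # (Ki, sigma) covariance via Jacobian of (a,b)->(a,-1/b)
    if np.all(np.isfinite(cov_ab)):
        J = np.array([[1.0, 0.0], [0.0, 1.0 / b**2]])
        cov_ks = J @ cov_ab @ J.T
    else:
        cov_ks = np.full((2, 2), np.inf)

    return ViabilityFit(
        species_id=tc.species_id,
        model="probit",
        Ki=Ki,
        sigma=sigma,
        cov_Ki_sigma=cov_ks,
        p50_days=p50,
        p50_se=p50_se,
        log_likelihood=loglik,
        converged=bool(best.success),
        censored=bool(p50 > t[-1]),
        degenerate=degenerate,
        n_withdrawals=len(tc),
    )


def fit_probit_ned(tc: GerminationTimeCourse) -> tuple[float, float]:
    """Secondary cross-check: OLS on NED-transformed fractions.

    Applies the (r+0.5)/(n+1) correction so 0 %/100 % withdrawals stay
    finite. Returns (Ki, sigma). Not the primary method -- the ML probit
    fit is.
    """
    t = np.asarray(tc.times, dtype=float)
    n = np.asarray(tc.n_tested, dtype=float)
    r = np.asarray(tc.n_germinated, dtype=float)
    ned = _PHI_INV((r + 0.5) / (n + 1.0))
    slope, intercept = np.polyfit(t, ned, 1)
    if slope >= 0:
        raise DegenerateFitError(f"{tc.species_id}: NED regression slope non-negative")
    return float(intercept), float(-1.0 / slope)


# ---------------------------------------------------------------------------
# Declining logistic fit
# ---------------------------------------------------------------------------

def logistic_percent(t: np.ndarray, alpha: float, beta: float, c: float) -> np.ndarray:
    """Declining logistic germination percent: (100-alpha)/(1+exp(beta(t-c)))."""
    return (100.0 - alpha) / (1.0 + np.exp(np.clip(beta * (np.asarray(t, float) - c), -500, 500)))


def fit_logistic(tc: GerminationTimeCourse, n_restarts: int = 5) -> ViabilityFit:
    """Binomial-ML fit of the declining logistic curve; p50 is the midpoint c."""
    t = np.asarray(tc.times, dtype=float)
    n = np.asarray(tc.n_tested)
    r = np.asarray(tc.n_germinated)
    frac = tc.fractions
    if np.all(r == 0) or np.all(r == n):
        raise DegenerateFitError(f"{tc.species_id}: all withdrawals at 0 % or 100 %")
    if np.allclose(frac, frac[0]):
        raise DegenerateFitError(f"{tc.species_id}: no viability decline in data")
    degenerate = len(tc) < 4  # 3 parameters need >=4 points for any SE

    def nll(x: np.ndarray) -> float:
        alpha, beta, c = x
        p = np.clip(logistic_percent(t, alpha, beta, c) / 100.0, _EPS_P, 1 - _EPS_P)
        return -float(np.sum(stats.binom.logpmf(r, n, p)))

    # moment starts: midpoint near where the fraction halves, beta from drop width
    half = frac[0] / 2.0
    c0 = float(t[int(np.argmin(np.abs(frac - half)))]) or float(t[-1] / 2.0)
    b0 = 4.0 / max(float(t[-1] - t[0]), 1.0)
    bounds = [(0.0, 99.9), (1e-6, 10.0), (1e-9, 10.0 * float(t[-1]) + 100.0)]
    rng = np.random.default_rng(0)
    best = None
    for k in range(1 + n_restarts):
        x0 = np.array([0.0, b0, c0]) if k == 0 else np.array(
            [rng.uniform(0, 30), b0 * np.exp(rng.normal(0, 0.7)), c0 * np.exp(rng.normal(0, 0.5))]
        )
        x0 = np.clip(x0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 1000, "ftol": 1e-12})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise DegenerateFitError(f"{tc.species_id}: logistic fit did not converge")

    alpha, beta, c = best.x
    loglik = -float(best.fun)
    H = _numeric_hessian(nll, best.x)
    try:
        cov = np.linalg.inv(H)
        c_var = float(cov[2, 2])
        if not np.isfinite(c_var) or c_var < 0:
            raise np.linalg.LinAlgError("bad variance")
        c_se = float(np.sqrt(c_var))
    except np.linalg.LinAlgError:
        degenerate = True
        c_se = np.inf

    return ViabilityFit(
        species_id=tc.species_id,
        model="logistic",
        alpha=float(alpha),
        beta=float(beta),
        c=float(c),
        c_se=c_se,
        p50_days=float(c),
        p50_se=c_se,
        log_likelihood=loglik,
        converged=bool(best.success),
        censored=bool(c > t[-1]),
        degenerate=degenerate or not np.isfinite(c_se),
        n_withdrawals=len(tc),
    )


# ---------------------------------------------------------------------------
# Model choice / prediction
# ---------------------------------------------------------------------------

def compare_fits(probit_fit: ViabilityFit, logistic_fit: ViabilityFit) -> str:
    """Pick the model with lower AIC; ties go to probit (the study default)."""
    if probit_fit.species_id != logistic_fit.species_id:
        raise InvalidInputError("fits are for different species")
    return "logistic" if logistic_fit.aic < probit_fit.aic else "probit"


def p50_standard_error(fit: ViabilityFit) -> float:
    """Delta-method SE of p50 (already computed at fit time)."""
    return fit.p50_se


def predict_survival_curve(fit: ViabilityFit, times: Iterable[float]) -> np.ndarray:
    """Model-predicted germination percent at each time (non-increasing)."""
    t = np.asarray(list(times), dtype=float)
    if fit.model == "probit":
        return 100.0 * _PHI(fit.Ki - t / fit.sigma)
    return logistic_percent(t, fit.alpha, fit.beta, fit.c)


def fit_auto(tc: GerminationTimeCourse) -> ViabilityFit:
    """Fit both models and return the AIC-preferred one (ties -> probit)."""
    pf = fit_probit(tc)
    try:
        lf = fit_logistic(tc)
    except DegenerateFitError:
        return pf
    return lf if compare_fits(pf, lf) == "logistic" else pf


# ---------------------------------------------------------------------------
# Long-format CSV I/O
# ---------------------------------------------------------------------------

def load_timecourses(path) -> list[GerminationTimeCourse]:
    """Read long-format CSV (species, time_days, n_tested, n_germinated)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"species", "time_days", "n_tested", "n_germinated"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for sp, grp in df.groupby("species", sort=False):
        grp = grp.sort_values("time_days")
        out.append(
            GerminationTimeCourse(
                species_id=str(sp),
                times=tuple(float(x) for x in grp["time_days"]),
                n_tested=tuple(int(x) for x in grp["n_tested"]),
                n_germinated=tuple(int(x) for x in grp["n_germinated"]),
            )
        )
    return out


def fits_to_frame(fits: Sequence[ViabilityFit]):
    """One row per species: model, parameters, p50, SE, flags, logLik."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "species": f.species_id,
                "model": f.model,
                "Ki": f.Ki,
                "sigma": f.sigma,
                "alpha": f.alpha,
                "beta": f.beta,
                "c": f.c,
                "p50": f.p50_days,
                "p50_se": f.p50_se,
                "logLik": f.log_likelihood,
                "converged": f.converged,
                "censored": f.censored,
                "degenerate": f.degenerate,
            }
            for f in fits
        ]
    )
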