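"""(P)GLS candidate models for log10 p50, AICc ranking and model averaging.

Non-phylogenetic fits are ordinary ML linear models (star phylogeny);
phylogenetic fits estimate Pagel's lambda jointly by ML, scaling the
off-diagonal phylogenetic covariances. Candidate sets are ranked by AICc
and combined by full model averaging (absent coefficients enter as 0)
with Burnham-Anderson unconditional standard errors. Group comparisons
(one-way ANOVA, Tukey HSD, group summaries) live here too.

Parameter counting: K = number of regression coefficients + 1 for the
residual variance, plus 1 more when lambda is estimated. This is one
consistent rule; published tables sometimes leave lambda and/or the
variance uncounted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from seedspan.errors import InvalidInputError
from seedspan.tree import PhyloCovariance, lambda_transform

logger = logging.getLogger(__name__)

PREDICTOR_NAMES = ("log10_vs", "log10_tsw", "log10_mct", "non_endospermic", "pd", "py")

#: the ten-candidate set used throughout: full model, single-trait models,
#: two two-term models and the null model.
DEFAULT_CANDIDATES: tuple[tuple[str, ...], ...] = (
    ("log10_vs", "log10_tsw", "log10_mct", "non_endospermic", "pd", "py"),
    ("py",),
    ("log10_mct", "py"),
    ("non_endospermic",),
    ("pd",),
    ("log10_vs",),
    ("log10_vs", "log10_tsw"),
    (),
    ("log10_mct",),
    ("log10_tsw",),
)


@dataclass(frozen=True)
class ModelSpec:
    response: str = "log10_p50"
    predictors: tuple[str, ...] = ()
    phylogenetic: bool = False

    def label(self) -> str:
        return " + ".join(self.predictors) if self.predictors else "null"


@dataclass
class ModelFit:
    spec: ModelSpec
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, SE)
    log_likelihood: float
    K: int
    n: int
    aicc: float
    lambda_hat: Optional[float] = None
    delta_i: Optional[float] = None
    weight: Optional[float] = None
    dropped_species: tuple[str, ...] = ()

    def to_row(self) -> dict:
        return {
            "model": self.spec.label(),
            "lambda": self.lambda_hat,
            "K": self.K,
            "logLik": self.log_likelihood,
            "AICc": self.aicc,
            "delta_i": self.delta_i,
            "weight": self.weight,
            "n": self.n,
        }


@dataclass
class AveragedModel:
    coefficients: dict[str, tuple[float, float, float, float]]  # est, SE, z, p
    lambda_avg: Optional[float] = None

    def to_rows(self) -> list[dict]:
        return [
            {"coefficient": k, "estimate": e, "se": s, "z": z, "p": p}
            for k, (e, s, z, p) in self.coefficients.items()
        ]


def aicc(log_likelihood: float, K: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise InvalidInputError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * log_likelihood + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """(delta_i, weights) from a list of AICc values."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise InvalidInputError("need at least one finite AICc value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def _design(matrix: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str], pd.Index]:
    cols = [spec.response, *spec.predictors]
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise InvalidInputError(f"matrix lacks column(s) {missing}")
    sub = matrix[cols].dropna()
    dropped = matrix.index.difference(sub.index)
    if len(dropped):
        logger.info("%s: dropped %d incomplete rows: %s",
                    spec.label(), len(dropped), list(dropped))
    y = sub[spec.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub))] + [sub[p].to_numpy(dtype=float) for p in spec.predictors])
    names = ["(Intercept)", *spec.predictors]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise InvalidInputError(
            f"rank-deficient design in model {spec.label()} (rank {rank} < {X.shape[1]})"
        )
    return X, y, names, sub.index


def _gls_ml(X: np.ndarray, y: np.ndarray, V: Optional[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ML GLS: (beta, cov_beta, sigma2_ml, logLik); V=None means identity."""
    n = len(y)
    if V is None:
        Xt, yt, logdet = X, y, 0.0
    else:
        L = np.linalg.cholesky(V)
        Xt = np.linalg.solve(L, X)
        yt = np.linalg.solve(L, y)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    resid = yt - Xt @ beta
    sigma2 = float(resid @ resid) / n
    scale = float(yt @ yt) / n
    if sigma2 <= 1e-12 * max(scale, 1e-12):
        raise InvalidInputError("degenerate fit: zero residual variance")
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    cov_beta = sigma2 * np.linalg.inv(XtX)
    return beta, cov_beta, sigma2, loglik


def gls_fit(matrix: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Non-phylogenetic ML linear model (identity residual covariance)."""
    X, y, names, idx = _design(matrix, spec)
    n = len(y)
    K = X.shape[1] + 1  # + residual variance
    if n <= K + 1:
        raise InvalidInputError(f"n={n} too small for model {spec.label()} (K={K})")
    beta, cov_beta, _, loglik = _gls_ml(X, y, None)
    ses = np.sqrt(np.diag(cov_beta))
    return ModelFit(
        spec=spec,
        coefficients={nm: (float(b), float(s)) for nm, b, s in zip(names, beta, ses)},
        log_likelihood=float(loglik),
        K=K, n=n,
        aicc=aicc(loglik, K, n),
        dropped_species=tuple(matrix.index.difference(idx)),
    )


def pgls_fit(matrix: pd.DataFrame, spec: ModelSpec, cov: PhyloCovariance,
             lam: Optional[float] = None) -> ModelFit:
    """PGLS with Pagel's lambda ML-estimated on [0, 1] (or fixed via ``lam``)."""
    X, y, names, idx = _design(matrix, spec)
    n = len(y)
    K = X.shape[1] + 1 + (1 if lam is None else 0)  # + variance (+ lambda)
    if n <= K + 1:
        raise InvalidInputError(f"n={n} too small for model {spec.label()} (K={K})")
    sub = cov.reorder(list(idx))

    def negll(l: float) -> float:
        V = lambda_transform(sub, l).matrix
        return -_gls_ml(X, y, V)[3]

    if lam is None:
        res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-6})
        candidates = {0.0: negll(0.0), 1.0: negll(1.0), float(res.x): float(res.fun)}
        lam_hat = min(candidates, key=candidates.get)
    else:
        lam_hat = float(lam)
    V = lambda_transform(sub, lam_hat).matrix
    beta, cov_beta, _, loglik = _gls_ml(X, y, V)
    ses = np.sqrt(np.diag(cov_beta))
    fit = ModelFit(
        spec=ModelSpec(spec.response, spec.predictors, phylogenetic=True),
        coefficients={nm: (float(b), float(s)) for nm, b, s in zip(names, beta, ses)},
        log_likelihood=float(loglik),
        K=K, n=n,
        aicc=aicc(loglik, K, n),
        lambda_hat=float(lam_hat),
        dropped_species=tuple(matrix.index.difference(idx)),
    )
    return fit


def rank_models(fits: Sequence[ModelFit]) -> list[ModelFit]:
    """Fill delta_i and Akaike weights; return fits sorted by AICc."""
    delta, w = akaike_weights([f.aicc for f in fits])
    for f, d, wi in zip(fits, delta, w):
        f.delta_i = float(d)
        f.weight = float(wi)
    return sorted(fits, key=lambda f: f.aicc)


def fit_candidates(
    matrix: pd.DataFrame,
    candidates: Sequence[Sequence[str]] = DEFAULT_CANDIDATES,
    cov: Optional[PhyloCovariance] = None,
    response: str = "log10_p50",
) -> list[ModelFit]:
    """Fit and rank the candidate set, phylogenetically when ``cov`` given."""
    fits = []
    for preds in candidates:
        spec = ModelSpec(response=response, predictors=tuple(preds),
                         phylogenetic=cov is not None)
        if cov is None:
            fits.append(gls_fit(matrix, spec))
        else:
            fits.append(pgls_fit(matrix, spec, cov))
    return rank_models(fits)


def model_average(fits: Sequence[ModelFit]) -> AveragedModel:
    """Full model averaging over a ranked candidate set.

    Coefficients absent from a model contribute 0 with variance 0; the
    unconditional SE combines within-model variance and between-model
    spread: SE_j = sum_i w_i * sqrt(var_ij + (b_ij - bbar_j)^2).
    """
    weights = np.array([f.weight if f.weight is not None else np.nan for f in fits])
    if np.any(np.isnan(weights)) or abs(weights.sum() - 1.0) > 1e-9:
        raise InvalidInputError("fits must carry weights summing to 1 (run rank_models first)")
    names: list[str] = []
    for f in fits:
        for nm in f.coefficients:
            if nm not in names:
                names.append(nm)
    out: dict[str, tuple[float, float, float, float]] = {}
    for nm in names:
        ests = np.array([f.coefficients.get(nm, (0.0, 0.0))[0] for f in fits])
        ses = np.array([f.coefficients.get(nm, (0.0, 0.0))[1] for f in fits])
        avg = float(weights @ ests)
        se = float(weights @ np.sqrt(ses**2 + (ests - avg) ** 2))
        z = abs(avg) / se if se > 0 else np.inf
        p = float(2.0 * stats.norm.sf(z)) if np.isfinite(z) else 0.0
        out[nm] = (avg, se, float(z), p)
    lam_avg = None
    lams = [f.lambda_hat for f in fits if f.lambda_hat is not None]
    if len(lams) == len(fits):
        lam_avg = float(weights @ np.array(lams))
    return AveragedModel(coefficients=out, lambda_avg=lam_avg)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def _split_groups(values: Sequence[float], groups: Sequence) -> dict:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(v) != len(g):
        raise InvalidInputError("values and groups differ in length")
    return {lvl: v[g == lvl] for lvl in pd.unique(g)}


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical one-way ANOVA (between/within decomposition)."""
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise InvalidInputError("ANOVA needs >=2 groups")
    if max(len(x) for x in by.values()) < 2:
        raise InvalidInputError("ANOVA needs at least one group with >=2 values")
    samples = list(by.values())
    v = np.concatenate(samples)
    if np.ptp(v) == 0:
        raise InvalidInputError("all values identical: F undefined")
    F, p = stats.f_oneway(*samples)
    if not np.isfinite(F):
        raise InvalidInputError("zero within-group variance: F undefined")
    df1 = len(by) - 1
    df2 = len(v) - len(by)
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=float(p))


def tukey_hsd(values: Sequence[float], groups: Sequence) -> dict[tuple, float]:
    """Studentized-range adjusted pairwise p-values after a one-way ANOVA."""
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise InvalidInputError("Tukey HSD needs >=2 groups")
    if min(len(x) for x in by.values()) < 2:
        raise InvalidInputError("Tukey HSD needs >=2 values per group")
    labels = list(by.keys())
    res = stats.tukey_hsd(*[by[lbl] for lbl in labels])
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[(labels[i], labels[j])] = float(res.pvalue[i, j])
    return out


def group_summary(values: Sequence[float], groups: Sequence) -> dict:
    """Per-group (mean, SE of the mean, n); SE is 0 for singleton groups."""
    by = _split_groups(values, groups)
    out = {}
    for lbl, x in by.items():
        n = len(x)
        se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out[lbl] = {"mean": float(np.mean(x)), "se": se, "n": n}
    return out
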