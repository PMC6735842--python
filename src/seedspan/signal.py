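"""Phylogenetic signal statistics: Pagel's lambda, Blomberg's K, Fritz-Purvis D.

All three compare the distribution of a tip trait against a Brownian
random-walk expectation encoded in the tree's covariance matrix. Lambda
is ML-estimated on [0, 1] with likelihood-ratio tests against the star
(lambda=0) and Brownian (lambda=1) ends; K uses the mean-squared-error
ratio with a tip-shuffle randomization test; D (binary traits) scales the
observed sum of nodal changes between simulated random and Brownian
reference distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

from seedspan.errors import InvalidInputError, PhylogenyError
from seedspan.tree import PhyloCovariance, lambda_transform, phylo_covariance

logger = logging.getLogger(__name__)


@dataclass
class SignalResult:
    statistic: Literal["lambda", "K", "D"]
    estimate: float
    n_tips: int
    p_vs_star: Optional[float] = None
    p_vs_brownian: Optional[float] = None
    n_permutations: Optional[int] = None
    log_likelihood: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "estimate": self.estimate,
            "n_tips": self.n_tips,
            "p_vs_star": self.p_vs_star,
            "p_vs_brownian": self.p_vs_brownian,
            "n_permutations": self.n_permutations,
            "log_likelihood": self.log_likelihood,
        }


def _as_cov(tree_or_cov) -> PhyloCovariance:
    if isinstance(tree_or_cov, PhyloCovariance):
        return tree_or_cov
    if isinstance(tree_or_cov, dendropy.Tree):
        return phylo_covariance(tree_or_cov)
    raise InvalidInputError(f"expected tree or covariance, got {type(tree_or_cov)}")


def _match(cov: PhyloCovariance, trait: dict | Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Align trait values to the covariance's species order."""
    if isinstance(trait, dict):
        from seedspan.tree import canonical_label

        lookup = {canonical_label(k): v for k, v in trait.items()}
        canon_taxa = [canonical_label(t) for t in cov.taxa]
        missing = [t for t in canon_taxa if t not in lookup]
        extra = [t for t in lookup if t not in set(canon_taxa)]
        if missing or extra:
            raise PhylogenyError(f"tip/trait mismatch; missing={missing}, extra={extra}")
        y = np.asarray([float(lookup[t]) for t in canon_taxa])
    else:
        y = np.asarray(trait, dtype=float)
        if len(y) != len(cov.taxa):
            raise PhylogenyError(
                f"trait length {len(y)} != {len(cov.taxa)} tips (pass a dict to match by name)"
            )
    return y, cov.matrix


def gls_mean_loglik(V: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile ML of the single-mean MVN model: (mu_hat, sigma2_hat, logLik)."""
    n = len(y)
    L = np.linalg.cholesky(V)
    one = np.ones(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, one)
    mu = float(one @ Vinv_y / (one @ Vinv_1))
    e = y - mu
    sigma2 = float(e @ np.linalg.solve(V, e) / n)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        raise InvalidInputError("degenerate trait (zero GLS residual variance)")
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return mu, sigma2, loglik


def pagel_lambda(tree_or_cov, trait) -> SignalResult:
    """ML Pagel's lambda on [0, 1] with chi-square(1) LRTs against 0 and 1."""
    cov = _as_cov(tree_or_cov)
    y, V = _match(cov, trait)
    n = len(y)
    if n < 4:
        raise InvalidInputError(f"lambda needs >=4 tips, got {n} (unidentifiable)")
    if np.ptp(y) == 0:
        raise InvalidInputError("constant trait: lambda undefined")

    def negll(lam: float) -> float:
        Vlam = lambda_transform(cov, lam).matrix
        return -gls_mean_loglik(Vlam, y)[2]

    res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    candidates = {0.0: negll(0.0), 1.0: negll(1.0), float(res.x): float(res.fun)}
    lam_hat = min(candidates, key=candidates.get)
    ll_hat = -candidates[lam_hat]
    lrt0 = max(0.0, 2.0 * (ll_hat - (-candidates[0.0])))
    lrt1 = max(0.0, 2.0 * (ll_hat - (-candidates[1.0])))
    p0 = float(stats.chi2.sf(lrt0, df=1))
    p1 = float(stats.chi2.sf(lrt1, df=1))
    return SignalResult(
        statistic="lambda", estimate=float(lam_hat), n_tips=n,
        p_vs_star=p0, p_vs_brownian=p1, log_likelihood=float(ll_hat),
    )


def _k_mse_parts(V: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(MSE0, MSE) around the phylogenetically weighted mean."""
    n = len(y)
    one = np.ones(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, one)
    a_hat = float(one @ Vinv_y / (one @ Vinv_1))
    e = y - a_hat
    mse0 = float(e @ e) / (n - 1)
    mse = float(e @ np.linalg.solve(V, e)) / (n - 1)
    return mse0, mse


def blomberg_k(tree_or_cov, trait, n_perm: int = 1000, seed: int = 1) -> SignalResult:
    """Blomberg's K with an MSE-based tip-shuffle randomization p-value.

    K = (MSE0/MSE)_obs / E[MSE0/MSE under Brownian motion]; the p-value is
    the fraction of tip shuffles whose GLS residual MSE is <= the observed
    one (smaller MSE = better phylogenetic fit), with the +1 correction.
    """
    cov = _as_cov(tree_or_cov)
    y, V = _match(cov, trait)
    n = len(y)
    if n < 4:
        raise InvalidInputError(f"K needs >=4 tips, got {n}")
    if np.ptp(y) == 0:
        raise InvalidInputError("constant trait: K undefined")
    mse0, mse = _k_mse_parts(V, y)
    one = np.ones(n)
    expected = (np.trace(V) - n / float(one @ np.linalg.solve(V, one))) / (n - 1)
    K = (mse0 / mse) / expected

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        _, mse_p = _k_mse_parts(V, rng.permutation(y))
        if mse_p <= mse:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return SignalResult(statistic="K", estimate=float(K), n_tips=n,
                        p_vs_star=float(p), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Fritz & Purvis D for binary traits
# ---------------------------------------------------------------------------

class _TreeArrays:
    """Postorder child-index structure for vectorized nodal averaging."""

    def __init__(self, tree: dendropy.Tree):
        leaves = tree.leaf_nodes()
        self.taxa = [lf.taxon.label for lf in leaves]
        index: dict = {lf: i for i, lf in enumerate(leaves)}
        self.n_tips = len(leaves)
        k = self.n_tips
        self.postorder: list[list[int]] = []  # children indices per internal node
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            index[node] = k
            k += 1
            self.postorder.append([index[c] for c in node.child_nodes()])
        self.n_nodes = k

    def d_sum(self, tip_values: np.ndarray) -> np.ndarray:
        """Sum over internal nodes of |child value - nodal mean|.

        ``tip_values`` has shape (n_tips,) or (n_tips, m); nodal values are
        means of child values (sister-clade averaging, polytomy-safe).
        Returns the d sum per dataset.
        """
        tv = np.atleast_2d(np.asarray(tip_values, dtype=float).T).T  # (n_tips, m)
        m = tv.shape[1]
        vals = np.empty((self.n_nodes, m))
        vals[: self.n_tips] = tv
        d = np.zeros(m)
        k = self.n_tips
        for children in self.postorder:
            child_vals = vals[children]  # (n_children, m)
            nodal = child_vals.mean(axis=0)
            d += np.abs(child_vals - nodal).sum(axis=0)
            vals[k] = nodal
            k += 1
        return d if np.ndim(tip_values) > 1 else float(d[0])


def fritz_purvis_d(
    tree: dendropy.Tree,
    trait,
    n_sim: int = 1000,
    seed: int = 1,
) -> SignalResult:
    """Fritz-Purvis D for a binary tip trait.

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian),
    where d sums absolute changes in sister-clade-averaged nodal values;
    d_random comes from prevalence-preserving tip shuffles and d_Brownian
    from threshold-Brownian liabilities rank-cut at the observed
    prevalence. One-sided p-values: p_vs_star is the fraction of random
    simulations at least as clumped (d <= d_obs); p_vs_brownian is the
    fraction of Brownian simulations at least as dispersed (d >= d_obs).
    """
    arrays = _TreeArrays(tree)
    cov = phylo_covariance(tree)
    if arrays.taxa != cov.taxa:
        cov = cov.reorder(arrays.taxa)
    y, V = _match(cov, trait)
    vals = set(np.unique(y))
    if not vals <= {0.0, 1.0}:
        raise InvalidInputError(f"D needs a 0/1 trait, got values {sorted(vals)}")
    if len(vals) < 2:
        raise InvalidInputError("monomorphic trait: D undefined")
    n = len(y)
    k_ones = int(y.sum())
    if min(k_ones, n - k_ones) < 2:
        warnings.warn("a state has <2 tips; D is very uncertain", stacklevel=2)
    if n < 10:
        warnings.warn(f"only {n} tips; D is recommended for >=10", stacklevel=2)

    d_obs = float(arrays.d_sum(y))

    rng = np.random.default_rng(seed)
    shuffles = np.stack([rng.permutation(y) for _ in range(n_sim)], axis=1)
    d_rand = arrays.d_sum(shuffles)

    jitter = 1e-10 * np.trace(V) / n
    L = np.linalg.cholesky(V + jitter * np.eye(n))
    liab = L @ rng.standard_normal((n, n_sim))
    # rank threshold: exactly the observed number of 1s in every simulation
    order = np.argsort(liab, axis=0)
    bm = np.zeros_like(liab)
    rows = order[-k_ones:, :]
    bm[rows, np.arange(n_sim)[None, :]] = 1.0
    d_bm = arrays.d_sum(bm)

    denom = float(d_rand.mean() - d_bm.mean())
    if abs(denom) < 1e-12:
        raise InvalidInputError("random and Brownian d expectations coincide; D undefined")
    D = (d_obs - float(d_bm.mean())) / denom
    p_star = float(np.mean(d_rand <= d_obs))
    p_bm = float(np.mean(d_bm >= d_obs))
    return SignalResult(
        statistic="D", estimate=float(D), n_tips=n,
        p_vs_star=p_star, p_vs_brownian=p_bm, n_permutations=n_sim,
    )
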