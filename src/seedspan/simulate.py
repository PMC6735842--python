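"""Synthetic data generators with known ground truth.

Everything needed to exercise the pipeline at desk scale: germination
time-courses drawn binomially from a probit decline curve, dated trees
(balanced / taxonomy-like / star), continuous traits under (optionally
lambda-damped) Brownian motion, binary traits from a thresholded Brownian
liability, and a full study-like dataset in which log10 p50 is a linear
function of the binary seed-trait indicators plus phylogenetically
structured noise. All generators are deterministic under a fixed rng and
emit their ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from seedspan.errors import InvalidInputError
from seedspan.tree import PhyloCovariance, lambda_transform, phylo_covariance
from seedspan.viability import GerminationTimeCourse, p50_of_initial, solve_sigma_for_p50

logger = logging.getLogger(__name__)

from scipy.special import ndtr as _PHI

#: initial viability in NED giving ~98 % initial germination
DEFAULT_KI = 2.054
#: withdrawal schedule: every 15 days until day 210
DEFAULT_SCHEDULE = tuple(range(0, 211, 15))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def balanced_tree(n_tips: int, root_age: float = 100.0) -> dendropy.Tree:
    """Ultrametric tree from recursive halving; node age halves per level."""
    if n_tips < 2:
        raise InvalidInputError("need >=2 tips")
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True

    def grow(node, labels, age):
        if len(labels) == 1:
            node.taxon = ns.new_taxon(label=labels[0])
            return
        half = len(labels) // 2
        for part in (labels[:half], labels[half:]):
            child_age = age / 2.0 if len(part) > 1 else 0.0
            child = node.new_child(edge_length=age - child_age)
            grow(child, part, child_age)

    labels = [f"t{i + 1}" for i in range(n_tips)]
    grow(tree.seed_node, labels, root_age)
    return tree


def star_tree(n_tips: int, root_age: float = 100.0) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    for i in range(n_tips):
        tip = tree.seed_node.new_child(edge_length=root_age)
        tip.taxon = ns.new_taxon(label=f"t{i + 1}")
    return tree


def taxonomy_like_tree(n_tips: int, root_age: float = 100.0,
                       rng: Optional[np.random.Generator] = None) -> dendropy.Tree:
    """Two-level clustered ultrametric tree (clades of random size)."""
    rng = rng or np.random.default_rng()
    if n_tips < 2:
        raise InvalidInputError("need >=2 tips")
    n_clades = max(2, int(round(np.sqrt(n_tips))))
    assignment = rng.integers(0, n_clades, size=n_tips)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    clade_age = root_age / 2.0
    i = 0
    for c in range(n_clades):
        members = np.flatnonzero(assignment == c)
        if len(members) == 0:
            continue
        if len(members) == 1:
            tip = tree.seed_node.new_child(edge_length=root_age)
            tip.taxon = ns.new_taxon(label=f"t{members[0] + 1}")
            continue
        clade = tree.seed_node.new_child(edge_length=root_age - clade_age)
        for m in members:
            tip = clade.new_child(edge_length=clade_age)
            tip.taxon = ns.new_taxon(label=f"t{m + 1}")
    return tree


def make_tree(shape: str, n_tips: int, root_age: float = 100.0,
              rng: Optional[np.random.Generator] = None) -> dendropy.Tree:
    if shape == "balanced":
        return balanced_tree(n_tips, root_age)
    if shape == "star":
        return star_tree(n_tips, root_age)
    if shape == "taxonomy-like":
        return taxonomy_like_tree(n_tips, root_age, rng)
    raise InvalidInputError(f"unknown tree shape {shape!r}")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_timecourse(
    Ki: float,
    sigma: float,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    n_tested: int = 50,
    rng: Optional[np.random.Generator] = None,
    species_id: str = "sim",
) -> GerminationTimeCourse:
    """Binomial germination counts on the probit decline curve."""
    rng = rng or np.random.default_rng()
    if sigma <= 0 or n_tested <= 0:
        raise InvalidInputError("sigma and n_tested must be positive")
    t = np.asarray(schedule, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("schedule must strictly increase")
    p = _PHI(Ki - t / sigma)
    r = rng.binomial(n_tested, p)
    return GerminationTimeCourse(
        species_id=species_id,
        times=tuple(t),
        n_tested=tuple([n_tested] * len(t)),
        n_germinated=tuple(int(x) for x in r),
    )


def _cov_of(tree_or_cov) -> PhyloCovariance:
    if isinstance(tree_or_cov, PhyloCovariance):
        return tree_or_cov
    return phylo_covariance(tree_or_cov)


def gen_bm_traits(
    tree_or_cov,
    sigma2: float,
    root: float = 0.0,
    lam: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, float]:
    """Brownian tip values: MVN(root, sigma2 * V(lambda)); keyed by tip label."""
    rng = rng or np.random.default_rng()
    if sigma2 < 0:
        raise InvalidInputError("sigma2 must be non-negative")
    cov = _cov_of(tree_or_cov)
    n = len(cov.taxa)
    if sigma2 == 0:
        return {t: float(root) for t in cov.taxa}
    V = lambda_transform(cov, lam).matrix * sigma2
    jitter = 1e-10 * np.trace(V) / n
    L = np.linalg.cholesky(V + jitter * np.eye(n))
    y = root + L @ rng.standard_normal(n)
    return dict(zip(cov.taxa, map(float, y)))


def gen_binary_threshold(
    tree_or_cov,
    prevalence: float,
    model: Literal["threshold-BM", "random"] = "threshold-BM",
    rng: Optional[np.random.Generator] = None,
) -> dict[str, int]:
    """Binary tip trait at the given prevalence.

    threshold-BM: Brownian liability rank-cut so exactly
    round(prevalence * n) tips get state 1; random: i.i.d. Bernoulli.
    """
    rng = rng or np.random.default_rng()
    if not (0.0 < prevalence < 1.0):
        raise InvalidInputError(f"prevalence must be in (0, 1), got {prevalence}")
    cov = _cov_of(tree_or_cov)
    n = len(cov.taxa)
    if model == "random":
        states = (rng.random(n) < prevalence).astype(int)
        return dict(zip(cov.taxa, map(int, states)))
    if model != "threshold-BM":
        raise InvalidInputError(f"unknown binary model {model!r}")
    liab = gen_bm_traits(cov, sigma2=1.0, root=0.0, lam=1.0, rng=rng)
    vals = np.array([liab[t] for t in cov.taxa])
    k = int(round(prevalence * n))
    k = min(max(k, 1), n - 1)
    states = np.zeros(n, dtype=int)
    states[np.argsort(vals)[-k:]] = 1
    return dict(zip(cov.taxa, map(int, states)))


@dataclass
class StudyConfig:
    """Knobs of the study-like generator; defaults mirror the real design."""

    n_species: int = 39
    tree_shape: Literal["balanced", "taxonomy-like", "star"] = "taxonomy-like"
    root_age: float = 100.0
    intercept: float = 1.3  # log10 days
    effect_non_endospermic: float = 0.33
    effect_py: float = 0.47
    effect_pd: float = -0.33
    prevalence_non_endospermic: float = 25 / 39
    prevalence_py: float = 7 / 39
    prevalence_pd: float = 12 / 39
    residual_sd: float = 0.15  # tip SD of the phylogenetic residual, log10 days
    residual_lambda: float = 1.0
    Ki: float = DEFAULT_KI
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    n_tested: int = 50


@dataclass
class SimulatedStudy:
    tree: dendropy.Tree
    matrix: pd.DataFrame  # AnalysisMatrix shape, indexed by species
    timecourses: list[GerminationTimeCourse]
    truth: dict


def gen_study(config: StudyConfig, rng: Optional[np.random.Generator] = None) -> SimulatedStudy:
    """End-to-end study generator with complete ground-truth record.

    log10 p50 = intercept + effects on the binary indicators + a Brownian
    residual rescaled to ``residual_sd`` at the tips; each species' sigma
    is solved from its p50 (Ki fixed), and a germination time-course is
    drawn from the implied decline curve.
    """
    rng = rng or np.random.default_rng()
    cfg = config
    tree = make_tree(cfg.tree_shape, cfg.n_species, cfg.root_age, rng)
    cov = phylo_covariance(tree)
    taxa = cov.taxa

    non_endo = gen_binary_threshold(cov, cfg.prevalence_non_endospermic, "threshold-BM", rng)
    # one dormancy liability: top fraction -> PY, bottom fraction -> PD
    liab = gen_bm_traits(cov, 1.0, 0.0, 1.0, rng)
    vals = np.array([liab[t] for t in taxa])
    n = len(taxa)
    k_py = min(max(int(round(cfg.prevalence_py * n)), 1), n - 2)
    k_pd = min(max(int(round(cfg.prevalence_pd * n)), 1), n - 1 - k_py)
    order = np.argsort(vals)
    py = np.zeros(n, dtype=int)
    pd_ = np.zeros(n, dtype=int)
    py[order[-k_py:]] = 1
    pd_[order[:k_pd]] = 1

    if cfg.residual_sd > 0:
        depth = float(np.mean(np.diag(cov.matrix)))
        resid = gen_bm_traits(cov, cfg.residual_sd**2 / depth, 0.0, cfg.residual_lambda, rng)
        eps = np.array([resid[t] for t in taxa])
    else:
        eps = np.zeros(n)

    log10_p50 = (
        cfg.intercept
        + cfg.effect_non_endospermic * np.array([non_endo[t] for t in taxa])
        + cfg.effect_py * py
        + cfg.effect_pd * pd_
        + eps
    )
    p50 = 10.0**log10_p50

    matrix = pd.DataFrame(
        {
            "log10_p50": log10_p50,
            "non_endospermic": [non_endo[t] for t in taxa],
            "py": py,
            "pd": pd_,
        },
        index=pd.Index(taxa, name="species"),
    )

    timecourses = []
    sigmas = {}
    for sp, target in zip(taxa, p50):
        sigma = solve_sigma_for_p50(float(target), cfg.Ki)
        sigmas[sp] = sigma
        timecourses.append(
            gen_timecourse(cfg.Ki, sigma, cfg.schedule, cfg.n_tested, rng, species_id=sp)
        )

    truth = {
        "intercept": cfg.intercept,
        "effects": {
            "non_endospermic": cfg.effect_non_endospermic,
            "py": cfg.effect_py,
            "pd": cfg.effect_pd,
        },
        "residual_sd": cfg.residual_sd,
        "residual_lambda": cfg.residual_lambda,
        "Ki": cfg.Ki,
        "sigma": sigmas,
        "p50": dict(zip(taxa, map(float, p50))),
    }
    return SimulatedStudy(tree=tree, matrix=matrix, timecourses=timecourses, truth=truth)


def timecourses_to_frame(timecourses: Sequence[GerminationTimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in timecourses:
        for t, n, r in zip(tc.times, tc.n_tested, tc.n_germinated):
            rows.append({"species": tc.species_id, "time_days": t,
                         "n_tested": n, "n_germinated": r})
    return pd.DataFrame(rows)
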