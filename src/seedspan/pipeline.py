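"""End-to-end orchestration: viability -> tree -> signal -> models -> groups.

``run_pipeline`` consumes a config dict (usually parsed from YAML), runs
the requested stages in their fixed order and writes machine-readable
reports (fits.csv, tree.nwk, signal.json, models.json, groups.json) plus
a MANIFEST recording seeds, versions and dropped-row accounting. A stage
failure aborts with a stage-named error; partial outputs are retained and
the MANIFEST flags incompleteness.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import seedspan
from seedspan.errors import StageError
from seedspan.models import (
    DEFAULT_CANDIDATES,
    fit_candidates,
    group_summary,
    model_average,
    one_way_anova,
    tukey_hsd,
)
from seedspan.signal import blomberg_k, fritz_purvis_d, pagel_lambda
from seedspan.trait_table import (
    build_analysis_matrix,
    load_study_fixture,
    load_trait_table,
    packaged_node_ages_path,
)
from seedspan.tree import (
    bladj_adjust,
    build_taxonomy_tree,
    load_node_ages,
    phylo_covariance,
    write_newick,
)
from seedspan.viability import fit_auto, fit_logistic, fit_probit, fits_to_frame, load_timecourses

logger = logging.getLogger(__name__)

STAGE_ORDER = ("viability", "tree", "signal", "models", "groups")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages; return the MANIFEST dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", []))
    if not stages:
        logger.warning("empty stage list: nothing to do")
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise StageError(f"unknown stage(s) {unknown}; valid: {STAGE_ORDER}")
    stages = [s for s in STAGE_ORDER if s in stages]
    seed = int(config.get("seed", 1))
    n_perm = int(config.get("n_perm", 1000))

    manifest: dict = {
        "seed": seed,
        "n_perm": n_perm,
        "stages": stages,
        "versions": {"seedspan": seedspan.__version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "outputs": {},
        "complete": False,
    }
    current = None
    try:
        table = None
        if config.get("traits"):
            table = load_trait_table(config["traits"])
        elif config.get("use_fixture", True):
            table = load_study_fixture()

        if "viability" in stages:
            current = "viability"
            tcs = load_timecourses(config["timecourses"])
            model = config.get("viability_model", "probit")
            fitter = {"probit": fit_probit, "logistic": fit_logistic, "auto": fit_auto}[model]
            fits = [fitter(tc) for tc in tcs]
            df = fits_to_frame(fits)
            df.to_csv(out / "fits.csv", index=False)
            manifest["outputs"]["fits.csv"] = len(df)

        tree = None
        if "tree" in stages or "signal" in stages or "models" in stages:
            current = "tree"
            tree = build_taxonomy_tree(table.records)
            ages = load_node_ages(config.get("node_ages", packaged_node_ages_path()))
            tree = bladj_adjust(tree, ages)
            write_newick(tree, out / "tree.nwk")
            manifest["outputs"]["tree.nwk"] = len(tree.leaf_nodes())

        matrix = build_analysis_matrix(table) if table is not None else None

        if "signal" in stages:
            current = "signal"
            cov = phylo_covariance(tree)
            y = matrix["log10_p50"].to_dict()
            results = {
                "log10_p50": {
                    "lambda": pagel_lambda(cov, y).to_dict(),
                    "K": blomberg_k(cov, y, n_perm=n_perm, seed=seed).to_dict(),
                },
            }
            for name in ("non_endospermic", "py", "pd"):
                results[name] = {
                    "D": fritz_purvis_d(tree, matrix[name].astype(float).to_dict(),
                                        n_sim=n_perm, seed=seed).to_dict()
                }
            _write_json(results, out / "signal.json")
            manifest["outputs"]["signal.json"] = list(results)

        if "models" in stages:
            current = "models"
            candidates = config.get("candidates", [list(c) for c in DEFAULT_CANDIDATES])
            # restrict the candidate set to predictors actually available
            avail = set(matrix.columns[matrix.notna().all()])
            usable = [c for c in candidates if set(c) <= avail]
            skipped = [c for c in candidates if set(c) - avail]
            if skipped:
                logger.warning("skipping candidates with unavailable predictors: %s", skipped)
            report = {}
            fits = fit_candidates(matrix, usable)
            avg = model_average(fits)
            report["non_phylogenetic"] = {
                "models": [f.to_row() for f in fits],
                "averaged": avg.to_rows(),
            }
            if config.get("phylogenetic", True):
                cov = phylo_covariance(tree)
                pfits = fit_candidates(matrix, usable, cov=cov)
                pavg = model_average(pfits)
                report["phylogenetic"] = {
                    "models": [f.to_row() for f in pfits],
                    "averaged": pavg.to_rows(),
                    "lambda_weight_averaged": pavg.lambda_avg,
                }
            _write_json(report, out / "models.json")
            manifest["outputs"]["models.json"] = list(report)

        if "groups" in stages:
            current = "groups"
            _write_json(study_group_report(table), out / "groups.json")
            manifest["outputs"]["groups.json"] = True

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        _write_json(manifest, out / "MANIFEST.json")
        raise StageError(f"stage {current!r} failed: {exc}") from exc
    _write_json(manifest, out / "MANIFEST.json")
    return manifest


def study_group_report(table=None) -> dict:
    """Group means, ANOVAs and Tukey comparisons on the (fixture) table.

    Means/SEs are reported on the raw day scale; ANOVAs and Tukey run on
    log10 p50.
    """
    import math

    if table is None:
        table = load_study_fixture()
    df = table.to_frame()
    p50 = df["p50"].to_numpy(float)
    log_p50 = np.log10(p50)
    endo = df["endosperm"].to_numpy()
    dorm = df["dormancy"].to_numpy()
    order = df["order"].to_numpy()

    report: dict = {"n": len(df)}
    report["by_endosperm"] = group_summary(p50, endo)
    report["by_order"] = group_summary(p50, order)
    no_py = dorm != "PY"
    report["by_endosperm_excl_py"] = group_summary(p50[no_py], endo[no_py])
    report["anova"] = {
        "endosperm": one_way_anova(log_p50, endo).__dict__,
        "endosperm_excl_py": one_way_anova(log_p50[no_py], endo[no_py]).__dict__,
        "dormancy_within_non_endospermic": one_way_anova(
            log_p50[endo == "N"], dorm[endo == "N"]
        ).__dict__,
        "dormancy_within_endospermic": one_way_anova(
            log_p50[endo == "E"], dorm[endo == "E"]
        ).__dict__,
    }
    mask = endo == "N"
    report["tukey_dormancy_within_non_endospermic"] = {
        f"{a} vs {b}": p for (a, b), p in tukey_hsd(log_p50[mask], dorm[mask]).items()
    }
    report["p50_range"] = {"min": float(p50.min()), "max": float(p50.max())}
    return report
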