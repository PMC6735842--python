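"""Basic rendering: survival curves and p50 box plots. Nothing fancy."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from seedspan.viability import GerminationTimeCourse, ViabilityFit, predict_survival_curve


def plot_survival_curve(fit: ViabilityFit, tc: Optional[GerminationTimeCourse] = None,
                        path: str | Path = "survival.png"):
    fig, ax = plt.subplots(figsize=(5, 4))
    t_max = max(tc.times) if tc is not None else fit.p50_days * 2.5
    tt = np.linspace(0, t_max * 1.05, 200)
    ax.plot(tt, predict_survival_curve(fit, tt), "--", color="C0", label=fit.model)
    if tc is not None:
        ax.plot(tc.times, 100 * tc.fractions, "o", color="k", ms=4, label="observed")
    ax.axvline(fit.p50_days, color="C3", lw=0.8)
    ax.set_xlabel("ageing time (days)")
    ax.set_ylabel("germination (%)")
    ax.set_title(fit.species_id)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_p50_boxplot(values: Sequence[float], groups: Sequence[str],
                     path: str | Path = "p50_box.png"):
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    data = [values[groups == g] for g in labels]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("p50 (days)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
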