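"""Minimal reporting figure: per-class mean waveforms with +/- 1 SD bands."""

from __future__ import annotations

from typing import Dict, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cycle import CYCLE_AXIS, GaitTrial

_DEFAULT_PANELS = (
    "ankle_power",
    "hip_adduction_angle",
    "knee_flexion_angle",
    "knee_varus_angle",
)


def plot_group_means(
    trials: Sequence[GaitTrial],
    classes: pd.Series,
    out_path,
    parameters: Sequence[str] = _DEFAULT_PANELS,
) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    colors = {"mild": "tab:green", "moderate": "tab:orange", "severe": "tab:red"}
    stacked: Dict[str, np.ndarray] = {
        p: np.vstack([t.waveforms[p].values for t in trials]) for p in parameters
    }
    labels = np.asarray([classes.loc[t.subject_id] for t in trials])
    for ax, param in zip(axes.ravel(), parameters):
        X = stacked[param]
        for cls, color in colors.items():
            sub = X[labels == cls]
            if not sub.size:
                continue
            mean, sd = sub.mean(axis=0), sub.std(axis=0)
            ax.plot(CYCLE_AXIS, mean, color=color, label=cls)
            ax.fill_between(CYCLE_AXIS, mean - sd, mean + sd, color=color, alpha=0.15)
        ax.set_title(param.replace("_", " "))
        ax.set_xlabel("% gait cycle")
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
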