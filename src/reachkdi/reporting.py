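"""Descriptive summaries and KD-trajectory plots.

The KDI table is the hand-off point for inferential modelling (mixed
models etc. in any stats package); here we provide per-group medians,
means and percentile-bootstrap confidence intervals, plus per-trial
KD-trajectory plots with the reference (zero line) overlay.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)


def summarize(
    kdi_table: pd.DataFrame,
    group_by: list[str] | str = "condition",
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-group median, mean and percentile-bootstrap CI of KDI.

    Deterministic given ``seed``; bootstrap resamples trials within
    each group.
    """
    if kdi_table is None or len(kdi_table) == 0:
        raise SchemaError("cannot summarize an empty KDI table")
    if isinstance(group_by, str):
        group_by = [group_by]
    missing = [c for c in group_by if c not in kdi_table.columns]
    if missing:
        raise SchemaError(f"unknown group column(s): {missing}")
    if "kdi" not in kdi_table.columns:
        raise SchemaError("KDI table lacks a 'kdi' column")

    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    rows = []
    for keys, grp in kdi_table.groupby(group_by, sort=True):
        values = grp["kdi"].to_numpy(dtype=float)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = rng.choice(values, size=len(values), replace=True).mean()
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        if not isinstance(keys, tuple):
            keys = (keys,)
        rows.append(
            dict(zip(group_by, keys))
            | {
                "n_trials": len(values),
                "median_kdi": float(np.median(values)),
                "mean_kdi": float(values.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def plot_kd_trajectories(
    trajectories: pd.DataFrame,
    out_path: str | os.PathLike,
    by: str = "animal_id",
) -> bool:
    """One panel per group of KD-trajectories (distance to reference vs
    % trial duration).  Plot failures are warnings, never errors."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        groups = list(trajectories.groupby(by, sort=True))
        ncols = min(len(groups), 3) or 1
        nrows = (len(groups) + ncols - 1) // ncols
        fig, axes = plt.subplots(
            nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False
        )
        for ax, (key, grp) in zip(axes.ravel(), groups):
            for _, trial in grp.groupby("trial_id"):
                ax.plot(trial["n"], trial["d"], alpha=0.5, lw=0.8)
            ax.axhline(0.0, color="black", lw=1.0)
            ax.set_title(str(key))
            ax.set_xlabel("% trial duration")
            ax.set_ylabel("distance to reference")
        for ax in axes.ravel()[len(groups):]:
            ax.set_visible(False)
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return True
    except Exception as exc:  # plotting must never fail the pipeline
        logger.warning("KD-trajectory plot failed: %s", exc)
        return False
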