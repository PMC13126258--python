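"""Report generation: trajectory, outcome-summary and mutation-profile files."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationOutcome
from .genome import GenePanel, default_panel
from .learning import D_MAX_DEFAULT, OutcomePair, mse_loss

__all__ = ["report_run", "outcome_summary", "tumor_decline_onset", "post_treatment_peak"]


def tumor_decline_onset(trajectory: pd.DataFrame, start: int, frac: float = 0.5) -> int:
    """Step at which the tumor burden first falls to ``frac`` of its value at
    the treatment start step (the onset of marked decline); the final
    recorded step if it never does."""
    post = trajectory[trajectory["step"] >= start].reset_index(drop=True)
    if post.empty:
        raise ValueError("trajectory ends before the treatment start")
    ref = post["tumor"].iloc[0]
    below = post[post["tumor"] <= ref * frac]
    return int(below["step"].iloc[0]) if len(below) else int(post["step"].iloc[-1])


def post_treatment_peak(trajectory: pd.DataFrame, kind: str, start: int) -> int:
    """Maximum count of one agent kind over the post-treatment window."""
    post = trajectory[trajectory["step"] >= start]
    if post.empty:
        raise ValueError("trajectory ends before the treatment start")
    return int(post[kind].max())


def outcome_summary(outcomes: Sequence[SimulationOutcome], os_true: int | None = None,
                    death_true: bool | None = None,
                    d_max: int = D_MAX_DEFAULT) -> Dict[str, float]:
    """Seed-aggregate outcome statistics for one patient.

    Reports mean OS and death fraction across seeds; when the observed
    outcome is supplied, also the mean and standard deviation of the
    saturated squared error.
    """
    if not outcomes:
        raise ValueError("need at least one outcome")
    os_hat = np.array([o.os for o in outcomes], dtype=float)
    death = np.array([not o.survived for o in outcomes], dtype=float)
    row: Dict[str, float] = {
        "n_seeds": len(outcomes),
        "avg_os": float(os_hat.mean()),
        "avg_death": float(death.mean()),
    }
    if os_true is not None and death_true is not None:
        losses = np.array([
            mse_loss(OutcomePair(os_hat=o.os, survived_hat=o.survived,
                                 os=os_true, survived=not death_true), d_max)
            for o in outcomes
        ])
        row["avg_mse"] = float(losses.mean())
        row["std_mse"] = float(losses.std())
    return row


def report_run(outcomes: Sequence[SimulationOutcome], out_dir: str | Path,
               patient_id: str = "patient", os_true: int | None = None,
               death_true: bool | None = None, d_max: int = D_MAX_DEFAULT,
               panel: GenePanel | None = None) -> List[str]:
    """Write per-seed trajectories, a mean+/-std trajectory, the outcome
    summary row, and the per-gene mutation profile. Returns written paths."""
    if not outcomes:
        raise ValueError("need at least one outcome")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = panel or default_panel()
    written: List[str] = []

    for i, o in enumerate(outcomes):
        p = out / f"{patient_id}_trajectory_seed{i}.csv"
        o.trajectory.to_csv(p, index=False)
        written.append(str(p))

    merged = pd.concat([o.trajectory.set_index("step") for o in outcomes],
                       keys=range(len(outcomes)), names=["seed"])
    stats = merged.groupby("step").agg(["mean", "std"]).fillna(0.0)
    stats.columns = [f"{col}_{stat}" for col, stat in stats.columns]
    p = out / f"{patient_id}_trajectory_mean.csv"
    stats.reset_index().to_csv(p, index=False)
    written.append(str(p))

    summary = outcome_summary(outcomes, os_true, death_true, d_max)
    summary = {"patient": patient_id, **summary}
    p = out / f"{patient_id}_summary.csv"
    pd.DataFrame([summary]).to_csv(p, index=False)
    written.append(str(p))

    gene_means = pd.DataFrame([o.final_mutation_profile.per_gene_mean for o in outcomes])
    p = out / f"{patient_id}_mutation_profile.csv"
    gene_means.mean(axis=0).rename("mean_fraction").rename_axis("gene").reset_index() \
        .to_csv(p, index=False)
    written.append(str(p))
    return written
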