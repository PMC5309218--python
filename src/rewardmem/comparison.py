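"""AIC model comparison across the six candidate encoding models.

The winner is the model with minimal cohort-mean AIC; paired sign-flip tests
of the per-participant AIC differences against every competitor are reported
alongside but do not decide the label.  Ties are broken by fewer parameters,
then by the fixed model-name order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .design import SessionDesign
from .learning import DEFAULT_V0, value_trajectories
from .models import MODEL_ORDER, get_model
from .stats import paired_mc_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-model AIC summary plus pairwise tests against the best model."""

    table: pd.DataFrame  # model, k, mean_lle, sem_lle, mean_aic, sem_aic, p_vs_best
    best_model: str


def compare_models(
    fits: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ComparisonResult:
    """Aggregate per-participant fits and declare an AIC winner.

    ``fits`` is the tidy frame from :func:`rewardmem.fitting.fit_cohort`;
    every participant must be fitted under every model present.
    """
    models = [m for m in MODEL_ORDER if m in set(fits["model"])]
    if len(models) < 2:
        raise ValueError("need fits from at least two models to compare")
    participants = sorted(fits["participant_id"].unique())
    gaps = []
    for m in models:
        have = set(fits.loc[fits["model"] == m, "participant_id"])
        gaps.extend((p, m) for p in participants if p not in have)
    if gaps:
        raise ValueError(f"missing (participant, model) fits: {gaps}")

    wide = fits.pivot_table(index="participant_id", columns="model", values="aic")
    rows = []
    for m in models:
        sub = fits[fits["model"] == m]
        rows.append(
            {
                "model": m,
                "k": get_model(m).k,
                "mean_lle": sub["lle"].mean(),
                "sem_lle": sub["lle"].std(ddof=1) / np.sqrt(len(sub)),
                "mean_aic": sub["aic"].mean(),
                "sem_aic": sub["aic"].std(ddof=1) / np.sqrt(len(sub)),
            }
        )
    table = pd.DataFrame(rows)

    best_aic = table["mean_aic"].min()
    tied = table[np.isclose(table["mean_aic"], best_aic, rtol=0, atol=1e-12)]
    if len(tied) > 1:
        order = {m: i for i, m in enumerate(MODEL_ORDER)}
        tied = tied.assign(_ord=tied["model"].map(order)).sort_values(["k", "_ord"])
        best_model = str(tied.iloc[0]["model"])
        logger.info(
            "mean-AIC tie between %s; broken by fewer parameters then name order",
            list(tied["model"]),
        )
    else:
        best_model = str(table.loc[table["mean_aic"].idxmin(), "model"])

    pvals = []
    for i, m in enumerate(models):
        if m == best_model:
            pvals.append(np.nan)
        else:
            res = paired_mc_test(
                wide[best_model].loc[participants],
                wide[m].loc[participants],
                n_perm=n_perm,
                seed=seed + i,
            )
            pvals.append(res.p_value)
    table["p_vs_best"] = pvals
    return ComparisonResult(table=table, best_model=best_model)


def aggregate_final_values(
    fits: pd.DataFrame,
    designs: Mapping[str, SessionDesign],
    model: str = "pe_ev",
    v0: float = DEFAULT_V0,
) -> pd.DataFrame:
    """Cohort mean +/- SEM of the final expected value per anticipation level.

    Trajectories are recomputed under each participant's fitted learning rate
    for ``model``; a participant's two characters per level are averaged
    before pooling across the cohort.
    """
    sub = fits[fits["model"] == model]
    if sub.empty:
        raise ValueError(f"no fits for model {model!r}")
    per_part = []
    for row in sub.itertuples():
        design = designs[row.participant_id]
        trajs = value_trajectories(design, row.alpha, v0)
        levels = design.levels()
        finals: Dict[str, list] = {}
        for cid, traj in trajs.items():
            finals.setdefault(levels[cid], []).append(traj.v_final)
        for lvl, vals in finals.items():
            per_part.append(
                {
                    "participant_id": row.participant_id,
                    "level": lvl,
                    "v_final": float(np.mean(vals)),
                }
            )
    df = pd.DataFrame(per_part)
    return (
        df.groupby("level")["v_final"]
        .agg(
            mean_v_final="mean",
            sem_v_final=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
            n="size",
        )
        .reset_index()
    )
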