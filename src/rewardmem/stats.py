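"""Behavioral statistics: condition averaging, sign-flip Monte-Carlo tests,
character-level regression slopes, trait bias and rank correlations.

The permutation tests build the null by randomly sign-flipping per-participant
(paired) values, two-sided, with the add-one correction
p = (#{|perm| >= |obs|} + 1) / (n_perm + 1), which keeps p >= 1/(n_perm + 1)
and makes the test exact-in-expectation under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .models import get_model

DEFAULT_N_PERM = 10_000
DEFAULT_LEVEL_CODING: Mapping[str, float] = {"low": -1.0, "medium": 0.0, "high": 1.0}


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    sided: str = "two"


def _sign_flip_p(d: np.ndarray, n_perm: int, seed: int) -> PermutationResult:
    if d.size < 2:
        raise ValueError("need at least 2 paired observations")
    rng = np.random.default_rng(seed)
    obs = float(d.mean())
    signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
    null = (signs * d).mean(axis=1)
    p = (np.count_nonzero(np.abs(null) >= abs(obs)) + 1) / (n_perm + 1)
    return PermutationResult(
        statistic=obs, p_value=float(p), n_permutations=n_perm, seed=seed
    )


def paired_mc_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided sign-flip test of mean(a - b) = 0 over paired participants."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return _sign_flip_p(a - b, n_perm, seed)


def one_sample_mc_test(
    x: Sequence[float], n_perm: int = DEFAULT_N_PERM, seed: int = 0
) -> PermutationResult:
    """Two-sided sign-flip test of mean(x) = 0."""
    return _sign_flip_p(np.asarray(x, dtype=float), n_perm, seed)


def condition_means(
    trials: pd.DataFrame, factors: Sequence[str]
) -> pd.DataFrame:
    """Cohort mean +/- SEM of per-participant proportion correct per cell.

    Proportions are computed within participant first (the participant is the
    statistical unit), then averaged across the cohort.  Cells of the full
    factor product with no trials are kept as missing rows, never dropped.
    """
    missing = [f for f in factors if f not in trials.columns]
    if missing:
        raise KeyError(f"factors not in trial table: {missing}")
    per_part = (
        trials.groupby(["participant_id", *factors], observed=True)["correct"]
        .agg(proportion="mean", n_trials="size")
        .reset_index()
    )
    cells = (
        per_part.groupby(list(factors), observed=True)
        .agg(
            n_participants=("participant_id", "nunique"),
            n_trials=("n_trials", "sum"),
            proportion_correct=("proportion", "mean"),
            sem=("proportion", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
        )
        .reset_index()
    )
    # reindex to the full factor product so empty cells surface as NaN
    full = pd.MultiIndex.from_product(
        [sorted(trials[f].unique()) for f in factors], names=list(factors)
    ).to_frame(index=False)
    return full.merge(cells, on=list(factors), how="left")


def character_slopes(
    trials: pd.DataFrame,
    level_coding: Mapping[str, float] = DEFAULT_LEVEL_CODING,
) -> pd.DataFrame:
    """Per-participant OLS slope of memory on coded anticipation level.

    One slope per feedback type plus their mean (``pooled``); a feedback type
    missing a level yields a missing slope rather than a silent drop.
    """
    codes = dict(level_coding)
    rows = []
    for pid, grp in trials.groupby("participant_id"):
        row: Dict[str, float] = {"participant_id": pid}
        slopes = []
        for fb, name in ((1, "slope_positive"), (0, "slope_negative")):
            sub = grp[grp["feedback"] == fb]
            props = sub.groupby("level")["correct"].mean()
            if set(props.index) != set(codes):
                row[name] = np.nan
            else:
                x = np.array([codes[lvl] for lvl in props.index])
                row[name] = float(np.polyfit(x, props.to_numpy(), 1)[0])
            slopes.append(row[name])
        row["pooled"] = float(np.mean(slopes))
        rows.append(row)
    return pd.DataFrame(rows)


def scale_factor_sign_tests(
    fits: pd.DataFrame,
    model: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> Dict[str, PermutationResult]:
    """One-sample sign-flip test against 0 for each fitted free scale factor."""
    spec = get_model(model)
    sub = fits[fits["model"] == model]
    if sub.empty:
        raise ValueError(f"no fits for model {model!r}")
    out = {}
    for i, term in enumerate(t for t in spec.free_scale_terms if t != "c0"):
        out[term] = one_sample_mc_test(
            sub[term].to_numpy(), n_perm=n_perm, seed=seed + i
        )
    return out


def sensitivity_bias(
    sr: Sequence[float], sp: Sequence[float]
) -> np.ndarray:
    """Sensitivity bias z(SR) - z(SP), z-scored within the cohort (ddof=1)."""
    sr = np.asarray(sr, dtype=float)
    sp = np.asarray(sp, dtype=float)
    if sr.size != sp.size or sr.size < 2:
        raise ValueError("need >= 2 participants with both SR and SP")
    ssr, ssp = sr.std(ddof=1), sp.std(ddof=1)
    if ssr == 0 or ssp == 0:
        raise ValueError("zero variance in SR or SP; bias undefined")
    return (sr - sr.mean()) / ssr - (sp - sp.mean()) / ssp


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal lengths >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; rank correlation undefined")
    return float(scipy.stats.spearmanr(x, y).statistic)


def cohort_trials_frame(records) -> pd.DataFrame:
    """Tidy per-trial table for a simulated cohort.

    Columns: design columns plus participant_id, V_before, delta, p_encoding,
    test_correct (also exposed as ``correct``) and confidence.  p_encoding is
    generator bookkeeping and is never an input to fitting.
    """
    frames = []
    for rec in records:
        f = rec.design.to_frame()
        f.insert(0, "participant_id", rec.participant_id)
        f["V_before"] = rec.v_before
        f["delta"] = rec.delta
        f["p_encoding"] = rec.p_memory
        f["test_correct"] = rec.y
        f["confidence"] = rec.confidence if rec.confidence is not None else pd.NA
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["correct"] = out["test_correct"]
    return out
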