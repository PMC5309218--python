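"""Maximum-likelihood fitting of the encoding models.

Fitting is per participant and per model, minimizing the negative
log-likelihood (LLE) of the binary test outcomes y(t) under the logistic
encoding probability:

    LLE = - sum_t [ y(t) * log p(t) + (1 - y(t)) * log(1 - p(t)) ]

in two stages: an exhaustive grid over the bounded parameter space (scale
factors in [-2, 2], alpha in [0, 1]), then a bounded Nelder-Mead refinement
in a box around the grid optimum.  Model fits are compared by
AIC = 2k + 2*LLE.

The grid is evaluated vectorized via the identity
LLE = sum_t softplus(-R_t) + sum_t (1 - y_t) * R_t, with R linear in the
scale factors for fixed alpha.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import SessionDesign
from .learning import DEFAULT_V0, trial_signals
from .models import (
    ALPHA_BOUNDS,
    SCALE_BOUNDS,
    ModelSpec,
    Params,
    encoding_probability,
    get_model,
    reward_signal,
)

logger = logging.getLogger(__name__)


def negative_log_likelihood(y: Sequence[float], p: Sequence[float]) -> float:
    """Bernoulli negative log-likelihood of outcomes ``y`` under ``p``.

    ``p`` must lie strictly inside (0, 1); under the bounded parameter space
    |R| <= 6 this always holds, so a boundary value signals misuse.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("y must be binary")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the two-stage fit.

    ``step_scale``/``step_alpha`` set the grid resolution; the refinement box
    radius defaults to one grid step.  ``max_grid_points`` rejects grids that
    would be prohibitively large (the literal 0.01 grid over four parameters
    has ~6.5e9 points).  ``grid_dtype`` controls the vectorized grid pass;
    float32 is ~3x faster and any rounding is absorbed by the float64
    refinement stage.
    """

    step_scale: float = 0.1
    step_alpha: float = 0.05
    v0: float = DEFAULT_V0
    simplex_radius: float | None = None  # default: max(step_scale, step_alpha)
    max_grid_points: int = 20_000_000
    simplex_fatol: float = 1e-8
    simplex_maxfev: int = 2000
    grid_dtype: str = "float32"

    @property
    def radius(self) -> float:
        if self.simplex_radius is not None:
            return self.simplex_radius
        return max(self.step_scale, self.step_alpha)


@dataclass(frozen=True)
class FitResult:
    """MLE of one model for one participant's session."""

    participant_id: str
    model: str
    params: Params
    lle: float
    k: int
    aic: float
    grid_lle: float
    n_trials: int


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def model_nll(
    model: ModelSpec,
    params: Params,
    design: SessionDesign,
    y: np.ndarray,
    v0: float = DEFAULT_V0,
) -> float:
    """Float64 LLE of one parameter vector (reference path for all stages)."""
    if model.needs_alpha:
        V, delta = trial_signals(design, params.alpha, v0)
    else:
        V = np.full(design.n_trials, v0)
        delta = np.zeros(design.n_trials)
    R = reward_signal(model, params, V, delta)
    p = encoding_probability(R)
    return negative_log_likelihood(y, p)


def _design_matrix(
    model: ModelSpec, design: SessionDesign, alpha: float | None, v0: float
) -> np.ndarray:
    """Columns of the linear predictor for the model's free scale terms."""
    n = design.n_trials
    if model.needs_alpha:
        V, delta = trial_signals(design, float(alpha), v0)
    else:
        V, delta = np.full(n, v0), np.zeros(n)
    cols = {
        "c0": np.ones(n),
        "c_delta": delta,
        "c_absdelta": np.abs(delta),
        "c_v": V,
    }
    return np.column_stack([cols[t] for t in model.free_scale_terms])


def _scale_grid(model: ModelSpec, step: float) -> np.ndarray:
    ax = _axis(*SCALE_BOUNDS, step)
    axes = [ax] * len(model.free_scale_terms)
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def grid_search(
    model: ModelSpec | str,
    design: SessionDesign,
    y: Sequence[float],
    options: FitOptions = FitOptions(),
) -> Tuple[Params, float]:
    """Exhaustive grid search over the bounded parameter space.

    Returns the grid point with minimal LLE (float64 re-evaluated) and that
    LLE.  Deterministic: ties are broken by the first minimum encountered,
    iterating alpha ascending and the scale factors lexicographically.
    """
    if isinstance(model, str):
        model = get_model(model)
    y = np.asarray(y, dtype=float)
    if y.size != design.n_trials:
        raise ValueError("y must have one entry per design trial")
    if options.step_scale <= 0 or options.step_alpha <= 0:
        raise ValueError("grid steps must be positive")

    alphas = _axis(*ALPHA_BOUNDS, options.step_alpha) if model.needs_alpha else [None]
    G = _scale_grid(model, options.step_scale)
    n_points = G.shape[0] * len(alphas)
    if n_points > options.max_grid_points:
        raise ValueError(
            f"grid for model {model.name!r} has {n_points} points, exceeding "
            f"the budget of {options.max_grid_points}; use coarser steps "
            f"(defaults: step_scale=0.1, step_alpha=0.05)"
        )

    dtype = np.dtype(options.grid_dtype)
    Gt = np.ascontiguousarray(G, dtype=dtype)
    yv = y.astype(dtype)
    best_nll = np.inf
    best_scale = None
    best_alpha = None
    for alpha in alphas:
        X = _design_matrix(model, design, alpha, options.v0).astype(dtype)
        R = Gt @ X.T  # (n_grid, n_trials)
        # softplus(-R) summed over trials, via log1p(exp(-|R|)) + max(-R, 0)
        sp = np.abs(R)
        np.negative(sp, out=sp)
        np.exp(sp, out=sp)
        np.log1p(sp, out=sp)
        nll = sp.sum(axis=1) + np.maximum(-R, 0.0).sum(axis=1) + R @ (1.0 - yv)
        i = int(np.argmin(nll))
        if nll[i] < best_nll:
            best_nll = float(nll[i])
            best_scale = G[i]
            best_alpha = alpha

    kw = dict(zip(model.free_scale_terms, (float(v) for v in best_scale)))
    if model.needs_alpha:
        kw["alpha"] = float(best_alpha)
    params = Params(**kw)
    grid_lle = model_nll(model, params, design, y, options.v0)
    return params, grid_lle


def _free_fields(model: ModelSpec) -> List[str]:
    fields = list(model.free_scale_terms)
    if model.needs_alpha:
        fields.append("alpha")
    return fields


def _bounds_for(fields: Iterable[str]) -> List[Tuple[float, float]]:
    return [ALPHA_BOUNDS if f == "alpha" else SCALE_BOUNDS for f in fields]


def refine_simplex(
    model: ModelSpec | str,
    design: SessionDesign,
    y: Sequence[float],
    start: Params,
    radius: float,
    options: FitOptions = FitOptions(),
) -> Params:
    """Nelder-Mead refinement within [start - radius, start + radius].

    The box is intersected with the global bounds and enforced by clipping
    candidate vertices.  Returns parameters with LLE <= LLE(start); if the
    simplex fails to improve, the start point is returned (with a warning on
    non-convergence).
    """
    if isinstance(model, str):
        model = get_model(model)
    y = np.asarray(y, dtype=float)
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return start

    fields = _free_fields(model)
    x0 = np.array([getattr(start, f) for f in fields])
    glb = np.array(_bounds_for(fields))
    lo = np.maximum(x0 - radius, glb[:, 0])
    hi = np.minimum(x0 + radius, glb[:, 1])

    def to_params(x: np.ndarray) -> Params:
        return Params(**dict(zip(fields, np.clip(x, lo, hi))))

    def objective(x: np.ndarray) -> float:
        return model_nll(model, to_params(x), design, y, options.v0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NM's own maxfev warning
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "fatol": options.simplex_fatol,
                "xatol": 1e-8,
                "maxfev": options.simplex_maxfev,
            },
        )
    if not res.success:
        logger.warning(
            "simplex refinement did not converge for model %s; "
            "keeping best evaluated point",
            model.name,
        )
    refined = to_params(res.x)
    start_nll = model_nll(model, start, design, y, options.v0)
    if model_nll(model, refined, design, y, options.v0) <= start_nll:
        return refined
    return start


def fit_participant(
    participant_id: str,
    model: ModelSpec | str,
    design: SessionDesign,
    y: Sequence[float],
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Two-stage MLE (grid then simplex) of one model for one participant."""
    if isinstance(model, str):
        model = get_model(model)
    y = np.asarray(y, dtype=float)
    start, grid_lle = grid_search(model, design, y, options)
    params = refine_simplex(model, design, y, start, options.radius, options)
    lle = model_nll(model, params, design, y, options.v0)
    return FitResult(
        participant_id=participant_id,
        model=model.name,
        params=params,
        lle=lle,
        k=model.k,
        aic=2 * model.k + 2 * lle,
        grid_lle=grid_lle,
        n_trials=int(y.size),
    )


def fit_cohort(
    records: Sequence,
    models: Sequence[str],
    options: FitOptions = FitOptions(),
) -> pd.DataFrame:
    """Fit each model to each participant record; tidy frame of results.

    ``records`` need ``participant_id``, ``design`` and ``y`` attributes
    (e.g. :class:`rewardmem.synthetic.ParticipantRecord`).
    """
    rows = []
    for rec, name in itertools.product(records, models):
        fr = fit_participant(rec.participant_id, name, rec.design, rec.y, options)
        row = {
            "participant_id": fr.participant_id,
            "session_id": rec.design.session_id,
            "delay": rec.design.delay,
            "model": fr.model,
        }
        row.update(fr.params.as_dict())
        row.update(
            lle=fr.lle,
            k=fr.k,
            aic=fr.aic,
            grid_lle=fr.grid_lle,
            n_trials=fr.n_trials,
            grid_step_scale=options.step_scale,
            grid_step_alpha=options.step_alpha,
        )
        rows.append(row)
    return pd.DataFrame(rows)
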