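"""Candidate encoding models linking reward signals to memory formation.

Each model defines a per-trial reward signal

    R(t) = C0 + C_delta * delta(t) + C_absdelta * |delta(t)| + C_V * V(t)

with a subset of the scale factors free, and maps it to the probability of
successfully encoding that trial's character-object association through a
logistic function  p = 1 / (1 + exp(-R)).  Six variants are compared:

=============  ==========================================  ==
name           reward terms                                k
=============  ==========================================  ==
baseline       none (constant C0)                          1
pe             signed prediction error (C_delta)           3
abs_pe         unsigned prediction error (C_absdelta)      3
ev             expected value (C_V)                        3
pe_ev          signed PE + expected value                  4
abs_pe_ev      unsigned PE + expected value                4
=============  ==========================================  ==

k counts the free parameters: C0 always, each free scale factor, and the
learning rate alpha whenever any value/PE term is present (alpha shapes the
V and delta trajectories entering R).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy.special import expit

#: bounds of the scale factors C_x and of the learning rate alpha
SCALE_BOUNDS: Tuple[float, float] = (-2.0, 2.0)
ALPHA_BOUNDS: Tuple[float, float] = (0.0, 1.0)

#: scale-factor field names in canonical order
SCALE_TERMS: Tuple[str, ...] = ("c0", "c_delta", "c_absdelta", "c_v")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate encoding model.

    Parameters
    ----------
    name
        Short identifier (``baseline``, ``pe``, ``abs_pe``, ``ev``,
        ``pe_ev``, ``abs_pe_ev``).
    uses
        The free scale-factor fields, subset of :data:`SCALE_TERMS`.
    needs_alpha
        Whether the model depends on the learning rate (any PE/value term).
    k
        Number of free parameters entering the AIC penalty.
    """

    name: str
    uses: frozenset = field(default_factory=frozenset)
    needs_alpha: bool = False
    k: int = 1

    @property
    def free_scale_terms(self) -> Tuple[str, ...]:
        return tuple(t for t in SCALE_TERMS if t in self.uses)


def _spec(name: str, *terms: str) -> ModelSpec:
    uses = frozenset(("c0",) + terms)
    needs_alpha = bool(terms)
    return ModelSpec(name=name, uses=uses, needs_alpha=needs_alpha,
                     k=len(uses) + int(needs_alpha))


#: registry of the six candidate models, in canonical comparison order
MODELS: Dict[str, ModelSpec] = {
    m.name: m
    for m in (
        _spec("baseline"),
        _spec("pe", "c_delta"),
        _spec("abs_pe", "c_absdelta"),
        _spec("ev", "c_v"),
        _spec("pe_ev", "c_delta", "c_v"),
        _spec("abs_pe_ev", "c_absdelta", "c_v"),
    )
}

MODEL_ORDER: Tuple[str, ...] = tuple(MODELS)


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from {', '.join(MODELS)}"
        ) from None


@dataclass
class Params:
    """Parameter vector for any of the six models.

    Scale factors are bounded in [-2, 2], alpha in [0, 1].  Fields not used
    by a model are fixed at 0 so every model shares one evaluation path.
    """

    c0: float = 0.0
    c_delta: float = 0.0
    c_absdelta: float = 0.0
    c_v: float = 0.0
    alpha: float = 0.0

    def as_dict(self) -> Dict[str, float]:
        return {
            "c0": self.c0,
            "c_delta": self.c_delta,
            "c_absdelta": self.c_absdelta,
            "c_v": self.c_v,
            "alpha": self.alpha,
        }

    def validate(self, model: ModelSpec) -> None:
        """Check bounds and that unused terms are exactly zero."""
        lo, hi = SCALE_BOUNDS
        d = self.as_dict()
        for term in SCALE_TERMS:
            v = d[term]
            if term in model.uses:
                if not (lo <= v <= hi):
                    raise ValueError(f"{term}={v} outside bounds [{lo}, {hi}]")
            elif v != 0.0:
                raise ValueError(
                    f"{term}={v} must be 0 for model {model.name!r}"
                )
        if model.needs_alpha:
            if not (ALPHA_BOUNDS[0] <= self.alpha <= ALPHA_BOUNDS[1]):
                raise ValueError(f"alpha={self.alpha} outside [0, 1]")

    def replace(self, **kw) -> "Params":
        return replace(self, **kw)


def reward_signal(model: ModelSpec, params: Params, V, delta):
    """Per-trial reward signal R(t) for one model.

    ``V`` and ``delta`` may be scalars or aligned arrays; the pre-update
    expected value and that trial's own prediction error are used, i.e. both
    are indexed at the current trial.
    """
    params.validate(model)
    V = np.asarray(V, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(V < 0) or np.any(V > 1):
        raise ValueError("V must lie in [0, 1]")
    if np.any(np.abs(delta) > 1):
        raise ValueError("delta must lie in [-1, 1]")
    R = (
        params.c0
        + params.c_delta * delta
        + params.c_absdelta * np.abs(delta)
        + params.c_v * V
    )
    return R if R.ndim else float(R)


def encoding_probability(R):
    """Logistic encoding probability p = 1 / (1 + exp(-R))."""
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("R must be finite")
    p = expit(R)
    return p if p.ndim else float(p)
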