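"""Delta-rule (Rescorla-Wagner / Q-learning) value updates per character.

Each character carries an expected value V in [0, 1], initialized at V0 and
updated after every feedback r in {0, 1}:

    delta(t) = r(t) - V(t)          (prediction error)
    V(t+1)   = V(t) + alpha * delta(t)

With r binary and V0 in [0, 1], V stays in [0, 1] for any alpha in [0, 1].
Under constant feedback r the recursion has the closed form
V(t) = r + (V0 - r) * (1 - alpha)**t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .design import SessionDesign

DEFAULT_V0 = 0.5


def _check_unit(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name}={x} outside [0, 1]")


def prediction_error(V: float, r: int) -> float:
    """Signed prediction error delta = r - V."""
    _check_unit("V", V)
    if r not in (0, 1):
        raise ValueError("r must be 0 or 1")
    return float(r) - float(V)


def update_value(V: float, delta: float, alpha: float) -> float:
    """One delta-rule step V + alpha * delta."""
    _check_unit("alpha", alpha)
    return float(V) + float(alpha) * float(delta)


@dataclass(frozen=True)
class ValueTrajectory:
    """Pre-update values and prediction errors over one character's block."""

    character_id: str
    alpha: float
    v_before: np.ndarray  # V at each trial, prior to that trial's update
    delta: np.ndarray  # that trial's prediction error r - V

    @property
    def v_final(self) -> float:
        """Expected value after the last trial's update."""
        return float(self.v_before[-1] + self.alpha * self.delta[-1])


def value_trajectory(
    feedback: np.ndarray, alpha: float, v0: float = DEFAULT_V0
) -> Tuple[np.ndarray, np.ndarray]:
    """Iterate the delta rule over one feedback sequence.

    Returns ``(v_before, delta)`` aligned with ``feedback``: ``v_before[i]``
    is the value held when trial ``i``'s feedback arrives and ``delta[i]``
    the resulting prediction error.
    """
    _check_unit("alpha", alpha)
    _check_unit("v0", v0)
    feedback = np.asarray(feedback, dtype=float)
    n = feedback.size
    v_before = np.empty(n)
    delta = np.empty(n)
    v = float(v0)
    for i in range(n):
        v_before[i] = v
        delta[i] = feedback[i] - v
        v += alpha * delta[i]
    return v_before, delta


def value_trajectories(
    design: SessionDesign, alpha: float, v0: float = DEFAULT_V0
) -> Dict[str, ValueTrajectory]:
    """Independent trajectory per character, in session order."""
    out: Dict[str, ValueTrajectory] = {}
    for char in design.characters:
        fb = design.feedback_for(char.character_id)
        v_before, delta = value_trajectory(fb, alpha, v0)
        out[char.character_id] = ValueTrajectory(
            character_id=char.character_id,
            alpha=alpha,
            v_before=v_before,
            delta=delta,
        )
    return out


def trial_signals(
    design: SessionDesign, alpha: float, v0: float = DEFAULT_V0
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-trial (v_before, delta) aligned with ``design.trials``.

    Convenience for model evaluation: concatenates each character's
    trajectory back into session order.
    """
    trajs = value_trajectories(design, alpha, v0)
    n = design.n_trials
    V = np.empty(n)
    D = np.empty(n)
    pos: Dict[str, int] = {c.character_id: 0 for c in design.characters}
    for i, t in enumerate(design.trials):
        j = pos[t.character_id]
        V[i] = trajs[t.character_id].v_before[j]
        D[i] = trajs[t.character_id].delta[j]
        pos[t.character_id] = j + 1
    return V, D
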