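"""Independent brute-force oracle used by the optimizer-equivalence tests.

Deliberately naive: plain nested loops over every grid point, evaluating the
float64 likelihood one point at a time, sharing no code with the vectorized
grid search it checks.
"""

import itertools

import numpy as np

import rewardmem as rm
from rewardmem.design import CharacterSpec, SessionDesign, TrialSlot
from rewardmem.fitting import model_nll
from rewardmem.models import Params


def toy_design(feedback, session_id="toy"):
    """Single-character design with the given feedback sequence."""
    chars = (CharacterSpec("c1", "high", int(sum(feedback))),)
    trials = tuple(
        TrialSlot(i + 1, "c1", f"p{i:02d}", int(f)) for i, f in enumerate(feedback)
    )
    return SessionDesign(session_id, "20min", chars, trials)


def brute_force_grid(model_name, design, y, step_scale, step_alpha, v0=0.5):
    """Enumerate every grid point; return (argmin Params, min NLL)."""
    model = rm.get_model(model_name)
    scale_axis = np.round(np.arange(-2, 2 + 1e-9, step_scale), 10)
    alpha_axis = (
        np.round(np.arange(0, 1 + 1e-9, step_alpha), 10)
        if model.needs_alpha
        else [0.0]
    )
    best = (np.inf, None)
    for alpha in alpha_axis:
        for combo in itertools.product(scale_axis, repeat=len(model.free_scale_terms)):
            kw = dict(zip(model.free_scale_terms, combo))
            if model.needs_alpha:
                kw["alpha"] = float(alpha)
            params = Params(**kw)
            nll = model_nll(model, params, design, np.asarray(y, float), v0)
            if nll < best[0] - 1e-12:
                best = (nll, params)
    return best[1], best[0]
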