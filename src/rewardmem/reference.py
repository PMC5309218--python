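"""Published group-level estimates used as generative defaults and test anchors.

These are the cohort means and standard errors (n = 25) of the fitted model
parameters, LLE and AIC reported for the original behavioral cohort, one row
per model and test delay.  They serve two purposes: default generative
parameters for the synthetic cohorts, and exact anchors for the
AIC = 2k + 2*LLE identity.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .models import MODELS, Params

N_PARTICIPANTS = 25
N_WITH_TRAITS = 19

# (delay, model) -> dict with mean lle/aic and mean/sem of each free parameter
GROUP_ESTIMATES: Dict[Tuple[str, str], Dict[str, Dict[str, float]]] = {
    ("20min", "baseline"): {
        "mean": {"lle": 70.755, "aic": 143.510, "c0": 0.721},
        "sem": {"lle": 1.928, "aic": 3.856, "c0": 0.075},
    },
    ("20min", "pe"): {
        "mean": {"lle": 60.440, "aic": 126.881, "c0": 0.735, "c_delta": 0.369,
                 "alpha": 0.395},
        "sem": {"lle": 1.636, "aic": 3.272, "c0": 0.071, "c_delta": 0.158,
                "alpha": 0.077},
    },
    ("20min", "abs_pe"): {
        "mean": {"lle": 61.718, "aic": 129.436, "c0": 0.562, "c_absdelta": 0.503,
                 "alpha": 0.583},
        "sem": {"lle": 1.989, "aic": 3.979, "c0": 0.107, "c_absdelta": 0.166,
                "alpha": 0.074},
    },
    ("20min", "ev"): {
        "mean": {"lle": 61.593, "aic": 129.186, "c0": 0.584, "c_v": 0.501,
                 "alpha": 0.372},
        "sem": {"lle": 2.124, "aic": 4.247, "c0": 0.104, "c_v": 0.221,
                "alpha": 0.064},
    },
    ("20min", "pe_ev"): {
        "mean": {"lle": 57.828, "aic": 123.656, "c0": 0.350, "c_delta": 0.725,
                 "c_v": 1.156, "alpha": 0.329},
        "sem": {"lle": 1.978, "aic": 3.957, "c0": 0.132, "c_delta": 0.154,
                "c_v": 0.180, "alpha": 0.057},
    },
    ("20min", "abs_pe_ev"): {
        "mean": {"lle": 59.625, "aic": 127.250, "c0": 0.530, "c_absdelta": 0.361,
                 "c_v": 0.360, "alpha": 0.456},
        "sem": {"lle": 2.143, "aic": 4.287, "c0": 0.099, "c_absdelta": 0.212,
                "c_v": 0.239, "alpha": 0.075},
    },
    ("24h", "baseline"): {
        "mean": {"lle": 76.445, "aic": 154.889, "c0": 0.496},
        "sem": {"lle": 1.723, "aic": 3.447, "c0": 0.026},
    },
    ("24h", "pe"): {
        "mean": {"lle": 64.079, "aic": 134.159, "c0": 0.507, "c_delta": 0.215,
                 "alpha": 0.333},
        "sem": {"lle": 1.625, "aic": 3.250, "c0": 0.073, "c_delta": 0.171,
                "alpha": 0.068},
    },
    ("24h", "abs_pe"): {
        "mean": {"lle": 65.270, "aic": 136.539, "c0": 0.417, "c_absdelta": 0.292,
                 "alpha": 0.404},
        "sem": {"lle": 2.201, "aic": 4.401, "c0": 0.108, "c_absdelta": 0.202,
                "alpha": 0.085},
    },
    ("24h", "ev"): {
        "mean": {"lle": 64.267, "aic": 134.535, "c0": 0.402, "c_v": 0.268,
                 "alpha": 0.456},
        "sem": {"lle": 1.968, "aic": 3.937, "c0": 0.117, "c_v": 0.265,
                "alpha": 0.080},
    },
    ("24h", "pe_ev"): {
        "mean": {"lle": 61.165, "aic": 130.329, "c0": 0.223, "c_delta": 0.469,
                 "c_v": 0.729, "alpha": 0.312},
        "sem": {"lle": 1.985, "aic": 3.970, "c0": 0.123, "c_delta": 0.173,
                "c_v": 0.274, "alpha": 0.066},
    },
    ("24h", "abs_pe_ev"): {
        "mean": {"lle": 62.943, "aic": 133.887, "c0": 0.284, "c_absdelta": 0.327,
                 "c_v": 0.277, "alpha": 0.433},
        "sem": {"lle": 2.291, "aic": 4.582, "c0": 0.146, "c_absdelta": 0.199,
                "c_v": 0.257, "alpha": 0.078},
    },
}

_PARAM_FIELDS = ("c0", "c_delta", "c_absdelta", "c_v", "alpha")


def group_mean_params(model: str, delay: str = "20min") -> Params:
    """Published group-mean parameter vector for one model and delay."""
    est = GROUP_ESTIMATES[(delay, model)]["mean"]
    return Params(**{f: est.get(f, 0.0) for f in _PARAM_FIELDS})


def group_param_sems(model: str, delay: str = "20min") -> Dict[str, float]:
    """Standard errors of the free parameters (n = 25)."""
    sem = GROUP_ESTIMATES[(delay, model)]["sem"]
    m = MODELS[model]
    fields = list(m.free_scale_terms) + (["alpha"] if m.needs_alpha else [])
    return {f: sem[f] for f in fields}
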