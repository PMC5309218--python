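"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator inverts the fitted likelihood: given a session design and a
generative encoding model, each trial's hit/miss outcome is a Bernoulli draw
with probability p_Memory(t) from the logistic of that model's reward
signal.  Confidence ratings and trait scores (Sensitivity to Reward /
Punishment) are layered on top with monotone stochastic mappings, since the
behavioral phenomena to reproduce are ordinal (confidence gradients, rank
correlations with the trait bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.stats import rankdata

from .design import DesignConfig, SessionDesign, generate_session_design
from .learning import DEFAULT_V0, trial_signals
from .models import ModelSpec, Params, encoding_probability, get_model, reward_signal
from .reference import group_mean_params, group_param_sems

CONFIDENCE_LEVELS = ("guess", "quite_certain", "certain")

#: probability of (guess, quite_certain, certain) within each p_Memory tercile
DEFAULT_CONFIDENCE_MAPPING = (
    (0.6, 0.3, 0.1),
    (0.3, 0.4, 0.3),
    (0.1, 0.3, 0.6),
)


@dataclass
class TraitScores:
    """Raw questionnaire scores and the cohort-referenced sensitivity bias."""

    sr: float
    sp: float
    bias: float = math.nan  # z(SR) - z(SP), recomputed per cohort


@dataclass
class ParticipantRecord:
    """One simulated participant: design, outcomes, and generative bookkeeping."""

    participant_id: str
    design: SessionDesign
    generative_model: str
    generative_params: Params
    y: np.ndarray  # binary test outcomes, one per trial
    p_memory: np.ndarray  # generative encoding probabilities
    v_before: np.ndarray
    delta: np.ndarray
    confidence: Optional[np.ndarray] = None
    traits: Optional[TraitScores] = None


def simulate_participant(
    design: SessionDesign,
    model: Union[ModelSpec, str],
    params: Params,
    seed: int,
    v0: float = DEFAULT_V0,
    participant_id: str = "p001",
) -> ParticipantRecord:
    """Draw one participant's test outcomes from the generative model."""
    if isinstance(model, str):
        model = get_model(model)
    params.validate(model)
    rng = np.random.default_rng(seed)
    alpha = params.alpha if model.needs_alpha else 0.0
    V, delta = trial_signals(design, alpha, v0)
    R = reward_signal(model, params, V, delta)
    p = encoding_probability(R)
    y = (rng.random(design.n_trials) < p).astype(int)
    return ParticipantRecord(
        participant_id=participant_id,
        design=design,
        generative_model=model.name,
        generative_params=params,
        y=y,
        p_memory=np.asarray(p),
        v_before=V,
        delta=delta,
    )


ParamSource = Union[Params, Callable[[np.random.Generator], Params]]


def sample_group_params(
    model: Union[ModelSpec, str], delay: str = "20min"
) -> Callable[[np.random.Generator], Params]:
    """Per-participant parameter sampler around the published group means.

    Truncated Gaussians centered on the group means with SD equal to the
    published SEM * sqrt(25) (the implied between-participant SD), truncated
    at the parameter bounds.
    """
    if isinstance(model, ModelSpec):
        model = model.name
    means = group_mean_params(model, delay)
    sds = {f: s * math.sqrt(25) for f, s in group_param_sems(model, delay).items()}
    spec = get_model(model)

    def sampler(rng: np.random.Generator) -> Params:
        kw: Dict[str, float] = {}
        for f, sd in sds.items():
            lo, hi = (0.0, 1.0) if f == "alpha" else (-2.0, 2.0)
            mu = getattr(means, f)
            x = rng.normal(mu, sd)
            while not (lo <= x <= hi):
                x = rng.normal(mu, sd)
            kw[f] = float(x)
        p = Params(**kw)
        p.validate(spec)
        return p

    return sampler


def simulate_cohort(
    n: int,
    model: Union[ModelSpec, str],
    param_source: ParamSource,
    base_seed: int,
    design_config: Optional[DesignConfig] = None,
    v0: float = DEFAULT_V0,
) -> List[ParticipantRecord]:
    """Simulate ``n`` participants with fresh designs and derived seeds.

    All randomness (design, parameters, outcomes) is derived from
    ``base_seed`` through a :class:`numpy.random.SeedSequence`, so identical
    calls produce identical cohorts.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if isinstance(model, str):
        model = get_model(model)
    ss = np.random.SeedSequence(base_seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    records = []
    for i, child in enumerate(ss.spawn(n), start=1):
        design_seed, sim_seed = (int(s) for s in child.generate_state(2) >> 1)
        cfg = design_config or DesignConfig()
        design = generate_session_design(design_seed, cfg)
        params = (
            param_source(param_rng) if callable(param_source) else param_source
        )
        rec = simulate_participant(
            design, model, params, sim_seed, v0, participant_id=f"p{i:03d}"
        )
        records.append(rec)
    return records


def cohort_manifest(records: Sequence[ParticipantRecord]) -> List[Dict[str, str]]:
    """Per-participant provenance summary (generative model and parameters)."""
    return [
        {
            "participant_id": r.participant_id,
            "generative_model": r.generative_model,
            **{k: repr(v) for k, v in r.generative_params.as_dict().items()},
        }
        for r in records
    ]


def _normal_scores(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    ranks = rankdata(x, method="average")
    return norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def _latent_pearson_for_spearman(target_rho: float, n: int) -> float:
    """Invert the bivariate-normal expectation of the sample Spearman rho.

    For bivariate normal data with Pearson correlation r the expected sample
    Spearman coefficient is 6/(pi*(n+1)) * [asin(r) + (n-2)*asin(r/2)];
    solving for r removes the small-sample attenuation of the naive
    2*sin(pi*rho/6) mapping.
    """
    if target_rho == 0:
        return 0.0
    sign = math.copysign(1.0, target_rho)
    t = abs(target_rho)

    def expected(r: float) -> float:
        return 6 / (math.pi * (n + 1)) * (math.asin(r) + (n - 2) * math.asin(r / 2))

    if t >= expected(1.0):
        return sign
    return sign * brentq(lambda r: expected(r) - t, 0.0, 1.0, xtol=1e-12)


def simulate_traits(
    records: Sequence[ParticipantRecord],
    target_rho: float,
    couple_to: Union[str, Sequence[float], Callable[[ParticipantRecord], float]],
    seed: int,
    sr_loc: float = 9.0,
    sp_loc: float = 10.0,
    scale: float = 4.0,
) -> List[ParticipantRecord]:
    """Attach SR/SP trait scores rank-coupled to a per-participant statistic.

    A Gaussian copula links the normal scores of the coupled statistic to a
    latent trait axis G with latent correlation calibrated so the expected
    sample Spearman correlation between the sensitivity bias (z(SR) - z(SP))
    and the statistic equals ``target_rho``.  SR and SP share a common
    nuisance component, so neither raw scale alone carries the signal:
    SR = sr_loc + scale*(G + W), SP = sp_loc + scale*(-G + W).

    ``couple_to`` may be an attribute/statistic callable, an aligned numeric
    sequence, or the name of a record attribute.
    """
    if not (-1.0 <= target_rho <= 1.0):
        raise ValueError("target_rho must lie in [-1, 1]")
    n = len(records)
    if callable(couple_to):
        stat = np.array([couple_to(r) for r in records], dtype=float)
    elif isinstance(couple_to, str):
        stat = np.array([getattr(r, couple_to) for r in records], dtype=float)
    else:
        stat = np.asarray(couple_to, dtype=float)
        if stat.size != n:
            raise ValueError("coupled statistic must align with the cohort")

    rng = np.random.default_rng(seed)
    z = _normal_scores(stat)
    r_lat = _latent_pearson_for_spearman(target_rho, n)
    lam = math.sqrt(max(0.0, 1.0 - r_lat**2))
    noise = rng.standard_normal(n) if lam > 0 else np.zeros(n)
    G = r_lat * z + lam * noise
    # shared nuisance; vanishes in the noise-free comonotone case so finite-
    # sample z-scoring cannot break exact rank agreement
    W = rng.standard_normal(n) * 0.8 * lam

    sr = sr_loc + scale * (G + W)
    sp = sp_loc + scale * (-G + W)
    zsr = (sr - sr.mean()) / sr.std(ddof=1)
    zsp = (sp - sp.mean()) / sp.std(ddof=1)
    bias = zsr - zsp
    for rec, a, b, c in zip(records, sr, sp, bias):
        rec.traits = TraitScores(sr=float(a), sp=float(b), bias=float(c))
    return list(records)


def simulate_confidence(
    record: ParticipantRecord,
    seed: int,
    mapping: Sequence[Sequence[float]] = DEFAULT_CONFIDENCE_MAPPING,
) -> ParticipantRecord:
    """Draw 3-level confidence labels, monotone in the generative p_Memory.

    Trials are binned at the terciles of the participant's p_Memory values;
    each bin has its own categorical distribution over (guess, quite_certain,
    certain) whose certain-share increases with the bin.
    """
    p = record.p_memory
    q1, q2 = np.quantile(p, [1 / 3, 2 / 3])
    bins = (p >= q1).astype(int) + (p >= q2).astype(int)
    rng = np.random.default_rng(seed)
    probs = np.asarray(mapping, dtype=float)
    labels = np.empty(p.size, dtype=object)
    for i, b in enumerate(bins):
        labels[i] = CONFIDENCE_LEVELS[rng.choice(3, p=probs[b] / probs[b].sum())]
    record.confidence = labels
    return record
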