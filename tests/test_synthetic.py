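import numpy as np
import pytest

import rewardmem as rm
from rewardmem.models import Params
from rewardmem.stats import cohort_trials_frame
from rewardmem.synthetic import (
    CONFIDENCE_LEVELS,
    simulate_confidence,
    simulate_participant,
    simulate_traits,
)


def test_simulate_participant_determinism(default_design, table1_params):
    a = simulate_participant(default_design, "pe_ev", table1_params, seed=5)
    b = simulate_participant(default_design, "pe_ev", table1_params, seed=5)
    assert np.array_equal(a.y, b.y)
    assert a.y.size == default_design.n_trials


def test_saturated_signal_yields_all_hits(default_design):
    # C0 = 2 in the baseline model: p = expit(2) ~ 0.88 each trial; push to
    # the positive bound via pe_ev with every term maxed and check clamping
    params = Params(c0=2.0)
    rec = simulate_participant(default_design, "baseline", params, seed=0)
    assert rec.p_memory == pytest.approx(np.full(60, 1 / (1 + np.exp(-2))))
    # saturation: all-positive terms, delta>=0 high-ratio trials have p near 1
    assert rec.y.mean() > 0.7


def test_neutral_baseline_hit_rate_near_half():
    """C0 = 0 gives p = 0.5 every trial; long-run hit rate converges."""
    cfg = rm.DesignConfig()
    rng_hits = []
    for seed in range(170):  # ~10k trials total
        d = rm.generate_session_design(seed, cfg)
        rec = simulate_participant(d, "baseline", Params(c0=0.0), seed=seed)
        rng_hits.append(rec.y)
    rate = np.concatenate(rng_hits).mean()
    assert rate == pytest.approx(0.5, abs=0.02)


def test_cohort_shapes_and_determinism(table1_params):
    recs = rm.simulate_cohort(25, "pe_ev", table1_params, base_seed=9)
    assert len(recs) == 25
    assert all(r.y.size == 60 for r in recs)
    again = rm.simulate_cohort(25, "pe_ev", table1_params, base_seed=9)
    for a, b in zip(recs, again):
        assert np.array_equal(a.y, b.y)
        assert a.design == b.design
    with pytest.raises(ValueError):
        rm.simulate_cohort(0, "pe_ev", table1_params, base_seed=9)


def test_singleton_cohort(table1_params):
    recs = rm.simulate_cohort(1, "pe_ev", table1_params, base_seed=3)
    assert len(recs) == 1


def test_hit_rate_calibration(small_cohort):
    """Cohort mean outcome matches cohort mean generative p within 3 SE."""
    y = np.concatenate([r.y for r in small_cohort])
    p = np.concatenate([r.p_memory for r in small_cohort])
    se = np.sqrt(np.sum(p * (1 - p))) / y.size
    assert abs(y.mean() - p.mean()) <= 3 * se


def test_round_trip_beats_baseline(small_cohort):
    """Fitting the generating model yields lower mean LLE than baseline."""
    opts = rm.FitOptions(step_scale=0.2, step_alpha=0.1)
    fits = rm.fit_cohort(small_cohort, ["baseline", "pe_ev"], opts)
    mean_lle = fits.groupby("model")["lle"].mean()
    assert mean_lle["pe_ev"] < mean_lle["baseline"]


def test_traits_comonotone_when_noise_free(small_cohort):
    stat = [r.y.mean() for r in small_cohort]
    recs = simulate_traits(small_cohort, target_rho=1.0, couple_to=stat, seed=1)
    bias = np.array([r.traits.bias for r in recs])
    assert rm.spearman_rho(bias, stat) == pytest.approx(1.0)


def test_traits_null_coupling(table1_params):
    recs = rm.simulate_cohort(100, "pe_ev", table1_params, base_seed=21)
    stat = [r.y.mean() for r in recs]
    recs = simulate_traits(recs, target_rho=0.0, couple_to=stat, seed=2)
    bias = [r.traits.bias for r in recs]
    assert abs(rm.spearman_rho(bias, stat)) < 0.25  # 95% null band at n=100


def test_traits_hit_target_rho_in_expectation():
    """Calibrated copula: mean sample Spearman rho ~ 0.55 at n=19."""
    rng = np.random.default_rng(3)
    obs = []
    for rep in range(1000):
        stat = rng.standard_normal(19)

        class R:  # minimal record stand-ins
            def __init__(self):
                self.traits = None

        recs = [R() for _ in range(19)]
        simulate_traits(recs, target_rho=0.55, couple_to=stat, seed=rep)
        bias = [r.traits.bias for r in recs]
        obs.append(rm.spearman_rho(bias, stat))
    assert np.mean(obs) == pytest.approx(0.55, abs=0.05)


def test_traits_rejects_bad_rho(small_cohort):
    with pytest.raises(ValueError):
        simulate_traits(small_cohort, 1.5, [r.y.mean() for r in small_cohort], seed=0)


def test_confidence_monotone_and_deterministic(default_design, table1_params):
    rec = simulate_participant(default_design, "pe_ev", table1_params, seed=4)
    simulate_confidence(rec, seed=11)
    labels1 = rec.confidence.copy()
    simulate_confidence(rec, seed=11)
    assert np.array_equal(labels1, rec.confidence)
    assert set(labels1) <= set(CONFIDENCE_LEVELS)


def test_confidence_certain_modal_when_p_uniformly_high(default_design):
    rec = simulate_participant(default_design, "baseline", Params(c0=2.0), seed=0)
    rec.p_memory = np.full(60, 0.999)
    simulate_confidence(rec, seed=5)
    values, counts = np.unique(rec.confidence, return_counts=True)
    assert values[np.argmax(counts)] == "certain"


def test_confidence_all_labels_occur_for_spread_p(table1_params):
    recs = rm.simulate_cohort(10, "pe_ev", table1_params, base_seed=8)
    labels = []
    for i, rec in enumerate(recs):  # 600 trials
        simulate_confidence(rec, seed=100 + i)
        labels.extend(rec.confidence)
    assert set(labels) == set(CONFIDENCE_LEVELS)


def test_trials_frame_schema(small_cohort):
    df = cohort_trials_frame(small_cohort[:3])
    for col in ("participant_id", "V_before", "delta", "p_encoding",
                "test_correct", "feedback", "level"):
        assert col in df.columns
    assert len(df) == 180
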