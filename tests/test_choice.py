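"""Psychometric discounting model: functional form, densities, fitting,
and z-normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from vtamap.choice import (
    EFFORT_MAX,
    EFFORT_MIN,
    TaskDesign,
    accept_probability,
    fit_discounting,
    internal_choice_density,
    normalize_effort,
    normalize_reward,
    znormalize,
    zscore_fit_table,
)
from vtamap.errors import DegenerateInputError, ParameterError
from vtamap.synthetic import SubjectTruth, make_trials


def _subject(bias_ext=0.1, sigma_ext=0.3, bias_int=0.2, sigma_int=0.3):
    return SubjectTruth(
        subject_id="s1",
        group="HC",
        sex="F",
        true_bias_internal=bias_int,
        true_bias_external=bias_ext,
        true_sigma_internal=sigma_int,
        true_sigma_external=sigma_ext,
        true_vta_intensity=1.08,
        true_vta_volume=19.0,
        true_sn_intensity=1.12,
        true_brain_volume_mm3=1.2e6,
    )


def test_accept_probability_values_and_symmetry():
    # indifference: normalized reward equals normalized effort, bias 0
    for sigma in (0.05, 0.3, 2.0):
        assert accept_probability(3, 0.25, 0.0, sigma) == pytest.approx(0.5)
    # frozen hand value: e=0, r=1, sigma=0.2 -> logistic(5)
    assert accept_probability(3, 2.00, 0.0, 0.2) == pytest.approx(1 / (1 + np.exp(-5)), abs=1e-12)
    with pytest.raises(ParameterError):
        accept_probability(10, 1.0, 0.0, -0.1)


def test_bias_is_a_translation_of_the_effort_axis():
    delta = 0.13
    e = np.linspace(3, 70, 12)
    p_shifted_bias = accept_probability(e, 1.0, 0.2 + delta, 0.3)
    # shifting normalized effort by delta is the same as raising bias by delta
    e_norm = normalize_effort(e) + delta
    e_back = EFFORT_MIN + e_norm * (EFFORT_MAX - EFFORT_MIN)
    p_shifted_axis = accept_probability(e_back, 1.0, 0.2, 0.3)
    assert np.allclose(p_shifted_bias, p_shifted_axis, atol=1e-12)


def test_monotonicity_in_effort_reward_bias_sigma():
    e = np.linspace(3, 70, 20)
    p = accept_probability(e, 1.0, 0.1, 0.3)
    assert np.all(np.diff(p) < 0)  # decreasing in effort
    r = np.linspace(0.25, 2.0, 20)
    p = accept_probability(30, r, 0.1, 0.3)
    assert np.all(np.diff(p) > 0)  # increasing in reward
    biases = np.linspace(-0.5, 0.5, 9)
    p = np.array([accept_probability(30, 1.0, b, 0.3) for b in biases])
    assert np.all(np.diff(p) < 0)  # decreasing in bias
    # gradient at the indifference point shrinks as sigma grows
    grads = []
    for sigma in (0.1, 0.2, 0.4, 0.8):
        h = 1e-4
        g = (accept_probability(3, 0.25 + h * 1.75, 0.0, sigma) - 0.5) / h
        grads.append(abs(g))
    assert np.all(np.diff(grads) < 0)


def test_internal_density_mode_normalization_and_limit():
    bias, sigma, reward = 0.1, 0.2, 1.0
    r = normalize_reward(reward)
    mode_e = r - bias
    mode_presses = EFFORT_MIN + mode_e * (EFFORT_MAX - EFFORT_MIN)
    d_mode = internal_choice_density(mode_presses, reward, bias, sigma)
    for off in (-0.2, 0.15):
        presses = EFFORT_MIN + (mode_e + off) * (EFFORT_MAX - EFFORT_MIN)
        assert internal_choice_density(presses, reward, bias, sigma) < d_mode

    total, _ = quad(
        lambda e: internal_choice_density(EFFORT_MIN + e * (EFFORT_MAX - EFFORT_MIN), reward, bias, sigma),
        0.0,
        1.0,
        limit=200,
    )
    assert total == pytest.approx(1.0, abs=1e-8)

    # sigma -> 0 concentrates at the indifference point: the peak density
    # approaches the untruncated logistic maximum 1/(4*sigma)
    tight = internal_choice_density(mode_presses, reward, bias, 0.005)
    assert tight == pytest.approx(1 / (4 * 0.005), rel=1e-6)
    assert tight > 20 * d_mode


def test_task_design_ranges_and_trial_counts():
    d = TaskDesign()
    subj = _subject()
    trials = make_trials(subj, d, seed=0)
    for cond in ("internal", "external"):
        sub = trials[trials["condition"] == cond]
        assert len(sub) == 64
        assert sub["effort_presses"].between(3, 70).all()
        assert sub["reward_usd"].between(0.25, 2.00).all()
    ext = trials[trials["condition"] == "external"]
    assert set(np.unique(ext["response"])) <= {0.0, 1.0}
    internal = trials[trials["condition"] == "internal"]
    assert internal["response"].between(3, 70).all()
    with pytest.raises(ParameterError):
        TaskDesign(effort_levels=(1, 50))
    with pytest.raises(ParameterError):
        TaskDesign(reward_levels=(0.25,))


def test_step_function_limit_of_external_responses():
    """sigma -> 0+ with bias 0: offers with r > e accepted, r < e rejected."""
    subj = _subject(bias_ext=0.0, sigma_ext=1e-6)
    trials = make_trials(subj, TaskDesign(conditions=("external",)), seed=1)
    e = normalize_effort(trials["effort_presses"])
    r = normalize_reward(trials["reward_usd"])
    off_boundary = np.abs(r - e) > 1e-3
    expected = (r > e)[off_boundary]
    assert np.array_equal(trials["response"].to_numpy()[off_boundary] > 0.5, expected)


def test_fit_determinism_and_recovery_direction():
    subj = _subject(bias_ext=0.1, sigma_ext=0.3)
    trials = make_trials(subj, TaskDesign(trials_per_cell=4, conditions=("external",)), seed=3)
    f1 = fit_discounting(trials, "external", seed=9)
    f2 = fit_discounting(trials, "external", seed=9)
    assert (f1.bias, f1.sigma, f1.loglik) == (f2.bias, f2.sigma, f2.loglik)
    assert f1.converged
    assert abs(f1.bias - 0.1) < 0.15
    assert abs(f1.sigma - 0.3) / 0.3 < 0.5


def test_sigma_groups_separate_in_rank_order():
    """Fits separate reward-sensitivity phenotypes at the two published
    magnitudes (0.45 vs 0.16) in nearly every simulated pair."""
    design = TaskDesign(trials_per_cell=2, conditions=("external",))
    wins = 0
    n_pairs = 20
    for i in range(n_pairs):
        hi = make_trials(_subject(sigma_ext=0.450), design, seed=100 + i)
        lo = make_trials(_subject(sigma_ext=0.159), design, seed=200 + i)
        f_hi = fit_discounting(hi, "external", seed=i)
        f_lo = fit_discounting(lo, "external", seed=i)
        wins += int(f_hi.sigma > f_lo.sigma)
    assert wins >= int(0.95 * n_pairs)


def test_internal_condition_fit_recovers_parameters():
    subj = _subject(bias_int=0.25, sigma_int=0.2)
    trials = make_trials(subj, TaskDesign(trials_per_cell=4, conditions=("internal",)), seed=5)
    fit = fit_discounting(trials, "internal", seed=2)
    assert abs(fit.bias - 0.25) < 0.1
    assert abs(fit.sigma - 0.2) / 0.2 < 0.4


def test_boundary_responses_flagged():
    subj = _subject(bias_ext=-5.0, sigma_ext=0.05)  # accepts everything
    trials = make_trials(subj, TaskDesign(conditions=("external",)), seed=6)
    with pytest.warns(UserWarning):
        fit = fit_discounting(trials, "external", seed=0)
    assert "boundary_responses" in fit.flags


def test_znormalize_and_affine_invariance():
    z = znormalize([1.0, 2.0, 3.0])
    assert np.allclose(z, [-1.0, 0.0, 1.0])
    rng = np.random.default_rng(0)
    x = rng.normal(3, 2, 50)
    z = znormalize(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(znormalize(5 * x - 2), z)
    with pytest.raises(DegenerateInputError):
        znormalize([2.0, 2.0, 2.0])


def test_zscore_fit_table_per_condition():
    df = pd.DataFrame(
        {
            "condition": ["external"] * 3 + ["internal"] * 3,
            "bias": [0.1, 0.2, 0.3, 1.0, 2.0, 3.0],
            "sigma": [0.3, 0.4, 0.5, 0.1, 0.2, 0.3],
        }
    )
    out = zscore_fit_table(df)
    for cond in ("external", "internal"):
        sub = out[out["condition"] == cond]
        assert sub["bias_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert sub["bias_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
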