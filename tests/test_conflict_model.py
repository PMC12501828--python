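"""Conflict-monitoring network: unit dynamics, trials, invariants."""

import numpy as np
import pytest

from erncancel import conflict_model as cm


def quiet_cfg(**kw):
    kw.setdefault("noise_sd", 0.0)
    return cm.SimConfig(**kw)


def state_at(cfg, value):
    s = cm.NetworkState.initial(cfg)
    s.activations[:] = value
    return s


# ---------------------------------------------------------------------------
# step_cycle
# ---------------------------------------------------------------------------

def test_rest_is_fixed_point_without_input():
    cfg = quiet_cfg()
    s = cm.NetworkState.initial(cfg)
    before = s.activations.copy()
    cm.step_cycle(s, np.zeros(9), cfg, None)
    np.testing.assert_allclose(s.activations, before, atol=1e-12)


def test_steady_state_matches_closed_form():
    # constant net input c > 0: a* = (c*a_max + decay*a_rest) / (c + decay)
    cfg = quiet_cfg()
    c = 0.1
    s = cm.NetworkState.initial(cfg)
    ext = np.full(9, c / cfg.extscale)
    zero_w = np.zeros((9, 9))  # isolate the external drive
    for _ in range(400):
        cm.step_cycle(s, ext, cfg, None, matrix=zero_w)
    a_star = (c * cfg.a_max + cfg.decay * cfg.a_rest) / (c + cfg.decay)
    assert a_star == pytest.approx(0.45)
    np.testing.assert_allclose(s.activations, a_star, atol=1e-6)


def test_single_euler_step_direct_substitution():
    # a = 0, input = 0.2 -> da = 0.2*(1-0) - 0.1*(0+0.1) = 0.19
    cfg = quiet_cfg()
    s = state_at(cfg, 0.0)
    cm.step_cycle(s, np.full(9, 0.2 / cfg.extscale), cfg, None,
                  matrix=np.zeros((9, 9)))
    np.testing.assert_allclose(s.activations, 0.19, atol=1e-12)


def test_negative_input_drives_toward_floor_under_standard_rule():
    cfg = quiet_cfg()
    s = state_at(cfg, 0.5)
    cm.step_cycle(s, np.full(9, -1.0), cfg, None, matrix=np.zeros((9, 9)))
    assert np.all(s.activations < 0.5)
    assert np.all(s.activations >= cfg.a_min)


def test_paper_literal_rule_flips_negative_drive():
    cfg_lit = quiet_cfg(activation_rule="paper_literal")
    s = state_at(cfg_lit, 0.5)
    cm.step_cycle(s, np.full(9, -0.05), cfg_lit, None, matrix=np.zeros((9, 9)))
    # input*(a_min - a) with input<0 and a>a_min pushes activation up
    assert np.all(s.activations > 0.5 - 0.1 * (0.5 + 0.1))


def test_activations_always_clamped():
    cfg = cm.SimConfig(noise_sd=0.5)  # exaggerated noise
    rng = np.random.default_rng(0)
    s = cm.NetworkState.initial(cfg)
    for _ in range(200):
        cm.step_cycle(s, rng.normal(0, 1, 9), cfg, rng)
        assert np.all(s.activations >= cfg.a_min - 1e-12)
        assert np.all(s.activations <= cfg.a_max + 1e-12)


# ---------------------------------------------------------------------------
# conflict energy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a_l, a_r, expected",
    [(0.5, 0.2, 0.6), (0.5, -0.1, 0.0), (0.0, 0.9, 0.0)],
)
def test_energy_direct_substitution(a_l, a_r, expected):
    cfg = quiet_cfg()
    s = cm.NetworkState.initial(cfg)
    s.activations[cm.IDX["L"]] = a_l
    s.activations[cm.IDX["R"]] = a_r
    assert cm.compute_conflict(s, cfg) == pytest.approx(expected)


def test_energy_nonnegative_and_zero_for_nonpositive_product():
    cfg = quiet_cfg()
    rng = np.random.default_rng(1)
    s = cm.NetworkState.initial(cfg)
    for _ in range(500):
        s.activations[4:6] = rng.uniform(cfg.a_min, cfg.a_max, 2)
        e = cm.compute_conflict(s, cfg)
        assert e >= 0
        if s.activations[4] * s.activations[5] <= 0:
            assert e == 0


# ---------------------------------------------------------------------------
# attention update
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ext_c_prev, energy, expected_c, expected_s",
    [
        (2.0, 0.1, 1.7605, 0.61975),
        (1.0, 0.0, 1.04, 0.98),
        (3.0, 10.0, 3.0, 0.0),  # clamped at the upper bound
    ],
)
def test_attention_update_examples(ext_c_prev, energy, expected_c, expected_s):
    cfg = quiet_cfg()
    s = cm.NetworkState.initial(cfg)
    s.ext_C = ext_c_prev
    s.energy_total = energy
    ext_c, ext_s = cm.update_attention(s, cfg)
    assert ext_c == pytest.approx(expected_c)
    assert ext_s == pytest.approx(expected_s)
    assert cfg.extC_bounds[0] <= ext_c <= cfg.extC_bounds[1]


# ---------------------------------------------------------------------------
# trials and datasets
# ---------------------------------------------------------------------------

def test_noise_free_trial_is_correct_with_offset():
    cfg = quiet_cfg()
    s = cm.NetworkState.initial(cfg)
    tr = cm.run_trial(s, "left", cfg, None)
    assert tr.accuracy == "correct"
    assert tr.responded_unit == "L"
    assert tr.offset_cycle > tr.onset_cycle
    assert tr.rt_ms == (tr.onset_cycle - cfg.prep_cycles) * cfg.ms_per_cycle
    assert tr.rd_ms == (tr.offset_cycle - tr.onset_cycle) * cfg.ms_per_cycle


def test_unreachable_threshold_yields_omission():
    with pytest.warns(UserWarning, match="threshold"):
        cfg = quiet_cfg(threshold=cm.SimConfig().a_max + 1)
    s = cm.NetworkState.initial(cfg)
    tr = cm.run_trial(s, "right", cfg, None)
    assert tr.accuracy == "omission"
    assert tr.onset_cycle is None and tr.offset_cycle is None
    assert tr.rt_ms is None and tr.rd_ms is None


def test_fixed_seed_gives_identical_trial_streams():
    cfg = cm.SimConfig(n_trials=40, seed=7)
    a = cm.run_dataset(cfg)
    b = cm.run_dataset(cfg)
    for x, y in zip(a, b):
        assert x.accuracy == y.accuracy
        assert x.onset_cycle == y.onset_cycle
        np.testing.assert_array_equal(x.conflict_trace, y.conflict_trace)


def test_dataset_produces_errors_with_short_durations():
    trials = cm.run_dataset(cm.SimConfig(n_trials=600, seed=3))
    s = cm.dataset_summary(trials)
    assert s["error_rate"] > 0
    assert s["mean_rd_error"] < s["mean_rd_correct"]


def test_surround_only_noise_is_supported_config():
    trials = cm.run_dataset(
        cm.SimConfig(n_trials=30, seed=0, noise_targets="surround_only"))
    assert len(trials) == 30


# ---------------------------------------------------------------------------
# response-locked conflict
# ---------------------------------------------------------------------------

def test_identical_traces_give_zero_difference():
    trace = np.linspace(0, 1, 50)
    trials = []
    for acc in ("correct", "commission_error"):
        trials.append(cm.SimTrial(
            stimulus="left", conflict_trace=trace.copy(), onset_cycle=10,
            offset_cycle=20, responded_unit="L", accuracy=acc,
            rt_ms=112.0, rd_ms=160.0))
    out = cm.response_locked_conflict(trials, "onset", window=(-3, 3))
    np.testing.assert_allclose(out["difference"], 0.0)


def test_single_trial_class_mean_equals_that_trial():
    trace = np.arange(50, dtype=float)
    tr = cm.SimTrial("left", trace, 10, 20, "L", "correct", 112.0, 160.0)
    out = cm.response_locked_conflict([tr], "onset", window=(0, 3))
    np.testing.assert_array_equal(out["correct"], trace[9:13])
    assert out["missing"] == ["commission_error"]


def test_onset_locked_difference_has_positive_post_onset_peak():
    trials = cm.run_dataset(cm.SimConfig(n_trials=600, seed=5))
    out = cm.response_locked_conflict(trials, "onset")
    ax, d = out["cycles"], out["difference"]
    post = d[(ax >= 0) & (ax <= 10)]
    assert post.max() > 0
    assert post.max() == pytest.approx(np.nanmax(d), abs=1e-12)
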