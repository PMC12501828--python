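"""Epoching, filtering, artifact screening, ICA cleaning, balancing."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from erncancel import preprocess as pre
from erncancel.containers import EpochSet


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def test_epoch_index_arithmetic():
    cont = np.arange(4000, dtype=float)[None, :]
    ep = pre.epoch(cont, [1000], 1000.0, ["FCz"], "response_onset")
    assert ep.data.shape == (1, 1, 1200)
    assert ep.data[0, 0, 0] == 400.0      # sample 1000 - 600
    assert ep.data[0, 0, -1] == 1599.0    # half-open window end
    assert ep.times[0] == -600.0


def test_epoch_drops_out_of_bounds_events():
    cont = np.zeros((1, 3000))
    with pytest.warns(UserWarning, match="outside recording"):
        ep = pre.epoch(cont, [100, 1500], 1000.0, ["FCz"], "stimulus")
    assert ep.n_trials == 1


def test_epoch_count_matches_markers():
    cont = np.zeros((2, 50000))
    events = np.arange(10) * 4000 + 1000
    ep = pre.epoch(cont, events, 1000.0, ["a", "b"], "stimulus")
    assert ep.n_trials == 10


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def test_baseline_removes_constant(flat_epochs):
    out = pre.baseline_correct(flat_epochs, (-100, 0))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_baseline_linearity_and_residual_mean(flat_epochs):
    rng = np.random.default_rng(0)
    flat_epochs.data[:] = rng.normal(size=flat_epochs.data.shape)
    zeroed = pre.baseline_correct(flat_epochs, (-100, 0))
    shifted = flat_epochs.copy()
    shifted.data += 3.0
    recovered = pre.baseline_correct(shifted, (-100, 0))
    np.testing.assert_allclose(recovered.data, zeroed.data, atol=1e-10)
    mask = zeroed.time_mask((-100, 0))
    assert np.abs(zeroed.data[:, :, mask].mean(axis=2)).max() < 1e-10


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def analytic_gain(kind, edges, order, freq, sfreq):
    """Magnitude of the zero-phase (forward-backward) Butterworth."""
    sos = pre._butter_sos(kind, edges, order, sfreq)
    _, h = sps.sosfreqz(sos, worN=[2 * np.pi * freq / sfreq])
    return float(np.abs(h[0]) ** 2)


@pytest.mark.parametrize(
    "kind, edges, freq, duration, bound",
    [
        ("bandstop", (47.5, 52.5), 50.0, 6.0, ("lt", 0.05)),
        ("lowpass", 20.0, 10.0, 6.0, ("range", 0.95, 1.05)),
        # the 0.1 Hz edge has a ~1.6 s transient: probe on a long record
        ("highpass", 0.1, 10.0, 60.0, ("range", 0.95, 1.05)),
        ("bandpass", (110.0, 140.0), 125.0, 6.0, ("range", 0.9, 1.1)),
    ],
)
def test_filter_matches_analytic_butterworth_response(kind, edges, freq,
                                                      duration, bound):
    sfreq = 1000.0
    t = np.arange(0, duration, 1 / sfreq)
    x = np.sin(2 * np.pi * freq * t)[None, :]
    y = pre.filter_data(x, kind, edges, sfreq)
    mid = slice(len(t) // 3, 2 * len(t) // 3)  # steady-state portion
    gain = np.sqrt(np.mean(y[0, mid] ** 2) / np.mean(x[0, mid] ** 2))
    ref = analytic_gain(kind, edges, 4, freq, sfreq)
    assert gain == pytest.approx(ref, abs=0.01)
    if bound[0] == "lt":
        assert gain < bound[1]
    else:
        assert bound[1] < gain < bound[2]


def test_highpass_removes_dc():
    sfreq = 500.0
    x = np.full((1, 4000), 7.0)
    y = pre.filter_data(x, "highpass", 0.1, sfreq)
    assert abs(y[0, 2000:].mean()) < 0.5


def test_filter_rejects_edges_beyond_nyquist():
    with pytest.raises(ValueError, match="Nyquist"):
        pre.filter_data(np.zeros((1, 100)), "lowpass", 600.0, 1000.0)


# ---------------------------------------------------------------------------
# artifact screen
# ---------------------------------------------------------------------------

def _noise_epochs(n=100, nch=4, nt=600, seed=0):
    rng = np.random.default_rng(seed)
    times = np.arange(-300.0, 300.0)
    data = rng.normal(0, 1, (n, nch, nt))
    return EpochSet(data, times, [f"c{i}" for i in range(nch)], 1000.0,
                    "response_onset", pd.DataFrame(index=range(n)))


def test_clean_noise_passes_jump_screen():
    ep = _noise_epochs()
    keep = pre.artifact_screen(ep, "jump", 20.0)
    assert keep.all()


def test_injected_step_is_rejected_as_jump():
    ep = _noise_epochs()
    ep.data[7, :, 300:] += 50.0  # 50-SD step on all channels
    keep = pre.artifact_screen(ep, "jump", 20.0)
    assert not keep[7]
    assert keep.sum() == ep.n_trials - 1


def test_muscle_burst_caught_by_muscle_screen_only():
    ep = _noise_epochs(seed=1)
    t = np.arange(600) / 1000.0
    burst = 8.0 * np.sin(2 * np.pi * 125.0 * t) * np.exp(
        -((np.arange(600) - 300) / 60.0) ** 2)
    ep.data[3] += burst[None, :]
    keep_m = pre.artifact_screen(ep, "muscle", 8.0)
    keep_j = pre.artifact_screen(ep, "jump", 20.0)
    assert not keep_m[3]
    assert keep_j[3]


def test_false_positive_rate_below_one_percent():
    rejected = 0
    for seed in range(3):
        ep = _noise_epochs(n=100, seed=seed)
        rejected += int((~pre.artifact_screen(ep, "jump", 20.0)).sum())
    assert rejected / 300 < 0.01


# ---------------------------------------------------------------------------
# ocular component removal
# ---------------------------------------------------------------------------

def _epochs_with_blinks(seed=0, blink_gain=1.0):
    rng = np.random.default_rng(seed)
    n, nt = 40, 500
    times = np.arange(-250.0, 250.0)
    chans = ["Fz", "Cz", "Pz", "VEOG"]
    data = rng.normal(0, 1, (n, 4, nt))
    blink = np.zeros((n, nt))
    for i in range(0, n, 3):
        c = rng.integers(100, 400)
        w = np.arange(nt)
        blink[i] = 40.0 * np.exp(-((w - c) / 40.0) ** 2)
    weights = np.array([0.5, 0.3, 0.1, 1.0]) * blink_gain
    data += weights[None, :, None] * blink[:, None, :]
    ep = EpochSet(data, times, chans, 1000.0, "response_onset",
                  pd.DataFrame(index=range(n)))
    return ep, blink


def test_blink_component_removed_and_correlation_broken():
    ep, blink = _epochs_with_blinks()
    cleaned, n_removed = pre.remove_eog_components(ep, ("VEOG",), 0.40)
    assert n_removed >= 1
    flat_blink = blink.ravel()
    for ch in ("Fz", "Cz"):
        ci = cleaned.channel_index(ch)
        r = np.corrcoef(cleaned.data[:, ci, :].ravel(), flat_blink)[0, 1]
        assert abs(r) < 0.1


def test_unreachable_threshold_is_identity():
    ep, _ = _epochs_with_blinks(seed=1)
    cleaned, n_removed = pre.remove_eog_components(ep, ("VEOG",), 1.01)
    assert n_removed == 0
    eeg = [i for i, c in enumerate(ep.channels) if c != "VEOG"]
    np.testing.assert_allclose(cleaned.data[:, eeg], ep.data[:, eeg], atol=1e-6)


def test_missing_eog_channel_raises():
    ep, _ = _epochs_with_blinks()
    with pytest.raises(ValueError, match="EOG"):
        pre.remove_eog_components(ep, ("HEOG",), 0.4)


# ---------------------------------------------------------------------------
# re-referencing
# ---------------------------------------------------------------------------

def _mastoid_epochs(fill=2.0):
    times = np.arange(-50.0, 50.0)
    data = np.full((3, 4, 100), fill)
    return EpochSet(data, times, ["FCz", "Cz", "M1", "M2"], 1000.0,
                    "response_onset", pd.DataFrame(index=range(3)))


def test_zero_mastoids_leave_data_unchanged():
    ep = _mastoid_epochs()
    ep.data[:, 2:, :] = 0.0
    out = pre.rereference_linked_mastoids(ep)
    np.testing.assert_array_equal(out.data[:, :2], ep.data[:, :2])


def test_common_mode_removed_and_idempotent():
    ep = _mastoid_epochs(2.0)
    once = pre.rereference_linked_mastoids(ep)
    np.testing.assert_allclose(once.data, 0.0, atol=1e-12)
    twice = pre.rereference_linked_mastoids(once)
    np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def test_balance_counts_and_subset_property():
    rds = np.array([100, 105, 110, 115, 120, 150, 160, 170.0])
    s, l = pre.balance_trial_counts([0, 1, 2, 3, 4], [5, 6, 7], rds)
    assert len(s) == len(l) == 3
    assert set(s) <= {0, 1, 2, 3, 4} and set(l) == {5, 6, 7}


def test_balance_removes_nearest_to_median():
    rds = np.zeros(8)
    rds[4:8] = [150, 160, 170, 200]
    s, l = pre.balance_trial_counts([0, 1], [4, 5, 6, 7], rds)
    assert set(rds[l]) == {150.0, 200.0}


def test_balance_noop_and_empty_bin():
    rds = np.array([1.0, 2.0])
    s, l = pre.balance_trial_counts([0], [1], rds)
    assert list(s) == [0] and list(l) == [1]
    with pytest.raises(ValueError):
        pre.balance_trial_counts([], [1], rds)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def test_pipeline_preserves_shape_and_labels():
    rng = np.random.default_rng(2)
    times = np.arange(-600.0, 600.0)
    chans = ["Fz", "FCz", "Cz", "M1", "M2", "VEOG", "HEOG"]
    data = rng.normal(0, 2, (30, len(chans), times.size))
    meta = pd.DataFrame({"rd": rng.uniform(100, 180, 30)})
    ep = EpochSet(data, times, chans, 1000.0, "response_onset", meta)
    out, report = pre.preprocess_epochs(ep)
    assert out.channels == chans
    assert out.n_times == ep.n_times
    assert report["n_out"] <= report["n_in"]
    assert out.metadata.shape[0] == out.n_trials
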