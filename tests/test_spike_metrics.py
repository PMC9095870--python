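"""Waveform classification, ISI screening, PSTHs, and multi-unit pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminamod import (
    CellClass,
    TrialTable,
    UnitRecord,
    build_psth,
    classify_rs_fs,
    contamination_ratio,
    is_single_unit,
    isi_violation_rate,
    led_onset_mi,
    pool_multiunit,
    spontaneous_rate,
)


def _unit(width, spikes=()):
    return UnitRecord(
        unit_id="u", spike_times=np.asarray(spikes, dtype=float), depth_um=100.0,
        trough_peak_ms=width,
    )


@pytest.mark.parametrize(
    "width,expected",
    [
        (0.4, CellClass.FS),  # boundary is inclusive
        (0.41, CellClass.RS),
        (0.2, CellClass.FS),
        (1.0, CellClass.RS),
        (None, CellClass.UNCLASSIFIED),
    ],
)
def test_rs_fs_classification(width, expected):
    assert classify_rs_fs(_unit(width)) is expected


def test_isi_violation_examples():
    regular = np.arange(0, 10, 0.1)  # 10 Hz, all ISIs 100 ms
    assert isi_violation_rate(regular, 2.0) == 0.0
    burst = np.arange(0, 0.05, 0.001)  # every interval 1 ms
    assert isi_violation_rate(burst, 2.0) == 1.0
    assert isi_violation_rate(np.array([1.0]), 2.0) == 0.0


def test_poisson_isi_violations_match_closed_form():
    """Exponential ISIs at 20 Hz: P(ISI < 2 ms) = 1 - exp(-0.04) ~ 0.0392."""
    rng = np.random.default_rng(0)
    isis = rng.exponential(1 / 20.0, 200_000)
    t = np.cumsum(isis)
    assert isi_violation_rate(t, 2.0) == pytest.approx(1 - np.exp(-20 * 0.002), rel=0.05)
    # the rate-corrected contamination of a pure Poisson train is ~1
    assert contamination_ratio(t, 2.0) == pytest.approx(1.0, rel=0.06)
    assert not is_single_unit(t, 2.0)


def test_refractory_train_passes_single_unit_screen():
    rng = np.random.default_rng(1)
    t = np.cumsum(0.003 + rng.exponential(1 / 30.0, 50_000))  # 3-ms dead time
    assert is_single_unit(t, 2.0)


def test_psth_rate_example():
    # 1 spike per trial landing in one 25-ms bin, 10 trials -> 40 Hz there
    events = 10.0 * np.arange(10)
    spikes = events + 0.055
    psth = build_psth(spikes, events, 25.0, (0.0, 0.2))
    assert psth.rate_hz[2] == pytest.approx(40.0)  # 10 / (10 x 0.025)
    assert psth.rate_hz.sum() == pytest.approx(40.0)


def test_psth_zero_trials_is_error():
    with pytest.raises(ValueError):
        build_psth(np.array([1.0]), np.empty(0), 25.0, (0.0, 0.2))


def test_psth_empty_train_is_all_zero():
    psth = build_psth(np.empty(0), np.array([1.0, 2.0]), 25.0, (0.0, 0.2))
    assert np.all(psth.rate_hz == 0.0)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 400), st.integers(1, 7), st.integers(0, 10_000))
def test_psth_conserves_spike_count(n_spikes, n_trials, seed):
    """PSTH integral x n_trials equals the number of in-window spikes."""
    rng = np.random.default_rng(seed)
    spikes = np.sort(rng.uniform(0, 50, n_spikes))
    events = np.sort(rng.uniform(1, 49, n_trials))
    psth = build_psth(spikes, events, 25.0, (-0.5, 0.5))
    total = sum(
        np.sum((spikes >= e - 0.5) & (spikes < e + 0.5)) for e in events
    )
    assert psth.rate_hz.sum() * 0.025 * n_trials == pytest.approx(total)


def _toy_trials(n=10, led_every_other=True):
    onsets = 5.0 * (1 + np.arange(n))
    led = np.arange(n) % 2 == 0 if led_every_other else np.zeros(n, bool)
    return TrialTable(
        pd.DataFrame(
            {
                "trial_id": np.arange(n),
                "tone_freq_khz": 8.0,
                "tone_onset_s": onsets,
                "tone_dur_s": 0.2,
                "led_on": led,
                "led_onset_s": np.where(led, onsets - 1.0, np.nan),
                "led_offset_s": np.where(led, onsets + 1.2, np.nan),
                "pupil_baseline_norm": 0.5,
            }
        )
    )


def test_spontaneous_rate_examples():
    trials = _toy_trials(20, led_every_other=False)
    # one spike in ten of twenty 0.5-s pre-tone windows -> 1 Hz overall
    spikes = trials.df["tone_onset_s"].to_numpy()[:10] - 0.25
    rates = spontaneous_rate(np.sort(spikes), trials, window_s=0.5)
    assert rates["control"] == pytest.approx(10 / (20 * 0.5))
    rates_empty = spontaneous_rate(np.empty(0), trials, window_s=0.5)
    assert rates_empty["control"] == 0.0


def test_pooling_merges_and_is_order_invariant():
    trials = _toy_trials()
    a = UnitRecord("a", np.array([1.0, 2.0]), 100.0)
    b = UnitRecord("b", np.array([0.5, 3.0]), 120.0)
    p1 = pool_multiunit([a, b], "layer", trials=trials, exclude_photoactivated=False)
    p2 = pool_multiunit([b, a], "layer", trials=trials, exclude_photoactivated=False)
    assert p1.spike_times.size == 4
    np.testing.assert_array_equal(p1.spike_times, p2.spike_times)


def test_photoactivated_unit_excluded_from_pool():
    trials = _toy_trials()
    led_onsets = trials.led_onsets()
    # unit firing a burst only in the first 50 ms of each LED window
    burst = np.sort(np.concatenate([o + np.linspace(0.001, 0.045, 30) for o in led_onsets]))
    photo = UnitRecord("photo", burst, 150.0)
    quiet = UnitRecord("quiet", np.arange(0.0, 60.0, 0.21), 160.0)
    assert led_onset_mi(photo.spike_times, trials) > 1 / 3
    pool = pool_multiunit([photo, quiet], "layer", trials=trials)
    assert pool.member_ids == ["quiet"]
    assert pool.excluded == {"photo": "photoactivated"}
    assert not np.isin(burst, pool.spike_times).any()
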