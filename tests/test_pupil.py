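"""Pupil extraction: Feret oracle equivalence, deviant flags, arousal bins."""

import numpy as np
import pandas as pd
import pytest

from laminamod import (
    PupilTrace,
    SimConfig,
    TrialTable,
    bin_trials_by_arousal,
    detect_deviants,
    extract_diameter,
    extract_trace,
    generate_pupil_movie,
    max_feret_diameter,
)


def _brute_force_feret(mask: np.ndarray) -> float:
    pts = np.argwhere(mask).astype(float)
    if pts.shape[0] == 0:
        return float("nan")
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _disk(r, shape=(64, 64), center=None):
    cy, cx = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def test_feret_matches_exhaustive_oracle_on_random_masks():
    rng = np.random.default_rng(0)
    masks = [
        _disk(20),
        _disk(1),
        np.zeros((5, 30), bool),
        np.eye(40, dtype=bool),  # diagonal line
    ]
    masks[2][2, 1:29] = True  # horizontal line
    for _ in range(60):
        m = rng.random((rng.integers(2, 64), rng.integers(2, 64))) < 0.15
        masks.append(m)
    for m in masks:
        if not m.any():
            continue
        assert max_feret_diameter(m) == pytest.approx(_brute_force_feret(m), abs=1e-9)


def test_feret_conventions():
    line = np.zeros((5, 40), bool)
    line[2, 5:35] = True  # 30 pixels -> 29 center-to-center
    assert max_feret_diameter(line) == pytest.approx(29.0)
    single = np.zeros((3, 3), bool)
    single[1, 1] = True
    assert max_feret_diameter(single) == 0.0
    assert np.isnan(max_feret_diameter(np.zeros((3, 3), bool)))


def test_disk_diameter_and_rotation_invariance():
    from scipy import ndimage

    disk = _disk(20, (80, 80))
    d0 = max_feret_diameter(disk)
    assert d0 == pytest.approx(40.0, abs=1.0)
    rot = ndimage.rotate(disk.astype(float), 30, reshape=False, order=0) > 0.5
    assert max_feret_diameter(rot) == pytest.approx(d0, abs=1.0)


def test_extract_diameter_from_synthetic_frame():
    cfg = SimConfig(movie_n_frames=1, movie_noise_sd=4.0)
    movie, _, true_d, _ = generate_pupil_movie(cfg, seed=2, diameter_px=np.array([40.0]))
    d, valid = extract_diameter(movie[0])
    assert valid
    assert d == pytest.approx(40.0, abs=1.5)


def test_extract_diameter_rejects_color_and_empty():
    with pytest.raises(ValueError):
        extract_diameter(np.zeros((4, 4, 3)))
    bright = np.full((40, 40), 200, dtype=np.uint8)
    d, valid = extract_diameter(bright, intensity_threshold=10)
    assert not valid and np.isnan(d)


def test_occluded_frames_flagged_invalid():
    cfg = SimConfig(movie_n_frames=40, movie_occluded_frac=0.3)
    flagged = total = 0
    for seed in range(5):
        movie, times, _, occ = generate_pupil_movie(cfg, seed=seed)
        trace = extract_trace(movie, times, eyelid_rows=cfg.movie_eyelid_rows)
        trace = detect_deviants(trace)
        total += occ.sum()
        flagged += (~trace.valid[occ]).sum()
    assert total > 20
    assert flagged / total >= 0.9


def test_deviant_detection_rules():
    t = np.arange(50) / 30.0
    const = PupilTrace(t, np.full(50, 30.0), np.ones(50, bool))
    assert detect_deviants(const).valid.all()
    spiky = np.full(50, 30.0)
    spiky[25] = 300.0
    out = detect_deviants(PupilTrace(t, spiky, np.ones(50, bool)))
    assert not out.valid[25]
    assert out.valid.sum() == 49


def test_trace_normalization_excludes_invalid_frames():
    t = np.arange(4) / 30.0
    d = np.array([10.0, 20.0, 30.0, 500.0])
    valid = np.array([True, True, True, False])
    trace = PupilTrace(t, d, valid)
    np.testing.assert_allclose(trace.normalized[:3], [0.0, 0.5, 1.0])
    assert np.isnan(trace.normalized[3])


def _trials_at(onsets, led=True):
    onsets = np.asarray(onsets, dtype=float)
    return TrialTable(
        pd.DataFrame(
            {
                "trial_id": np.arange(onsets.size),
                "tone_freq_khz": 8.0,
                "tone_onset_s": onsets,
                "tone_dur_s": 0.2,
                "led_on": led,
                "led_onset_s": onsets - 1.0 if led else np.nan,
                "led_offset_s": onsets + 1.2 if led else np.nan,
                "pupil_baseline_norm": np.nan,
            }
        )
    )


def test_arousal_binning_quartiles_and_closed_last_bin():
    # frames at 30 Hz; normalized diameters chosen per trial window
    n = 30 * 20
    t = np.arange(n) / 30.0
    d = np.full(n, 25.0)
    trials = _trials_at([3.0, 6.0, 9.0, 12.0, 15.0])
    # pre-LED windows are [t-1.3, t-1.0); set diameters there
    levels = [0.1, 0.4, 0.6, 0.9, 1.0]
    lo, hi = 10.0, 50.0
    d[0], d[1] = lo, hi  # pin the normalization range
    for onset, lev in zip(trials.df["tone_onset_s"], levels):
        sel = (t >= onset - 1.3) & (t < onset - 1.0)
        d[sel] = lo + lev * (hi - lo)
    trace = PupilTrace(t, d, np.ones(n, bool))
    bins = bin_trials_by_arousal(trace, trials, n_bins=4)
    assert list(bins) == [0, 1, 2, 3, 3]  # diameter 1.0 falls in the closed last bin


def test_arousal_binning_missing_without_valid_frames():
    n = 30 * 10
    t = np.arange(n) / 30.0
    d = np.full(n, 25.0)
    valid = np.ones(n, bool)
    trials = _trials_at([3.0, 6.0])
    sel = (t >= 6.0 - 1.3) & (t < 6.0 - 1.0)
    valid[sel] = False  # occluded baseline window of the second trial
    d[0], d[1] = 10.0, 50.0
    trace = PupilTrace(t, d, valid)
    bins = bin_trials_by_arousal(trace, trials, n_bins=4)
    assert np.isfinite(bins.iloc[0])
    assert np.isnan(bins.iloc[1])
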