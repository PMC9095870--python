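"""Modulation index, responsiveness, tuning metrics, and gain decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminamod import (
    FsCategory,
    GainClass,
    ModClass,
    TONE_FREQS_KHZ,
    calibrate_threshold_roc,
    classify_fs_dynamics,
    classify_gain,
    classify_spontaneous,
    compute_mi,
    evoked_response,
    fit_threshold_linear,
    mi_by_arousal,
    responsiveness_test,
    tuning_metrics,
)
from laminamod.modulation import GainFit


@pytest.mark.parametrize(
    "L,C,expected",
    [
        (1.25, 1.0, 1 / 9),  # 25% increase
        (0.8, 1.0, -1 / 9),  # 20% decrease
        (1.4, 1.0, 1 / 6),  # 40% increase
        (5 / 7, 1.0, -1 / 6),  # ~29% decrease
        (1.0, 1.0, 0.0),
        (0.0, 5.0, -1.0),  # complete loss of activity
        (5.0, 0.0, 1.0),  # emergence from nothing
    ],
)
def test_mi_percent_change_identities(L, C, expected):
    assert compute_mi(L, C) == pytest.approx(expected, abs=1e-12)


def test_mi_undefined_and_invalid():
    assert np.isnan(compute_mi(0.0, 0.0))
    with pytest.raises(ValueError):
        compute_mi(-1.0, 2.0)


@settings(deadline=None, max_examples=100)
@given(
    st.floats(0, 1e6, allow_nan=False),
    st.floats(0, 1e6, allow_nan=False),
)
def test_mi_antisymmetric_and_bounded(a, b):
    mi = compute_mi(a, b)
    if np.isnan(mi):
        assert np.isnan(compute_mi(b, a))
    else:
        assert -1.0 <= mi <= 1.0
        assert compute_mi(b, a) == pytest.approx(-mi, abs=1e-12)


@pytest.mark.parametrize(
    "mi,rl,rc,expected",
    [
        (0.2, 2.0, 3.0, ModClass.ENHANCED),
        (-0.5, 0.3, 0.1, ModClass.UNCHANGED),  # both rates below 0.4 Hz
        (-0.112, 2.0, 3.0, ModClass.SUPPRESSED),  # just past -1/9
        (0.1, 2.0, 3.0, ModClass.UNCHANGED),  # inside the band (0.1 < 1/9)
        (float("nan"), 2.0, 3.0, ModClass.UNCHANGED),
    ],
)
def test_spontaneous_classification(mi, rl, rc, expected):
    assert classify_spontaneous(mi, rl, rc) is expected


def test_evoked_response_examples():
    edges = np.arange(0.0, 0.225, 0.025)
    flat = np.full(8, 5.0)
    assert evoked_response(flat, edges, 5.0, 0.2) == 0.0
    rect = np.full(8, 20.0)  # 20 Hz over a 5 Hz baseline for 200 ms
    assert evoked_response(rect, edges, 5.0, 0.2) == pytest.approx(3.0)  # (20-5)x0.2
    suppressed = np.full(8, 2.0)  # below baseline: positive-going only
    assert evoked_response(suppressed, edges, 5.0, 0.2) == 0.0


def test_responsiveness_criteria():
    n_trials, n_base, n_resp = 9, 8, 8
    base = np.tile([0.0, 20.0], (n_trials, n_base // 2))  # mean 10, SD 10
    quiet = np.zeros((n_trials, n_resp))
    assert not responsiveness_test(
        np.hstack([base, quiet]), np.arange(16) < 8
    )
    # a 10xSD response at one bin in all trials -> responsive
    strong = quiet.copy()
    strong[:, 3] = 10 + 10 * 10.0
    assert responsiveness_test(np.hstack([base, strong]), np.arange(16) < 8)
    # response in only 3/9 trials is not *more than* one third
    sparse = quiet.copy()
    sparse[:3, 3] = 10 + 10 * 10.0
    assert not responsiveness_test(np.hstack([base, sparse]), np.arange(16) < 8)
    # all-zero data is never responsive
    assert not responsiveness_test(np.zeros((9, 16)), np.arange(16) < 8)


def test_roc_calibration_recovers_ninety_percent_multiplier():
    """Constructed set whose 90% true-positive multiplier is exactly 3.7."""
    n_trials = 6
    base = np.tile([0.0, 20.0], (n_trials, 4))  # mean 10, SD 10
    amps = [3.0, 3.75, 4.0, 4.5, 5.0, 5.5, 6.0, 7.0, 8.0, 9.0]
    sets, labels = [], []
    for a in amps:
        resp = np.zeros((n_trials, 8))
        resp[:, 2] = 10 + 10 * a
        sets.append(np.hstack([base, resp]))
        labels.append(True)
    m = calibrate_threshold_roc(sets, np.arange(16) < 8, labels)
    assert m == pytest.approx(3.7, abs=0.5)
    # shuffled/unseparated labels: only a near-zero multiplier can reach 90% TPR
    weak = [np.hstack([base, np.zeros((n_trials, 8))]) for _ in range(10)]
    with pytest.raises(ValueError):
        calibrate_threshold_roc(weak, np.arange(16) < 8, [True] * 10)


def test_tuning_metrics_examples():
    freqs = np.asarray(TONE_FREQS_KHZ)
    resp = np.array([0, 0, 1, 4, 9, 3, 1, 0, 0], dtype=float)
    responsive = np.zeros(9, bool)
    responsive[2:7] = True  # middle five
    bf, bw = tuning_metrics(freqs, resp, responsive)
    assert bf == pytest.approx(16.0)
    assert bw == pytest.approx(2.0)  # (5 - 1) x 0.5 octaves
    bf1, bw1 = tuning_metrics(freqs, resp, np.eye(9, dtype=bool)[4])
    assert bw1 == 0.0
    bf_none, bw_none = tuning_metrics(freqs, resp, np.zeros(9, bool))
    assert np.isnan(bf_none) and np.isnan(bw_none)
    # halving all responses does not move the best frequency
    bf2, _ = tuning_metrics(freqs, resp / 2, responsive)
    assert bf2 == bf


def test_threshold_linear_fit_closed_forms():
    ctrl = np.array([0.5, 1.0, 2.0, 3.0, 3.5, 4.0])
    fit = fit_threshold_linear(ctrl, 0.5 * ctrl)
    assert fit.slope == pytest.approx(0.5, abs=1e-9)
    assert fit.y_intercept_norm == pytest.approx(0.0, abs=1e-9)
    assert fit.pearson_r == pytest.approx(1.0)
    ctrl2 = np.array([0.4, 0.55, 0.7, 0.85, 1.0])
    fit2 = fit_threshold_linear(ctrl2, ctrl2 - 0.2)
    assert fit2.slope == pytest.approx(1.0, abs=1e-9)
    assert fit2.y_intercept_norm == pytest.approx(-0.2, abs=1e-9)
    fit3 = fit_threshold_linear(ctrl, ctrl)
    assert fit3.slope == pytest.approx(1.0) and fit3.y_intercept_norm == pytest.approx(0.0)


def test_threshold_linear_fit_exclusions():
    # fewer than 3 usable points -> unit excluded
    assert fit_threshold_linear(np.array([1.0, 0.5]), np.array([1.0, 0.5])) is None
    # the largest excluded point ("first below threshold") joins the fit once
    ctrl = np.array([0.02, 0.08, 0.5, 1.0])
    led = 0.5 * ctrl
    fit = fit_threshold_linear(ctrl, led)
    assert fit is not None and fit.n_points == 3  # two included + first-below


def _grid_search_line(x, y):
    """Brute-force least-squares line for the oracle comparison."""
    best = (np.inf, None, None)
    s_grid = np.linspace(-1, 3, 401)
    i_grid = np.linspace(-1, 1, 401)
    for _ in range(3):
        for s in s_grid:
            r = y - s * x
            for i in i_grid:
                sse = np.sum((r - i) ** 2)
                if sse < best[0]:
                    best = (sse, s, i)
        s_grid = best[1] + np.linspace(-0.02, 0.02, 81)
        i_grid = best[2] + np.linspace(-0.02, 0.02, 81)
    return best[1], best[2]


def test_least_squares_agrees_with_grid_search_oracle():
    rng = np.random.default_rng(4)
    for _ in range(4):
        x = np.sort(rng.uniform(0.2, 1.0, 7))
        y = 0.6 * x - 0.1 + rng.normal(0, 0.05, 7)
        fit = fit_threshold_linear(x / x.max(), y / x.max())
        xs, ys = x / x.max(), y / x.max()
        sel = (xs > 0.1) & (ys > 0.1)
        s, i = _grid_search_line(xs[sel], ys[sel])
        if sel.sum() == fit.n_points:
            assert fit.slope == pytest.approx(s, abs=1e-3)
            assert fit.y_intercept_norm == pytest.approx(i, abs=1e-3)


@pytest.mark.parametrize(
    "slope,intercept,mi,expected",
    [
        (0.5, 0.0, -0.4, GainClass.DIVISIVE),
        (0.9, -0.12, -0.4, GainClass.SUBTRACTIVE),
        (0.6, -0.1, -0.4, GainClass.MIXED),  # both suppressive criteria
        (1.3, 0.0, 0.4, GainClass.MULTIPLICATIVE),  # boundary inclusive
        (0.7, 0.0, -0.4, GainClass.DIVISIVE),  # boundary inclusive
        (1.0, 0.16, 0.4, GainClass.ADDITIVE),
        (1.5, 0.2, 0.4, GainClass.MIXED),  # both enhancing criteria
        (1.0, 0.0, 0.0, GainClass.NO_CHANGE),
        (1.0, 0.0, -0.5, GainClass.OTHER),  # MI changed but no criterion fires
    ],
)
def test_gain_classification(slope, intercept, mi, expected):
    fit = GainFit(slope=slope, y_intercept_norm=intercept, pearson_r=0.9,
                  good_fit=True, n_points=6)
    assert classify_gain(fit, mi) is expected


def test_gain_classification_requires_good_fit():
    fit = GainFit(slope=0.5, y_intercept_norm=0.0, pearson_r=0.2,
                  good_fit=False, n_points=6)
    assert classify_gain(fit, -0.4) is None


def test_fs_dynamics_rules():
    d = classify_fs_dynamics("u", (4.0, 2.0), (4.0, 2.0))  # gain 2 throughout
    assert d.category is FsCategory.SUSTAINED_ENHANCED
    d = classify_fs_dynamics("u", (6.0, 2.0), (1.0, 2.0))  # onset burst then drop
    assert d.category is FsCategory.TRANSIENT_ENHANCED
    d = classify_fs_dynamics("u", (2.0, 2.0), (0.5, 2.0))
    assert d.category is FsCategory.SUPPRESSED
    d = classify_fs_dynamics("u", (0.2, 0.2), (0.2, 0.2))  # low-rate rule
    assert d.category is FsCategory.NO_CHANGE


def test_arousal_mi_flat_for_constant_gain():
    g = 0.5
    rates = {b: (g * r, r) for b, r in zip(range(4), (8.0, 5.0, 4.0, 7.0))}
    out = mi_by_arousal(rates, 4)
    for b in range(4):
        assert out[b]["mi"] == pytest.approx((g - 1) / (g + 1))
    assert out[1]["rate_ctrl_norm"] == pytest.approx(5.0 / 6.0)
    out2 = mi_by_arousal({0: (1.0, 2.0), 1: None}, 2)
    assert np.isnan(out2[1]["mi"])
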