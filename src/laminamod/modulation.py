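"""Modulation-index statistics, tone responsiveness, tuning metrics, and
divisive/subtractive gain decomposition.

The modulation index MI = (L - C)/(L + C) compares activity in LED trials
(L) against interleaved No-LED controls (C); it is bounded in [-1, 1],
where -1 is a complete loss of activity, +1 the emergence of activity from
nothing, and 0 no change. Spontaneous-activity classes use |MI| > 1/9 (a
25% increase / 20% decrease); tone-evoked classes use the more conservative
|MI| > 1/6 (a 40% increase / ~29% decrease) because of trial variability.
The LED-versus-control relation of tone-evoked responses is decomposed into
multiplicative/divisive (slope) and additive/subtractive (intercept)
components with a threshold-linear fit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import AnalysisConfig, log


class ModClass(str, enum.Enum):
    ENHANCED = "enhanced"
    SUPPRESSED = "suppressed"
    UNCHANGED = "unchanged"


class GainClass(str, enum.Enum):
    MULTIPLICATIVE = "multiplicative"
    DIVISIVE = "divisive"
    ADDITIVE = "additive"
    SUBTRACTIVE = "subtractive"
    MIXED = "mixed"
    OTHER = "other"
    NO_CHANGE = "no_change"


class FsCategory(str, enum.Enum):
    SUSTAINED_ENHANCED = "sustained_enhanced"
    TRANSIENT_ENHANCED = "transient_enhanced"
    SUPPRESSED = "suppressed"
    NO_CHANGE = "no_change"


def compute_mi(L: float, C: float) -> float:
    """(L - C)/(L + C); NaN (undefined) when both activities are zero."""
    if L < 0 or C < 0:
        raise ValueError("activities must be nonnegative")
    if L + C == 0:
        return float("nan")
    return (L - C) / (L + C)


def classify_spontaneous(
    mi: float,
    rate_led_hz: float,
    rate_ctrl_hz: float,
    config: Optional[AnalysisConfig] = None,
) -> ModClass:
    """Enhanced / suppressed / unchanged from spontaneous MI.

    Units firing below the low-rate cutoff (0.4 Hz) in both conditions are
    classified unchanged regardless of MI, as are units with undefined MI.
    """
    config = config or AnalysisConfig()
    if rate_led_hz < config.low_rate_hz and rate_ctrl_hz < config.low_rate_hz:
        return ModClass.UNCHANGED
    if not np.isfinite(mi):
        return ModClass.UNCHANGED
    if mi > config.mi_threshold_spont:
        return ModClass.ENHANCED
    if mi < -config.mi_threshold_spont:
        return ModClass.SUPPRESSED
    return ModClass.UNCHANGED


def classify_evoked(mi: float, config: Optional[AnalysisConfig] = None) -> ModClass:
    """Evoked-activity class with the higher 1/6 threshold."""
    config = config or AnalysisConfig()
    if not np.isfinite(mi):
        return ModClass.UNCHANGED
    if mi > config.mi_threshold_evoked:
        return ModClass.ENHANCED
    if mi < -config.mi_threshold_evoked:
        return ModClass.SUPPRESSED
    return ModClass.UNCHANGED


def evoked_response(
    rate_hz: np.ndarray,
    bin_edges_s: np.ndarray,
    baseline_rate_hz: float,
    tone_dur_s: float,
) -> float:
    """Baseline-subtracted evoked response in spikes.

    Sum of the positive-going part of the PSTH during the tone, after
    subtracting the baseline rate measured 0-200 ms before tone onset in
    the same condition — so the response excludes any LED-induced change of
    the spontaneous rate. Negative-going bins contribute zero.
    """
    rate_hz = np.asarray(rate_hz, dtype=float)
    edges = np.asarray(bin_edges_s, dtype=float)
    widths = np.diff(edges)
    in_tone = (edges[:-1] >= 0.0) & (edges[:-1] < tone_dur_s)
    excess = np.maximum(rate_hz - baseline_rate_hz, 0.0)
    return float(np.sum(excess[in_tone] * widths[in_tone]))


def responsiveness_test(
    trial_rate_hz: np.ndarray,
    baseline_bins: np.ndarray,
    multiplier: float = 3.7,
    trial_frac: float = 1.0 / 3.0,
    response_bins: Optional[np.ndarray] = None,
) -> bool:
    """Two-criteria responsiveness test on per-trial PSTHs.

    ``trial_rate_hz`` is (n_trials, n_bins); ``baseline_bins`` and
    ``response_bins`` are boolean masks over bins. The threshold is the
    baseline mean plus ``multiplier`` times the SD of the trial-averaged
    baseline PSTH across its bins. A unit-frequency pair is responsive iff
    some response bin exceeds the threshold in more than ``trial_frac`` of
    trials AND the trial-averaged PSTH exceeds the threshold at some
    response bin.
    """
    x = np.asarray(trial_rate_hz, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a (n_trials >= 3, n_bins) matrix")
    baseline_bins = np.asarray(baseline_bins, dtype=bool)
    if response_bins is None:
        response_bins = ~baseline_bins
    base = x[:, baseline_bins].mean(axis=0)  # trial-averaged baseline PSTH
    mu, sd = float(base.mean()), float(base.std(ddof=0))
    if sd == 0.0:
        # degenerate baseline: fall back to the Poisson-expected bin SD
        sd = float(np.sqrt(max(mu, 1e-12)))
        log.debug("zero baseline SD; falling back to Poisson expectation")
    thresh = mu + multiplier * sd
    resp = x[:, response_bins]
    n_trials = x.shape[0]
    frac_exceeding = (resp > thresh).mean(axis=0)
    crit1 = bool(np.any(frac_exceeding > trial_frac))
    crit2 = bool(np.any(resp.mean(axis=0) > thresh))
    return crit1 and crit2


def calibrate_threshold_roc(
    trial_rates: Sequence[np.ndarray],
    baseline_bins: np.ndarray,
    labels: Sequence[bool],
    target_tpr: float = 0.9,
    grid: Optional[np.ndarray] = None,
    trial_frac: float = 1.0 / 3.0,
    response_bins: Optional[np.ndarray] = None,
) -> float:
    """Most stringent multiplier that still yields the target true-positive
    rate on a labeled set.

    Sweeps candidate multipliers (descending) and returns the largest one
    whose TPR over the positively-labeled examples reaches ``target_tpr``.
    """
    if grid is None:
        grid = np.arange(0.1, 10.0 + 1e-9, 0.1)
    labels = np.asarray(labels, dtype=bool)
    pos = [x for x, lab in zip(trial_rates, labels) if lab]
    if not pos:
        raise ValueError("no positive examples")
    best = None
    for m in sorted(grid, reverse=True):
        hits = sum(
            responsiveness_test(x, baseline_bins, m, trial_frac, response_bins) for x in pos
        )
        if hits / len(pos) >= target_tpr:
            best = float(m)
            break
    if best is None:
        max_tpr = max(
            sum(responsiveness_test(x, baseline_bins, float(grid.min()), trial_frac,
                                    response_bins) for x in pos) / len(pos),
            0.0,
        )
        raise ValueError(f"target TPR {target_tpr} unattainable; max achievable {max_tpr:.3f}")
    return best


@dataclass
class TuningCurve:
    """Evoked response per (frequency, condition), with responsive flags."""

    freqs_khz: np.ndarray
    evoked_ctrl: np.ndarray  # spikes, per frequency
    evoked_led: np.ndarray
    responsive_ctrl: np.ndarray  # bool per frequency
    responsive_led: np.ndarray

    def responsive_any(self) -> np.ndarray:
        return self.responsive_ctrl | self.responsive_led


def tuning_metrics(
    freqs_khz: np.ndarray,
    evoked: np.ndarray,
    responsive: np.ndarray,
) -> tuple[float, float]:
    """Best frequency and bandwidth for one condition.

    BF is the frequency with the maximal evoked response among responsive
    frequencies. BW70 is (number of responsive frequencies - 1) x 0.5
    octaves on the 0.5-octave tone grid (0 octaves when exactly one
    frequency is responsive; NaN when none are).
    """
    responsive = np.asarray(responsive, dtype=bool)
    if not np.any(responsive):
        return float("nan"), float("nan")
    freqs = np.asarray(freqs_khz, dtype=float)
    ev = np.where(responsive, np.asarray(evoked, dtype=float), -np.inf)
    bf = float(freqs[int(np.argmax(ev))])
    bw70 = 0.5 * (int(responsive.sum()) - 1)
    return bf, float(bw70)


@dataclass
class GainFit:
    """Threshold-linear fit of LED vs control tone-evoked responses."""

    slope: float
    y_intercept_norm: float
    pearson_r: float
    good_fit: bool
    n_points: int
    gain_class: Optional[GainClass] = None


def fit_threshold_linear(
    ctrl_responses: np.ndarray,
    led_responses: np.ndarray,
    include_frac: float = 0.10,
    good_fit_r: float = 0.4,
) -> Optional[GainFit]:
    """Least-squares line through the included (control, LED) points.

    Both response vectors are normalized to the unit's control best-
    frequency (peak) response. Points are included when both normalized
    responses exceed ``include_frac`` of the peak; the largest-response
    excluded point ("the first data point below the threshold") is included
    once. Returns None with fewer than 3 usable points (the unit is then
    excluded as poorly fit).
    """
    c = np.asarray(ctrl_responses, dtype=float)
    l = np.asarray(led_responses, dtype=float)
    peak = c.max() if c.size else 0.0
    if peak <= 0:
        return None
    c, l = c / peak, l / peak
    above = (c > include_frac) & (l > include_frac)
    sel = above.copy()
    below = np.flatnonzero(~above)
    if below.size:
        first_below = below[np.argmax(np.maximum(c[below], l[below]))]
        sel[first_below] = True
    if sel.sum() < 3:
        return None
    res = stats.linregress(c[sel], l[sel])
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 0.0
    return GainFit(
        slope=float(res.slope),
        y_intercept_norm=float(res.intercept),
        pearson_r=r,
        good_fit=bool(r > good_fit_r),
        n_points=int(sel.sum()),
    )


def classify_gain(
    fit: Optional[GainFit],
    overall_mi: float,
    config: Optional[AnalysisConfig] = None,
) -> Optional[GainClass]:
    """Gain class from the fitted slope and normalized intercept.

    Cut-offs (non-strict, as printed): slope >= 1.3 multiplicative,
    slope <= 0.7 divisive, intercept >= 0.15 additive, intercept <= -0.08
    subtractive. Two same-direction criteria give ``mixed``; opposing
    criteria give ``other``; neither criterion with an unchanged overall
    evoked MI gives ``no_change``.
    """
    config = config or AnalysisConfig()
    if fit is None or not fit.good_fit:
        return None
    div = fit.slope <= config.slope_divisive
    mult = fit.slope >= config.slope_multiplicative
    sub = fit.y_intercept_norm <= config.intercept_subtractive
    add = fit.y_intercept_norm >= config.intercept_additive
    if (div and sub) or (mult and add):
        cls = GainClass.MIXED
    elif (div and add) or (mult and sub):
        cls = GainClass.OTHER
    elif div:
        cls = GainClass.DIVISIVE
    elif mult:
        cls = GainClass.MULTIPLICATIVE
    elif sub:
        cls = GainClass.SUBTRACTIVE
    elif add:
        cls = GainClass.ADDITIVE
    else:
        cls = (
            GainClass.NO_CHANGE
            if (not np.isfinite(overall_mi))
            or abs(overall_mi) <= config.mi_threshold_evoked
            else GainClass.OTHER
        )
    fit.gain_class = cls
    return cls


@dataclass
class FsDynamics:
    """LED-onset dynamics category of one fast-spiking unit."""

    unit_id: str
    category: FsCategory
    onset_mi: float
    steady_mi: float


def classify_fs_dynamics(
    unit_id: str,
    onset_rates: tuple[float, float],
    steady_rates: tuple[float, float],
    config: Optional[AnalysisConfig] = None,
) -> FsDynamics:
    """Sustained/transient enhancement vs suppression of an FS unit.

    ``onset_rates`` and ``steady_rates`` are (LED, control) firing rates in
    the first 100 ms of LED and in the late steady-state window. Both MIs
    above 1/9 is sustained enhancement; onset-only enhancement is
    transient; steady-state suppression without onset enhancement is
    suppressed. The 0.4 Hz low-rate rule forces ``no_change``.
    """
    config = config or AnalysisConfig()
    thr = config.mi_threshold_spont
    onset_mi = compute_mi(*onset_rates)
    steady_mi = compute_mi(*steady_rates)
    all_rates = list(onset_rates) + list(steady_rates)
    if all(r < config.low_rate_hz for r in all_rates):
        cat = FsCategory.NO_CHANGE
    elif np.isfinite(onset_mi) and onset_mi > thr and np.isfinite(steady_mi) and steady_mi > thr:
        cat = FsCategory.SUSTAINED_ENHANCED
    elif np.isfinite(onset_mi) and onset_mi > thr:
        cat = FsCategory.TRANSIENT_ENHANCED
    elif np.isfinite(steady_mi) and steady_mi < -thr and (
        not np.isfinite(onset_mi) or onset_mi <= thr
    ):
        cat = FsCategory.SUPPRESSED
    else:
        cat = FsCategory.NO_CHANGE
    return FsDynamics(unit_id=unit_id, category=cat,
                      onset_mi=onset_mi, steady_mi=steady_mi)


def mi_by_arousal(
    rates_by_bin: dict,
    n_bins: int = 4,
) -> dict:
    """Per-arousal-bin MI and rates normalized to the No-LED grand mean.

    ``rates_by_bin`` maps bin index -> (rate_led, rate_ctrl) in Hz, or None
    for bins without trials. Normalization uses the mean control rate over
    the populated bins.
    """
    ctrl = [v[1] for v in rates_by_bin.values() if v is not None and np.isfinite(v[1])]
    grand = float(np.mean(ctrl)) if ctrl else np.nan
    out = {}
    for b in range(n_bins):
        v = rates_by_bin.get(b)
        if v is None or not all(np.isfinite(v)):
            out[b] = {"mi": np.nan, "rate_led_norm": np.nan, "rate_ctrl_norm": np.nan}
            continue
        rl, rc = v
        out[b] = {
            "mi": compute_mi(rl, rc),
            "rate_led_norm": rl / grand if grand else np.nan,
            "rate_ctrl_norm": rc / grand if grand else np.nan,
        }
    return out
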