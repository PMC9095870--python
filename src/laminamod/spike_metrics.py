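"""Unit-level spike-train primitives.

Regular- vs fast-spiking classification by waveform trough-to-peak width,
inter-spike-interval contamination screening, PSTH construction with
optional Gaussian smoothing, spontaneous-rate measurement per LED
condition, and multi-unit pooling with exclusion of putative directly
photoactivated units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_io import (
    Alignment,
    AnalysisConfig,
    CellClass,
    Psth,
    TrialTable,
    UnitRecord,
    log,
)


def classify_rs_fs(unit: UnitRecord, cutoff_ms: float = 0.4) -> CellClass:
    """FS iff trough-to-peak width <= cutoff (boundary inclusive); else RS."""
    if unit.trough_peak_ms is None:
        return CellClass.UNCLASSIFIED
    return CellClass.FS if unit.trough_peak_ms <= cutoff_ms else CellClass.RS


def isi_violation_rate(spike_times: np.ndarray, refractory_ms: float) -> float:
    """Fraction of inter-spike intervals shorter than the refractory period."""
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return 0.0
    isi = np.diff(t)
    return float(np.mean(isi < refractory_ms * 1e-3))


def contamination_ratio(
    spike_times: np.ndarray,
    refractory_ms: float,
    duration_s: Optional[float] = None,
) -> float:
    """Observed ISI-violation fraction over the chance fraction of a
    Poisson train with the unit's mean rate.

    For exponential ISIs at rate ``lambda`` the chance violation fraction is
    ``1 - exp(-lambda * t_ref)``; a ratio < 1 indicates fewer short
    intervals than a rate-matched Poisson process (i.e. a refractory
    period), a ratio near 1 indicates contamination at the Poisson level.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return 0.0
    duration = float(duration_s) if duration_s else float(t[-1] - t[0])
    if duration <= 0:
        return 0.0
    rate = t.size / duration
    chance = 1.0 - np.exp(-rate * refractory_ms * 1e-3)
    if chance <= 0:
        return 0.0
    return isi_violation_rate(t, refractory_ms) / chance


def is_single_unit(
    spike_times: np.ndarray,
    refractory_ms: float,
    max_frac: float = 0.05,
    duration_s: Optional[float] = None,
) -> bool:
    """Single-unit flag: the rate-corrected contamination stays below the
    acceptable violation fraction (default 5%)."""
    return contamination_ratio(spike_times, refractory_ms, duration_s) < max_frac


def trial_count_matrix(
    spike_times: np.ndarray,
    events_s: np.ndarray,
    bin_ms: float,
    window_s: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial spike counts: returns (counts (n_trials, n_bins), edges)."""
    t0, t1 = window_s
    bin_s = bin_ms * 1e-3
    n_bins = round((t1 - t0) / bin_s)
    if not np.isclose(n_bins * bin_s, t1 - t0):
        raise ValueError("bin size must divide the window evenly")
    edges = t0 + bin_s * np.arange(n_bins + 1)
    events_s = np.asarray(events_s, dtype=float)
    counts = np.empty((events_s.size, n_bins), dtype=float)
    st = np.asarray(spike_times, dtype=float)
    for i, ev in enumerate(events_s):
        counts[i] = np.histogram(st - ev, bins=edges)[0]
    return counts, edges


def build_psth(
    spike_times: np.ndarray,
    events_s: np.ndarray,
    bin_ms: float,
    window_s: tuple[float, float],
    alignment: Alignment = Alignment.TONE_ONSET,
    baseline_window_s: Optional[tuple[float, float]] = None,
    smooth_ms: Optional[float] = None,
) -> Psth:
    """Trial-averaged PSTH: rate[b] = count[b] / (n_trials * bin_s).

    ``smooth_ms`` applies a Gaussian kernel of that SD (used only where the
    analysis calls for it, e.g. before exponential fitting).
    """
    events_s = np.asarray(events_s, dtype=float)
    if events_s.size == 0:
        raise ValueError("PSTH needs at least one trial")
    counts, edges = trial_count_matrix(spike_times, events_s, bin_ms, window_s)
    rate = counts.sum(axis=0) / (events_s.size * bin_ms * 1e-3)
    if smooth_ms is not None:
        rate = ndimage.gaussian_filter1d(rate, sigma=smooth_ms / bin_ms, mode="nearest")
    return Psth(
        bin_edges_s=edges,
        rate_hz=np.maximum(rate, 0.0),
        n_trials=int(events_s.size),
        alignment=alignment,
        baseline_window_s=baseline_window_s,
    )


def _window_rate(spike_times: np.ndarray, starts: np.ndarray, dur_s: float) -> float:
    st = np.asarray(spike_times, dtype=float)
    total = 0
    for s in starts:
        total += np.searchsorted(st, s + dur_s) - np.searchsorted(st, s)
    return total / (starts.size * dur_s) if starts.size else np.nan


def spontaneous_rate(
    spike_times: np.ndarray,
    trials: TrialTable,
    window_s: float = 0.5,
) -> dict:
    """Mean firing rate in the pre-tone window, per LED condition.

    The window is the ``window_s`` seconds immediately preceding the tone;
    on LED trials this window lies after the LED onset (the LED starts 1 s
    before the tone), so it measures the LED steady state.
    """
    out = {}
    for led in (False, True):
        onsets = trials.tone_onsets(led_on=led)
        starts = onsets - window_s
        out["led" if led else "control"] = (
            _window_rate(spike_times, starts, window_s) if starts.size else np.nan
        )
    return out


@dataclass
class MultiUnitPool:
    """Pooled multi-unit spike train over a scope (depth bin / layer / region)."""

    member_ids: list
    scope: str
    spike_times: np.ndarray
    excluded: dict = field(default_factory=dict)  # unit_id -> reason

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def led_onset_mi(
    spike_times: np.ndarray, trials: TrialTable, window_s: float = 0.05
) -> float:
    """MI of firing in the first ``window_s`` of LED vs the matched
    pre-LED window, used to screen directly photoactivated units."""
    led_starts = trials.led_onsets()
    if led_starts.size == 0:
        return np.nan
    l = _window_rate(spike_times, led_starts, window_s)
    c = _window_rate(spike_times, led_starts - window_s, window_s)
    if l + c == 0 or not np.isfinite(l + c):
        return np.nan
    return (l - c) / (l + c)


def pool_multiunit(
    units: Sequence[UnitRecord],
    scope: str,
    trials: Optional[TrialTable] = None,
    config: Optional[AnalysisConfig] = None,
    exclude_photoactivated: bool = True,
) -> MultiUnitPool:
    """Merge spikes of the given units into one multi-unit train.

    Putative directly photoactivated units (LED-onset MI above the
    configured threshold in the first 50 ms of LED) are excluded so they do
    not dominate the pooled count.
    """
    config = config or AnalysisConfig()
    members, excluded, trains = [], {}, []
    for u in units:
        if exclude_photoactivated and trials is not None:
            mi0 = led_onset_mi(u.spike_times, trials, config.photoactivated_window_s)
            if np.isfinite(mi0) and mi0 > config.photoactivated_mi:
                excluded[u.unit_id] = "photoactivated"
                continue
        members.append(u.unit_id)
        trains.append(u.spike_times)
    if not members:
        log.warning("empty multi-unit pool for scope %s", scope)
        pooled = np.empty(0)
    else:
        pooled = np.sort(np.concatenate(trains)) if trains else np.empty(0)
    return MultiUnitPool(member_ids=members, scope=scope, spike_times=pooled, excluded=excluded)
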