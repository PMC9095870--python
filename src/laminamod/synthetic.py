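"""Synthetic experiment generator with known ground truth.

Emulates the statistical structure the analysis assumes: layer-structured
inhomogeneous-Poisson units whose rate during LED illumination approaches a
multiplicative steady-state gain through a delayed fast+slow exponential
onset, Gaussian log-frequency tuning over nine tones (4-64 kHz, 0.5-octave
steps, 200 ms, nine repeats per condition), interleaved LED / No-LED trials
with the LED lasting 1 s before and after the tone, a click-evoked LFP whose
second spatial derivative has a known early sink inside L4, biphasic
("transient") fast-spiking dynamics, and an infrared eye movie of a noisy
dark ellipse whose diameter co-varies with a U-shaped firing-rate modifier.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_io import (
    CellClass,
    LaminarMap,
    Layer,
    LfpSnippet,
    TONE_FREQS_KHZ,
    TrialTable,
    UnitRecord,
    log,
)
import pandas as pd

CORTICAL_LAYERS = (Layer.L1_3, Layer.L4, Layer.L5, Layer.L6)


@dataclass
class LayerKinetics:
    """Onset kinetics of the LED-induced rate change in one layer.

    The rate factor approaches the steady-state gain ``g`` as
    ``f(t) = 1 + (g - 1) * S(t)`` with
    ``S(t) = w_f (1 - e^{-(t-d)/tau_f}) + (1 - w_f)(1 - e^{-(t-d-d2)/tau_s})``
    (each term zero before its delay), so a normalized PSTH during
    suppression is exactly the dual-exponential model the kinetics module
    fits, with fast amplitude ``(1-g) w_f`` and slow amplitude
    ``(1-g)(1-w_f)``.
    """

    delay_ms: float = 5.0
    fast_frac: float = 1.0
    tau_fast_ms: float = 10.0
    tau_slow_ms: float = 80.0
    slow_extra_delay_ms: float = 0.0

    def factor(self, t_s: np.ndarray, gain: float) -> np.ndarray:
        """Rate factor at times ``t_s`` (seconds) after LED onset."""
        t = np.asarray(t_s, dtype=float) * 1e3  # ms
        d1 = self.delay_ms
        d2 = self.delay_ms + self.slow_extra_delay_ms
        fast = np.where(t > d1, 1.0 - np.exp(-np.maximum(t - d1, 0.0) / self.tau_fast_ms), 0.0)
        slow = np.where(t > d2, 1.0 - np.exp(-np.maximum(t - d2, 0.0) / self.tau_slow_ms), 0.0)
        s = self.fast_frac * fast + (1.0 - self.fast_frac) * slow
        return 1.0 + (gain - 1.0) * s


@dataclass
class UnitTruth:
    unit_id: str
    layer: Layer
    depth_um: float
    cell_class: CellClass
    trough_peak_ms: float
    baseline_rate_hz: float
    led_gain: float
    best_freq_khz: float
    bandwidth_octaves: float
    peak_evoked_hz: float
    fs_dynamics: str = "none"  # sustained | transient | suppressed | none
    onset_gain: float = 1.0  # transient excess at LED onset (FS biphasic)


@dataclass
class GroundTruth:
    """Everything the generators decided, for recovery checks downstream."""

    laminar: LaminarMap
    layer_gains: dict
    layer_kinetics: dict
    units: dict = field(default_factory=dict)  # unit_id -> UnitTruth
    pupil_vertex: float = 0.5
    pupil_coeff: float = 1.6
    pupil_base: float = 0.8
    evoked_onset_ms: float = 10.0
    evoked_decay_tau_ms: float = 30.0
    lfp_sink_channel: Optional[int] = None
    pupil_diameter_px: Optional[np.ndarray] = None
    pupil_occluded: Optional[np.ndarray] = None

    def pupil_modifier(self, p: np.ndarray) -> np.ndarray:
        """U-shaped multiplicative rate modifier vs normalized diameter."""
        p = np.asarray(p, dtype=float)
        return self.pupil_base + self.pupil_coeff * (p - self.pupil_vertex) ** 2


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions emulated."""

    # units per layer
    n_rs_per_layer: int = 20
    n_fs_per_layer: int = 4
    # column geometry (um below pia)
    surface_um: float = 0.0
    l4_upper_um: float = 400.0
    l4_lower_um: float = 500.0
    wm_um: float = 1100.0
    # steady-state LED gains per layer for RS units (L5 photoactivated;
    # superficial layers suppressed more strongly than L4, L6 variable)
    rs_layer_gains: tuple = (0.3, 0.55, 2.5, 0.9)
    gain_jitter_sd: float = 0.10  # lognormal sd of per-unit gain
    # baseline rates (uniform ranges, Hz)
    rs_rate_range: tuple = (2.0, 8.0)
    fs_rate_range: tuple = (5.0, 15.0)
    # waveform widths (ms)
    rs_width_range: tuple = (0.45, 1.0)
    fs_width_range: tuple = (0.15, 0.4)
    # FS dynamics in L2/3-L4: fractions of transient / sustained / suppressed
    fs_transient_frac: float = 0.4
    fs_sustained_frac: float = 0.2
    fs_suppressed_frac: float = 0.4
    fs_onset_gain: float = 3.0
    fs_onset_tau_ms: float = 40.0
    fs_steady_gain: float = 0.5
    # stimulus protocol
    n_reps: int = 9
    tone_dur_s: float = 0.2
    iti_s: float = 3.5
    led_pre_s: float = 1.0
    led_post_s: float = 1.0
    # tuning
    tuning_sigma_oct: float = 0.5
    peak_evoked_range: tuple = (10.0, 40.0)
    evoked_onset_ms: float = 10.0
    evoked_decay_tau_ms: float = 30.0
    # pupil coupling (U-shape) and trajectory
    pupil_vertex: float = 0.5
    pupil_coeff: float = 1.6
    pupil_base: float = 0.8
    pupil_walk_sd: float = 0.08
    # optional absolute refractory dead time (ms); None = pure Poisson
    dead_time_ms: Optional[float] = None
    # LFP / CSD
    lfp_n_channels: int = 45
    lfp_spacing_um: float = 25.0
    lfp_sink_sigma_um: float = 80.0
    lfp_snr: float = 10.0
    lfp_t_start_ms: float = -50.0
    lfp_t_stop_ms: float = 100.0
    lfp_dt_ms: float = 0.5
    lfp_sink_peak_ms: float = 10.0
    lfp_sink_width_ms: float = 4.0
    # pupil movie
    movie_n_frames: int = 90
    movie_fps: float = 30.0
    movie_shape: tuple = (120, 160)
    movie_iris_radius_px: int = 45
    movie_diameter_range_px: tuple = (20.0, 50.0)
    movie_noise_sd: float = 6.0
    movie_occluded_frac: float = 0.0
    movie_eyelid_rows: int = 12

    @property
    def laminar(self) -> LaminarMap:
        return LaminarMap(self.surface_um, self.l4_upper_um, self.l4_lower_um, self.wm_um)


#: Layer-wise onset kinetics of the LED effect. Superficial layers carry a
#: short-delay dual-exponential (fast intracortical + slow subcortical)
#: component; L4 a longer-delay single exponential; L5 is directly driven.
DEFAULT_LAYER_KINETICS = {
    Layer.L1_3: LayerKinetics(delay_ms=9.0, fast_frac=0.63, tau_fast_ms=3.0,
                              tau_slow_ms=18.0, slow_extra_delay_ms=5.0),
    Layer.L4: LayerKinetics(delay_ms=18.5, fast_frac=1.0, tau_fast_ms=15.0),
    Layer.L5: LayerKinetics(delay_ms=2.0, fast_frac=1.0, tau_fast_ms=5.0),
    Layer.L6: LayerKinetics(delay_ms=12.0, fast_frac=1.0, tau_fast_ms=20.0),
}


def _layer_bounds(cfg: SimConfig, layer: Layer) -> tuple[float, float]:
    lm = cfg.laminar
    mid = lm.l56_midpoint_um
    return {
        Layer.L1_3: (lm.surface_depth_um, lm.l4_upper_um),
        Layer.L4: (lm.l4_upper_um, lm.l4_lower_um),
        Layer.L5: (lm.l4_lower_um, mid),
        Layer.L6: (mid, lm.wm_depth_um),
    }[layer]


def generate_units(cfg: SimConfig, seed: int) -> tuple[list[UnitRecord], GroundTruth]:
    """Draw layer-structured units with class-specific waveform widths.

    FS widths are <= 0.4 ms and RS widths > 0.4 ms by construction.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        laminar=cfg.laminar,
        layer_gains={lay: g for lay, g in zip(CORTICAL_LAYERS, cfg.rs_layer_gains)},
        layer_kinetics={lay: DEFAULT_LAYER_KINETICS[lay] for lay in CORTICAL_LAYERS},
        pupil_vertex=cfg.pupil_vertex,
        pupil_coeff=cfg.pupil_coeff,
        pupil_base=cfg.pupil_base,
        evoked_onset_ms=cfg.evoked_onset_ms,
        evoked_decay_tau_ms=cfg.evoked_decay_tau_ms,
    )
    units: list[UnitRecord] = []
    if cfg.n_rs_per_layer == 0 and cfg.n_fs_per_layer == 0:
        log.warning("zero units requested")
        return units, truth
    fs_cats = ["transient", "sustained", "suppressed"]
    fs_probs = [cfg.fs_transient_frac, cfg.fs_sustained_frac, cfg.fs_suppressed_frac]
    rest = 1.0 - sum(fs_probs)
    fs_cats.append("none")
    fs_probs.append(max(rest, 0.0))
    fs_probs = np.asarray(fs_probs) / np.sum(fs_probs)

    for layer, layer_gain in zip(CORTICAL_LAYERS, cfg.rs_layer_gains):
        lo, hi = _layer_bounds(cfg, layer)
        for cls, n in ((CellClass.RS, cfg.n_rs_per_layer), (CellClass.FS, cfg.n_fs_per_layer)):
            for i in range(n):
                uid = f"{layer.value}_{cls.value}_{i:03d}"
                depth = float(rng.uniform(lo, hi))
                if cls is CellClass.RS:
                    width = float(rng.uniform(*cfg.rs_width_range))
                    rate = float(rng.uniform(*cfg.rs_rate_range))
                    gain = float(layer_gain * rng.lognormal(0.0, cfg.gain_jitter_sd))
                    dyn, onset_gain = "none", 1.0
                else:
                    width = float(rng.uniform(*cfg.fs_width_range))
                    rate = float(rng.uniform(*cfg.fs_rate_range))
                    if layer in (Layer.L1_3, Layer.L4):
                        dyn = str(rng.choice(fs_cats, p=fs_probs))
                    else:
                        dyn = "none"
                    if dyn == "sustained":
                        gain, onset_gain = 2.0, 1.0
                    elif dyn == "transient":
                        gain, onset_gain = cfg.fs_steady_gain, cfg.fs_onset_gain
                    elif dyn == "suppressed":
                        gain, onset_gain = cfg.fs_steady_gain, 1.0
                    else:
                        gain, onset_gain = 1.0, 1.0
                truth.units[uid] = UnitTruth(
                    unit_id=uid,
                    layer=layer,
                    depth_um=depth,
                    cell_class=cls,
                    trough_peak_ms=width,
                    baseline_rate_hz=rate,
                    led_gain=gain,
                    best_freq_khz=float(rng.choice(TONE_FREQS_KHZ)),
                    bandwidth_octaves=cfg.tuning_sigma_oct,
                    peak_evoked_hz=float(rng.uniform(*cfg.peak_evoked_range)),
                    fs_dynamics=dyn,
                    onset_gain=onset_gain,
                )
                units.append(
                    UnitRecord(
                        unit_id=uid,
                        spike_times=np.empty(0),
                        depth_um=depth,
                        trough_peak_ms=width,
                        cell_class=cls,
                    )
                )
    return units, truth


def generate_trials(cfg: SimConfig, seed: int) -> TrialTable:
    """Interleaved LED/No-LED tone trials: 9 frequencies x n_reps x 2."""
    rng = np.random.default_rng(seed)
    freqs = np.repeat(np.asarray(TONE_FREQS_KHZ), cfg.n_reps * 2)
    led = np.tile(np.array([True, False]), freqs.size // 2)
    order = rng.permutation(freqs.size)
    freqs, led = freqs[order], led[order]
    onsets = cfg.iti_s * (np.arange(freqs.size) + 1.0)
    # bounded random walk of arousal across trials
    p = np.empty(freqs.size)
    p[0] = 0.5
    steps = rng.normal(0.0, cfg.pupil_walk_sd, freqs.size - 1)
    for k in range(1, freqs.size):
        p[k] = np.clip(p[k - 1] + steps[k - 1], 0.02, 0.98)
    df = pd.DataFrame(
        {
            "trial_id": np.arange(freqs.size),
            "tone_freq_khz": freqs,
            "tone_onset_s": onsets,
            "tone_dur_s": cfg.tone_dur_s,
            "led_on": led,
            "led_onset_s": np.where(led, onsets - cfg.led_pre_s, np.nan),
            "led_offset_s": np.where(led, onsets + cfg.tone_dur_s + cfg.led_post_s, np.nan),
            "pupil_baseline_norm": p,
        }
    )
    return TrialTable(df)


def _evoked_shape(cfg: SimConfig, dt_s: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular-rise / exponential-decay evoked rate template (peak 1)."""
    onset = cfg.evoked_onset_ms * 1e-3
    tau = cfg.evoked_decay_tau_ms * 1e-3
    t = np.arange(0.0, cfg.tone_dur_s + 5.0 * tau, dt_s)
    shape = np.where(
        t < onset, 0.0, np.where(t < cfg.tone_dur_s, 1.0, np.exp(-(t - cfg.tone_dur_s) / tau))
    )
    return t, shape


def generate_spikes(
    units: list[UnitRecord],
    trials: TrialTable,
    truth: GroundTruth,
    seed: int,
    cfg: Optional[SimConfig] = None,
) -> list[UnitRecord]:
    """Sample inhomogeneous-Poisson spike trains for every unit.

    rate(t) = baseline x pupil_modifier x led_factor(t) + tuning_response(t);
    LED modulation is applied by exact thinning (factor < 1) plus additive
    Poisson spikes (factor > 1), so counts in any window are Poisson with
    the integrated rate.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    df = trials.df
    onsets = df["tone_onset_s"].to_numpy(dtype=float)
    pupil = df["pupil_baseline_norm"].to_numpy(dtype=float)
    led_on = df["led_on"].to_numpy(dtype=bool)
    led_onset = df["led_onset_s"].to_numpy(dtype=float)
    led_offset = df["led_offset_s"].to_numpy(dtype=float)
    freqs = df["tone_freq_khz"].to_numpy(dtype=float)
    # segment boundaries: halfway between consecutive tone onsets
    mids = np.concatenate(([0.0], 0.5 * (onsets[:-1] + onsets[1:]),
                           [onsets[-1] + cfg.iti_s]))
    seg_start, seg_end = mids[:-1], mids[1:]
    shape_t, shape = _evoked_shape(cfg)
    shape_dt = shape_t[1] - shape_t[0]
    shape_int = float(np.sum(shape) * shape_dt)  # integral of template (s)
    shape_cdf = np.cumsum(shape) / np.sum(shape)
    n_clipped = 0

    out: list[UnitRecord] = []
    for u in units:
        ut = truth.units[u.unit_id]
        kin = truth.layer_kinetics[ut.layer]
        base = ut.baseline_rate_hz * truth.pupil_modifier(pupil)  # per trial
        # 1) baseline spikes, piecewise-constant rate per trial segment
        durs = seg_end - seg_start
        counts = rng.poisson(np.maximum(base, 0.0) * durs)
        spikes = rng.random(int(counts.sum())) * np.repeat(durs, counts) + np.repeat(
            seg_start, counts
        )
        # 2) LED modulation of the baseline process
        extras = []
        keep = np.ones(spikes.size, dtype=bool)
        for k in np.flatnonzero(led_on):
            t0, t1 = led_onset[k], led_offset[k]
            in_win = (spikes >= t0) & (spikes < t1)
            if np.any(in_win):
                f = _unit_factor(spikes[in_win] - t0, ut, kin, cfg)
                keep[in_win] &= rng.random(int(in_win.sum())) < np.minimum(f, 1.0)
            # additive part where factor > 1
            grid = np.arange(t0, t1, 1e-3)
            f = _unit_factor(grid - t0, ut, kin, cfg)
            excess = np.maximum(f - 1.0, 0.0) * base[k]
            if np.any(excess > 0):
                c = rng.poisson(excess * 1e-3)
                tot = int(c.sum())
                if tot:
                    extras.append(np.repeat(grid, c) + rng.random(tot) * 1e-3)
        spikes = spikes[keep]
        # 3) tone-evoked additive bumps
        doct = np.log2(freqs / ut.best_freq_khz)
        amp = ut.peak_evoked_hz * np.exp(-(doct ** 2) / (2.0 * ut.bandwidth_octaves ** 2))
        amp = np.where(led_on, amp * min(ut.led_gain, 2.0), amp)
        neg = amp < 0
        if np.any(neg):
            n_clipped += int(neg.sum())
            amp = np.maximum(amp, 0.0)
        for k in range(len(df)):
            if amp[k] * shape_int < 1e-4:
                continue
            n = rng.poisson(amp[k] * shape_int)
            if n:
                q = rng.random(n)
                times = np.interp(q, shape_cdf, shape_t)
                extras.append(onsets[k] + times)
        if extras:
            spikes = np.concatenate([spikes] + extras)
        spikes.sort()
        if cfg.dead_time_ms is not None and spikes.size:
            spikes = _apply_dead_time(spikes, cfg.dead_time_ms * 1e-3)
        out.append(
            UnitRecord(
                unit_id=u.unit_id,
                spike_times=spikes,
                depth_um=u.depth_um,
                trough_peak_ms=u.trough_peak_ms,
                is_single_unit=u.is_single_unit,
                cell_class=u.cell_class,
                layer=u.layer,
            )
        )
    if n_clipped:
        log.warning("clipped %d negative composite rates to 0", n_clipped)
    return out


def _unit_factor(t_s: np.ndarray, ut: UnitTruth, kin: LayerKinetics, cfg: SimConfig) -> np.ndarray:
    """LED rate factor for one unit, including biphasic FS onset dynamics."""
    f = kin.factor(t_s, ut.led_gain)
    if ut.fs_dynamics == "transient" and ut.onset_gain > 1.0:
        t_ms = np.asarray(t_s, dtype=float) * 1e3
        d = kin.delay_ms
        tr = np.where(
            t_ms > d,
            (ut.onset_gain - 1.0) * np.exp(-np.maximum(t_ms - d, 0.0) / cfg.fs_onset_tau_ms),
            0.0,
        )
        f = f + tr
    return f


def _apply_dead_time(spikes: np.ndarray, dead_s: float) -> np.ndarray:
    keep = np.ones(spikes.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(spikes):
        if t - last < dead_s:
            keep[i] = False
        else:
            last = t
    return spikes[keep]


def generate_lfp(cfg: SimConfig, seed: int) -> tuple[LfpSnippet, int]:
    """Click-aligned LFP whose CSD has a known early sink centered in L4.

    The potential is a negative spatial Gaussian at the L4 center with an
    early temporal bump, so the discrete second difference (CSD) has a sink
    (negative) at the center channel. Returns the snippet and the true sink
    channel index.
    """
    if cfg.lfp_n_channels < 5:
        raise ValueError("CSD needs at least 5 channels")
    rng = np.random.default_rng(seed)
    depths = cfg.surface_um + cfg.lfp_spacing_um * np.arange(cfg.lfp_n_channels)
    t = np.arange(cfg.lfp_t_start_ms, cfg.lfp_t_stop_ms, cfg.lfp_dt_ms)
    center_um = 0.5 * (cfg.l4_upper_um + cfg.l4_lower_um)
    sink_ch = int(np.argmin(np.abs(depths - center_um)))
    u = (depths - depths[sink_ch]) / cfg.lfp_sink_sigma_um
    g = np.exp(-((t - cfg.lfp_sink_peak_ms) ** 2) / (2.0 * cfg.lfp_sink_width_ms ** 2))
    # potential scaled so the continuous CSD sink amplitude is ~1; the white
    # potential noise is scaled so the CSD-domain noise SD is sink/snr
    # (the second difference amplifies white noise by sqrt(6)/h^2)
    v = -cfg.lfp_sink_sigma_um**2 * np.outer(np.exp(-(u ** 2) / 2.0), g)
    noise_sd = cfg.lfp_spacing_um**2 / (np.sqrt(6.0) * cfg.lfp_snr)
    noise = rng.normal(0.0, noise_sd, v.shape)
    return LfpSnippet(data=v + noise, channel_depths_um=depths, time_s=t * 1e-3), sink_ch


def generate_pupil_movie(
    cfg: SimConfig, seed: int, diameter_px: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Noisy dark-pupil movie.

    Returns ``(movie uint8 (n, h, w), frame_times_s, true_diameter_px,
    occluded flags)``. Occluded frames carry a dark eyelid band across the
    top of the frame reaching into the pupil.
    """
    rng = np.random.default_rng(seed)
    h, w = cfg.movie_shape
    n = cfg.movie_n_frames
    lo, hi = cfg.movie_diameter_range_px
    if diameter_px is None:
        # smooth bounded walk between lo and hi
        x = np.empty(n)
        x[0] = 0.5
        for k in range(1, n):
            x[k] = np.clip(x[k - 1] + rng.normal(0.0, 0.05), 0.0, 1.0)
        diameter_px = lo + (hi - lo) * x
    diameter_px = np.asarray(diameter_px, dtype=float)
    if np.any(diameter_px >= min(h, w)):
        raise ValueError("pupil diameter exceeds frame size")
    occluded = rng.random(n) < cfg.movie_occluded_frac
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    iris = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.movie_iris_radius_px ** 2
    movie = np.empty((n, h, w), dtype=np.uint8)
    for k in range(n):
        frame = np.full((h, w), 200.0)
        frame[iris] = 140.0
        r = diameter_px[k] / 2.0
        pupil = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        frame[pupil] = 30.0
        if occluded[k]:
            frame[: cy - int(r // 2), :] = 25.0  # eyelid covering down into the pupil
        frame += rng.normal(0.0, cfg.movie_noise_sd, (h, w))
        movie[k] = np.clip(frame, 0, 255).astype(np.uint8)
    times = np.arange(n) / cfg.movie_fps
    return movie, times, diameter_px, occluded
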