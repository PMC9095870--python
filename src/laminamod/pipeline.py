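"""End-to-end analysis: simulate -> layers -> analyze -> kinetics -> pupil.

The figure-level analyses (per-unit spontaneous and tone-evoked modulation,
laminar MI profiles on the normalized column, threshold-linear gain
decomposition, FS LED-onset dynamics, arousal-conditioned MI, and per-layer
suppression kinetics) are plain functions over the domain objects; the
pipeline stage runner wires them together through the on-disk dataset
formats so each stage is independently reproducible. A single global seed
is expanded into per-stage child seeds as ``stage_seed = (seed * 8 + k)
mod 2^31`` for stage index k.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import laminar as lam_mod
from . import modulation as mod
from . import pupil as pupil_mod
from . import spike_metrics as sm
from . import synthetic as syn
from .core_io import (
    Alignment,
    AnalysisConfig,
    CellClass,
    LaminarMap,
    Layer,
    TrialTable,
    UnitRecord,
    log,
    read_dataset,
    write_dataset,
    write_nested,
    write_table,
)

__version__ = "0.1.0"


def stage_seed(seed: int, k: int) -> int:
    return (seed * 8 + k) % (2**31)


# ---------------------------------------------------------------------------
# spontaneous modulation
# ---------------------------------------------------------------------------

def spontaneous_table(
    units: Sequence[UnitRecord],
    trials: TrialTable,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Per-unit spontaneous rates (LED / control), MI, and class."""
    config = config or AnalysisConfig()
    rows = []
    for u in units:
        rates = sm.spontaneous_rate(u.spike_times, trials, config.spont_window_s)
        rl, rc = rates["led"], rates["control"]
        mi = mod.compute_mi(rl, rc) if np.isfinite(rl + rc) else float("nan")
        rows.append(
            {
                "unit_id": u.unit_id,
                "layer": u.layer.value if u.layer else "",
                "cell_class": u.cell_class.value,
                "conservative_l6": u.conservative_l6,
                "rate_ctrl_hz": rc,
                "rate_led_hz": rl,
                "mi": mi,
                "mod_class": mod.classify_spontaneous(mi, rl, rc, config).value,
            }
        )
    return pd.DataFrame(rows)


def laminar_mi_profile(
    units: Sequence[UnitRecord],
    trials: TrialTable,
    lam: LaminarMap,
    config: Optional[AnalysisConfig] = None,
    cell_class: CellClass = CellClass.RS,
) -> pd.DataFrame:
    """Multi-unit spontaneous MI per normalized-depth bin.

    Spikes of same-class units are pooled within each depth bin (putative
    photoactivated units excluded), and the MI of the pooled spontaneous
    rate is computed per bin — the laminar profile of the LED effect.
    """
    config = config or AnalysisConfig()
    scheme = (
        config.rs_bins_per_layer if cell_class is CellClass.RS else config.fs_bins_per_layer
    )
    sel = [u for u in units if u.cell_class is cell_class and u.layer is not Layer.OUTSIDE]
    bins = lam_mod.normalize_depths(sel, lam, scheme)
    rows = []
    for b in range(bins.n_bins):
        members = [u for u in sel if bins.bin_index[u.unit_id] == b]
        pool = sm.pool_multiunit(members, scope=f"depth_bin_{b}", trials=trials, config=config)
        if pool.spike_times.size:
            rates = sm.spontaneous_rate(pool.spike_times, trials, config.spont_window_s)
            mi = mod.compute_mi(rates["led"], rates["control"])
        else:
            mi = float("nan")
        rows.append({"depth_bin": b, "n_units": pool.n_members, "mi": mi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tone-evoked modulation, tuning, gain decomposition
# ---------------------------------------------------------------------------

@dataclass
class EvokedResult:
    unit_id: str
    freqs_khz: np.ndarray
    evoked_ctrl: np.ndarray
    evoked_led: np.ndarray
    responsive_ctrl: np.ndarray
    responsive_led: np.ndarray
    bf_ctrl: float
    bf_led: float
    bw70_ctrl: float
    bw70_led: float
    overall_mi: float
    pair_mi: np.ndarray  # per frequency; NaN where the pair is unresponsive
    gain_fit: Optional[mod.GainFit]
    gain_class: Optional[mod.GainClass]

    @property
    def responsive_any(self) -> np.ndarray:
        return self.responsive_ctrl | self.responsive_led

    @property
    def is_responsive_unit(self) -> bool:
        return bool(np.any(self.responsive_any))


def analyze_evoked_unit(
    unit: UnitRecord,
    trials: TrialTable,
    config: Optional[AnalysisConfig] = None,
) -> EvokedResult:
    """Tone-evoked analysis of one unit across the nine frequencies.

    Per frequency and LED condition: per-trial PSTHs at 25-ms bins; the
    responsiveness threshold uses the single-trial baseline bins from
    before the LED (the pre-tone window on control trials, the pre-LED
    window on LED trials); evoked responses are the positive-going,
    baseline-subtracted PSTH sum during the tone, with the baseline taken
    0-200 ms before the tone within the same condition so LED-induced
    changes in spontaneous rate do not leak into the evoked measure.
    """
    config = config or AnalysisConfig()
    freqs = trials.frequencies
    tone_dur = float(trials.tone_trials["tone_dur_s"].iloc[0])
    bin_ms = config.psth_bin_ms
    bin_s = bin_ms * 1e-3
    nf = freqs.size
    evoked = {False: np.zeros(nf), True: np.zeros(nf)}
    responsive = {False: np.zeros(nf, dtype=bool), True: np.zeros(nf, dtype=bool)}
    tone_bins = round(tone_dur / bin_s)
    base_bins = round(config.evoked_baseline_s / bin_s)

    for j, f in enumerate(freqs):
        for led in (False, True):
            onsets = trials.tone_onsets(led_on=led, freq_khz=f)
            if onsets.size < 3:
                continue
            # response + same-condition baseline, tone-aligned
            counts, edges = sm.trial_count_matrix(
                unit.spike_times, onsets, bin_ms,
                (-config.evoked_baseline_s, tone_dur),
            )
            rate = counts / bin_s
            base_rate = float(rate[:, :base_bins].mean())
            mean_rate = rate[:, base_bins:].mean(axis=0)
            evoked[led][j] = mod.evoked_response(
                mean_rate, edges[base_bins:], base_rate, tone_dur
            )
            # pre-LED baseline for the responsiveness threshold
            if led:
                pre, _ = sm.trial_count_matrix(
                    unit.spike_times, onsets, bin_ms,
                    (-1.0 - config.evoked_baseline_s, -1.0),
                )
            else:
                pre = counts[:, :base_bins]
            mat = np.hstack([pre / bin_s, rate[:, base_bins:]])
            masks = np.zeros(mat.shape[1], dtype=bool)
            masks[: pre.shape[1]] = True
            responsive[led][j] = mod.responsiveness_test(
                mat, masks, config.resp_multiplier, config.resp_trial_frac
            )

    resp_any = responsive[False] | responsive[True]
    bf_ctrl, bw_ctrl = mod.tuning_metrics(freqs, evoked[False], responsive[False])
    bf_led, bw_led = mod.tuning_metrics(freqs, evoked[True], responsive[True])
    total_c = float(evoked[False][resp_any].sum())
    total_l = float(evoked[True][resp_any].sum())
    overall_mi = mod.compute_mi(total_l, total_c) if np.any(resp_any) else float("nan")
    pair_mi = np.full(nf, np.nan)
    for j in range(nf):
        if resp_any[j] and (evoked[False][j] + evoked[True][j]) > 0:
            pair_mi[j] = mod.compute_mi(evoked[True][j], evoked[False][j])
    fit = (
        mod.fit_threshold_linear(
            evoked[False], evoked[True], config.fit_include_frac, config.good_fit_r
        )
        if np.any(resp_any)
        else None
    )
    gain_class = mod.classify_gain(fit, overall_mi, config) if fit is not None else None
    return EvokedResult(
        unit_id=unit.unit_id,
        freqs_khz=freqs,
        evoked_ctrl=evoked[False],
        evoked_led=evoked[True],
        responsive_ctrl=responsive[False],
        responsive_led=responsive[True],
        bf_ctrl=bf_ctrl,
        bf_led=bf_led,
        bw70_ctrl=bw_ctrl,
        bw70_led=bw_led,
        overall_mi=overall_mi,
        pair_mi=pair_mi,
        gain_fit=fit,
        gain_class=gain_class,
    )


def evoked_table(results: Sequence[EvokedResult], units: Sequence[UnitRecord]) -> pd.DataFrame:
    by_id = {u.unit_id: u for u in units}
    rows = []
    for r in results:
        u = by_id[r.unit_id]
        rows.append(
            {
                "unit_id": r.unit_id,
                "layer": u.layer.value if u.layer else "",
                "cell_class": u.cell_class.value,
                "responsive": r.is_responsive_unit,
                "bf_ctrl_khz": r.bf_ctrl,
                "bf_led_khz": r.bf_led,
                "bw70_ctrl_oct": r.bw70_ctrl,
                "bw70_led_oct": r.bw70_led,
                "overall_mi": r.overall_mi,
                "slope": r.gain_fit.slope if r.gain_fit else np.nan,
                "intercept_norm": r.gain_fit.y_intercept_norm if r.gain_fit else np.nan,
                "pearson_r": r.gain_fit.pearson_r if r.gain_fit else np.nan,
                "good_fit": bool(r.gain_fit.good_fit) if r.gain_fit else False,
                "gain_class": r.gain_class.value if r.gain_class else "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FS dynamics, arousal, kinetics
# ---------------------------------------------------------------------------

def fs_dynamics_table(
    units: Sequence[UnitRecord],
    trials: TrialTable,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """LED-onset dynamics category per FS unit (and RS for the comparison).

    Rates are measured on LED trials in the first 100 ms after LED onset
    and in the last 500 ms before LED offset, against the same windows of
    the interleaved No-LED trials (whose nominal LED onset is 1 s before
    the tone).
    """
    config = config or AnalysisConfig()
    df = trials.df
    led = df[df["led_on"].astype(bool)]
    ctrl = df[~df["led_on"].astype(bool)]
    led_on_t = led["led_onset_s"].to_numpy(dtype=float)
    led_off_t = led["led_offset_s"].to_numpy(dtype=float)
    # matched windows on control trials
    ctrl_on_t = ctrl["tone_onset_s"].to_numpy(dtype=float) - 1.0
    dur = float(np.mean(led_off_t - led_on_t))
    ctrl_off_t = ctrl_on_t + dur
    w_on, w_st = config.fs_onset_window_s, config.fs_steady_window_s
    rows = []
    for u in units:
        on = (
            sm._window_rate(u.spike_times, led_on_t, w_on),
            sm._window_rate(u.spike_times, ctrl_on_t, w_on),
        )
        st = (
            sm._window_rate(u.spike_times, led_off_t - w_st, w_st),
            sm._window_rate(u.spike_times, ctrl_off_t - w_st, w_st),
        )
        d = mod.classify_fs_dynamics(u.unit_id, on, st, config)
        rows.append(
            {
                "unit_id": u.unit_id,
                "cell_class": u.cell_class.value,
                "layer": u.layer.value if u.layer else "",
                "onset_mi": d.onset_mi,
                "steady_mi": d.steady_mi,
                "category": d.category.value,
            }
        )
    return pd.DataFrame(rows)


def arousal_mi(
    units: Sequence[UnitRecord],
    trials: TrialTable,
    pupil_bins: pd.Series,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Pooled multi-unit spontaneous MI and normalized rates per arousal bin."""
    config = config or AnalysisConfig()
    pool = sm.pool_multiunit(units, scope="arousal", trials=trials, config=config)
    df = trials.df
    rates_by_bin: dict = {}
    for b in range(config.n_pupil_bins):
        in_bin = pupil_bins.to_numpy() == b
        vals = []
        for led in (True, False):
            sel = df[in_bin & (df["led_on"].astype(bool) == led)]
            onsets = sel["tone_onset_s"].to_numpy(dtype=float)
            vals.append(
                sm._window_rate(
                    pool.spike_times, onsets - config.spont_window_s, config.spont_window_s
                )
                if onsets.size
                else np.nan
            )
        rates_by_bin[b] = (vals[0], vals[1]) if all(np.isfinite(vals)) else None
    per_bin = mod.mi_by_arousal(rates_by_bin, config.n_pupil_bins)
    return pd.DataFrame(
        [{"pupil_bin": b, **per_bin[b]} for b in range(config.n_pupil_bins)]
    )


def suppression_kinetics(
    units: Sequence[UnitRecord],
    trials: TrialTable,
    config: Optional[AnalysisConfig] = None,
    max_components: int = 2,
) -> tuple[kin.ExpFitResult, np.ndarray, np.ndarray]:
    """Per-layer-pool suppression-onset fit on the LED-aligned PSTH.

    Pools the given units (photoactivated units removed), builds a fine-bin
    PSTH around LED onset normalized to the pre-LED baseline, and fits the
    delayed-exponential suppression model. Returns (fit, time_ms,
    normalized PSTH).
    """
    config = config or AnalysisConfig()
    pool = sm.pool_multiunit(units, scope="kinetics", trials=trials, config=config)
    led_onsets = trials.led_onsets()
    bin_ms = config.psth_bin_fine_ms
    psth = sm.build_psth(
        pool.spike_times,
        led_onsets,
        bin_ms,
        (-0.3, config.fit_window_ms * 1e-3 + 0.02),
        alignment=Alignment.LED_ONSET,
    )
    t_ms = psth.bin_centers_s * 1e3
    baseline = float(psth.rate_hz[t_ms < 0].mean())
    if baseline <= 0:
        raise ValueError("no pre-LED baseline activity to normalize by")
    norm = psth.rate_hz / baseline
    fit = kin.fit_suppression_onset(norm, t_ms, max_components, config)
    return fit, t_ms, norm


def tone_kinetics(
    units: Sequence[UnitRecord],
    trials: TrialTable,
    led_on: bool,
    config: Optional[AnalysisConfig] = None,
    bin_ms: Optional[float] = None,
) -> kin.KineticsResult:
    """Latency / decay / FWHM of the pooled baseline-subtracted tone PSTH."""
    config = config or AnalysisConfig()
    bin_ms = bin_ms or config.psth_bin_fast_ms
    pool = sm.pool_multiunit(units, scope="tone_kinetics", trials=trials, config=config)
    onsets = trials.tone_onsets(led_on=led_on)
    tone_dur = float(trials.tone_trials["tone_dur_s"].iloc[0])
    psth = sm.build_psth(
        pool.spike_times, onsets, bin_ms, (-config.evoked_baseline_s, tone_dur + 0.3),
        alignment=Alignment.TONE_ONSET,
    )
    t_ms = psth.bin_centers_s * 1e3
    base = float(psth.rate_hz[t_ms < 0].mean())
    sub = np.maximum(psth.rate_hz - base, 0.0)
    resp = sub.copy()
    resp[t_ms < 0] = 0.0
    from .core_io import Psth

    shifted = Psth(
        bin_edges_s=psth.bin_edges_s, rate_hz=resp, n_trials=psth.n_trials,
        alignment=psth.alignment,
    )
    return kin.measure_kinetics(shifted, config)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str = __version__
    stages: list = field(default_factory=list)

    def record(self, name: str, status: str, **info) -> None:
        self.stages.append({"stage": name, "status": status, **info})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "stages": self.stages,
        }


def simulate(
    sim_cfg: syn.SimConfig, seed: int, out_dir: Path | str
) -> tuple[list[UnitRecord], TrialTable, syn.GroundTruth]:
    """Generate and write a full synthetic dataset plus its ground truth."""
    out_dir = Path(out_dir)
    units, truth = syn.generate_units(sim_cfg, stage_seed(seed, 0))
    trials = syn.generate_trials(sim_cfg, stage_seed(seed, 1))
    units = syn.generate_spikes(units, trials, truth, stage_seed(seed, 2), sim_cfg)
    lfp, sink_ch = syn.generate_lfp(sim_cfg, stage_seed(seed, 3))
    truth.lfp_sink_channel = sink_ch
    write_dataset(out_dir, units, trials, lfp=lfp)
    write_nested(
        {
            "laminar": {
                "surface_um": truth.laminar.surface_depth_um,
                "l4_upper_um": truth.laminar.l4_upper_um,
                "l4_lower_um": truth.laminar.l4_lower_um,
                "wm_um": truth.laminar.wm_depth_um,
            },
            "lfp_sink_channel": sink_ch,
            "layer_gains": {k.value: v for k, v in truth.layer_gains.items()},
            "units": {
                uid: {
                    "layer": ut.layer.value,
                    "cell_class": ut.cell_class.value,
                    "baseline_rate_hz": ut.baseline_rate_hz,
                    "led_gain": ut.led_gain,
                    "best_freq_khz": ut.best_freq_khz,
                    "peak_evoked_hz": ut.peak_evoked_hz,
                    "fs_dynamics": ut.fs_dynamics,
                }
                for uid, ut in truth.units.items()
            },
        },
        out_dir / "ground_truth.yaml",
    )
    return units, trials, truth


def run_pipeline(
    seed: int,
    out_dir: Path | str,
    sim_cfg: Optional[syn.SimConfig] = None,
    config: Optional[AnalysisConfig] = None,
) -> RunManifest:
    """Run simulate -> layers -> analyze -> kinetics on one synthetic session."""
    sim_cfg = sim_cfg or syn.SimConfig()
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_path = out_dir / "analysis_config.yaml"
    config.to_yaml(cfg_path)
    manifest = RunManifest(
        seed=seed, config_hash=hashlib.sha256(cfg_path.read_bytes()).hexdigest()[:16]
    )
    try:
        data_dir = out_dir / "dataset"
        units, trials, truth = simulate(sim_cfg, seed, data_dir)
        manifest.record("simulate", "ok", out=str(data_dir))

        units, trials, lfp, _ = read_dataset(data_dir)
        csd = lam_mod.compute_csd(lfp)
        lam = lam_mod.find_l4_borders(csd, config)
        units = lam_mod.assign_layers(units, lam)
        write_nested(
            {
                "surface_um": lam.surface_depth_um,
                "l4_upper_um": lam.l4_upper_um,
                "l4_lower_um": lam.l4_lower_um,
                "wm_um": lam.wm_depth_um,
            },
            out_dir / "laminar_map.yaml",
        )
        manifest.record("layers", "ok")

        spont = spontaneous_table(units, trials, config)
        write_table(spont, out_dir / "spontaneous_mi.csv")
        profile = laminar_mi_profile(units, trials, lam, config, CellClass.RS)
        write_table(profile, out_dir / "laminar_mi_profile.csv")
        rs_single = [
            u for u in units
            if u.cell_class is CellClass.RS and u.layer in (Layer.L1_3, Layer.L4)
        ]
        ev_results = [analyze_evoked_unit(u, trials, config) for u in rs_single]
        write_table(evoked_table(ev_results, units), out_dir / "evoked_gain.csv")
        fs_table = fs_dynamics_table(
            [u for u in units if u.layer in (Layer.L1_3, Layer.L4)], trials, config
        )
        write_table(fs_table, out_dir / "fs_dynamics.csv")
        bins = pupil_mod.assign_bins_from_baseline(trials, config.n_pupil_bins)
        l23 = [u for u in units if u.layer is Layer.L1_3 and u.cell_class is CellClass.RS]
        write_table(arousal_mi(l23, trials, bins, config), out_dir / "arousal_mi.csv")
        manifest.record("analyze", "ok")

        kin_out = {}
        for layer, name in ((Layer.L1_3, "L2_3"), (Layer.L4, "L4")):
            sel = [u for u in units if u.layer is layer and u.cell_class is CellClass.RS]
            fit, t_ms, norm = suppression_kinetics(sel, trials, config)
            kin_out[name] = {
                "delay_ms": fit.delay1_ms,
                "n_components": fit.n_components,
                "components": [[a, tau] for a, tau in fit.components],
                "fast_fraction": fit.fast_fraction,
                "no_suppression": fit.no_suppression,
            }
        write_nested(kin_out, out_dir / "suppression_kinetics.yaml")
        manifest.record("kinetics", "ok")
    except Exception as exc:  # record failure, skip downstream
        manifest.record("failed", "error", message=str(exc))
        write_nested(manifest.to_dict(), out_dir / "run_manifest.yaml")
        raise
    write_nested(manifest.to_dict(), out_dir / "run_manifest.yaml")
    return manifest


def report_summary(out_dir: Path | str) -> dict:
    """Human-readable summary: per-layer modulation-class counts, median MI
    with quartiles, and gain-class fractions."""
    out_dir = Path(out_dir)
    spont = pd.read_csv(out_dir / "spontaneous_mi.csv")
    report: dict = {"layers": {}}
    for layer, g in spont.groupby("layer"):
        counts = g["mod_class"].value_counts().to_dict()
        n = int(len(g))
        mi = g["mi"].dropna()
        report["layers"][layer] = {
            "n_units": n,
            "fraction_enhanced": counts.get("enhanced", 0) / n if n else np.nan,
            "fraction_suppressed": counts.get("suppressed", 0) / n if n else np.nan,
            "fraction_unchanged": counts.get("unchanged", 0) / n if n else np.nan,
            "median_mi": float(mi.median()) if len(mi) else np.nan,
            "q25_mi": float(mi.quantile(0.25)) if len(mi) else np.nan,
            "q75_mi": float(mi.quantile(0.75)) if len(mi) else np.nan,
        }
    gain_path = out_dir / "evoked_gain.csv"
    if gain_path.exists():
        gain = pd.read_csv(gain_path)
        good = gain[gain["good_fit"] == True]  # noqa: E712
        if len(good):
            report["gain_classes"] = (
                good["gain_class"].value_counts(normalize=True).to_dict()
            )
    write_nested(report, out_dir / "summary.yaml")
    return report
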