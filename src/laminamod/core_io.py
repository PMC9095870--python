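"""Domain types, configuration, and on-disk formats.

Conventions used throughout the package: times in seconds, depths in
micrometres below the pial surface, rates in Hz. Time windows are half-open
``[start, end)``. An undefined modulation index (no activity in either
condition) is represented as NaN in memory and as an empty field on disk —
"no evidence" is distinct from "no change".

On-disk layout of a dataset directory (everything plain text except the LFP
payload and the pupil movie):

* ``manifest.yaml``  — file names and recording span
* ``units.csv``      — one row per sorted unit
* ``spikes.csv``     — long format ``unit_id,time_s``
* ``trials.csv``     — one row per trial
* ``lfp.bin`` + ``lfp.yaml`` — click-aligned multichannel average, float32,
  with a sidecar header (channel depths, sample times)
* ``pupil.tif``      — multi-page TIFF eye movie (optional)
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("laminamod")

MANIFEST_NAME = "manifest.yaml"

#: The nine tone frequencies in kHz: 4 kHz to 64 kHz in 0.5-octave steps.
TONE_FREQS_KHZ = tuple(float(f) for f in 4.0 * 2.0 ** (np.arange(9) / 2.0))


def configure_logging(verbose: bool = False) -> None:
    """Route package logging to stderr; ``verbose`` enables DEBUG."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


class CellClass(str, enum.Enum):
    RS = "RS"
    FS = "FS"
    UNCLASSIFIED = "unclassified"


class Layer(str, enum.Enum):
    L1_3 = "L1_3"
    L4 = "L4"
    L5 = "L5"
    L6 = "L6"
    OUTSIDE = "outside"


class Alignment(str, enum.Enum):
    TONE_ONSET = "tone_onset"
    LED_ONSET = "led_onset"
    CLICK_ONSET = "click_onset"


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass
class UnitRecord:
    """One sorted unit.

    Parameters
    ----------
    unit_id:
        Opaque identifier.
    spike_times:
        Spike times in seconds from recording start, nondecreasing.
    depth_um:
        Depth below the pial surface in micrometres.
    trough_peak_ms:
        Waveform trough-to-peak interval in ms; separates fast-spiking
        (putative inhibitory, <= 0.4 ms) from regular-spiking units.
    """

    unit_id: str
    spike_times: np.ndarray
    depth_um: float
    trough_peak_ms: Optional[float] = None
    is_single_unit: bool = True
    cell_class: CellClass = CellClass.UNCLASSIFIED
    layer: Optional[Layer] = None
    conservative_l6: bool = False

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times are not sorted")
        if self.depth_um < 0:
            raise ValidationError(f"unit {self.unit_id}: negative depth")
        if self.trough_peak_ms is not None and not self.trough_peak_ms > 0:
            raise ValidationError(f"unit {self.unit_id}: trough_peak_ms must be > 0")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


TRIAL_COLUMNS = [
    "trial_id",
    "tone_freq_khz",
    "tone_onset_s",
    "tone_dur_s",
    "led_on",
    "led_onset_s",
    "led_offset_s",
    "pupil_baseline_norm",
]


@dataclass
class TrialTable:
    """Per-trial stimulus/LED/pupil metadata, backed by a DataFrame.

    For LED tone trials the LED window brackets the tone
    (``led_onset < tone_onset`` and ``led_offset > tone_onset``), matching a
    protocol where illumination lasts 1 s before and after the tone.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"trial table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        led = self.df[self.df["led_on"].astype(bool)]
        bad = led[~(led["led_offset_s"] > led["led_onset_s"])]
        if len(bad):
            raise ValidationError(
                f"trials with led_offset <= led_onset: {list(bad['trial_id'])}"
            )
        tone_led = led[np.isfinite(led["tone_onset_s"]) & np.isfinite(led["tone_freq_khz"])]
        bad = tone_led[
            ~(
                (tone_led["led_onset_s"] < tone_led["tone_onset_s"])
                & (tone_led["tone_onset_s"] < tone_led["led_offset_s"])
            )
        ]
        if len(bad):
            raise ValidationError(
                f"LED tone trials where LED does not bracket the tone: {list(bad['trial_id'])}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tone_trials(self) -> pd.DataFrame:
        return self.df[np.isfinite(self.df["tone_freq_khz"])]

    def tone_onsets(self, led_on: Optional[bool] = None,
                    freq_khz: Optional[float] = None) -> np.ndarray:
        sel = self.tone_trials
        if led_on is not None:
            sel = sel[sel["led_on"].astype(bool) == led_on]
        if freq_khz is not None:
            sel = sel[np.isclose(sel["tone_freq_khz"], freq_khz)]
        return sel["tone_onset_s"].to_numpy(dtype=float)

    def led_onsets(self) -> np.ndarray:
        sel = self.df[self.df["led_on"].astype(bool)]
        return sel["led_onset_s"].to_numpy(dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        f = self.tone_trials["tone_freq_khz"].to_numpy(dtype=float)
        return np.unique(f)


@dataclass
class Psth:
    """Trial-averaged binned firing rate aligned to an event."""

    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    alignment: Alignment
    baseline_window_s: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.bin_edges_s = np.asarray(self.bin_edges_s, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        if self.rate_hz.size != self.bin_edges_s.size - 1:
            raise ValidationError("rate_hz length must be n_edges - 1")
        widths = np.diff(self.bin_edges_s)
        if not np.allclose(widths, widths[0]):
            raise ValidationError("PSTH bins must be uniform")
        if np.any(self.rate_hz < -1e-12):
            raise ValidationError("negative PSTH rate")

    @property
    def bin_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


@dataclass
class LaminarMap:
    """Depths of the laminar landmarks (pia, L4 borders, white matter)."""

    surface_depth_um: float
    l4_upper_um: float
    l4_lower_um: float
    wm_depth_um: float

    def __post_init__(self) -> None:
        seq = [self.surface_depth_um, self.l4_upper_um, self.l4_lower_um, self.wm_depth_um]
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValidationError(f"laminar landmarks must increase: {seq}")

    @property
    def l56_midpoint_um(self) -> float:
        return 0.5 * (self.l4_lower_um + self.wm_depth_um)


@dataclass
class LfpSnippet:
    """Click-aligned multichannel average LFP."""

    data: np.ndarray  # (n_channels, n_samples)
    channel_depths_um: np.ndarray
    time_s: np.ndarray  # relative to click onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_depths_um = np.asarray(self.channel_depths_um, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.data.shape != (self.channel_depths_um.size, self.time_s.size):
            raise ValidationError("LFP shape must be (n_channels, n_samples)")


@dataclass
class AnalysisConfig:
    """Every numeric knob of the pipeline, with the published defaults.

    The defaults mirror the analysis protocol the package implements:
    modulation-index class thresholds of 1/9 (spontaneous, a 25% increase /
    20% decrease) and 1/6 (tone-evoked, a 40% increase / ~29% decrease), the
    0.4 Hz low-rate rule, the 3.7 x SD responsiveness threshold with the
    more-than-one-third-of-trials criterion, the 10% inclusion rule and
    R > 0.4 good-fit rule of the threshold-linear gain fit with class
    cut-offs 1.3 / 0.7 / 0.15 / -0.08, the 0.4 ms fast-spiking cutoff, PSTH
    bin sizes of 25 / 10 / 0.5 ms, kinetic fractions 0.2 / 0.3 / 0.5, the
    60 ms exponential fitting window with a 1-ms delay grid and 2-ms
    Gaussian smoothing, the 4/4/6/6 (RS) and 2/2/3/3 (FS) normalized-depth
    binning, and baseline windows of 500 ms (spontaneous), 200 ms
    (pre-tone), and 300 ms (pre-LED pupil).
    """

    # modulation classes
    mi_threshold_spont: float = 1.0 / 9.0
    mi_threshold_evoked: float = 1.0 / 6.0
    low_rate_hz: float = 0.4
    # responsiveness
    resp_multiplier: float = 3.7
    resp_trial_frac: float = 1.0 / 3.0
    # threshold-linear gain fit
    fit_include_frac: float = 0.10
    good_fit_r: float = 0.4
    slope_multiplicative: float = 1.3
    slope_divisive: float = 0.7
    intercept_additive: float = 0.15
    intercept_subtractive: float = -0.08
    # waveform classes and unit quality
    fs_cutoff_ms: float = 0.4
    refractory_rs_ms: float = 2.0
    refractory_fs_ms: float = 1.5
    isi_max_frac: float = 0.05
    # PSTH binning
    psth_bin_ms: float = 25.0
    psth_bin_fast_ms: float = 10.0
    psth_bin_fine_ms: float = 0.5
    # kinetics
    latency_frac: float = 0.2
    decay_frac: float = 0.3
    half_frac: float = 0.5
    fit_window_ms: float = 60.0
    delay_step_ms: float = 1.0
    delay_max_ms: float = 30.0
    smooth_window_ms: float = 2.0
    a2_negligible: float = 0.05
    # laminar binning
    rs_bins_per_layer: tuple[int, int, int, int] = (4, 4, 6, 6)
    fs_bins_per_layer: tuple[int, int, int, int] = (2, 2, 3, 3)
    csd_early_window_ms: tuple[float, float] = (0.0, 20.0)
    # baseline windows
    spont_window_s: float = 0.5
    evoked_baseline_s: float = 0.2
    pupil_baseline_s: float = 0.3
    # FS LED-onset dynamics windows
    fs_onset_window_s: float = 0.1
    fs_steady_window_s: float = 0.5
    # photoactivated-unit screen: MI over the first 50 ms of LED
    photoactivated_mi: float = 1.0 / 3.0
    photoactivated_window_s: float = 0.05
    # pupillometry
    n_pupil_bins: int = 4
    deviant_window_frames: int = 11
    deviant_mad_factor: float = 5.0
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.rs_bins_per_layer = tuple(self.rs_bins_per_layer)
        self.fs_bins_per_layer = tuple(self.fs_bins_per_layer)
        self.csd_early_window_ms = tuple(self.csd_early_window_ms)
        for name in (
            "mi_threshold_spont", "mi_threshold_evoked", "low_rate_hz",
            "resp_multiplier", "resp_trial_frac", "fit_include_frac",
            "good_fit_r", "fs_cutoff_ms", "psth_bin_ms", "latency_frac",
            "decay_frac", "half_frac", "fit_window_ms", "delay_step_ms",
            "smooth_window_ms", "spont_window_s", "evoked_baseline_s",
            "pupil_baseline_s",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"config field {name} must be positive")

    def to_yaml(self, path: Path | str) -> None:
        d = dataclasses.asdict(self)
        d["rs_bins_per_layer"] = list(self.rs_bins_per_layer)
        d["fs_bins_per_layer"] = list(self.fs_bins_per_layer)
        d["csd_early_window_ms"] = list(self.csd_early_window_ms)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# dataset reading / writing
# ---------------------------------------------------------------------------

def write_dataset(
    path: Path | str,
    units: Sequence[UnitRecord],
    trials: TrialTable,
    lfp: Optional[LfpSnippet] = None,
    pupil_movie: Optional[np.ndarray] = None,
    pupil_frame_times_s: Optional[np.ndarray] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Write a dataset directory in the package's on-disk layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "laminamod-dataset", "version": 1}

    unit_rows = []
    spike_frames = []
    for u in units:
        unit_rows.append(
            {
                "unit_id": u.unit_id,
                "depth_um": u.depth_um,
                "trough_peak_ms": u.trough_peak_ms,
                "is_single_unit": u.is_single_unit,
                "cell_class": u.cell_class.value,
                "layer": u.layer.value if u.layer is not None else "",
                "conservative_l6": u.conservative_l6,
            }
        )
        if u.n_spikes:
            spike_frames.append(
                pd.DataFrame({"unit_id": u.unit_id, "time_s": u.spike_times})
            )
    pd.DataFrame(unit_rows, columns=[
        "unit_id", "depth_um", "trough_peak_ms", "is_single_unit",
        "cell_class", "layer", "conservative_l6",
    ]).to_csv(path / "units.csv", index=False)
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    spikes.to_csv(path / "spikes.csv", index=False, float_format="%.9f")
    trials.df.to_csv(path / "trials.csv", index=False)
    manifest["units"] = "units.csv"
    manifest["spikes"] = "spikes.csv"
    manifest["trials"] = "trials.csv"

    if lfp is not None:
        lfp.data.astype(np.float32).tofile(path / "lfp.bin")
        header = {
            "n_channels": int(lfp.data.shape[0]),
            "n_samples": int(lfp.data.shape[1]),
            "dtype": "float32",
            "channel_depths_um": [float(d) for d in lfp.channel_depths_um],
            "time_s": [float(t) for t in lfp.time_s],
        }
        (path / "lfp.yaml").write_text(yaml.safe_dump(header, sort_keys=False))
        manifest["lfp"] = "lfp.bin"
        manifest["lfp_header"] = "lfp.yaml"

    if pupil_movie is not None:
        import tifffile

        tifffile.imwrite(path / "pupil.tif", np.asarray(pupil_movie))
        manifest["pupil"] = "pupil.tif"
        if pupil_frame_times_s is not None:
            pd.DataFrame({"time_s": np.asarray(pupil_frame_times_s, dtype=float)}).to_csv(
                path / "pupil_times.csv", index=False
            )
            manifest["pupil_times"] = "pupil_times.csv"

    if extra:
        manifest.update(extra)
    (path / MANIFEST_NAME).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_dataset(path: Path | str):
    """Read a dataset directory back into memory.

    Returns ``(units, trials, lfp, pupil)`` where ``lfp`` is an
    :class:`LfpSnippet` or None and ``pupil`` is a dict with keys
    ``movie_path`` and ``frame_times_s`` or None.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    for key in ("units", "spikes", "trials"):
        if not (path / manifest[key]).exists():
            raise FileNotFoundError(f"manifest references missing file {manifest[key]}")

    unit_df = pd.read_csv(path / manifest["units"])
    spike_df = pd.read_csv(path / manifest["spikes"])
    spikes_by_unit = (
        {k: g["time_s"].to_numpy(dtype=float) for k, g in spike_df.groupby("unit_id")}
        if len(spike_df)
        else {}
    )
    units = []
    for row in unit_df.itertuples(index=False):
        layer = getattr(row, "layer", "")
        layer = Layer(layer) if isinstance(layer, str) and layer else None
        tp = getattr(row, "trough_peak_ms", None)
        units.append(
            UnitRecord(
                unit_id=str(row.unit_id),
                spike_times=spikes_by_unit.get(str(row.unit_id), np.empty(0)),
                depth_um=float(row.depth_um),
                trough_peak_ms=None if tp is None or pd.isna(tp) else float(tp),
                is_single_unit=bool(row.is_single_unit),
                cell_class=CellClass(row.cell_class),
                layer=layer,
                conservative_l6=bool(getattr(row, "conservative_l6", False)),
            )
        )

    trial_df = pd.read_csv(path / manifest["trials"])
    trials = TrialTable(trial_df)

    lfp = None
    if "lfp" in manifest:
        header = yaml.safe_load((path / manifest["lfp_header"]).read_text())
        data = np.fromfile(path / manifest["lfp"], dtype=np.float32).reshape(
            header["n_channels"], header["n_samples"]
        )
        lfp = LfpSnippet(
            data=data.astype(float),
            channel_depths_um=np.asarray(header["channel_depths_um"], dtype=float),
            time_s=np.asarray(header["time_s"], dtype=float),
        )

    pupil = None
    if "pupil" in manifest:
        pupil = {"movie_path": path / manifest["pupil"], "frame_times_s": None}
        if "pupil_times" in manifest:
            pupil["frame_times_s"] = pd.read_csv(path / manifest["pupil_times"])[
                "time_s"
            ].to_numpy(dtype=float)

    return units, trials, lfp, pupil


def write_table(df: pd.DataFrame, path: Path | str) -> None:
    """Write a tabular result as CSV; NaN (undefined MI etc.) as empty field."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_nested(obj: dict, path: Path | str) -> None:
    """Write a nested result as YAML, converting numpy scalars/arrays."""

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.ndarray):
            return [clean(v) for v in x.tolist()]
        if isinstance(x, (np.floating, np.integer)):
            x = x.item()
        if isinstance(x, float) and not np.isfinite(x):
            return None
        return x

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(clean(obj), sort_keys=False))


def read_nested(path: Path | str) -> dict:
    return yaml.safe_load(Path(path).read_text())
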