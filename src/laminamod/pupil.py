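"""Pupil diameter extraction and arousal binning from infrared eye movies.

Frames are binarized at a per-movie intensity threshold (Otsu by default),
cleaned with morphological opening, closing, and hole filling, and the
pupil diameter is the maximum Feret diameter (max caliper distance,
center-to-center) of the largest connected component. Deviant frames are
flagged by a rolling-median / MAD rule (an automated stand-in for manual
exclusion of undetectable pupils), diameters are min-max normalized over
the valid frames of the recording, and trials are assigned to four equal
arousal bins from the mean normalized diameter in the 300 ms preceding the
LED onset (No-LED trials use the matching within-trial window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .core_io import TrialTable, log


def _auto_threshold(img: np.ndarray) -> float:
    """Histogram split isolating the darkest mode (the pupil).

    An eye image has at least three intensity populations (pupil, iris,
    sclera/skin); a three-class Otsu split returns the boundary below the
    iris. Falls back to plain Otsu for (near-)bimodal images.
    """
    from skimage.filters import threshold_multiotsu, threshold_otsu

    try:
        return float(threshold_multiotsu(np.asarray(img), classes=3)[0])
    except ValueError:
        return float(threshold_otsu(np.asarray(img)))


def max_feret_diameter(mask: np.ndarray) -> float:
    """Maximum pairwise (center-to-center) distance between mask pixels.

    Uses the convex hull of the pixel centers — the farthest pair of any
    point set lies on its hull — with a brute-force fallback for degenerate
    (e.g. collinear) masks. A single pixel has diameter 0.
    """
    pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        return float("nan")
    if pts.shape[0] == 1:
        return 0.0
    pts = pts.astype(float)
    if pts.shape[0] > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # collinear; fall through to brute force
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def extract_diameter(
    frame: np.ndarray,
    intensity_threshold: Optional[float] = None,
    eyelid_rows: Optional[int] = None,
) -> tuple[float, bool]:
    """Pupil diameter of one grayscale frame; returns (diameter_px, valid).

    Pixels below the threshold form the pupil mask; the mask is opened,
    closed, and hole-filled with a 3x3 structuring element, and the largest
    connected component is kept. The frame is invalid when the mask is
    empty or touches the eyelid exclusion band (the top ``eyelid_rows``
    rows), e.g. when the lid covers part of the pupil.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    if intensity_threshold is None:
        intensity_threshold = _auto_threshold(frame)
    mask = frame < intensity_threshold
    st = np.ones((3, 3), dtype=bool)
    mask = ndimage.binary_opening(mask, structure=st)
    mask = ndimage.binary_closing(mask, structure=st)
    mask = ndimage.binary_fill_holes(mask, structure=st)
    labels, n = ndimage.label(mask)
    if n == 0:
        return float("nan"), False
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    if eyelid_rows is not None and np.any(mask[:eyelid_rows, :]):
        return float("nan"), False
    return max_feret_diameter(mask), True


@dataclass
class PupilTrace:
    """Per-frame pupil diameter with validity flags and normalization."""

    frame_times_s: np.ndarray
    diameter_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.diameter_px = np.asarray(self.diameter_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.valid = self.valid & np.isfinite(self.diameter_px)

    @property
    def normalized(self) -> np.ndarray:
        """(d - min)/(max - min) over valid frames; NaN on invalid frames."""
        d = np.where(self.valid, self.diameter_px, np.nan)
        lo, hi = np.nanmin(d), np.nanmax(d)
        if hi == lo:
            return np.where(self.valid, 0.5, np.nan)
        return (d - lo) / (hi - lo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.diameter_px.size),
                "time_s": self.frame_times_s,
                "diameter_px": self.diameter_px,
                "valid": self.valid,
                "normalized": self.normalized,
            }
        )


def extract_trace(
    movie: np.ndarray,
    frame_times_s: np.ndarray,
    intensity_threshold: Optional[float] = None,
    eyelid_rows: Optional[int] = None,
) -> PupilTrace:
    """Run :func:`extract_diameter` over a movie with one shared threshold."""
    movie = np.asarray(movie)
    if intensity_threshold is None:
        intensity_threshold = _auto_threshold(movie)
    d = np.empty(movie.shape[0])
    valid = np.empty(movie.shape[0], dtype=bool)
    for k in range(movie.shape[0]):
        d[k], valid[k] = extract_diameter(movie[k], intensity_threshold, eyelid_rows)
    return PupilTrace(frame_times_s=frame_times_s, diameter_px=d, valid=valid)


def detect_deviants(
    trace: PupilTrace,
    window_frames: int = 11,
    mad_factor: float = 5.0,
) -> PupilTrace:
    """Flag frames deviating from an 11-frame rolling median by more than
    ``mad_factor`` times the median absolute deviation."""
    d = trace.diameter_px
    valid = trace.valid.copy()
    if valid.sum() < 10:
        return trace
    s = pd.Series(np.where(valid, d, np.nan))
    rolling = s.rolling(window_frames, center=True, min_periods=1).median()
    resid = (s - rolling).abs()
    mad = float(np.nanmedian(resid[valid]))
    if mad == 0.0:
        cut = 1e-9
    else:
        cut = mad_factor * mad
    dev = resid.to_numpy() > cut
    flagged = valid & dev
    if flagged.any():
        log.debug("deviant detection flagged %d frames", int(flagged.sum()))
    valid[flagged] = False
    return PupilTrace(frame_times_s=trace.frame_times_s, diameter_px=d, valid=valid)


def bin_trials_by_arousal(
    trace: PupilTrace,
    trials: TrialTable,
    n_bins: int = 4,
    baseline_s: float = 0.3,
) -> pd.Series:
    """Arousal bin per trial from the pre-LED normalized pupil diameter.

    The per-trial mean normalized diameter in the ``baseline_s`` window
    preceding the LED onset (No-LED trials: the matching window preceding
    where the LED would start, 1 s before the tone) is assigned to
    ``n_bins`` equal-width bins on [0, 1]; bins are half-open with the last
    bin closed. Trials without valid frames in their window get NaN.
    """
    norm = trace.normalized
    times = trace.frame_times_s
    out = np.full(len(trials.df), np.nan)
    for i, row in trials.df.iterrows():
        if row["led_on"] and np.isfinite(row["led_onset_s"]):
            t1 = row["led_onset_s"]
        elif np.isfinite(row["tone_onset_s"]):
            t1 = row["tone_onset_s"] - 1.0  # where the LED would have started
        else:
            continue
        sel = (times >= t1 - baseline_s) & (times < t1) & np.isfinite(norm)
        if not np.any(sel):
            continue
        p = float(np.mean(norm[sel]))
        b = min(int(p * n_bins), n_bins - 1)  # diameter 1.0 falls in the last bin
        out[i] = b
    return pd.Series(out, index=trials.df.index, name="pupil_bin")


def assign_bins_from_baseline(
    trials: TrialTable, n_bins: int = 4
) -> pd.Series:
    """Arousal bins straight from the trials' stored normalized baseline
    diameter (used when no eye movie accompanies the dataset)."""
    p = trials.df["pupil_baseline_norm"].to_numpy(dtype=float)
    out = np.full(p.size, np.nan)
    ok = np.isfinite(p)
    out[ok] = np.minimum((p[ok] * n_bins).astype(int), n_bins - 1)
    return pd.Series(out, index=trials.df.index, name="pupil_bin")
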