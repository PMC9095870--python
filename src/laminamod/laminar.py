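"""Laminar assignment from click-evoked current source density.

The CSD is the (negated) discrete second spatial difference of the laminar
LFP; the earliest prominent sink marks the thalamorecipient L4. Borders are
the contiguous channels whose early-window CSD stays below half the sink
amplitude, the span from the L4 lower border to the white matter is split at
its midpoint into L5 and L6, and depths are mapped onto a normalized
cortical column (4/4/6/6 bins for RS analyses, 2/2/3/3 for the sparser FS
units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AnalysisConfig, LaminarMap, Layer, LfpSnippet, UnitRecord, log


class NoSinkError(RuntimeError):
    """Raised when no CSD channel drops below the noise floor."""


@dataclass
class CsdProfile:
    """CSD per (interior channel, time bin); sinks are negative."""

    csd: np.ndarray  # (n_channels - 2, n_samples)
    channel_depths_um: np.ndarray
    time_s: np.ndarray

    def early_amplitude(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Most negative CSD per channel inside the early window."""
        lo, hi = (w * 1e-3 for w in window_ms)
        sel = (self.time_s >= lo) & (self.time_s < hi)
        if not np.any(sel):
            raise ValueError("early window contains no samples")
        return self.csd[:, sel].min(axis=1)


def compute_csd(lfp: LfpSnippet, spacing_um: float | None = None) -> CsdProfile:
    """Second-difference CSD: ``-(V[i-1] - 2 V[i] + V[i+1]) / spacing^2``."""
    depths = lfp.channel_depths_um
    if depths.size < 5:
        raise ValueError("CSD needs at least 5 channels")
    steps = np.diff(depths)
    if not np.allclose(steps, steps[0]):
        raise ValueError("channel spacing must be uniform")
    h = float(steps[0]) if spacing_um is None else float(spacing_um)
    v = lfp.data
    csd = -(v[:-2] - 2.0 * v[1:-1] + v[2:]) / h**2
    return CsdProfile(csd=csd, channel_depths_um=depths[1:-1], time_s=lfp.time_s)


def find_l4_borders(
    csd: CsdProfile,
    config: AnalysisConfig | None = None,
    surface_depth_um: float | None = None,
    wm_depth_um: float | None = None,
) -> LaminarMap:
    """Locate L4 as the early sink and read off its half-amplitude extent.

    The sink is the most negative CSD value inside the early window
    (default 0-20 ms post-click). The L4 borders are the contiguous run of
    channels around the sink whose early-window CSD is at or below half the
    sink amplitude. A sink must exceed the noise floor (3x the SD of the
    pre-click CSD), otherwise :class:`NoSinkError` is raised.
    """
    config = config or AnalysisConfig()
    amp = csd.early_amplitude(config.csd_early_window_ms)
    sink_ch = int(np.argmin(amp))
    # noise floor from the matched statistic on pre-click data: the
    # per-channel minimum over a window of the same length, so the extreme-
    # value bias of taking minima does not mimic a sink
    pre = csd.csd[:, csd.time_s < 0.0]
    lo, hi = (w * 1e-3 for w in config.csd_early_window_ms)
    n_early = int(np.sum((csd.time_s >= lo) & (csd.time_s < hi)))
    if pre.shape[1] >= n_early > 0:
        pre_min = pre[:, -n_early:].min(axis=1)
        # a genuine sink must stand well clear of the extreme pre-click
        # excursion of the same min-statistic
        floor = 2.0 * float(pre_min.min())
        if floor < 0 and amp[sink_ch] > floor:
            raise NoSinkError(
                f"no early sink below the noise floor (min {amp[sink_ch]:.3g}, "
                f"floor {floor:.3g})"
            )
    if amp[sink_ch] >= 0:
        raise NoSinkError("early-window CSD has no negative deflection")
    half = 0.5 * amp[sink_ch]
    below = amp <= half
    lo = sink_ch
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = sink_ch
    while hi < amp.size - 1 and below[hi + 1]:
        hi += 1
    depths = csd.channel_depths_um
    spacing = float(depths[1] - depths[0])
    l4_upper = float(depths[lo] - 0.5 * spacing)
    l4_lower = float(depths[hi] + 0.5 * spacing)
    surface = float(surface_depth_um if surface_depth_um is not None else depths[0] - spacing)
    wm = float(wm_depth_um if wm_depth_um is not None else depths[-1] + spacing)
    surface = min(surface, l4_upper - 1e-9)
    wm = max(wm, l4_lower + 1e-9)
    return LaminarMap(surface, l4_upper, l4_lower, wm)


def assign_layers(units: list[UnitRecord], lam: LaminarMap) -> list[UnitRecord]:
    """Assign each unit a layer from its depth (half-open intervals).

    Ties at a border go to the deeper layer. The span between the L4 lower
    border and the white matter is split at its midpoint into L5 and L6;
    units in the lowest third of that span additionally get a conservative
    L6 flag for single-unit analyses (to avoid contamination by opsin-
    expressing L5 cells).
    """
    mid = lam.l56_midpoint_um
    l6_conservative_start = lam.l4_lower_um + (2.0 / 3.0) * (lam.wm_depth_um - lam.l4_lower_um)
    n_outside = 0
    for u in units:
        d = u.depth_um
        if d < lam.surface_depth_um or d >= lam.wm_depth_um:
            u.layer = Layer.OUTSIDE
            n_outside += 1
        elif d < lam.l4_upper_um:
            u.layer = Layer.L1_3
        elif d < lam.l4_lower_um:
            u.layer = Layer.L4
        elif d < mid:
            u.layer = Layer.L5
        else:
            u.layer = Layer.L6
        u.conservative_l6 = bool(
            u.layer in (Layer.L5, Layer.L6) and d >= l6_conservative_start
        )
    if n_outside:
        log.warning("%d units outside the cortical column", n_outside)
    return units


@dataclass
class NormalizedDepthBins:
    """Bin index per unit on the normalized cortical column."""

    bin_index: dict  # unit_id -> int or None (outside)
    scheme: tuple[int, int, int, int]

    @property
    def n_bins(self) -> int:
        return int(sum(self.scheme))


def normalize_depths(
    units: list[UnitRecord],
    lam: LaminarMap,
    scheme: tuple[int, int, int, int] = (4, 4, 6, 6),
) -> NormalizedDepthBins:
    """Map unit depths onto the normalized column's depth bins.

    Within each layer the relative depth is mapped linearly onto that
    layer's bin range; bins are half-open with the last bin of the column
    closed.
    """
    edges = {
        Layer.L1_3: (lam.surface_depth_um, lam.l4_upper_um),
        Layer.L4: (lam.l4_upper_um, lam.l4_lower_um),
        Layer.L5: (lam.l4_lower_um, lam.l56_midpoint_um),
        Layer.L6: (lam.l56_midpoint_um, lam.wm_depth_um),
    }
    offsets = np.concatenate(([0], np.cumsum(scheme)))
    order = (Layer.L1_3, Layer.L4, Layer.L5, Layer.L6)
    index: dict = {}
    for u in units:
        if u.layer is None:
            raise ValueError(f"unit {u.unit_id} has no layer; run assign_layers first")
        if u.layer is Layer.OUTSIDE:
            index[u.unit_id] = None
            continue
        li = order.index(u.layer)
        lo, hi = edges[u.layer]
        frac = (u.depth_um - lo) / (hi - lo)
        b = int(offsets[li] + min(int(frac * scheme[li]), scheme[li] - 1))
        index[u.unit_id] = b
    return NormalizedDepthBins(bin_index=index, scheme=tuple(scheme))
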