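"""CSD, L4 border detection, layer assignment, and depth normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminamod import (
    LaminarMap,
    Layer,
    LfpSnippet,
    NoSinkError,
    UnitRecord,
    assign_layers,
    compute_csd,
    find_l4_borders,
    normalize_depths,
)
from laminamod.laminar import CsdProfile


def _snippet(v: np.ndarray, spacing: float = 25.0) -> LfpSnippet:
    n_ch, n_t = v.shape
    return LfpSnippet(
        data=v,
        channel_depths_um=spacing * np.arange(n_ch),
        time_s=np.linspace(-0.02, 0.05, n_t),
    )


@settings(deadline=None, max_examples=30)
@given(
    a=st.floats(-5, 5, allow_nan=False),
    b=st.floats(-5, 5, allow_nan=False),
)
def test_csd_of_affine_potential_is_zero(a, b):
    depths = 25.0 * np.arange(12)
    v = np.outer(a * depths + b, np.ones(40))
    csd = compute_csd(_snippet(v))
    np.testing.assert_allclose(csd.csd, 0.0, atol=1e-10)


def test_csd_of_quadratic_potential_is_constant():
    depths = 25.0 * np.arange(10)
    v = np.outer(depths**2, np.ones(30))
    csd = compute_csd(_snippet(v))
    np.testing.assert_allclose(csd.csd, -2.0, rtol=1e-9)


def test_csd_rejects_nonuniform_spacing():
    lfp = LfpSnippet(
        data=np.zeros((6, 10)),
        channel_depths_um=np.array([0, 25, 50, 80, 105, 130.0]),
        time_s=np.linspace(0, 0.01, 10),
    )
    with pytest.raises(ValueError, match="uniform"):
        compute_csd(lfp)


def _profile(amp: np.ndarray, spacing: float = 25.0) -> CsdProfile:
    """CSD profile whose early-window amplitude equals ``amp`` exactly."""
    t = np.linspace(-0.02, 0.05, 140)
    bump = np.exp(-((t - 0.01) ** 2) / (2 * 0.004**2))
    csd = np.outer(amp, bump)
    return CsdProfile(csd=csd, channel_depths_um=spacing * (1 + np.arange(amp.size)), time_s=t)


def test_gaussian_sink_borders_follow_half_maximum():
    """Half-max extent of a Gaussian sink: |i - i0| <= sigma*sqrt(2 ln 2)."""
    i = np.arange(30, dtype=float)
    i0, sigma = 14.0, 2.0
    amp = -np.exp(-((i - i0) ** 2) / (2 * sigma**2))
    prof = _profile(amp)
    lam = find_l4_borders(prof)
    half_w = sigma * np.sqrt(2 * np.log(2.0))
    first = int(np.ceil(i0 - half_w))
    last = int(np.floor(i0 + half_w))
    depths = prof.channel_depths_um
    spacing = 25.0
    assert lam.l4_upper_um == pytest.approx(depths[first] - spacing / 2)
    assert lam.l4_lower_um == pytest.approx(depths[last] + spacing / 2)


def test_early_sink_preferred_over_later_deeper_sink():
    t = np.linspace(-0.02, 0.06, 160)
    early = np.exp(-((t - 0.01) ** 2) / (2 * 0.003**2))
    late = np.exp(-((t - 0.04) ** 2) / (2 * 0.003**2))
    csd = np.zeros((20, t.size))
    csd[5] = -1.0 * early
    csd[14] = -3.0 * late  # deeper sink, but outside the early window
    prof = CsdProfile(csd=csd, channel_depths_um=25.0 * (1 + np.arange(20)), time_s=t)
    lam = find_l4_borders(prof)
    center = 0.5 * (lam.l4_upper_um + lam.l4_lower_um)
    assert abs(center - prof.channel_depths_um[5]) < 25.0


def test_all_noise_csd_raises_no_sink():
    rng = np.random.default_rng(0)
    t = np.linspace(-0.02, 0.05, 140)
    csd = rng.normal(0, 1.0, (20, t.size))
    prof = CsdProfile(csd=csd, channel_depths_um=25.0 * (1 + np.arange(20)), time_s=t)
    with pytest.raises(NoSinkError):
        find_l4_borders(prof)


def _unit(depth: float) -> UnitRecord:
    return UnitRecord(unit_id=f"d{depth}", spike_times=np.empty(0), depth_um=depth)


def test_layer_assignment_examples():
    lam = LaminarMap(0.0, 400.0, 500.0, 1100.0)
    units = [_unit(d) for d in (0.0, 399.9, 400.0, 500.0, 790.0, 810.0, 950.0, 1200.0)]
    assign_layers(units, lam)
    layers = [u.layer for u in units]
    assert layers == [
        Layer.L1_3, Layer.L1_3, Layer.L4, Layer.L5,  # border ties go deeper
        Layer.L5, Layer.L6,  # split at the 800 um midpoint
        Layer.L6, Layer.OUTSIDE,
    ]
    # conservative-L6 flag: lowest third of the 500-1100 um span starts at 900
    assert not units[5].conservative_l6  # 810
    assert units[6].conservative_l6  # 950


def test_layer_assignment_is_a_partition():
    lam = LaminarMap(0.0, 400.0, 500.0, 1100.0)
    rng = np.random.default_rng(1)
    units = [_unit(d) for d in rng.uniform(0, 1099.9, 300)]
    assign_layers(units, lam)
    assert all(u.layer in (Layer.L1_3, Layer.L4, Layer.L5, Layer.L6) for u in units)


def test_normalized_depth_bin_examples():
    lam = LaminarMap(0.0, 400.0, 500.0, 1100.0)
    top = _unit(0.0)
    l4_mid = _unit(450.0)
    units = assign_layers([top, l4_mid], lam)
    bins = normalize_depths(units, lam, (4, 4, 6, 6))
    assert bins.bin_index[top.unit_id] == 0
    assert bins.bin_index[l4_mid.unit_id] == 6  # bins 4-7 are L4; midpoint -> 6
    assert bins.n_bins == 20


def test_uniform_depths_fill_bins_proportional_to_thickness():
    lam = LaminarMap(0.0, 400.0, 500.0, 1100.0)
    rng = np.random.default_rng(2)
    units = assign_layers([_unit(d) for d in rng.uniform(0, 1100, 6000)], lam)
    bins = normalize_depths(units, lam, (4, 4, 6, 6))
    counts = np.bincount(
        [b for b in bins.bin_index.values() if b is not None], minlength=20
    )
    widths = np.array([100.0] * 4 + [25.0] * 4 + [50.0] * 6 + [50.0] * 6)
    expected = 6000 * widths / 1100.0
    np.testing.assert_allclose(counts, expected, rtol=0.25)
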