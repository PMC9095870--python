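"""Temporal response metrics and exponential decomposition of LED-onset
suppression.

Kinetics of tone-evoked multi-unit responses are summarized by onset
latency (time to 20% of maximum), decay time (100% to 30% of maximum), and
full width at half maximum, all with linear interpolation of the crossing
times between PSTH samples. The onset of LED-triggered suppression is
decomposed, on a baseline-normalized PSTH, into one or two delayed
exponential components

    r(t) = 1 - sum_i A_i (1 - exp(-(t - d_i)/tau_i)),   t in [d, 60 ms]

with the delays searched on a 1-ms grid; a fast intracortical plus a slow
subcortical component in superficial layers, a single component elsewhere.
The second component is kept only when its amplitude exceeds a
negligibility threshold (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .core_io import AnalysisConfig, Psth


@dataclass
class KineticsResult:
    latency_ms: float
    decay_ms: float
    fwhm_ms: float


@dataclass
class ExpFitResult:
    """Result of the suppression-onset exponential decomposition."""

    delay1_ms: float
    components: list  # [(magnitude, tau_ms), ...] ordered fast -> slow
    delay2_ms: Optional[float]
    residual: float
    n_components: int
    no_suppression: bool = False

    @property
    def fast_fraction(self) -> float:
        """A_fast / (A_fast + A_slow); 1 for a single component."""
        if self.no_suppression:
            return float("nan")
        amps = [a for a, _ in self.components]
        total = sum(amps)
        return amps[0] / total if total > 0 else float("nan")


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> Optional[float]:
    """First time y crosses ``level`` (linear interpolation between samples)."""
    if rising:
        idx = np.flatnonzero(y >= level)
    else:
        idx = np.flatnonzero(y <= level)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def response_latency(psth: Psth, frac: float = 0.2) -> float:
    """Time (ms) at which the baseline-subtracted rate first reaches
    ``frac`` of its maximum; NaN without a positive response."""
    y = psth.rate_hz
    if y.size == 0 or y.max() <= 0:
        return float("nan")
    t = psth.bin_centers_s * 1e3
    x = _crossing_time(t, y, frac * y.max(), rising=True)
    return float("nan") if x is None else x


def decay_time(psth: Psth, frac: float = 0.3) -> float:
    """Time (ms) from the peak to the first crossing below ``frac`` of the
    maximum; NaN if the rate never falls that far in the window."""
    y = psth.rate_hz
    if y.size == 0 or y.max() <= 0:
        return float("nan")
    t = psth.bin_centers_s * 1e3
    ipk = int(np.argmax(y))
    x = _crossing_time(t[ipk:], y[ipk:], frac * y.max(), rising=False)
    return float("nan") if x is None else x - float(t[ipk])


def fwhm(psth: Psth) -> float:
    """Width (ms) between the interpolated half-maximum crossings on the
    rising and falling phases; NaN when either crossing is missing."""
    y = psth.rate_hz
    if y.size == 0 or y.max() <= 0:
        return float("nan")
    t = psth.bin_centers_s * 1e3
    half = 0.5 * y.max()
    ipk = int(np.argmax(y))
    rise = _crossing_time(t[: ipk + 1], y[: ipk + 1], half, rising=True)
    fall = _crossing_time(t[ipk:], y[ipk:], half, rising=False)
    if rise is None or fall is None:
        return float("nan")
    return fall - rise


def measure_kinetics(psth: Psth, config: Optional[AnalysisConfig] = None) -> KineticsResult:
    config = config or AnalysisConfig()
    return KineticsResult(
        latency_ms=response_latency(psth, config.latency_frac),
        decay_ms=decay_time(psth, config.decay_frac),
        fwhm_ms=fwhm(psth),
    )


# ---------------------------------------------------------------------------
# dual-exponential suppression-onset fit
# ---------------------------------------------------------------------------

_TAU_GRID_MS = np.geomspace(1.0, 60.0, 10)
_TAU_BOUNDS_MS = (0.5, 60.0)
_A_BOUNDS = (0.0, 1.5)
_TAU_SEPARATION = 2.0  # minimal tau ratio for a distinct second component


def _basis(t: np.ndarray, d: float, tau: float) -> np.ndarray:
    """(1 - exp(-(t-d)/tau)) clamped to zero before the delay."""
    u = np.maximum(t - d, 0.0)
    return np.where(t > d, 1.0 - np.exp(-u / tau), 0.0)


def _nnls1(y: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Nonnegative LS amplitude for one basis column, with residual."""
    bb = float(b @ b)
    a = max(float(b @ y) / bb, 0.0) if bb > 0 else 0.0
    r = float(y @ y) - 2.0 * a * float(b @ y) + a * a * bb
    return a, r


def _nnls2(y: np.ndarray, b1: np.ndarray, b2: np.ndarray) -> tuple[float, float, float]:
    """Analytic nonnegative LS for two basis columns, with residual."""
    g11, g22, g12 = float(b1 @ b1), float(b2 @ b2), float(b1 @ b2)
    c1, c2 = float(b1 @ y), float(b2 @ y)
    det = g11 * g22 - g12 * g12
    if det > 1e-12 * g11 * g22 + 1e-30:
        a1 = (g22 * c1 - g12 * c2) / det
        a2 = (g11 * c2 - g12 * c1) / det
        if a1 >= 0 and a2 >= 0:
            r = float(y @ y) - a1 * c1 - a2 * c2
            return a1, a2, r
    # boundary: one amplitude clamped at zero
    a1, r1 = _nnls1(y, b1)
    a2, r2 = _nnls1(y, b2)
    return (a1, 0.0, r1) if r1 <= r2 else (0.0, a2, r2)


def fit_suppression_onset(
    psth_norm: np.ndarray,
    time_ms: np.ndarray,
    max_components: int = 2,
    config: Optional[AnalysisConfig] = None,
    smooth: bool = True,
) -> ExpFitResult:
    """Fit delayed exponential suppression to a baseline-normalized PSTH.

    ``psth_norm`` is the multi-unit PSTH normalized to the pre-LED baseline
    (=1), with photoactivated units already removed; ``time_ms`` is time
    from LED onset. The fit window runs from the candidate delay to 60 ms
    after LED onset; candidate delays are searched on a 1-ms grid (0-30 ms,
    second delay constrained >= the first), amplitudes are solved by
    nonnegative least squares over a log-spaced tau grid, and the best
    combination is polished with bounded least squares. The reported delay
    is the first time the fitted curve falls below one, which for this
    model is the first component's delay.
    """
    config = config or AnalysisConfig()
    t = np.asarray(time_ms, dtype=float)
    y = np.asarray(psth_norm, dtype=float)
    sigma_bins = 0.0
    if smooth and t.size > 2:
        dt = float(np.median(np.diff(t)))
        # Gaussian-weighted moving average with a 2-ms window: the kernel's
        # support is the window, i.e. sigma ~ window/5
        sigma_bins = max(config.smooth_window_ms / 5.0 / dt, 1e-6)
        y = ndimage.gaussian_filter1d(y, sigma=sigma_bins, mode="nearest")
    # noise floor from pre-onset samples when available, else from the
    # high-frequency residual of the trace
    if np.any(t < 0):
        noise_sd = float(np.std(y[t < 0]))
    elif y.size > 2:
        noise_sd = float(np.std(np.diff(y)) / np.sqrt(2.0))
    else:
        noise_sd = 0.0
    sel = (t >= 0.0) & (t <= config.fit_window_ms)
    t, y = t[sel], y[sel]
    drop = 1.0 - y
    # suppression is present when the mean drop over the late part of the
    # window clears 3x its standard error (smoothing correlates ~2.5*sigma
    # neighboring samples)
    late = t >= (2.0 / 3.0) * config.fit_window_ms
    if drop.size and np.any(late):
        corr_len = max(1.0, 2.5 * sigma_bins)
        se_late = noise_sd * np.sqrt(corr_len / max(np.sum(late), 1))
        late_drop = float(drop[late].mean())
    else:
        se_late, late_drop = 0.0, 0.0
    if drop.size == 0 or late_drop <= max(3.0 * se_late, 0.02):
        return ExpFitResult(
            delay1_ms=float("nan"), components=[(0.0, float("nan"))],
            delay2_ms=None, residual=0.0, n_components=0, no_suppression=True,
        )

    delays = np.arange(0.0, config.delay_max_ms + 1e-9, config.delay_step_ms)

    def sbasis(d: float, tau: float) -> np.ndarray:
        """Basis convolved with the same smoothing kernel as the data,
        so smoothing introduces no fitting bias."""
        b = _basis(t, d, tau)
        if sigma_bins > 0.25:
            b = ndimage.gaussian_filter1d(b, sigma=sigma_bins, mode="nearest")
        return b

    # precompute basis vectors for every (delay, tau) pair
    bases = {(d, tau): sbasis(d, tau) for d in delays for tau in _TAU_GRID_MS}

    def grid_search(n_comp: int, n_best: int = 1):
        found = []
        if n_comp == 1:
            for (d1, tau1), b in bases.items():
                a, r = _nnls1(drop, b)
                found.append((r, (d1, None, (a,), (tau1,))))
        else:
            for d1 in delays:
                for i, tau1 in enumerate(_TAU_GRID_MS):
                    b1 = bases[(d1, tau1)]
                    for d2 in delays[delays >= d1]:
                        for tau2 in _TAU_GRID_MS[i:]:
                            # the slow component must be kinetically distinct
                            if tau2 < _TAU_SEPARATION * tau1:
                                continue
                            a1, a2, r = _nnls2(drop, b1, bases[(d2, tau2)])
                            found.append((r, (d1, d2, (a1, a2), (tau1, tau2))))
        found.sort(key=lambda x: x[0])
        if n_best == 1:
            return found[0]
        # keep the best candidate per distinct delay pair
        seen, picks = set(), []
        for r, params in found:
            key = (params[0], params[1])
            if key in seen:
                continue
            seen.add(key)
            picks.append((r, params))
            if len(picks) >= n_best:
                break
        return picks

    def delay_regrid(tau1: float, tau2: float):
        """Best delay pair for fixed time constants."""
        b1s = {d: sbasis(d, tau1) for d in delays}
        b2s = {d: sbasis(d, tau2) for d in delays}
        best = (np.inf, None)
        for d1 in delays:
            b1 = b1s[d1]
            for d2 in delays[delays >= d1]:
                a1, a2, r = _nnls2(drop, b1, b2s[d2])
                if r < best[0]:
                    best = (r, (d1, d2, (a1, a2), (tau1, tau2)))
        return best

    def polish(n_comp: int, d1: float, d2, a0, taus):
        def resid(p):
            if n_comp == 1:
                a1, tau1 = p
                model = a1 * sbasis(d1, tau1)
            else:
                # tau2 parametrized as rho * tau1 with rho >= the minimal
                # separation, so the polish cannot collapse the components
                a1, tau1, a2, rho = p
                tau2 = min(rho * tau1, _TAU_BOUNDS_MS[1])
                model = a1 * sbasis(d1, tau1) + a2 * sbasis(d2, tau2)
            return model - drop

        if n_comp == 1:
            p0 = [float(a0[0]), float(taus[0])]
            lb = [_A_BOUNDS[0], _TAU_BOUNDS_MS[0]]
            ub = [_A_BOUNDS[1], _TAU_BOUNDS_MS[1]]
        else:
            rho0 = float(taus[1]) / float(taus[0])
            p0 = [float(a0[0]), float(taus[0]), float(a0[1]), rho0]
            lb = [_A_BOUNDS[0], _TAU_BOUNDS_MS[0], _A_BOUNDS[0], _TAU_SEPARATION]
            ub = [_A_BOUNDS[1], _TAU_BOUNDS_MS[1], _A_BOUNDS[1], 120.0]
        p0 = np.clip(p0, lb, ub)
        sol = optimize.least_squares(resid, p0, bounds=(lb, ub))
        x = sol.x.copy()
        if n_comp == 2:
            x[3] = min(x[3] * x[1], _TAU_BOUNDS_MS[1])  # back to tau2
        return x, float(np.sum(sol.fun**2))

    r1, (d1, _, a0, taus) = grid_search(1)
    p1, r1 = polish(1, d1, None, a0, taus)
    one = ExpFitResult(
        delay1_ms=float(d1), components=[(float(p1[0]), float(p1[1]))],
        delay2_ms=None, residual=r1, n_components=1,
    )
    if max_components < 2:
        return one

    # multistart: polish the best grid candidates, then alternate between
    # re-searching the delay grid at the polished time constants and
    # re-polishing, keeping the overall best
    best2 = (np.inf, None)
    for rg, (d1b, d2b, a0b, tausb) in grid_search(2, n_best=4):
        p2, r2 = polish(2, d1b, d2b, a0b, tausb)
        for _ in range(2):
            rr, (d1n, d2n, a0n, tausn) = delay_regrid(float(p2[1]), float(p2[3]))
            pn, rn = polish(2, d1n, d2n, a0n, tausn)
            if rn < r2 - 1e-12:
                d1b, d2b, p2, r2 = d1n, d2n, pn, rn
            else:
                break
        if r2 < best2[0]:
            best2 = (r2, (d1b, d2b, p2))
    r2, (d1b, d2b, p2) = best2
    comps = [(float(p2[0]), float(p2[1])), (float(p2[2]), float(p2[3]))]
    # order fast -> slow by time constant
    comps.sort(key=lambda c: c[1])
    # attribute delays to components consistently with amplitude order:
    # delay1 stays the earliest (the curve leaves baseline there)
    two = ExpFitResult(
        delay1_ms=float(min(d1b, d2b)), components=comps,
        delay2_ms=float(max(d1b, d2b)), residual=r2, n_components=2,
    )
    a2 = min(c[0] for c in comps)
    degenerate = comps[1][1] < 0.99 * _TAU_SEPARATION * comps[0][1]
    # BIC-style margin: the second component adds 3 parameters and must
    # reduce the residual beyond that penalty, not just absorb noise
    n = drop.size
    bic_margin = float(np.exp(-3.0 * np.log(n) / n)) if n > 1 else 1.0
    if a2 < config.a2_negligible or degenerate or two.residual >= bic_margin * one.residual:
        return one
    return two
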