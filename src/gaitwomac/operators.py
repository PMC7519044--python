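"""Signal operators applied to gait waveforms to produce scalar features.

These are the feature "vocabulary": time-domain summary statistics (mean,
RMS, crest factor, kurtosis, ...), windowed extrema and areas under the
curve, frequency-domain descriptors from the one-sided periodogram
(spectral AUC and 99 %-occupied bandwidth), the lower bound of the
normalized autocorrelation, the mid-reference level of the bilevel
histogram, and the dynamic-time-warping distance between the stance and
swing portions of the cycle.

Conventions:
- sd/variance use the n-1 denominator; kurtosis is the *non-excess* fourth
  standardized moment m4/m2^2 with n-denominator moments (Gaussian -> 3).
- peak2rms (crest factor) = max|x| / rms.
- The periodogram treats the cycle axis as sampled at 1 % intervals, so
  frequencies are in cycles per % of gait cycle.
- DTW uses absolute difference as the local cost with the unit step pattern
  {(1,0),(0,1),(1,1)} and no warping window (squared cost is available as a
  config switch).
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy import signal as sp_signal

from .cycle import GaitWaveform, PhaseMap, Window
from .errors import UndefinedStatisticError, ValidationError

SUMMARY_STAT_NAMES = (
    "mean",
    "mean_abs",
    "sd",
    "sd_abs",
    "variance",
    "rms",
    "peak2rms",
    "kurtosis",
    "max",
    "min",
    "max_minus_min",
)

_EPS = 0.0  # exact-zero checks; noise-free degenerate inputs are the only risk


def _as_1d(x, min_len: int, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < min_len:
        raise ValidationError(f"{what} requires a 1-D sequence of length >= {min_len}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} input contains non-finite values")
    return arr


def summary_statistics(x, stats=None) -> Dict[str, float]:
    """Time-domain summary statistics of a sequence.

    Requires length >= 2; kurtosis additionally requires length >= 4.
    ``stats`` restricts the computation to a subset of statistic names
    (default: all).  Zero variance makes kurtosis undefined and the
    all-zero signal makes peak2rms undefined; requesting either raises
    :class:`UndefinedStatisticError`.
    """
    arr = _as_1d(x, 2, "summary_statistics")
    requested = tuple(SUMMARY_STAT_NAMES) if stats is None else tuple(stats)
    unknown = [s for s in requested if s not in SUMMARY_STAT_NAMES]
    if unknown:
        raise ValidationError(f"unknown summary statistics {unknown}")
    if "kurtosis" in requested and arr.size < 4:
        if stats is None:
            requested = tuple(s for s in requested if s != "kurtosis")
        else:
            raise ValidationError("kurtosis requires length >= 4")
    out: Dict[str, float] = {}
    absx = np.abs(arr)
    for stat in requested:
        if stat == "mean":
            out[stat] = float(arr.mean())
        elif stat == "mean_abs":
            out[stat] = float(absx.mean())
        elif stat == "sd":
            out[stat] = float(arr.std(ddof=1))
        elif stat == "sd_abs":
            out[stat] = float(absx.std(ddof=1))
        elif stat == "variance":
            out[stat] = float(arr.var(ddof=1))
        elif stat == "rms":
            out[stat] = float(np.sqrt(np.mean(arr**2)))
        elif stat == "peak2rms":
            rms = float(np.sqrt(np.mean(arr**2)))
            if rms == 0.0:
                raise UndefinedStatisticError("peak2rms undefined for the all-zero signal")
            out[stat] = float(absx.max() / rms)
        elif stat == "kurtosis":
            m2 = float(np.mean((arr - arr.mean()) ** 2))
            if m2 == 0.0:
                raise UndefinedStatisticError("kurtosis undefined for a constant sequence")
            m4 = float(np.mean((arr - arr.mean()) ** 4))
            out[stat] = m4 / m2**2
        elif stat == "max":
            out[stat] = float(arr.max())
        elif stat == "min":
            out[stat] = float(arr.min())
        elif stat == "max_minus_min":
            out[stat] = float(arr.max() - arr.min())
    return out


def area_under_curve(waveform: GaitWaveform | np.ndarray, window: Window, phase_map: PhaseMap) -> float:
    """Signed trapezoidal integral of value against cycle-percent within the
    window (units: value x % cycle)."""
    idx = phase_map.window_indices(window)
    values = waveform.values if isinstance(waveform, GaitWaveform) else np.asarray(waveform, float)
    return float(np.trapezoid(values[idx], idx.astype(float)))


def phase_extremum(
    waveform: GaitWaveform | np.ndarray, window: Window, phase_map: PhaseMap, which: str
) -> float:
    """Minimum or maximum of the waveform within a (possibly compound)
    sub-phase window."""
    if which not in ("min", "max"):
        raise ValidationError(f"which must be 'min' or 'max', got {which!r}")
    idx = phase_map.window_indices(window)
    values = waveform.values if isinstance(waveform, GaitWaveform) else np.asarray(waveform, float)
    sl = values[idx]
    return float(sl.min() if which == "min" else sl.max())


def periodogram_cycle(x) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of a mean-removed cycle-normalized sequence.

    Sampling interval is 1 % of the cycle, so frequencies are in cycles per
    percent of gait cycle and the density integrates to the population
    variance (Parseval).
    """
    arr = _as_1d(x, 16, "periodogram_cycle")
    centred = arr - arr.mean()
    freqs, pxx = sp_signal.periodogram(
        centred, fs=1.0, window="boxcar", detrend=False, scaling="density"
    )
    return freqs, pxx


def psd_features(x, occupied_fraction: float = 0.99) -> Dict[str, float]:
    """Spectral features: periodogram AUC plus the occupied bandwidth.

    The occupied bandwidth is the width of the smallest centered frequency
    interval containing ``occupied_fraction`` (default 99 %) of the total
    power, i.e. the interval excluding the lowest and highest
    (1-fraction)/2 tails of cumulative power; its (lower, upper) bounds are
    reported alongside.
    """
    if not (0.0 < occupied_fraction < 1.0):
        raise ValidationError("occupied_fraction must lie in (0, 1)")
    freqs, pxx = periodogram_cycle(x)
    total = float(np.sum(pxx))
    if total <= 0.0:
        raise UndefinedStatisticError("spectral features undefined for a constant sequence")
    df = float(freqs[1] - freqs[0])
    auc = float(np.trapezoid(pxx, freqs))
    cum = np.cumsum(pxx)
    tail = (1.0 - occupied_fraction) / 2.0

    def _crossing(target: float) -> float:
        # each bin j carries its power uniformly over [f_j - df/2, f_j + df/2]
        j = int(np.searchsorted(cum, target, side="left"))
        j = min(j, pxx.size - 1)
        prev = float(cum[j - 1]) if j > 0 else 0.0
        frac = (target - prev) / float(pxx[j]) if pxx[j] > 0 else 0.5
        return float(freqs[j]) - df / 2 + frac * df

    lower = max(_crossing(tail * total), float(freqs[0]))
    upper = min(_crossing((1.0 - tail) * total), float(freqs[-1]))
    return {
        "psd_auc": auc,
        "occupied_bandwidth": upper - lower,
        "bandwidth_lower": lower,
        "bandwidth_upper": upper,
    }


def autocorr_lower_bound(x) -> float:
    """Minimum over lags 1..n-1 of the biased, mean-removed, normalized
    autocorrelation r(k) = sum (x_t - xbar)(x_{t+k} - xbar) / sum (x_t - xbar)^2."""
    arr = _as_1d(x, 2, "autocorr_lower_bound")
    d = arr - arr.mean()
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise UndefinedStatisticError("autocorrelation undefined for a constant sequence")
    full = np.correlate(d, d, mode="full")
    r = full[arr.size :] / denom  # lags 1..n-1 (r(0)=1 excluded)
    return float(r.min())


def mid_reference_level(x, bins: int = 100) -> float:
    """Midpoint of the two state levels of a (nominally bilevel) signal.

    State levels are estimated by the bimodal-histogram method: histogram
    the samples (default 100 bins over the data range), split the occupied
    bins into a lower and an upper half, and take the mode of each half as
    the low/high state.  A constant input is its own mid-reference level.
    """
    arr = _as_1d(x, 8, "mid_reference_level")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(arr, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = np.flatnonzero(counts)
    half = occupied.size // 2
    low_bins = occupied[: half or 1]
    high_bins = occupied[half or 1 :]
    low_state = centers[low_bins[np.argmax(counts[low_bins])]]
    high_state = centers[high_bins[np.argmax(counts[high_bins])]]
    return float(0.5 * (low_state + high_state))


def dtw_distance(a, b, cost: str = "abs") -> float:
    """Classic dynamic-time-warping distance between two sequences.

    Local cost is |a_i - b_j| (or squared difference with cost='squared'),
    step pattern {(1,0),(0,1),(1,1)}, boundary-aligned, no warping window.
    Returns the accumulated cost of the optimal path.
    """
    from ._dtw import dtw_cost  # deferred: numba compilation on first use

    arr_a = _as_1d(a, 1, "dtw_distance")
    arr_b = _as_1d(b, 1, "dtw_distance")
    if cost not in ("abs", "squared"):
        raise ValidationError(f"cost must be 'abs' or 'squared', got {cost!r}")
    return float(dtw_cost(arr_a, arr_b, cost == "squared"))


def dtw_stance_swing(
    waveform: GaitWaveform | np.ndarray, phase_map: PhaseMap, cost: str = "abs"
) -> float:
    """DTW distance between the stance-phase and swing-phase portions of a
    waveform — a shape-dissimilarity measure between the two halves of the
    gait cycle."""
    values = waveform.values if isinstance(waveform, GaitWaveform) else np.asarray(waveform, float)
    stance = values[phase_map.window_indices("stance")]
    swing = values[phase_map.window_indices("swing")]
    if stance.size < 2 or swing.size < 2:
        raise ValidationError("stance and swing slices must each have length >= 2")
    return dtw_distance(stance, swing, cost=cost)
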