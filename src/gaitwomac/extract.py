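"""Build the subjects x features matrix from gait trials and a registry.

Two paths compute the same features:

- :func:`extract_all` evaluates one trial descriptor-by-descriptor through
  the public scalar operators — the reference path.
- :func:`extract_matrix` evaluates a whole cohort with vectorized numpy
  (and a batched DTW kernel), grouping descriptors by operator and window.
  Values agree with the scalar path to floating-point round-off.

Statistics that are undefined for a subject's data (zero-variance kurtosis,
zero-signal crest factor) are recorded in the missing mask rather than
raising, so downstream selection can drop affected features explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import operators as ops
from ._dtw import dtw_batch
from .cycle import GaitTrial, PhaseMap, default_phase_map
from .errors import UndefinedStatisticError, ValidationError
from .registry import FeatureDescriptor

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Subjects x features with provenance metadata and a missing mask."""

    subject_ids: List[str]
    descriptors: List[FeatureDescriptor]
    values: np.ndarray  # (n_subjects, n_features)
    missing: np.ndarray = field(default=None)  # bool, same shape

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.subject_ids), len(self.descriptors)
        if self.values.shape != (n, p):
            raise ValidationError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{n} subjects x {p} descriptors"
            )
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        nan_unmasked = ~np.isfinite(self.values) & ~self.missing
        if nan_unmasked.any():
            raise ValidationError("feature matrix contains non-finite values outside the mask")

    @property
    def feature_ids(self) -> List[str]:
        return [d.feature_id for d in self.descriptors]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_ids)
        df.index.name = "subject_id"
        return df.mask(pd.DataFrame(self.missing, index=df.index, columns=df.columns))

    def drop_masked_features(self) -> "FeatureMatrix":
        """Drop any feature with a masked value for any subject (logged)."""
        bad = self.missing.any(axis=0)
        if bad.any():
            logger.warning(
                "dropping %d feature(s) with undefined values: %s",
                int(bad.sum()),
                [d.feature_id for d, b in zip(self.descriptors, bad) if b][:10],
            )
        keep = ~bad
        return FeatureMatrix(
            subject_ids=list(self.subject_ids),
            descriptors=[d for d, k in zip(self.descriptors, keep) if k],
            values=self.values[:, keep],
            missing=self.missing[:, keep],
        )


def _scalar_feature(trial: GaitTrial, desc: FeatureDescriptor) -> float:
    """Evaluate one descriptor on one trial through the public operators.
    Returns NaN for undefined statistics (masked by the caller)."""
    pm = trial.phase_map
    if desc.window is None or desc.operator == "value":
        if desc.parameter not in trial.spatiotemporal:
            raise ValidationError(f"unknown spatiotemporal parameter {desc.parameter!r}")
        return float(trial.spatiotemporal[desc.parameter])
    if desc.parameter not in trial.waveforms:
        raise ValidationError(f"trial {trial.subject_id!r} lacks parameter {desc.parameter!r}")
    wf = trial.waveforms[desc.parameter]
    try:
        if desc.operator in ("min", "max"):
            return ops.phase_extremum(wf, desc.window, pm, desc.operator)
        if desc.operator in ops.SUMMARY_STAT_NAMES:
            sl = wf.values[pm.window_indices(desc.window)]
            return ops.summary_statistics(sl, stats=[desc.operator])[desc.operator]
        if desc.operator == "auc":
            return ops.area_under_curve(wf, desc.window, pm)
        if desc.operator in ("psd_auc", "occupied_bandwidth", "bandwidth_lower", "bandwidth_upper"):
            return ops.psd_features(wf.values)[desc.operator]
        if desc.operator == "autocorr_lower_bound":
            return ops.autocorr_lower_bound(wf.values)
        if desc.operator == "mid_reference_level":
            return ops.mid_reference_level(wf.values)
        if desc.operator == "dtw_stance_swing":
            return ops.dtw_stance_swing(wf, pm)
    except UndefinedStatisticError:
        return np.nan
    raise ValidationError(f"unknown operator {desc.operator!r}")


def extract_all(trial: GaitTrial, registry: Sequence[FeatureDescriptor]) -> np.ndarray:
    """One feature row for a single trial, in registry order (NaN marks an
    undefined statistic; callers mask it)."""
    return np.array([_scalar_feature(trial, d) for d in registry], dtype=float)


# ---------------------------------------------------------------------------
# vectorized cohort path


def _stack_parameter(trials: Sequence[GaitTrial], parameter: str) -> np.ndarray:
    try:
        return np.vstack([t.waveforms[parameter].values for t in trials])
    except KeyError:
        missing = [t.subject_id for t in trials if parameter not in t.waveforms][:5]
        raise ValidationError(
            f"parameter {parameter!r} missing for subjects {missing}"
        ) from None


def _batch_summary(X: np.ndarray, stat: str) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        if stat == "mean":
            return X.mean(axis=1)
        if stat == "mean_abs":
            return np.abs(X).mean(axis=1)
        if stat == "sd":
            return X.std(axis=1, ddof=1)
        if stat == "sd_abs":
            return np.abs(X).std(axis=1, ddof=1)
        if stat == "variance":
            return X.var(axis=1, ddof=1)
        if stat == "rms":
            return np.sqrt(np.mean(X**2, axis=1))
        if stat == "peak2rms":
            rms = np.sqrt(np.mean(X**2, axis=1))
            out = np.abs(X).max(axis=1) / rms
            out[rms == 0] = np.nan
            return out
        if stat == "kurtosis":
            if X.shape[1] < 4:
                return np.full(X.shape[0], np.nan)
            c = X - X.mean(axis=1, keepdims=True)
            m2 = np.mean(c**2, axis=1)
            m4 = np.mean(c**4, axis=1)
            out = m4 / m2**2
            out[m2 == 0] = np.nan
            return out
        if stat == "max":
            return X.max(axis=1)
        if stat == "min":
            return X.min(axis=1)
        if stat == "max_minus_min":
            return X.max(axis=1) - X.min(axis=1)
    raise ValidationError(f"unknown summary statistic {stat!r}")


def _batch_psd(X: np.ndarray, occupied_fraction: float) -> Dict[str, np.ndarray]:
    centred = X - X.mean(axis=1, keepdims=True)
    freqs, pxx = sp_signal.periodogram(
        centred, fs=1.0, window="boxcar", detrend=False, scaling="density", axis=1
    )
    df = float(freqs[1] - freqs[0])
    auc = np.trapezoid(pxx, freqs, axis=1)
    cum = np.cumsum(pxx, axis=1)
    total = cum[:, -1]
    tail = (1.0 - occupied_fraction) / 2.0
    n = X.shape[0]
    lower = np.full(n, np.nan)
    upper = np.full(n, np.nan)
    for i in range(n):  # crossing search is cheap relative to the FFT
        if total[i] <= 0:
            continue
        for target, out in ((tail * total[i], lower), ((1 - tail) * total[i], upper)):
            j = min(int(np.searchsorted(cum[i], target, side="left")), pxx.shape[1] - 1)
            prev = cum[i, j - 1] if j > 0 else 0.0
            frac = (target - prev) / pxx[i, j] if pxx[i, j] > 0 else 0.5
            out[i] = freqs[j] - df / 2 + frac * df
    lower = np.maximum(lower, freqs[0])
    upper = np.minimum(upper, freqs[-1])
    auc = np.where(total > 0, auc, np.nan)
    return {
        "psd_auc": auc,
        "occupied_bandwidth": upper - lower,
        "bandwidth_lower": lower,
        "bandwidth_upper": upper,
    }


def _batch_autocorr_lower(X: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    d = X - X.mean(axis=1, keepdims=True)
    denom = np.sum(d**2, axis=1)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(d, n=nfft, axis=1)
    acov = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, 1:n]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = acov / denom[:, None]
    out = r.min(axis=1)
    out[denom == 0] = np.nan
    return out


def _batch_mid_reference(X: np.ndarray, bins: int = 100) -> np.ndarray:
    return np.array([ops.mid_reference_level(row, bins=bins) for row in X])


def extract_matrix(
    trials: Sequence[GaitTrial],
    registry: Sequence[FeatureDescriptor],
    occupied_fraction: float = 0.99,
) -> FeatureMatrix:
    """Vectorized cohort extraction; one row per trial, registry order."""
    if len(trials) == 0:
        raise ValidationError("no trials to extract")
    pm: PhaseMap = trials[0].phase_map if trials else default_phase_map()
    # group descriptor columns by (parameter, operator-family) for batching
    n, p = len(trials), len(registry)
    values = np.empty((n, p))
    by_param: Dict[str, List[int]] = {}
    for col, desc in enumerate(registry):
        by_param.setdefault(desc.parameter, []).append(col)

    param_cache: Dict[str, np.ndarray] = {}
    psd_cache: Dict[str, Dict[str, np.ndarray]] = {}
    for param, cols in by_param.items():
        first = registry[cols[0]]
        if first.window is None or first.operator == "value":
            vals = []
            for t in trials:
                if param not in t.spatiotemporal:
                    raise ValidationError(
                        f"trial {t.subject_id!r} lacks spatiotemporal parameter {param!r}"
                    )
                vals.append(float(t.spatiotemporal[param]))
            col_vals = np.asarray(vals)
            for col in cols:
                values[:, col] = col_vals
            continue
        X = param_cache.setdefault(param, _stack_parameter(trials, param))
        for col in cols:
            desc = registry[col]
            op = desc.operator
            if op in ops.SUMMARY_STAT_NAMES:
                idx = pm.window_indices(desc.window)
                values[:, col] = _batch_summary(X[:, idx], op)
            elif op == "auc":
                idx = pm.window_indices(desc.window)
                values[:, col] = np.trapezoid(X[:, idx], idx.astype(float), axis=1)
            elif op in ("psd_auc", "occupied_bandwidth", "bandwidth_lower", "bandwidth_upper"):
                if param not in psd_cache:
                    psd_cache[param] = _batch_psd(X, occupied_fraction)
                values[:, col] = psd_cache[param][op]
            elif op == "autocorr_lower_bound":
                values[:, col] = _batch_autocorr_lower(X)
            elif op == "mid_reference_level":
                values[:, col] = _batch_mid_reference(X)
            elif op == "dtw_stance_swing":
                values[:, col] = dtw_batch(
                    X, pm.window_indices("stance"), pm.window_indices("swing")
                )
            else:
                raise ValidationError(f"unknown operator {op!r}")

    return FeatureMatrix(
        subject_ids=[t.subject_id for t in trials],
        descriptors=list(registry),
        values=values,
    )
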