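"""Gait-cycle waveforms, cycle normalization, and phase segmentation.

A gait cycle runs from one initial contact of a foot to its next initial
contact.  Waveforms (joint angles in degrees, moments in N·m/kg, powers in
W/kg) are resampled onto a common axis of 101 points at 0, 1, ..., 100 % of
the cycle — the dominant gait-lab convention.

The cycle splits at toe-off (default 60 %) into stance and swing, and
further into seven named sub-phases.  Stance sub-phases follow the standard
proportional split (loading response = first 1/6 of stance, mid-stance and
terminal stance 2/6 each, pre-swing the final 1/6 — the classic
0/10/30/50/60 boundaries at a 60 % toe-off); swing is split into equal
initial/mid/terminal thirds.  Windows are half-open [start, end) with the
final window closed at 100 so the seven sub-phases partition the cycle
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple, Union

import numpy as np

from .errors import ValidationError

N_CYCLE_POINTS = 101
CYCLE_AXIS = np.arange(N_CYCLE_POINTS, dtype=float)  # 0..100 % inclusive

STANCE_SUBPHASES = ("loading_response", "mid_stance", "terminal_stance", "pre_swing")
SWING_SUBPHASES = ("initial_swing", "mid_swing", "terminal_swing")
SUBPHASES = STANCE_SUBPHASES + SWING_SUBPHASES

#: Stance sub-phase boundaries as fractions of the stance interval.
_STANCE_FRACTIONS = (0.0, 1 / 6, 3 / 6, 5 / 6, 1.0)

Window = Union[str, Tuple[str, ...]]


@dataclass(frozen=True)
class PhaseMap:
    """Stance/swing boundary plus the seven named sub-phase windows."""

    toe_off_pct: float
    subphases: Dict[str, Tuple[float, float]]

    def window_bounds(self, window: Window) -> Tuple[float, float]:
        """Resolve a window name (sub-phase, 'stance', 'swing', 'full', or a
        tuple of adjacent sub-phases) to (start_pct, end_pct)."""
        if isinstance(window, tuple):
            return _compound_bounds(self, window)
        if window == "full":
            return (0.0, 100.0)
        if window == "stance":
            return (0.0, self.toe_off_pct)
        if window == "swing":
            return (self.toe_off_pct, 100.0)
        try:
            return self.subphases[window]
        except KeyError:
            raise ValidationError(
                f"unknown window {window!r}; expected one of "
                f"{SUBPHASES + ('stance', 'swing', 'full')} or a tuple of adjacent sub-phases"
            ) from None

    def window_indices(self, window: Window) -> np.ndarray:
        """Integer cycle positions covered by the window: [start, end), with
        the cycle endpoint 100 included when end == 100."""
        start, end = self.window_bounds(window)
        lo = int(np.ceil(start - 1e-9))
        hi_exclusive = end - 1e-9
        idx = np.arange(lo, int(np.floor(hi_exclusive)) + 1)
        if end >= 100.0 - 1e-9:
            idx = np.arange(lo, N_CYCLE_POINTS)
        if idx.size == 0:
            raise ValidationError(f"window {window!r} with bounds {(start, end)} is empty")
        return idx


def _compound_bounds(phase_map: PhaseMap, names: Tuple[str, ...]) -> Tuple[float, float]:
    """Bounds of a union of adjacent sub-phases, e.g. terminal stance
    through pre-swing."""
    if not names or any(n not in phase_map.subphases for n in names):
        raise ValidationError(f"compound window {names!r} must name sub-phases")
    order = [SUBPHASES.index(n) for n in names]
    if order != list(range(order[0], order[0] + len(order))):
        raise ValidationError(f"compound window {names!r} must list adjacent sub-phases in order")
    return (phase_map.subphases[names[0]][0], phase_map.subphases[names[-1]][1])


def window_label(window: Window) -> str:
    """Canonical string form of a window for feature ids."""
    if isinstance(window, tuple):
        return "+".join(window)
    return window


def default_phase_map(toe_off_pct: float = 60.0) -> PhaseMap:
    """Build the standard proportional sub-phase map for a given toe-off.

    Stance sub-phases scale within [0, toe_off]; swing splits into thirds of
    [toe_off, 100].  toe-off must lie in [30, 80] % (physiological range).
    """
    if not (30.0 <= toe_off_pct <= 80.0):
        raise ValidationError(f"toe_off_pct must be in [30, 80], got {toe_off_pct}")
    to = float(toe_off_pct)
    bounds = [f * to for f in _STANCE_FRACTIONS]
    sub: Dict[str, Tuple[float, float]] = {}
    for name, lo, hi in zip(STANCE_SUBPHASES, bounds[:-1], bounds[1:]):
        sub[name] = (lo, hi)
    swing_len = 100.0 - to
    for k, name in enumerate(SWING_SUBPHASES):
        sub[name] = (to + k * swing_len / 3, to + (k + 1) * swing_len / 3)
    sub["terminal_swing"] = (sub["terminal_swing"][0], 100.0)
    return PhaseMap(toe_off_pct=to, subphases=sub)


@dataclass(frozen=True)
class GaitWaveform:
    """One gait parameter's values over the normalized 0..100 % cycle."""

    parameter_name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_CYCLE_POINTS,):
            raise ValidationError(
                f"waveform {self.parameter_name!r} must have {N_CYCLE_POINTS} samples, "
                f"got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"waveform {self.parameter_name!r} contains non-finite values")
        object.__setattr__(self, "values", vals)


@dataclass
class GaitTrial:
    """One subject's waveform set plus spatiotemporal scalars (right side
    only, to avoid statistical dependency between limbs)."""

    subject_id: str
    waveforms: Dict[str, GaitWaveform]
    spatiotemporal: Dict[str, float] = field(default_factory=dict)
    phase_map: PhaseMap = field(default_factory=default_phase_map)
    side: str = "right"

    def __post_init__(self):
        if self.side != "right":
            raise ValidationError("only right-side trials are supported")


def normalize_cycle(
    raw_samples: Sequence[float], parameter_name: str = "", units: str = ""
) -> GaitWaveform:
    """Resample one gait cycle onto 101 evenly spaced cycle positions by
    linear interpolation, preserving the endpoints.

    ``raw_samples`` must span exactly one cycle and contain at least 8
    finite samples (e.g. a stride captured at 120 Hz).
    """
    raw = np.asarray(raw_samples, dtype=float)
    if raw.ndim != 1 or raw.size < 8:
        raise ValidationError(f"need at least 8 samples spanning one cycle, got {raw.size}")
    if not np.all(np.isfinite(raw)):
        raise ValidationError("raw samples contain non-finite values")
    src = np.linspace(0.0, 100.0, raw.size)
    values = np.interp(CYCLE_AXIS, src, raw)
    return GaitWaveform(parameter_name=parameter_name, values=values, units=units)


def slice_phase(
    waveform: GaitWaveform | np.ndarray, window: Window, phase_map: PhaseMap
) -> np.ndarray:
    """Samples of a normalized waveform whose cycle position falls in the
    window ([start, end); the final window is right-inclusive at 100)."""
    values = waveform.values if isinstance(waveform, GaitWaveform) else np.asarray(waveform)
    return values[phase_map.window_indices(window)]


def average_trials(cycles: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise mean of several normalized cycles (multi-trial averaging of
    the five-or-six walks collected per subject)."""
    if not cycles:
        raise ValidationError("no cycles to average")
    stack = np.vstack([np.asarray(c, dtype=float) for c in cycles])
    if stack.shape[1] != N_CYCLE_POINTS:
        raise ValidationError("cycles must be normalized to 101 points before averaging")
    return stack.mean(axis=0)
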