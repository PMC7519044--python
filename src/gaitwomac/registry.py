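"""Feature registries: which (parameter, operator, window) triples to extract.

Two registries ship with the package:

- :func:`default_registry` — the full grid: every summary statistic and the
  windowed AUC over the ten windows (full cycle, stance, swing, and the
  seven sub-phases), the four spectral features, the autocorrelation lower
  bound, the mid-reference level and the stance/swing DTW distance per
  waveform parameter, plus the spatiotemporal scalars as identity features.
  With the twelve standard waveform parameters this exceeds 1500 features.

- :func:`key_feature_registry` — the pinned 42-feature sub-registry of
  severity-discriminating features (windowed extrema, AUCs, crest factors,
  spectral and autocorrelation descriptors across hip, pelvis, knee, ankle,
  foot and spatiotemporal parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .cycle import SUBPHASES, Window, window_label
from .errors import ValidationError
from .operators import SUMMARY_STAT_NAMES

#: The twelve standard waveform parameters with their units.
WAVEFORM_PARAMETERS: Dict[str, str] = {
    "hip_rotation_moment": "N·m/kg",
    "hip_flexion_angle": "deg",
    "hip_adduction_angle": "deg",
    "hip_power": "W/kg",
    "pelvic_obliquity_angle": "deg",
    "knee_extension_moment": "N·m/kg",
    "knee_flexion_angle": "deg",
    "knee_power": "W/kg",
    "knee_varus_angle": "deg",
    "ankle_plantarflexion_moment": "N·m/kg",
    "ankle_power": "W/kg",
    "foot_progression_angle": "deg",
}

#: Default spatiotemporal scalars (a configurable registry of further
#: characteristics may extend this).
SPATIOTEMPORAL_PARAMETERS: Dict[str, str] = {
    "total_speed": "cm/s",
    "single_limb_support_duration": "% cycle",
    "initial_double_limb_support_timing": "% cycle",
    "weight_acceptance_timing": "% cycle",
}

#: Windows over which summary statistics and AUC are computed.
GRID_WINDOWS: Tuple[str, ...] = ("full", "stance", "swing") + SUBPHASES

#: Operators computed on the full cycle only.
FULL_ONLY_OPERATORS = (
    "psd_auc",
    "occupied_bandwidth",
    "bandwidth_lower",
    "bandwidth_upper",
    "autocorr_lower_bound",
    "mid_reference_level",
    "dtw_stance_swing",
)


@dataclass(frozen=True)
class FeatureDescriptor:
    """A named feature: parameter + operator + window, with a canonical id
    of the form ``parameter.operator.window`` (window omitted for
    spatiotemporal identity features)."""

    parameter: str
    operator: str
    window: Optional[Window] = "full"
    units: str = ""

    @property
    def feature_id(self) -> str:
        if self.window is None:
            return f"{self.parameter}.{self.operator}"
        return f"{self.parameter}.{self.operator}.{window_label(self.window)}"


def _check_unique(descriptors: Sequence[FeatureDescriptor]) -> List[FeatureDescriptor]:
    seen = set()
    for d in descriptors:
        if d.feature_id in seen:
            raise ValidationError(f"duplicate feature id {d.feature_id!r} in registry")
        seen.add(d.feature_id)
    return list(descriptors)


def default_registry(
    waveform_parameters: Optional[Dict[str, str]] = None,
    spatiotemporal_parameters: Optional[Dict[str, str]] = None,
) -> List[FeatureDescriptor]:
    """The full operator x window x parameter grid (>= 1000 features)."""
    wparams = WAVEFORM_PARAMETERS if waveform_parameters is None else waveform_parameters
    sparams = (
        SPATIOTEMPORAL_PARAMETERS
        if spatiotemporal_parameters is None
        else spatiotemporal_parameters
    )
    descriptors: List[FeatureDescriptor] = []
    for param, units in wparams.items():
        for window in GRID_WINDOWS:
            for stat in SUMMARY_STAT_NAMES:
                descriptors.append(FeatureDescriptor(param, stat, window, units))
            descriptors.append(FeatureDescriptor(param, "auc", window, f"{units}·%"))
        for op in FULL_ONLY_OPERATORS:
            descriptors.append(FeatureDescriptor(param, op, "full", units))
    for name, units in sparams.items():
        descriptors.append(FeatureDescriptor(name, "value", None, units))
    return _check_unique(descriptors)


def key_feature_registry() -> List[FeatureDescriptor]:
    """The pinned 42-entry registry of severity-discriminating key features."""
    u = WAVEFORM_PARAMETERS
    ts_pre = ("terminal_stance", "pre_swing")
    entries: List[FeatureDescriptor] = [
        FeatureDescriptor("hip_rotation_moment", "sd", "full", u["hip_rotation_moment"]),
        FeatureDescriptor("hip_flexion_angle", "autocorr_lower_bound", "full", ""),
        FeatureDescriptor("hip_flexion_angle", "bandwidth_lower", "full", "cycles/%"),
        FeatureDescriptor("hip_adduction_angle", "auc", "stance", "deg·%"),
        FeatureDescriptor("hip_adduction_angle", "sd_abs", "full", "deg"),
        FeatureDescriptor("hip_power", "min", "mid_stance", u["hip_power"]),
        FeatureDescriptor("hip_power", "max", "terminal_stance", u["hip_power"]),
        FeatureDescriptor("hip_power", "auc", "full", "W/kg·%"),
        FeatureDescriptor("hip_power", "max_minus_min", "full", u["hip_power"]),
        FeatureDescriptor("hip_power", "dtw_stance_swing", "full", u["hip_power"]),
        FeatureDescriptor("hip_power", "max", "mid_swing", u["hip_power"]),
        FeatureDescriptor("hip_power", "min", "terminal_swing", u["hip_power"]),
        FeatureDescriptor("pelvic_obliquity_angle", "min", ts_pre, "deg"),
        FeatureDescriptor("knee_extension_moment", "kurtosis", "full", ""),
        FeatureDescriptor("knee_extension_moment", "peak2rms", "full", ""),
        FeatureDescriptor("knee_flexion_angle", "variance", "full", "deg²"),
        FeatureDescriptor("knee_flexion_angle", "sd", "full", "deg"),
        FeatureDescriptor("knee_flexion_angle", "max_minus_min", "full", "deg"),
        FeatureDescriptor("knee_flexion_angle", "psd_auc", "full", "deg²"),
        FeatureDescriptor("knee_power", "max", "terminal_swing", u["knee_power"]),
        FeatureDescriptor("knee_varus_angle", "max", "mid_stance", "deg"),
        FeatureDescriptor("knee_varus_angle", "max", "terminal_stance", "deg"),
        FeatureDescriptor("knee_varus_angle", "auc", "stance", "deg·%"),
        FeatureDescriptor("knee_varus_angle", "auc", "full", "deg·%"),
        FeatureDescriptor("knee_varus_angle", "rms", "full", "deg"),
        FeatureDescriptor("knee_varus_angle", "peak2rms", "full", ""),
        FeatureDescriptor("knee_varus_angle", "mid_reference_level", "full", "deg"),
        FeatureDescriptor("knee_varus_angle", "psd_auc", "full", "deg²"),
        FeatureDescriptor("knee_varus_angle", "max", "terminal_swing", "deg"),
        FeatureDescriptor("knee_varus_angle", "min", "loading_response", "deg"),
        FeatureDescriptor("ankle_plantarflexion_moment", "min", "loading_response", "N·m/kg"),
        FeatureDescriptor("ankle_plantarflexion_moment", "max", "initial_swing", "N·m/kg"),
        FeatureDescriptor("ankle_plantarflexion_moment", "max_minus_min", "full", "N·m/kg"),
        FeatureDescriptor("ankle_power", "kurtosis", "full", ""),
        FeatureDescriptor("ankle_power", "peak2rms", "full", ""),
        FeatureDescriptor("ankle_power", "max_minus_min", "full", u["ankle_power"]),
        FeatureDescriptor("ankle_power", "autocorr_lower_bound", "full", ""),
        FeatureDescriptor("ankle_power", "occupied_bandwidth", "full", "cycles/%"),
        FeatureDescriptor("foot_progression_angle", "mean_abs", "full", "deg"),
        FeatureDescriptor("total_speed", "value", None, "cm/s"),
        FeatureDescriptor("single_limb_support_duration", "value", None, "% cycle"),
        FeatureDescriptor("initial_double_limb_support_timing", "value", None, "% cycle"),
    ]
    return _check_unique(entries)


def registry_by_name(name: str) -> List[FeatureDescriptor]:
    if name in ("full", "default"):
        return default_registry()
    if name in ("key", "key42"):
        return key_feature_registry()
    raise ValidationError(f"unknown registry {name!r}; expected 'full' or 'key'")
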