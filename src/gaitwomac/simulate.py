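"""Synthetic gait cohorts with severity-dependent structure.

A single latent severity scalar in [0, 1] drives both the gait waveform
effects and the WOMAC score of each synthetic subject, reflecting the
premise that gait degrades with symptomatic severity.  Subjects are
generated in three groups (default sizes 140/182/53) whose WOMAC totals are
calibrated to group means/SDs of 18.9 (11.9), 48.5 (6.8) and 71.7 (10.3)
points, and whose waveforms are a per-parameter baseline template plus a
latent-scaled effect profile plus smooth low-order Fourier noise (so
waveforms stay physiological).

Effect directions follow the severity-discriminating pattern of the key
features: knee varus angle amplifies with severity (so its stance AUC, RMS
and mid-reference level increase), knee flexion excursion compresses about
its mean (variance, SD and range decrease), hip adduction attenuates,
walking speed and single-limb support decrease, and initial double-limb
support lengthens.  Magnitudes and template shapes are set for clear
statistical detectability rather than biomechanical fidelity; see
docs/methods.md.

``planted_truth`` defines the ground-truth key-feature set operationally: a
feature is planted when its generator-implied *pairwise detectability* — the
minimum over the three severity-class pairs of the pairwise Cohen's d
divided by that pair's critical effect size at the Bonferroni alpha and the
study's class sizes — reaches 75 % (estimated on one large internal
cohort).  Features at the detectability edge are deliberately counted as
planted, so recovery tests measure the selection procedure rather than the
generator; clearly sub-critical features (score well below the threshold)
must not be selected.  The default effects are shaped so this score
spectrum is strongly bimodal around the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .cycle import CYCLE_AXIS, GaitTrial, GaitWaveform, default_phase_map
from .errors import ValidationError
from .extract import extract_matrix
from .registry import WAVEFORM_PARAMETERS, FeatureDescriptor, default_registry
from .womac import N_ITEMS, SUBSCALE_ITEMS, WOMACRecord, score_womac

GROUPS = ("mild", "moderate", "severe")

#: WOMAC total calibration targets per group: (mean, sd).
WOMAC_GROUP_MEANS = {"mild": 18.9, "moderate": 48.5, "severe": 71.7}
WOMAC_GROUP_SDS = {"mild": 11.9, "moderate": 6.8, "severe": 10.3}

#: Latent severity distribution per group (before truncation to [0, 1]).
LATENT_GROUP_MEANS = {"mild": 0.15, "moderate": 0.5, "severe": 0.85}
LATENT_WITHIN_SD = 0.07
_Z_TRUNC = 2.1  # latent z truncated to +/- 2.1 so latents stay in [0, 1]


def _vm(t: np.ndarray, center: float, kappa: float) -> np.ndarray:
    """Periodic (von Mises style) bump on the unit cycle: 1 at ``center``,
    decaying with sharpness ``kappa``."""
    return np.exp(kappa * (np.cos(2 * np.pi * (t - center)) - 1.0))


def _templates(t: np.ndarray) -> Dict[str, np.ndarray]:
    """Baseline waveform per parameter: low-order harmonic/bump mixtures
    shaped by eye to canonical gait curves."""
    return {
        "hip_rotation_moment": 0.15 * np.sin(2 * np.pi * t) + 0.10 * np.sin(4 * np.pi * t),
        "hip_flexion_angle": 10.0 + 20.0 * np.cos(2 * np.pi * t),
        "hip_adduction_angle": 7.5 + 0.7 * np.cos(2 * np.pi * (t - 0.17)),
        "hip_power": (
            0.8 * _vm(t, 0.08, 20)
            - 1.2 * _vm(t, 0.42, 20)
            + 2.2 * _vm(t, 0.62, 30)
            - 0.6 * _vm(t, 0.85, 15)
        ),
        "pelvic_obliquity_angle": 1.0 + 4.0 * np.sin(2 * np.pi * t),
        "knee_extension_moment": (
            0.35 * _vm(t, 0.15, 25) - 0.25 * _vm(t, 0.45, 20) + 0.10 * np.sin(2 * np.pi * t)
        ),
        "knee_flexion_angle": 8.0 + 55.0 * _vm(t, 0.73, 10),
        "knee_power": (
            -1.0 * _vm(t, 0.10, 25)
            + 0.5 * _vm(t, 0.35, 20)
            - 2.5 * _vm(t, 0.58, 35)
            - 1.8 * _vm(t, 0.92, 25)
        ),
        "knee_varus_angle": 5.5 + 0.7 * _vm(t, 0.30, 8) + 0.5 * _vm(t, 0.80, 10),
        "ankle_plantarflexion_moment": 1.45 * _vm(t, 0.44, 6) - 0.20 * _vm(t, 0.05, 25),
        "ankle_power": (
            -0.6 * _vm(t, 0.30, 4) + 3.8 * _vm(t, 0.55, 45) - 0.3 * _vm(t, 0.85, 10)
        ),
        "foot_progression_angle": -8.0 + 2.0 * np.cos(2 * np.pi * t) + 1.5 * _vm(t, 0.60, 5),
    }


@dataclass(frozen=True)
class WaveformEffect:
    """Additive severity effect profile for one parameter.

    kind 'offset'          : magnitude * 1 over the whole cycle
    kind 'scale'           : magnitude * template (shrinks/amplifies)
    kind 'scale_excursion' : magnitude * (template - min template)
    kind 'scale_centered'  : magnitude * (template - mean template)
                             (compresses the excursion about the mean:
                             variance/range shrink, the mean level stays)
    kind 'bump'            : magnitude * periodic bump(center, kappa)
    The subject's waveform gains latent * effect_scale * profile.
    """

    kind: str
    magnitude: float
    center: float = 0.0
    kappa: float = 20.0

    def profile(self, t: np.ndarray, template: np.ndarray) -> np.ndarray:
        if self.kind == "offset":
            return self.magnitude * np.ones_like(t)
        if self.kind == "scale":
            return self.magnitude * template
        if self.kind == "scale_excursion":
            return self.magnitude * (template - template.min())
        if self.kind == "scale_centered":
            return self.magnitude * (template - template.mean())
        if self.kind == "bump":
            return self.magnitude * _vm(t, self.center, self.kappa)
        raise ValidationError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class SpatiotemporalSpec:
    """Baseline + latent slope + gaussian noise for one scalar."""

    baseline: float
    slope: float
    noise_sd: float


#: per-parameter noise composition as (offset, harmonics 1-3, harmonics 4-6)
#: weights on the parameter's noise scale.  The excursion-compressed knee
#: flexion gets little offset noise: its planted signal lives in the window
#: levels and dispersion, so a large common offset would only blur it.
_NOISE_WEIGHTS: Dict[str, Tuple[float, float, float]] = {
    "knee_flexion_angle": (0.3, 0.6, 0.2),
}
_DEFAULT_NOISE_WEIGHTS = (1.0, 0.6, 0.15)


def _default_waveform_effects() -> Dict[str, WaveformEffect]:
    return {
        "knee_varus_angle": WaveformEffect("scale", 0.80),
        "hip_adduction_angle": WaveformEffect("scale", -0.65),
        "knee_flexion_angle": WaveformEffect("scale_centered", -0.85),
    }


def _default_spatiotemporal() -> Dict[str, SpatiotemporalSpec]:
    return {
        "total_speed": SpatiotemporalSpec(88.0, -16.0, 3.5),
        "single_limb_support_duration": SpatiotemporalSpec(36.5, -4.5, 0.9),
        "initial_double_limb_support_timing": SpatiotemporalSpec(13.5, 4.5, 0.9),
        "weight_acceptance_timing": SpatiotemporalSpec(8.0, 0.0, 1.0),
    }


def _default_noise_sds() -> Dict[str, float]:
    """Per-parameter smooth-noise scale (units of the parameter)."""
    return {
        "hip_rotation_moment": 0.05,
        "hip_flexion_angle": 1.5,
        "hip_adduction_angle": 0.6,
        "hip_power": 0.25,
        "pelvic_obliquity_angle": 0.8,
        "knee_extension_moment": 0.06,
        "knee_flexion_angle": 1.1,
        "knee_power": 0.30,
        "knee_varus_angle": 0.6,
        "ankle_plantarflexion_moment": 0.08,
        "ankle_power": 0.30,
        "foot_progression_angle": 1.2,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a reproducible synthetic cohort."""

    group_sizes: Tuple[int, int, int] = (140, 182, 53)
    seed: int = 0
    effect_scale: float = 1.0
    noise_scale: float = 1.0
    womac_noise_sd: float = 0.0
    womac_latent_rho: float = 0.6
    toe_off_pct: float = 60.0
    subscale_decoupled: Optional[str] = None

    def __post_init__(self):
        if any(n < 2 for n in self.group_sizes):
            raise ValidationError("each severity group needs at least 2 subjects")
        if self.effect_scale < 0:
            raise ValidationError("effect_scale must be >= 0")
        if not (0.0 <= self.womac_latent_rho < 1.0):
            raise ValidationError("womac_latent_rho must lie in [0, 1)")
        if self.subscale_decoupled is not None and self.subscale_decoupled not in SUBSCALE_ITEMS:
            raise ValidationError(f"unknown subscale {self.subscale_decoupled!r}")

    # effect/noise tables are part of the study conditions; exposed as
    # methods so variants can be built with dataclasses.replace + overrides
    def waveform_effects(self) -> Dict[str, WaveformEffect]:
        return _default_waveform_effects()

    def spatiotemporal_specs(self) -> Dict[str, SpatiotemporalSpec]:
        return _default_spatiotemporal()

    def noise_sds(self) -> Dict[str, float]:
        return _default_noise_sds()

    def cache_key(self) -> str:
        return repr(self)


@dataclass(frozen=True)
class CustomCohortConfig(CohortConfig):
    """CohortConfig with overridden effect profiles (e.g. a single planted
    parameter, or no spatiotemporal effects)."""

    effects_override: Optional[Tuple[Tuple[str, WaveformEffect], ...]] = None
    spatiotemporal_override: Optional[Tuple[Tuple[str, SpatiotemporalSpec], ...]] = None

    def waveform_effects(self) -> Dict[str, WaveformEffect]:
        if self.effects_override is None:
            return {}
        return dict(self.effects_override)

    def spatiotemporal_specs(self) -> Dict[str, SpatiotemporalSpec]:
        if self.spatiotemporal_override is None:
            return {
                k: SpatiotemporalSpec(v.baseline, 0.0, v.noise_sd)
                for k, v in _default_spatiotemporal().items()
            }
        return dict(self.spatiotemporal_override)


@dataclass
class SyntheticSubject:
    """A generated subject: gait trial + WOMAC record + the latent severity
    (and generating group) that drove both."""

    trial: GaitTrial
    womac: WOMACRecord
    latent_severity: float
    group: str


def _truncated_std_normal(rng: np.random.Generator, size: int, bound: float = _Z_TRUNC) -> np.ndarray:
    z = rng.standard_normal(size)
    bad = np.abs(z) > bound
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > bound
    return z

def _trunc_var(bound: float = _Z_TRUNC) -> float:
    # variance of a standard normal truncated to +/- bound
    phi = stats.norm.pdf(bound)
    mass = 2 * stats.norm.cdf(bound) - 1
    return 1.0 - 2 * bound * phi / mass


def _censored_normal_mean(mu, sigma, lo: float, hi: float):
    """Mean of clip(X, lo, hi) for X ~ N(mu, sigma); broadcasts over mu."""
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    return lo * Fa + hi * (1 - Fb) + mu * (Fb - Fa) - sigma * (fb - fa)


def _calibrated_location(
    target_mean: float,
    s_g: float,
    rho: float,
    sd_u: float,
    extra_sd: float = 0.0,
    lo: float = 0.0,
    hi: float = 96.0,
) -> float:
    """Location such that clip(loc + s_g * u, lo, hi) has the target mean,
    where u = (rho * z_trunc + sqrt(1-rho^2) * eps) / sd_u.  Compensates the
    clipping bias (material mainly for the mild group) by quadrature over
    the truncated latent z."""
    z = np.linspace(-_Z_TRUNC, _Z_TRUNC, 201)
    w = stats.norm.pdf(z)
    w /= w.sum()
    cond_sd = float(np.sqrt((s_g * np.sqrt(1 - rho**2) / sd_u) ** 2 + extra_sd**2))
    shift = s_g * rho * z / sd_u

    def clipped_mean(loc: float) -> float:
        return float(np.sum(w * _censored_normal_mean(loc + shift, cond_sd, lo, hi)))

    f = lambda loc: clipped_mean(loc) - target_mean
    return float(optimize.brentq(f, target_mean - 3 * s_g, target_mean + 3 * s_g, xtol=1e-10))


def _allocate_items(
    rng: np.random.Generator, total: int, decoupled: Optional[str]
) -> List[int]:
    """Decompose a WOMAC total into 24 item responses.

    Subscale targets are proportional to item counts (largest-remainder
    rounding); within a subscale, units are spread multinomially and capped
    at 4 with deterministic redistribution.  A decoupled subscale instead
    receives an independent binomial target (its association with severity
    is destroyed on purpose for calibration tests).
    """
    names = list(SUBSCALE_ITEMS)
    sizes = np.array([SUBSCALE_ITEMS[s] for s in names])
    raw = total * sizes / N_ITEMS
    base = np.floor(raw).astype(int)
    order = np.argsort(-(raw - base), kind="stable")
    for k in range(total - int(base.sum())):
        base[order[k % len(names)]] += 1
    targets = dict(zip(names, base))
    if decoupled is not None:
        targets[decoupled] = int(rng.binomial(4 * SUBSCALE_ITEMS[decoupled], 0.45))
    items: List[int] = []
    for s in names:
        n_s, t_s = SUBSCALE_ITEMS[s], min(targets[s], 4 * SUBSCALE_ITEMS[s])
        alloc = rng.multinomial(t_s, np.full(n_s, 1.0 / n_s))
        excess = int(np.maximum(alloc - 4, 0).sum())
        alloc = np.minimum(alloc, 4)
        while excess > 0:
            room = np.flatnonzero(alloc < 4)
            take = room[np.argsort(alloc[room], kind="stable")][: excess]
            alloc[take] += 1
            excess -= take.size
        items.extend(int(v) for v in alloc)
    return items


def generate_cohort(config: CohortConfig) -> List[SyntheticSubject]:
    """Generate the cohort described by ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    t = CYCLE_AXIS / 100.0
    templates = _templates(t)
    effects = config.waveform_effects()
    st_specs = config.spatiotemporal_specs()
    noise_sds = config.noise_sds()
    phase_map = default_phase_map(config.toe_off_pct)

    sizes = dict(zip(GROUPS, config.group_sizes))
    n_total = sum(sizes.values())
    groups = np.repeat(GROUPS, list(sizes.values()))

    # latent severity and WOMAC totals, group by group
    rho = config.womac_latent_rho
    sd_u = float(np.sqrt(rho**2 * _trunc_var() + (1 - rho**2)))
    latent = np.empty(n_total)
    totals = np.empty(n_total, dtype=int)
    pos = 0
    for g in GROUPS:
        n_g = sizes[g]
        z = _truncated_std_normal(rng, n_g)
        eps = rng.standard_normal(n_g)
        latent[pos : pos + n_g] = np.clip(
            LATENT_GROUP_MEANS[g] + LATENT_WITHIN_SD * z, 0.0, 1.0
        )
        s_g = WOMAC_GROUP_SDS[g]
        u = (rho * z + np.sqrt(1 - rho**2) * eps) / sd_u
        loc = _calibrated_location(
            WOMAC_GROUP_MEANS[g], s_g, rho, sd_u, config.womac_noise_sd
        )
        y = loc + s_g * u
        if config.womac_noise_sd > 0:
            y = y + rng.normal(0.0, config.womac_noise_sd, n_g)
        totals[pos : pos + n_g] = np.rint(np.clip(y, 0.0, 96.0)).astype(int)
        pos += n_g

    # waveforms: template + latent * effect_scale * profile + smooth noise
    drive = config.effect_scale * latent
    waveform_values: Dict[str, np.ndarray] = {}
    for param in WAVEFORM_PARAMETERS:
        base = templates[param]
        profile = (
            effects[param].profile(t, base) if param in effects else np.zeros_like(t)
        )
        s_p = noise_sds[param] * config.noise_scale
        w0, w_lo, w_hi = _NOISE_WEIGHTS.get(param, _DEFAULT_NOISE_WEIGHTS)
        c0 = rng.normal(0.0, w0 * s_p, n_total)
        sds = np.repeat([w_lo, w_lo, w_lo, w_hi, w_hi, w_hi], 2) * s_p
        coefs = rng.normal(0.0, 1.0, (n_total, 12)) * sds
        harmonics = np.stack(
            [f(2 * np.pi * k * t) for k in (1, 2, 3, 4, 5, 6) for f in (np.cos, np.sin)]
        )  # (12, 101)
        noise = c0[:, None] + coefs @ harmonics
        waveform_values[param] = base[None, :] + drive[:, None] * profile[None, :] + noise

    # spatiotemporal scalars
    st_values: Dict[str, np.ndarray] = {}
    for name, spec in st_specs.items():
        st_values[name] = (
            spec.baseline
            + spec.slope * drive
            + rng.normal(0.0, spec.noise_sd * config.noise_scale, n_total)
        )

    subjects: List[SyntheticSubject] = []
    for i in range(n_total):
        sid = f"S{i + 1:04d}"
        waveforms = {
            p: GaitWaveform(p, waveform_values[p][i], WAVEFORM_PARAMETERS[p])
            for p in WAVEFORM_PARAMETERS
        }
        trial = GaitTrial(
            subject_id=sid,
            waveforms=waveforms,
            spatiotemporal={k: float(v[i]) for k, v in st_values.items()},
            phase_map=phase_map,
        )
        items = _allocate_items(rng, int(totals[i]), config.subscale_decoupled)
        womac = score_womac(items, subject_id=sid)
        subjects.append(
            SyntheticSubject(
                trial=trial,
                womac=womac,
                latent_severity=float(latent[i]),
                group=str(groups[i]),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# ground truth for selection-recovery tests

#: detectability score above which a feature is declared planted.  The
#: score is the minimum over class pairs of (pairwise Cohen's d) /
#: (critical d at the Bonferroni alpha and the study's class sizes); 1.0 is
#: the 50 %-power edge, so 0.75 places the truth boundary at the bottom of
#: the power-transition zone and edge features count as planted.
PLANTED_DETECTABILITY_THRESHOLD = 0.75

_truth_cache: Dict[str, "pd.Series"] = {}


def detectability_score(
    config: CohortConfig,
    registry: Optional[Sequence[FeatureDescriptor]] = None,
    alpha: float = 3e-5,
    oversample: int = 4,
):
    """Generator-implied detectability spectrum.

    For every feature, simulate one large internal cohort (config-derived
    seed), classify subjects by their generated WOMAC totals (as the
    analysis does), and compute for each of the three class pairs the
    pooled-SD Cohen's d divided by the critical d for a two-sided pooled
    t-test at ``alpha`` with the class sizes of a default-scale cohort.
    The score is the minimum over pairs; 1.0 is the 50 %-power boundary of
    the selection procedure.  Returns a pandas Series by feature id.
    """
    import pandas as pd

    from .womac import classify_total

    key = f"{config.cache_key()}|{alpha}|{oversample}|{len(registry) if registry is not None else -1}"
    if key in _truth_cache:
        return _truth_cache[key]
    reg = default_registry() if registry is None else list(registry)
    big_sizes = tuple(int(n * oversample) for n in config.group_sizes)
    internal_seed = (config.seed * 1_000_003 + 12_345) % (2**31)
    big = replace(config, group_sizes=big_sizes, seed=internal_seed)
    subjects = generate_cohort(big)
    fm = extract_matrix([s.trial for s in subjects], reg).drop_masked_features()
    labels = np.array([classify_total(s.womac).label for s in subjects])
    means, variances, counts = {}, {}, {}
    for g in GROUPS:
        Xg = fm.values[labels == g]
        means[g] = Xg.mean(axis=0)
        variances[g] = Xg.var(axis=0, ddof=1)
        counts[g] = max(Xg.shape[0] / oversample, 2.0)  # study-scale class size
    score = None
    for a, b in (("mild", "moderate"), ("moderate", "severe"), ("mild", "severe")):
        na, nb = counts[a], counts[b]
        pooled = np.sqrt(((na - 1) * variances[a] + (nb - 1) * variances[b]) / (na + nb - 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.abs(means[a] - means[b]) / pooled
        t_crit = stats.t.ppf(1 - alpha / 2, na + nb - 2)
        d_crit = t_crit * np.sqrt(1 / na + 1 / nb)
        s = d / d_crit
        score = s if score is None else np.minimum(score, s)
    series = pd.Series(score, index=fm.feature_ids).fillna(0.0)
    _truth_cache[key] = series
    return series


def planted_truth(
    config: CohortConfig,
    registry: Optional[Sequence[FeatureDescriptor]] = None,
    threshold: float = PLANTED_DETECTABILITY_THRESHOLD,
) -> List[str]:
    """Feature ids with a non-negligible planted severity effect: the
    ground-truth key-feature set for selection-recovery tests."""
    score = detectability_score(config, registry)
    return sorted(score.index[score >= threshold])


def attainable_correlation(
    config: CohortConfig,
    balance_target: int = 231,
    n_mc: int = 200_000,
    seed: int = 987_654_321,
) -> float:
    """Analytic ceiling for hold-out Pearson r between actual and estimated
    WOMAC under this generator.

    A model that recovers the latent severity perfectly predicts at best
    E[WOMAC | latent]; the attainable correlation is Cor(E[y|l], y) under
    the class-balanced sampling the estimation pipeline uses.  Computed by
    Monte Carlo on the WOMAC generative model alone (no waveforms), with
    the censored-normal conditional mean in closed form.
    """
    from .estimation import greedy_balanced_sizes
    from .womac import severity_cutpoints

    rng = np.random.default_rng(seed)
    rho = config.womac_latent_rho
    sd_u = float(np.sqrt(rho**2 * _trunc_var() + (1 - rho**2)))
    n_groups = np.array(config.group_sizes, dtype=float)
    n_per = np.rint(n_mc * n_groups / n_groups.sum()).astype(int)
    ys, mus = [], []
    for g, n_g in zip(GROUPS, n_per):
        z = _truncated_std_normal(rng, int(n_g))
        eps = rng.standard_normal(int(n_g))
        s_g = WOMAC_GROUP_SDS[g]
        extra = config.womac_noise_sd
        loc = _calibrated_location(WOMAC_GROUP_MEANS[g], s_g, rho, sd_u, extra)
        u = (rho * z + np.sqrt(1 - rho**2) * eps) / sd_u
        y = np.clip(loc + s_g * u + (rng.normal(0, extra, int(n_g)) if extra > 0 else 0.0), 0, 96)
        cond_mu = loc + s_g * rho * z / sd_u
        cond_sd = float(np.sqrt((s_g * np.sqrt(1 - rho**2) / sd_u) ** 2 + extra**2))
        mu = _censored_normal_mean(cond_mu, cond_sd, 0.0, 96.0)
        ys.append(y)
        mus.append(mu)
    y = np.concatenate(ys)
    mu = np.concatenate(mus)
    lower, upper = severity_cutpoints(24)
    yr = np.rint(y)
    labels = np.where(yr < lower, "mild", np.where(yr <= upper, "moderate", "severe"))
    counts = {g: int((labels == g).sum()) for g in GROUPS}
    scale = y.size / sum(config.group_sizes)
    targets = greedy_balanced_sizes(
        {g: counts[g] for g in GROUPS}, int(round(balance_target * scale))
    )
    keep = np.zeros(y.size, dtype=bool)
    for g in GROUPS:
        idx = np.flatnonzero(labels == g)
        keep[rng.choice(idx, size=min(targets[g], idx.size), replace=False)] = True
    return float(np.corrcoef(mu[keep], y[keep])[0, 1])
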