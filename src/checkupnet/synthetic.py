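"""Synthetic health-checkup cohorts with known ground truth.

All planted structure lives in a joint Gaussian latent space: one latent per
variable, with a latent correlation matrix assembled from the planted direct
edges and confounder fans, checked for positive definiteness before sampling.
Marginals are then transformed — thresholds for the binary/ordinal items, a
discrete (volume x frequency) answer ladder for drinking, a lognormal for
CRP, linear maps for the continuous measurements.

Correlation targets are specified on the *observed* scale.  A monotone
marginal transform f attenuates Pearson correlation by exactly
c = corr(f(Z), Z) whenever the other endpoint is linear, so each latent
entry is pre-inflated by 1/(c_i c_j); c has a closed form for step functions
and the lognormal.  When both endpoints are transformed the product rule is
the leading-order (first Hermite polynomial) approximation — adequate for
the modest default strengths and documented in the methods note.

The longitudinal generator applies per-variable five-year declines plus
noise, and moves each subject's drinking answers along the ladder according
to the change mixture (no change / below 100 g per week / at least 100 g per
week).  The FVC change is shifted by ``attenuation_beta`` liters per
100 g/week of alcohol change; by default beta is solved so the population
delta-correlation equals ``target_delta_correlation``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable, PairedCohort, VariableDescriptor
from .questionnaire import (
    DRINKING_CATEGORIES,
    CategoryQuantificationConfig,
    DEFAULT_QUANTIFICATION,
    assign_drinking_category,
)

SEX_LEVELS = ("female", "male")
SMOKING_LEVELS = ("never", "previous", "current")

#: observed variable name -> latent name (identity unless listed)
_OBS_TO_LATENT = {"alcohol_weekly_g": "alcohol"}

DEFAULT_PLANTED_EDGES: tuple[tuple[str, str, float], ...] = (
    # the alcohol associations of interest
    ("alcohol_weekly_g", "FVC", 0.35),
    ("alcohol_weekly_g", "FEV1", 0.30),
    ("alcohol_weekly_g", "skeletal_muscle_mass", 0.39),
    ("alcohol_weekly_g", "grip", 0.30),
    ("alcohol_weekly_g", "sex", 0.30),
    ("alcohol_weekly_g", "height", 0.20),
    # well-established anatomy/physiology (sex and height load on body size;
    # internally consistent so the joint matrix stays positive definite)
    ("FVC", "FEV1", 0.70),
    ("skeletal_muscle_mass", "grip", 0.60),
    ("height", "FVC", 0.45),
    ("height", "FEV1", 0.35),
    ("height", "skeletal_muscle_mass", 0.45),
    ("height", "grip", 0.35),
    ("sex", "height", 0.55),
    ("sex", "FVC", 0.30),
    ("sex", "FEV1", 0.25),
    ("sex", "skeletal_muscle_mass", 0.40),
    ("sex", "grip", 0.40),
    ("FVC", "skeletal_muscle_mass", 0.30),
    ("FVC", "grip", 0.20),
    ("FEV1", "skeletal_muscle_mass", 0.25),
    ("FEV1", "grip", 0.18),
)

#: (source, target1, target2, strength1, strength2) on the observed scale;
#: smoking accompanies drinking but is detrimental to lung function
DEFAULT_CONFOUNDERS: tuple[tuple[str, str, str, float, float], ...] = (
    ("smoking_status", "alcohol_weekly_g", "FEV1", 0.20, -0.15),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator (defaults emulate the checkup cohort)."""

    n: int = 6036
    seed: int = 0
    male_fraction: float = 0.612
    age_mean: float = 60.0
    age_sd: float = 13.0
    height_mean: float = 165.2
    height_sd: float = 8.8
    bmi_mean: float = 23.2
    bmi_sd: float = 3.2
    smoking_mix: tuple[float, float, float] = (0.495, 0.391, 0.106)
    drinking_mix: tuple[float, float, float, float] = (0.264, 0.285, 0.360, 0.087)
    fvc_mean: float = 3.60
    fvc_sd: float = 0.90
    fev1_mean: float = 2.71
    fev1_sd: float = 0.72
    muscle_mean: float = 22.0
    muscle_sd: float = 4.5
    grip_mean: float = 32.0
    grip_sd: float = 8.5
    crp_log_mean: float = -2.0
    crp_log_sd: float = 0.9
    planted_edges: tuple[tuple[str, str, float], ...] = DEFAULT_PLANTED_EDGES
    confounders: tuple[tuple[str, str, str, float, float], ...] = DEFAULT_CONFOUNDERS
    extra_variables: tuple[str, ...] = ()
    include_checkup: bool = True
    quantification: CategoryQuantificationConfig = field(
        default_factory=lambda: DEFAULT_QUANTIFICATION
    )
    decline: Mapping[str, float] = field(
        default_factory=lambda: {
            "FVC": -0.10,
            "FEV1": -0.16,
            "height": -0.4,
            "skeletal_muscle_mass": -0.6,
            "grip": -1.2,
        }
    )
    followup_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "FVC": 0.25,
            "FEV1": 0.20,
            "height": 0.4,
            "skeletal_muscle_mass": 0.8,
            "grip": 2.0,
        }
    )
    attenuation_beta: float | None = None
    target_delta_correlation: float = 0.10
    change_mix: tuple[float, float, float] = (0.533, 0.348, 0.119)
    change_small_cutoff: float = 100.0
    baseline_timepoint: str = "2013"
    followup_timepoint: str = "2018"

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be at least 10")
        for mix, k in ((self.drinking_mix, 4), (self.smoking_mix, 3), (self.change_mix, 3)):
            if len(mix) != k or any(p < 0 for p in mix) or sum(mix) <= 0:
                raise ValueError(f"invalid mixture {mix}")
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must be in (0, 1)")
        for v1, v2, r in self.planted_edges:
            if not abs(r) < 1:
                raise ValueError(f"planted correlation |r| must be < 1 for ({v1}, {v2})")

    @classmethod
    def gaussian(
        cls,
        variables: Sequence[str],
        planted_edges: Sequence[tuple[str, str, float]] = (),
        confounders: Sequence[tuple[str, str, str, float, float]] = (),
        n: int = 1000,
        seed: int = 0,
        **kwargs,
    ) -> "SyntheticConfig":
        """Plain multivariate-Gaussian cohort of named continuous variables."""
        return cls(
            n=n,
            seed=seed,
            include_checkup=False,
            extra_variables=tuple(variables),
            planted_edges=tuple(planted_edges),
            confounders=tuple(confounders),
            **kwargs,
        )


@dataclass(frozen=True)
class GroundTruth:
    """The generator's contract with the test suite."""

    edges: tuple[tuple[str, str, float], ...]
    confounded_pairs: tuple[tuple[str, str, float, str], ...]
    decline_parameters: Mapping[str, float] = field(default_factory=dict)
    attenuation_beta: float | None = None
    zero_change_fraction: float | None = None
    category_change_fraction: float | None = None

    def __post_init__(self) -> None:
        direct = {tuple(sorted((a, b))) for a, b, _ in self.edges}
        indirect = {tuple(sorted((a, b))) for a, b, _, _ in self.confounded_pairs}
        if direct & indirect:
            raise ValueError("a pair cannot be both planted and purely confounded")


# ---------------------------------------------------------------------------
# marginal transforms and their attenuation coefficients

@dataclass(frozen=True)
class _StepTransform:
    """Monotone step function of a standard normal: interval -> encoded value."""

    thresholds: tuple[float, ...]  # inner z-thresholds, ascending
    values: tuple[float, ...]      # len(thresholds) + 1 encoded values

    def interval_index(self, z: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.thresholds), z, side="left")

    def attenuation(self) -> float:
        """c = corr(f(Z), Z), exact via Gaussian interval moments."""
        t = np.concatenate(([-np.inf], self.thresholds, [np.inf]))
        g = np.asarray(self.values, dtype=float)
        probs = stats.norm.cdf(t[1:]) - stats.norm.cdf(t[:-1])
        pdf = stats.norm.pdf(t)
        pdf[~np.isfinite(t)] = 0.0
        e_f = float((g * probs).sum())
        e_fz = float((g * (pdf[:-1] - pdf[1:])).sum())
        var_f = float((g * g * probs).sum()) - e_f**2
        if var_f <= 0:
            raise ValueError("degenerate step transform (zero variance)")
        return e_fz / np.sqrt(var_f)


def _mixture_thresholds(mix: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(mix, dtype=float)
    probs = probs / probs.sum()
    cum = np.cumsum(probs)[:-1]
    return probs, stats.norm.ppf(cum)


@dataclass(frozen=True)
class _AlcoholLadder:
    """Discrete (volume, frequency) answer rungs ordered by weekly grams."""

    grams: tuple[float, ...]
    volume_labels: tuple[str, ...]
    frequency_labels: tuple[str, ...]
    categories: tuple[str, ...]
    probs: tuple[float, ...]
    thresholds: tuple[float, ...]

    @property
    def step(self) -> _StepTransform:
        return _StepTransform(self.thresholds, self.grams)


def build_alcohol_ladder(
    qc: CategoryQuantificationConfig, drinking_mix: Sequence[float]
) -> _AlcoholLadder:
    """Distribute the drinking-category mixture over the answer ladder.

    The never mass sits on the (none, never) rung; each remaining category's
    mass is shared equally by the answer combinations whose weekly grams fall
    in that category's band.
    """
    rungs = [(0.0, "none", "never", "never")]
    for vol, gv in qc.volume_means.items():
        if gv <= 0:
            continue
        for freq, gf in qc.frequency_means.items():
            if gf <= 0:
                continue
            g = gv * gf
            rungs.append((g, vol, freq, assign_drinking_category(g, qc)))
    nonzero = sorted(rungs[1:], key=lambda t: (t[0], t[1], t[2]))
    rungs = [rungs[0]] + nonzero
    mix = np.asarray(drinking_mix, dtype=float)
    mix = mix / mix.sum()
    counts = {
        cat: sum(1 for r in rungs if r[3] == cat) for cat in DRINKING_CATEGORIES
    }
    for cat, share in zip(DRINKING_CATEGORIES, mix):
        if share > 0 and counts[cat] == 0:
            raise ValueError(f"no answer combination reaches category {cat!r}")
    probs = [
        dict(zip(DRINKING_CATEGORIES, mix))[r[3]] / counts[r[3]] for r in rungs
    ]
    cum = np.cumsum(probs)[:-1]
    thresholds = stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    return _AlcoholLadder(
        grams=tuple(r[0] for r in rungs),
        volume_labels=tuple(r[1] for r in rungs),
        frequency_labels=tuple(r[2] for r in rungs),
        categories=tuple(r[3] for r in rungs),
        probs=tuple(probs),
        thresholds=tuple(thresholds),
    )


def _lognormal_attenuation(sigma: float) -> float:
    # corr(exp(sigma Z), Z) = sigma / sqrt(exp(sigma^2) - 1)
    return sigma / np.sqrt(np.expm1(sigma**2))


# ---------------------------------------------------------------------------
# model assembly

_CHECKUP_LATENTS = (
    "sex", "age", "height", "BMI", "smoking_status", "alcohol",
    "FVC", "FEV1", "skeletal_muscle_mass", "grip", "CRP",
)


@dataclass
class _Model:
    latent_names: tuple[str, ...]
    chol: np.ndarray
    attenuation: Mapping[str, float]
    ladder: _AlcoholLadder | None
    sex_threshold: float
    smoking_thresholds: np.ndarray


def _latent_name(observed: str) -> str:
    return _OBS_TO_LATENT.get(observed, observed)


def build_model(config: SyntheticConfig) -> _Model:
    if config.include_checkup:
        latents = list(_CHECKUP_LATENTS) + list(config.extra_variables)
        ladder = build_alcohol_ladder(config.quantification, config.drinking_mix)
        _, sex_thr = _mixture_thresholds(
            (1 - config.male_fraction, config.male_fraction)
        )
        _, smoke_thr = _mixture_thresholds(config.smoking_mix)
        smoke_step = _StepTransform(tuple(smoke_thr), (1.0, 2.0, 3.0))
        atten = {name: 1.0 for name in latents}
        atten["sex"] = _StepTransform(tuple(sex_thr), (0.0, 1.0)).attenuation()
        atten["smoking_status"] = smoke_step.attenuation()
        atten["alcohol"] = ladder.step.attenuation()
        atten["CRP"] = _lognormal_attenuation(config.crp_log_sd)
        sex_threshold = float(sex_thr[0])
        smoking_thresholds = smoke_thr
    else:
        if not config.extra_variables:
            raise ValueError("a Gaussian-only config needs extra_variables")
        latents = list(config.extra_variables)
        ladder = None
        atten = {name: 1.0 for name in latents}
        sex_threshold = 0.0
        smoking_thresholds = np.array([])
    index = {name: i for i, name in enumerate(latents)}
    p = len(latents)
    sigma = np.eye(p)

    def set_entry(v1: str, v2: str, target: float) -> None:
        a, b = _latent_name(v1), _latent_name(v2)
        for v in (a, b):
            if v not in index:
                raise ValueError(f"unknown variable {v!r} in planted structure")
        rho = target / (atten[a] * atten[b])
        if not abs(rho) < 0.999:
            raise ValueError(
                f"target correlation {target} for ({v1}, {v2}) is infeasible "
                f"after marginal attenuation (latent {rho:.3f})"
            )
        sigma[index[a], index[b]] = sigma[index[b], index[a]] = rho

    planted = {tuple(sorted((a, b))) for a, b, _ in config.planted_edges}
    for v1, v2, r in config.planted_edges:
        set_entry(v1, v2, r)
    for src, t1, t2, s1, s2 in config.confounders:
        set_entry(src, t1, s1)
        set_entry(src, t2, s2)
        if tuple(sorted((t1, t2))) not in planted:
            set_entry(t1, t2, s1 * s2)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "planted correlation structure is not positive definite"
        ) from exc
    return _Model(
        tuple(latents), chol, atten, ladder, sex_threshold, smoking_thresholds
    )


def _ground_truth_cross(config: SyntheticConfig) -> GroundTruth:
    planted = {tuple(sorted((a, b))) for a, b, _ in config.planted_edges}
    confounded = tuple(
        (t1, t2, s1 * s2, src)
        for src, t1, t2, s1, s2 in config.confounders
        if tuple(sorted((t1, t2))) not in planted
    )
    return GroundTruth(
        edges=tuple(config.planted_edges),
        confounded_pairs=confounded,
        decline_parameters=dict(config.decline),
        attenuation_beta=None,
    )


# ---------------------------------------------------------------------------
# sampling

def _observe(
    model: _Model, config: SyntheticConfig, Z: np.ndarray
) -> tuple[pd.DataFrame, tuple[VariableDescriptor, ...], np.ndarray]:
    """Transform latent draws to the observed table; returns the alcohol rungs."""
    n = Z.shape[0]
    col = {name: Z[:, i] for i, name in enumerate(model.latent_names)}
    data: dict[str, object] = {}
    schema: list[VariableDescriptor] = []
    rung = np.zeros(n, dtype=np.int64)
    if config.include_checkup:
        ladder = model.ladder
        assert ladder is not None
        sex = np.where(col["sex"] > model.sex_threshold, "male", "female")
        smoke_idx = np.searchsorted(model.smoking_thresholds, col["smoking_status"])
        rung = ladder.step.interval_index(col["alcohol"])
        grams = np.asarray(ladder.grams)[rung]
        fvc = np.maximum(config.fvc_mean + config.fvc_sd * col["FVC"], 0.5)
        fev1 = np.maximum(config.fev1_mean + config.fev1_sd * col["FEV1"], 0.3)
        data["sex"] = sex
        schema.append(VariableDescriptor("sex", "binary", ordinal_levels=SEX_LEVELS))
        data["age"] = config.age_mean + config.age_sd * col["age"]
        schema.append(VariableDescriptor("age", "continuous", units="years"))
        data["height"] = config.height_mean + config.height_sd * col["height"]
        schema.append(VariableDescriptor("height", "continuous", units="cm"))
        data["BMI"] = np.maximum(config.bmi_mean + config.bmi_sd * col["BMI"], 12.0)
        schema.append(VariableDescriptor("BMI", "continuous", units="kg/m^2"))
        data["smoking_status"] = np.asarray(SMOKING_LEVELS)[smoke_idx]
        schema.append(
            VariableDescriptor(
                "smoking_status", "ordinal", ordinal_levels=SMOKING_LEVELS
            )
        )
        vol_levels = tuple(config.quantification.volume_means)
        freq_levels = tuple(config.quantification.frequency_means)
        data["alcohol_volume_level"] = np.asarray(ladder.volume_labels)[rung]
        schema.append(
            VariableDescriptor(
                "alcohol_volume_level",
                "ordinal",
                units="g/day band",
                ordinal_levels=vol_levels,
                numeric_map=dict(config.quantification.volume_means),
            )
        )
        data["alcohol_frequency_level"] = np.asarray(ladder.frequency_labels)[rung]
        schema.append(
            VariableDescriptor(
                "alcohol_frequency_level",
                "ordinal",
                units="days/week band",
                ordinal_levels=freq_levels,
                numeric_map=dict(config.quantification.frequency_means),
            )
        )
        data["alcohol_weekly_g"] = grams
        schema.append(
            VariableDescriptor("alcohol_weekly_g", "continuous", units="g/week")
        )
        data["drinking_category"] = np.asarray(ladder.categories)[rung]
        schema.append(
            VariableDescriptor(
                "drinking_category", "ordinal", ordinal_levels=DRINKING_CATEGORIES
            )
        )
        data["FVC"] = fvc
        schema.append(VariableDescriptor("FVC", "continuous", units="L"))
        data["FEV1"] = fev1
        schema.append(VariableDescriptor("FEV1", "continuous", units="L"))
        data["FEV1_FVC_ratio"] = fev1 / fvc * 100.0
        schema.append(VariableDescriptor("FEV1_FVC_ratio", "continuous", units="%"))
        data["skeletal_muscle_mass"] = np.maximum(
            config.muscle_mean + config.muscle_sd * col["skeletal_muscle_mass"], 5.0
        )
        schema.append(
            VariableDescriptor("skeletal_muscle_mass", "continuous", units="kg")
        )
        data["grip"] = np.maximum(config.grip_mean + config.grip_sd * col["grip"], 5.0)
        schema.append(VariableDescriptor("grip", "continuous", units="kg"))
        data["CRP"] = np.exp(config.crp_log_mean + config.crp_log_sd * col["CRP"])
        schema.append(VariableDescriptor("CRP", "continuous", units="mg/dL"))
    for name in config.extra_variables:
        data[name] = col[name]
        schema.append(VariableDescriptor(name, "continuous"))
    ids = pd.Index([f"S{i:06d}" for i in range(1, n + 1)], name="subject_id")
    df = pd.DataFrame(data, index=ids)
    return df, tuple(schema), rung


def generate_cross_sectional(
    config: SyntheticConfig,
) -> tuple[CohortTable, GroundTruth]:
    """One-timepoint cohort with the planted correlation structure."""
    model = build_model(config)
    rng = np.random.default_rng(config.seed)
    Z = rng.standard_normal((config.n, len(model.latent_names))) @ model.chol.T
    df, schema, _ = _observe(model, config, Z)
    table = CohortTable(df, schema, timepoint=config.followup_timepoint)
    return table, _ground_truth_cross(config)


# ---------------------------------------------------------------------------
# longitudinal machinery

def _change_candidates(
    ladder: _AlcoholLadder, cutoff: float
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    g = np.asarray(ladder.grams)
    small, large = [], []
    for i in range(g.size):
        d = np.abs(g - g[i])
        s = np.where((d > 0) & (d < cutoff))[0]
        l = np.where(d >= cutoff)[0]
        if s.size == 0:  # top rung: fall back to the nearest non-zero move
            moving = np.where(d > 0)[0]
            s = moving[np.argsort(d[moving], kind="stable")][:1]
        if l.size == 0:
            moving = np.where(d > 0)[0]
            l = moving[np.argsort(-d[moving], kind="stable")][:1]
        small.append(s)
        large.append(l)
    return small, large


def delta_alcohol_moments(config: SyntheticConfig) -> tuple[float, float]:
    """Exact population mean and sd of the weekly-grams change (g/week)."""
    ladder = build_alcohol_ladder(config.quantification, config.drinking_mix)
    small, large = _change_candidates(ladder, config.change_small_cutoff)
    g = np.asarray(ladder.grams)
    mix = np.asarray(config.change_mix, dtype=float)
    mix = mix / mix.sum()
    e1 = e2 = 0.0
    for i, p_i in enumerate(ladder.probs):
        for cls_p, cand in ((mix[1], small[i]), (mix[2], large[i])):
            d = g[cand] - g[i]
            e1 += p_i * cls_p * d.mean()
            e2 += p_i * cls_p * (d**2).mean()
    var = e2 - e1**2
    return e1, float(np.sqrt(var))


def attenuation_beta_for_correlation(
    target_r: float, config: SyntheticConfig
) -> float:
    """Solve the FVC shift per 100 g/week giving a chosen delta-correlation."""
    if not 0 <= abs(target_r) < 1:
        raise ValueError("target correlation must satisfy |r| < 1")
    _, sd_delta = delta_alcohol_moments(config)
    sd_noise = float(config.followup_noise_sd.get("FVC", 0.25))
    if sd_delta == 0:
        raise ValueError("degenerate change mixture: zero alcohol-change variance")
    return target_r * sd_noise / ((sd_delta / 100.0) * np.sqrt(1 - target_r**2))


def resolved_attenuation_beta(config: SyntheticConfig) -> float:
    if config.attenuation_beta is not None:
        return float(config.attenuation_beta)
    return attenuation_beta_for_correlation(config.target_delta_correlation, config)


def generate_longitudinal(
    config: SyntheticConfig,
) -> tuple[PairedCohort, GroundTruth]:
    """Paired baseline/follow-up cohort with declines and alcohol-change effects.

    The baseline table is a cross-sectional draw.  Drinking answers move along
    the ladder per the change mixture; the subject's FVC change is the mean
    decline plus ``attenuation_beta`` x (alcohol change / 100 g/week) plus
    noise.  Other measured declines carry no alcohol dependence.
    """
    model = build_model(config)
    rng = np.random.default_rng(config.seed)
    n = config.n
    Z = rng.standard_normal((n, len(model.latent_names))) @ model.chol.T
    base_df, schema, rung = _observe(model, config, Z)
    base = CohortTable(base_df, schema, timepoint=config.baseline_timepoint)

    fol = base_df.copy()
    decline = dict(config.decline)
    noise_sd = dict(config.followup_noise_sd)
    truth = _ground_truth_cross(config)
    if config.include_checkup:
        ladder = model.ladder
        assert ladder is not None
        small, large = _change_candidates(ladder, config.change_small_cutoff)
        mix = np.asarray(config.change_mix, dtype=float)
        mix = mix / mix.sum()
        cls = rng.choice(3, size=n, p=mix)
        new_rung = rung.copy()
        for i in range(len(ladder.grams)):
            for c, cands in ((1, small[i]), (2, large[i])):
                idx = np.where((cls == c) & (rung == i))[0]
                if idx.size:
                    new_rung[idx] = cands[rng.integers(0, cands.size, size=idx.size)]
        g = np.asarray(ladder.grams)
        d_alc = g[new_rung] - g[rung]
        beta = resolved_attenuation_beta(config)
        fol["alcohol_volume_level"] = np.asarray(ladder.volume_labels)[new_rung]
        fol["alcohol_frequency_level"] = np.asarray(ladder.frequency_labels)[new_rung]
        fol["alcohol_weekly_g"] = g[new_rung]
        fol["drinking_category"] = np.asarray(ladder.categories)[new_rung]
        fvc2 = np.maximum(
            base_df["FVC"].to_numpy()
            + decline.get("FVC", 0.0)
            + beta * d_alc / 100.0
            + rng.normal(0.0, noise_sd.get("FVC", 0.25), size=n),
            0.5,
        )
        fev2 = np.maximum(
            base_df["FEV1"].to_numpy()
            + decline.get("FEV1", 0.0)
            + rng.normal(0.0, noise_sd.get("FEV1", 0.2), size=n),
            0.3,
        )
        fol["FVC"] = fvc2
        fol["FEV1"] = fev2
        fol["FEV1_FVC_ratio"] = fev2 / fvc2 * 100.0
        fol["age"] = base_df["age"] + 5.0
        for var, clip in (
            ("height", 100.0),
            ("skeletal_muscle_mass", 5.0),
            ("grip", 5.0),
        ):
            fol[var] = np.maximum(
                base_df[var].to_numpy()
                + decline.get(var, 0.0)
                + rng.normal(0.0, noise_sd.get(var, 0.5), size=n),
                clip,
            )
        fol["BMI"] = np.maximum(
            base_df["BMI"].to_numpy() + rng.normal(0.0, 0.5, size=n), 12.0
        )
        fol["CRP"] = base_df["CRP"].to_numpy() * np.exp(rng.normal(0.0, 0.3, size=n))
        truth = replace(
            truth,
            attenuation_beta=beta,
            zero_change_fraction=float(mix[0]),
            category_change_fraction=float(
                np.mean(
                    np.asarray(ladder.categories)[new_rung]
                    != np.asarray(ladder.categories)[rung]
                )
            ),
        )
    for name in config.extra_variables:
        fol[name] = (
            base_df[name].to_numpy()
            + decline.get(name, 0.0)
            + rng.normal(0.0, noise_sd.get(name, 0.5), size=n)
        )
    followup = CohortTable(fol, schema, timepoint=config.followup_timepoint)
    paired = PairedCohort(base, followup, base.subject_ids)
    return paired, truth


def truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Flat listing of every planted parameter, for assertions and reports."""
    rows = []
    for v1, v2, r in truth.edges:
        rows.append({"kind": "direct", "var1": v1, "var2": v2, "value": r, "source": ""})
    for v1, v2, r, src in truth.confounded_pairs:
        rows.append(
            {"kind": "indirect", "var1": v1, "var2": v2, "value": r, "source": src}
        )
    for var, d in truth.decline_parameters.items():
        rows.append({"kind": "decline", "var1": var, "var2": "", "value": d, "source": ""})
    if truth.attenuation_beta is not None:
        rows.append(
            {
                "kind": "attenuation_beta",
                "var1": "alcohol_weekly_g",
                "var2": "FVC",
                "value": truth.attenuation_beta,
                "source": "",
            }
        )
    return pd.DataFrame(rows, columns=["kind", "var1", "var2", "value", "source"])
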