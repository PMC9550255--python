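"""Synthetic CHARLS-like cohort generator with a known latent aging pace.

The generator emulates the statistical structure an aging-clock pipeline
needs, with ground truth attached:

* each participant has a chronological age and a latent *effective age* —
  chronological age shifted by signed, additive year-scale effects of
  disease history, smoking, demographic and psychosocial state, plus a
  residual pace draw;
* the 22 continuous predictors (16 blood panel + 6 biometric variables)
  are affine-in-age curves (optional quadratic term) with a sex offset and
  Gaussian noise, evaluated at the participant's *effective* age — so any
  competent regressor of chronological age learns chronological age plus
  the injected acceleration;
* disease flags, covariates and the fasting flag are independent draws at
  configured prevalences.

Every cohort comes with a :class:`SyntheticTruth` sidecar holding the
per-participant acceleration and the injected per-factor effects, so
downstream recovery can be checked exactly.

Default effect sizes place smoking at +1.25 y, marriage at −0.59 y, the
eight psychological "rarely" indicators between −0.44 and +0.35 y, and the
five serious conditions between −1.07 and +2.2 y. Default biomarker noise
is calibrated so the age signal carried jointly by the 22 continuous
predictors has an irreducible posterior spread of roughly 1.3 years —
small enough that sub-year injected effects are recoverable at cohort
sizes around 10⁴ (see the methods note; real blood panels are noisier).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schema import INDICATOR_ORDER, PSYCH_INDICATORS, VariableSchema, default_schema

__all__ = [
    "BiomarkerSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "ConfigError",
    "generate_cohort",
    "biomarker_value",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """Affine-in-age generative curve for one continuous predictor.

    value = baseline + slope_per_decade * d + quadratic_per_decade2 * d**2
            + sex_offset * [male] + noise,   d = (effective_age - 45) / 10
    """

    baseline: float  # value at age 45 for females
    slope_per_decade: float
    sex_offset: float = 0.0  # added for males
    noise_sd: float = 0.0
    quadratic_per_decade2: float = 0.0


# Baselines/slopes are plausible adult clinical values; noise_sd = 0.6 ×
# |slope_per_decade| keeps the joint age signal recoverable (module docstring):
# across the 22 continuous predictors the irreducible posterior SD of age is
# ≈ 1.3 years, so year-scale injected effects survive the clock.
DEFAULT_BIOMARKER_SPECS: dict[str, BiomarkerSpec] = {
    "total_cholesterol": BiomarkerSpec(185.0, 6.0, -6.0, 3.6),
    "ldl_cholesterol": BiomarkerSpec(110.0, 5.0, -4.0, 3.0),
    "hdl_cholesterol": BiomarkerSpec(55.0, 1.5, -8.0, 0.9),
    "c_reactive_protein": BiomarkerSpec(1.8, 0.5, 0.1, 0.3),
    "glucose": BiomarkerSpec(95.0, 3.5, 2.0, 2.1),
    "triglycerides": BiomarkerSpec(130.0, 6.0, 12.0, 3.6),
    "uric_acid": BiomarkerSpec(5.0, 0.3, 1.1, 0.18),
    "cystatin_c": BiomarkerSpec(0.82, 0.11, 0.06, 0.066, 0.01),
    "mcv": BiomarkerSpec(89.0, 1.1, 0.6, 0.66),
    "creatinine": BiomarkerSpec(0.82, 0.06, 0.22, 0.036),
    "hba1c": BiomarkerSpec(5.5, 0.18, 0.0, 0.108),
    "hemoglobin": BiomarkerSpec(14.2, -0.35, 1.3, 0.21),
    "hematocrit": BiomarkerSpec(42.0, -0.9, 3.4, 0.54),
    "bun": BiomarkerSpec(14.0, 1.3, 1.4, 0.78),
    "platelet_count": BiomarkerSpec(245.0, -7.0, -14.0, 4.2),
    "wbc_count": BiomarkerSpec(6.2, 0.15, 0.3, 0.09),
    "systolic_bp": BiomarkerSpec(122.0, 6.0, 3.0, 3.6, 0.5),
    "diastolic_bp": BiomarkerSpec(78.0, 1.0, 2.0, 0.6, -0.5),
    "bmi": BiomarkerSpec(24.5, -0.4, -0.3, 0.24, -0.1),
    "waist_circumference": BiomarkerSpec(87.0, 1.2, 4.0, 0.72),
    "heart_rate": BiomarkerSpec(72.0, 0.6, -2.0, 0.36),
    "spirometry": BiomarkerSpec(400.0, -30.0, 90.0, 18.0, -2.0),
}

# Years of acceleration per active binary indicator (signed).
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "is_male": 0.42,
    "is_married": -0.59,
    "is_widowed": 0.27,
    "is_rural": 0.39,
    "rarely_bothered": 0.09,
    "rarely_lacks_focus": -0.05,
    "rarely_depressed": -0.09,
    "rarely_hopeful": 0.28,
    "rarely_fearful": -0.29,
    "restless_sleep_is_rare": -0.44,
    "rarely_happy": 0.35,
    "rarely_lonely": 0.05,
    "currently_smoking": 1.25,
}

# Years of acceleration per disease-history flag.
DEFAULT_DISEASE_EFFECTS: dict[str, float] = {
    "hypertension": 0.0,
    "arthritis": 0.0,
    "dyslipidemia": 0.0,
    "kidney_disease": 0.0,
    "diabetes": 0.0,
    "heart_disease": -0.03,
    "cancer": -1.07,
    "stroke": 1.49,
    "lung_disease": 2.2,
    "liver_disease": 0.97,
}

# Flag prevalences sized to mirror the per-condition counts of an
# 11,914-participant cohort (flags drawn independently).
DEFAULT_DISEASE_PREVALENCES: dict[str, float] = {
    "hypertension": 0.107,
    "arthritis": 0.077,
    "dyslipidemia": 0.023,
    "kidney_disease": 0.017,
    "diabetes": 0.010,
    "cancer": 0.006,
    "heart_disease": 0.073,
    "stroke": 0.010,
    "lung_disease": 0.066,
    "liver_disease": 0.024,
}

# Prevalence of each active indicator (is_male comes from sex_fraction_male).
DEFAULT_COVARIATE_PREVALENCES: dict[str, float] = {
    "is_married": 0.78,
    "is_widowed": 0.14,
    "is_rural": 0.60,
    "currently_smoking": 0.30,
    "rarely_bothered": 0.55,
    "rarely_lacks_focus": 0.50,
    "rarely_depressed": 0.55,
    "rarely_hopeful": 0.40,
    "rarely_fearful": 0.70,
    "restless_sleep_is_rare": 0.45,
    "rarely_happy": 0.30,
    "rarely_lonely": 0.60,
}


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic cohort."""

    n_participants: int = 11_914
    age_range: tuple[float, float] = (45.0, 90.0)
    sex_fraction_male: float = 0.48
    fasting_fraction: float = 0.70
    biomarker_specs: dict[str, BiomarkerSpec] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_SPECS)
    )
    disease_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_EFFECTS)
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    disease_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_PREVALENCES)
    )
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    residual_pace_sd: float = 1.5
    missing_sex_fraction: float = 0.0  # injected for exclusion-logic testing
    seed: int = 0

    # -- derived / helpers -------------------------------------------------
    def validate(self, schema: VariableSchema | None = None) -> None:
        schema = schema or default_schema()
        errors: list[str] = []
        if self.n_participants < 1:
            errors.append("n_participants must be >= 1")
        low, high = self.age_range
        if not low < high:
            errors.append("age_range low must be < high")
        for name, p in [
            ("sex_fraction_male", self.sex_fraction_male),
            ("fasting_fraction", self.fasting_fraction),
            ("missing_sex_fraction", self.missing_sex_fraction),
            *self.disease_prevalences.items(),
            *self.covariate_prevalences.items(),
        ]:
            if not 0.0 <= p <= 1.0:
                errors.append(f"{name} must lie in [0, 1], got {p}")
        if self.residual_pace_sd < 0:
            errors.append("residual_pace_sd must be >= 0")
        if not self.biomarker_specs:
            errors.append("biomarker_specs must not be empty")
        expected = set(schema.continuous_predictors)
        got = set(self.biomarker_specs)
        if got != expected:
            missing, extra = expected - got, got - expected
            if missing:
                errors.append(f"biomarker_specs missing {sorted(missing)}")
            if extra:
                errors.append(f"biomarker_specs has unknown {sorted(extra)}")
        for name, spec in self.biomarker_specs.items():
            if spec.noise_sd < 0:
                errors.append(f"{name}: noise_sd must be >= 0")
        pm = self.covariate_prevalences.get("is_married", 0.0)
        pw = self.covariate_prevalences.get("is_widowed", 0.0)
        if pm + pw > 1.0:
            errors.append("is_married + is_widowed prevalence exceeds 1")
        if errors:
            raise ConfigError("; ".join(errors))

    def with_noise_scale(self, factor: float) -> "SyntheticConfig":
        """Copy with all biomarker noise SDs and the residual pace SD scaled."""
        specs = {
            name: dataclasses.replace(spec, noise_sd=spec.noise_sd * factor)
            for name, spec in self.biomarker_specs.items()
        }
        return dataclasses.replace(
            self,
            biomarker_specs=specs,
            residual_pace_sd=self.residual_pace_sd * factor,
        )

    def with_effects_zeroed(self) -> "SyntheticConfig":
        """Copy with every injected disease/covariate effect set to 0."""
        return dataclasses.replace(
            self,
            disease_effects={k: 0.0 for k in self.disease_effects},
            covariate_effects={k: 0.0 for k in self.covariate_effects},
        )

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["age_range"] = list(self.age_range)
        doc["biomarker_specs"] = {
            k: dataclasses.asdict(v) for k, v in self.biomarker_specs.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_mapping(doc)

    @classmethod
    def from_mapping(cls, doc: dict) -> "SyntheticConfig":
        doc = dict(doc)
        if "age_range" in doc:
            doc["age_range"] = tuple(float(x) for x in doc["age_range"])
        if "biomarker_specs" in doc and doc["biomarker_specs"]:
            doc["biomarker_specs"] = {
                k: v if isinstance(v, BiomarkerSpec) else BiomarkerSpec(**v)
                for k, v in doc["biomarker_specs"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort.

    ``table`` has one row per participant: chronological age, the summed
    active factor effects, the residual pace draw, the total latent
    acceleration, and the effective age at which biomarkers were generated.
    ``injected_effects`` maps every factor (condition or indicator) to its
    configured effect in years.
    """

    table: pd.DataFrame
    injected_effects: dict[str, float]

    def conservation_residual(self) -> np.ndarray:
        """effective_age − chronological_age − Σ effects − residual (≡ 0)."""
        t = self.table
        return (
            t["effective_age"]
            - t["chronological_age"]
            - t["factor_effect_sum"]
            - t["residual_pace"]
        ).to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def biomarker_value(
    spec: BiomarkerSpec,
    effective_age: float | np.ndarray,
    sex: str | np.ndarray,
    noise_draw: float | np.ndarray = 0.0,
):
    """Evaluate one biomarker curve at an effective age (pure function)."""
    d = (np.asarray(effective_age, dtype=float) - 45.0) / 10.0
    male = np.asarray(sex) == "male"
    return (
        spec.baseline
        + spec.slope_per_decade * d
        + spec.quadratic_per_decade2 * d**2
        + spec.sex_offset * male
        + noise_draw
    )


def generate_cohort(
    config: SyntheticConfig, schema: VariableSchema | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a cohort table and its ground truth.

    Deterministic given ``config.seed``. Draw order (single stream):
    ages, sex, fasting, area, marital status, smoking, the eight psych
    items, the ten disease flags, the residual pace, per-biomarker noise,
    and finally any missing-sex injection.
    """
    schema = schema or default_schema()
    config.validate(schema)
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    sex = np.where(rng.random(n) < config.sex_fraction_male, "male", "female")
    fasting = (rng.random(n) < config.fasting_fraction).astype(int)
    area = np.where(
        rng.random(n) < config.covariate_prevalences.get("is_rural", 0.0),
        "rural",
        "urban",
    )
    pm = config.covariate_prevalences.get("is_married", 0.0)
    pw = config.covariate_prevalences.get("is_widowed", 0.0)
    u = rng.random(n)
    marital = np.where(u < pm, "married", np.where(u < pm + pw, "widowed", "never_married"))
    smoking = (
        rng.random(n) < config.covariate_prevalences.get("currently_smoking", 0.0)
    ).astype(int)

    # 4-level frequency items: level 0 ("rarely") at the indicator prevalence,
    # the remainder split over levels 1..3 with fixed 0.5/0.3/0.2 weights.
    psych_levels: dict[str, np.ndarray] = {}
    for item in schema.psych_items:
        ind = schema.indicator_for(item)
        p0 = config.covariate_prevalences.get(ind, 0.0)
        u = rng.random(n)
        rest = np.maximum(1.0 - p0, 1e-12)
        lvl = np.select(
            [u < p0, u < p0 + 0.5 * rest, u < p0 + 0.8 * rest],
            [0, 1, 2],
            default=3,
        )
        psych_levels[item] = lvl

    flags = {
        cond: (rng.random(n) < config.disease_prevalences.get(cond, 0.0)).astype(int)
        for cond in schema.disease_flags
    }
    residual = (
        rng.normal(0.0, config.residual_pace_sd, size=n)
        if config.residual_pace_sd > 0
        else np.zeros(n)
    )

    indicators = _indicator_matrix(
        schema, sex=sex, marital=marital, area=area, smoking=smoking,
        psych_levels=psych_levels,
    )
    effect_sum = np.zeros(n)
    injected: dict[str, float] = {}
    for cond in schema.disease_flags:
        eff = float(config.disease_effects.get(cond, 0.0))
        injected[cond] = eff
        effect_sum += eff * flags[cond]
    for name in INDICATOR_ORDER:
        eff = float(config.covariate_effects.get(name, 0.0))
        injected[name] = eff
        effect_sum += eff * indicators[name]

    effective_age = age + effect_sum + residual

    data: dict[str, object] = {
        "id": [f"S{i:06d}" for i in range(1, n + 1)],
        "chronological_age": np.round(age, 4),
    }
    for name in schema.predictor_names:
        if name == "sex":
            data["sex"] = sex.copy()
        elif name == "fasting":
            data["fasting"] = fasting
        else:
            spec = config.biomarker_specs[name]
            noise = (
                rng.normal(0.0, spec.noise_sd, size=n)
                if spec.noise_sd > 0
                else np.zeros(n)
            )
            data[name] = biomarker_value(spec, effective_age, sex, noise)
    for cond in schema.disease_flags:
        data[cond] = flags[cond]
    data["area"] = area
    data["marital_status"] = marital
    data["smoking"] = smoking
    for item in schema.psych_items:
        data[item] = psych_levels[item]

    cohort = pd.DataFrame(data)[schema.column_order]
    if config.missing_sex_fraction > 0:
        mask = rng.random(n) < config.missing_sex_fraction
        cohort.loc[mask, "sex"] = pd.NA

    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "id": cohort["id"],
                "chronological_age": age,
                "factor_effect_sum": effect_sum,
                "residual_pace": residual,
                "latent_acceleration": effect_sum + residual,
                "effective_age": effective_age,
            }
        ),
        injected_effects=injected,
    )
    return cohort, truth


def _indicator_matrix(schema, *, sex, marital, area, smoking, psych_levels):
    ind: dict[str, np.ndarray] = {
        "is_male": (np.asarray(sex) == "male").astype(int),
        "is_married": (marital == "married").astype(int),
        "is_widowed": (marital == "widowed").astype(int),
        "is_rural": (area == "rural").astype(int),
        "currently_smoking": np.asarray(smoking).astype(int),
    }
    for item in schema.psych_items:
        ind[schema.indicator_for(item)] = (psych_levels[item] == 0).astype(int)
    assert set(ind) == set(INDICATOR_ORDER)
    return ind
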