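"""Model parameter sets: validation, uncertainty specs, fixture and I/O.

A :class:`ModelParameters` holds one complete point-estimate input set for
the three-arm prevention model.  A :class:`ParameterSetWithUncertainty`
pairs it with per-parameter :class:`DistributionSpec` entries (beta for
probabilities and utilities, gamma for costs, log-normal for odds ratios)
for probabilistic sensitivity analysis.

:func:`reference_fixture` returns the package's canonical parameter set.
Values printed in the source material are used verbatim; quantities that
the underlying study sourced from references without printing are filled
with documented assumptions and carry ``assumed: true`` in serialized form.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import epi_math

__all__ = [
    "ScreeningPerformance",
    "ModelParameters",
    "DistributionSpec",
    "ParameterSetWithUncertainty",
    "ParameterFileError",
    "UNCERTAIN_FIELDS",
    "reference_fixture",
    "random_parameter_set",
    "load_parameters",
    "save_parameters",
]


class ScreeningPerformance(BaseModel):
    """Operating point of the risk-score screen at one threshold."""

    model_config = ConfigDict(frozen=True)

    threshold_label: float
    sensitivity: float = Field(ge=0.0, le=1.0)
    specificity: float = Field(ge=0.0, le=1.0)


class ModelParameters(BaseModel):
    """Complete point-estimate input set for one model run.

    Utilities are annual weights on the 0-1 scale; costs are GBP.  A model
    cycle is 3 months.  ``or_application`` selects how prevention odds
    ratios act on baseline risks: ``"risk"`` multiplies the risk directly,
    ``"odds"`` converts through the odds scale.
    """

    model_config = ConfigDict(frozen=True)

    cohort_size: int = Field(ge=1)
    horizon_cycles: int = Field(ge=1)
    annual_incidence: float = Field(ge=0.0, lt=1.0)
    recovery_prob_6m: float = Field(ge=0.0, le=1.0)
    screening: ScreeningPerformance
    or_targeted: float = Field(gt=0.0)
    or_universal: float = Field(gt=0.0)
    utility_well: float = Field(ge=0.0, le=1.0)
    utility_depressed: float = Field(ge=0.0, le=1.0)
    utility_recovered: float = Field(ge=0.0, le=1.0)
    annual_treatment_cost: float = Field(ge=0.0)
    programme_cost_per_patient: float = Field(ge=0.0)
    nurse_minutes_per_patient: float = Field(ge=0.0)
    nurse_cost_per_hour: float = Field(ge=0.0)
    training_cost: float = Field(ge=0.0)
    universal_uptake: float = Field(ge=0.0, le=1.0)
    wtp: float = Field(ge=0.0)
    half_cycle_correction: bool = False
    or_application: Literal["risk", "odds"] = "risk"

    @model_validator(mode="after")
    def _utility_ordering(self) -> "ModelParameters":
        if not (
            self.utility_depressed <= self.utility_recovered <= self.utility_well
        ):
            raise ValueError(
                "utility ordering violated: require utility_depressed <= "
                f"utility_recovered <= utility_well, got {self.utility_depressed}, "
                f"{self.utility_recovered}, {self.utility_well}"
            )
        return self

    def with_updates(self, **updates: object) -> "ModelParameters":
        """Return a re-validated copy with fields replaced.

        ``sensitivity`` / ``specificity`` / ``threshold_label`` address the
        nested screening block.
        """
        data = self.model_dump()
        for key, value in updates.items():
            if key in ("sensitivity", "specificity", "threshold_label"):
                data["screening"][key] = value
            else:
                if key not in data:
                    raise KeyError(f"unknown parameter {key!r}")
                data[key] = value
        return ModelParameters.model_validate(data)


class DistributionSpec(BaseModel):
    """Uncertainty description of one parameter for PSA sampling.

    When the SE of a non-fixed parameter is unreported the SE=mean rule is
    applied (``effective_se`` equals the mean and ``se_is_fallback`` is
    True).  Log-normal specs prefer a 95% CI for the spread; the ``mean``
    of a log-normal spec is the odds ratio itself (distribution median).
    """

    model_config = ConfigDict(frozen=True)

    family: Literal["beta", "gamma", "lognormal", "fixed"]
    mean: float
    se: Optional[float] = Field(default=None, gt=0.0)
    ci_low: Optional[float] = Field(default=None, gt=0.0)
    ci_high: Optional[float] = Field(default=None, gt=0.0)
    assumed: bool = False
    source: Optional[str] = None

    @model_validator(mode="after")
    def _family_constraints(self) -> "DistributionSpec":
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValueError(f"beta mean must lie in (0, 1), got {self.mean}")
        if self.family in ("gamma", "lognormal") and self.mean <= 0.0:
            raise ValueError(f"{self.family} mean must be positive, got {self.mean}")
        if self.family == "lognormal":
            has_ci = self.ci_low is not None and self.ci_high is not None
            if not has_ci and self.se is None:
                raise ValueError("lognormal spec needs either se or both CI bounds")
            if has_ci and not self.ci_low < self.mean < self.ci_high:
                raise ValueError(
                    f"require ci_low < mean < ci_high, got "
                    f"({self.ci_low}, {self.mean}, {self.ci_high})"
                )
        return self

    @property
    def se_is_fallback(self) -> bool:
        if self.family == "fixed":
            return False
        if self.family == "lognormal" and self.ci_low is not None:
            return False
        return self.se is None

    @property
    def effective_se(self) -> float:
        """The SE used for sampling; equals the mean when unreported."""
        return self.se if self.se is not None else self.mean

    def fitted(self, name: str = "") -> tuple:
        """Distribution parameters for sampling: ("beta", a, b) etc."""
        if self.family == "fixed":
            return ("fixed", self.mean)
        if self.family == "beta":
            a, b = epi_math.beta_from_mean_se(self.mean, self.effective_se, name)
            return ("beta", a, b)
        if self.family == "gamma":
            shape, scale = epi_math.gamma_from_mean_se(self.mean, self.effective_se, name)
            return ("gamma", shape, scale)
        if self.ci_low is not None and self.ci_high is not None:
            mu, sigma = epi_math.lognormal_from_or_ci(
                self.mean, self.ci_low, self.ci_high, name
            )
        else:
            mu, sigma = epi_math.lognormal_from_or_se(self.mean, self.effective_se, name)
        return ("lognormal", mu, sigma)


#: Parameter names that may carry a DistributionSpec, with how they map onto
#: ModelParameters fields ("sensitivity"/"specificity" live on the nested
#: screening block).
UNCERTAIN_FIELDS: tuple[str, ...] = (
    "annual_incidence",
    "recovery_prob_6m",
    "sensitivity",
    "specificity",
    "or_targeted",
    "or_universal",
    "utility_well",
    "utility_depressed",
    "utility_recovered",
    "annual_treatment_cost",
    "programme_cost_per_patient",
)


def _point_value(point: ModelParameters, name: str) -> float:
    if name in ("sensitivity", "specificity"):
        return getattr(point.screening, name)
    return getattr(point, name)


class ParameterSetWithUncertainty(BaseModel):
    """A point-estimate set plus the uncertainty of each sampled parameter."""

    model_config = ConfigDict(frozen=True)

    point: ModelParameters
    dists: dict[str, DistributionSpec]

    @model_validator(mode="after")
    def _consistency(self) -> "ParameterSetWithUncertainty":
        for name, spec in self.dists.items():
            if name not in UNCERTAIN_FIELDS:
                raise ValueError(f"unknown uncertain parameter {name!r}")
            value = _point_value(self.point, name)
            if abs(spec.mean - value) > 1e-9:
                raise ValueError(
                    f"distribution mean for {name!r} ({spec.mean}) does not "
                    f"match the point estimate ({value})"
                )
        return self

    def with_point_updates(self, **updates: object) -> "ParameterSetWithUncertainty":
        """Update point values, re-centring any matching distribution.

        Beta/gamma specs keep their SE; log-normal specs have their CI
        shifted multiplicatively so the log-scale spread is preserved.
        """
        point = self.point.with_updates(**updates)
        dists = dict(self.dists)
        for key, value in updates.items():
            if key in dists:
                spec = dists[key]
                patch: dict[str, object] = {"mean": float(value)}
                if spec.family == "lognormal" and spec.ci_low is not None:
                    ratio = float(value) / spec.mean
                    patch["ci_low"] = spec.ci_low * ratio
                    patch["ci_high"] = spec.ci_high * ratio
                dists[key] = spec.model_copy(update=patch)
        return ParameterSetWithUncertainty(point=point, dists=dists)

    def with_dist(self, name: str, spec: DistributionSpec) -> "ParameterSetWithUncertainty":
        dists = dict(self.dists)
        dists[name] = spec
        point = self.point.with_updates(**{name: spec.mean})
        return ParameterSetWithUncertainty(point=point, dists=dists)


_SETTINGS_FIELDS = (
    "cohort_size",
    "horizon_cycles",
    "nurse_minutes_per_patient",
    "nurse_cost_per_hour",
    "training_cost",
    "universal_uptake",
    "wtp",
    "half_cycle_correction",
    "or_application",
)


def reference_fixture() -> ParameterSetWithUncertainty:
    """The canonical parameter set of the model.

    Printed values (12-month incidence 8.8%; screen sensitivity 0.506 /
    specificity 0.8 at threshold 0.133; targeted prevention OR 0.66;
    programme cost mean GBP 100 over a 0-200 range; GBP 2000 training; 15
    nurse-minutes per screen; utility 0.86 when well; cohort 1000; four
    quarterly cycles; WTP GBP 20,000/QALY) are used verbatim.  Quantities
    sourced in the underlying study from references without printed values
    are assumptions, flagged ``assumed`` in serialization and documented in
    docs/methods.md: 6-month recovery probability 0.50, utilities 0.58
    (depressed) / 0.72 (recovered), weighted annual treatment cost GBP 400,
    nurse rate GBP 42/hour, universal-programme OR 0.909 (calibrated so the
    universal arm prevents 8 of the 88 expected cases), and all SEs/CIs
    marked assumed below.
    """
    point = ModelParameters(
        cohort_size=1000,
        horizon_cycles=4,
        annual_incidence=0.088,
        recovery_prob_6m=0.50,
        screening=ScreeningPerformance(
            threshold_label=0.133, sensitivity=0.506, specificity=0.8
        ),
        or_targeted=0.66,
        or_universal=0.909,
        utility_well=0.86,
        utility_depressed=0.58,
        utility_recovered=0.72,
        annual_treatment_cost=400.0,
        programme_cost_per_patient=100.0,
        nurse_minutes_per_patient=15.0,
        nurse_cost_per_hour=42.0,
        training_cost=2000.0,
        universal_uptake=1.0,
        wtp=20000.0,
        half_cycle_correction=False,
        or_application="risk",
    )
    dists = {
        "annual_incidence": DistributionSpec(
            family="beta", mean=0.088, se=0.009, assumed=True,
            source="12-month incidence in primary-care attenders; SE assumed",
        ),
        "recovery_prob_6m": DistributionSpec(
            family="beta", mean=0.50, se=0.05, assumed=True,
            source="6-month recovery probability; value and SE assumed",
        ),
        "sensitivity": DistributionSpec(
            family="beta", mean=0.506, se=0.05, assumed=True,
            source="risk-score sensitivity at threshold 0.133; SE assumed "
                   "(binomial precision of the validation sample)",
        ),
        "specificity": DistributionSpec(
            family="beta", mean=0.8, se=0.015, assumed=True,
            source="risk-score specificity at threshold 0.133; SE assumed",
        ),
        "or_targeted": DistributionSpec(
            family="lognormal", mean=0.66, ci_low=0.552, ci_high=0.790,
            assumed=True,
            source="pooled prevention-programme OR; CI width assumed from the "
                   "precision of the source meta-analysis pooled estimate",
        ),
        "or_universal": DistributionSpec(
            family="lognormal", mean=0.909, ci_low=0.65, ci_high=1.27,
            assumed=True,
            source="universal-programme OR calibrated to 8 prevented cases "
                   "per 88 expected; wide CI assumed (two source studies)",
        ),
        "utility_well": DistributionSpec(
            family="beta", mean=0.86, se=0.02, assumed=True,
            source="general-population utility; SE assumed",
        ),
        "utility_depressed": DistributionSpec(
            family="beta", mean=0.58, se=0.05, assumed=True,
            source="utility while depressed; value and SE assumed",
        ),
        "utility_recovered": DistributionSpec(
            family="beta", mean=0.72, se=0.05, assumed=True,
            source="utility after recovery; value and SE assumed",
        ),
        "annual_treatment_cost": DistributionSpec(
            family="gamma", mean=400.0, assumed=True,
            source="weighted annual treatment cost; level assumed, SE "
                   "unreported so the SE=mean rule applies",
        ),
        "programme_cost_per_patient": DistributionSpec(
            family="gamma", mean=100.0, se=50.0, assumed=False,
            source="prevention-programme cost, mean GBP 100 over GBP 0-200; "
                   "SE 50 places ~95% of mass inside the printed range",
        ),
    }
    return ParameterSetWithUncertainty(point=point, dists=dists)


def random_parameter_set(seed: int) -> ParameterSetWithUncertainty:
    """A valid random parameter set from plausible ranges (for fuzzing).

    Deterministic for a given seed.  Betas receive SEs at 20% of the
    feasibility bound, gammas SE = mean/2, log-normals a CI spanning a
    factor of ~2; every returned set satisfies all model invariants.
    """
    rng = np.random.default_rng(seed)

    def u(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    utility_well = u(0.70, 0.95)
    utility_recovered = utility_well - u(0.02, 0.20)
    utility_depressed = max(utility_recovered - u(0.02, 0.30), 0.05)
    point = ModelParameters(
        cohort_size=int(rng.integers(100, 5000)),
        horizon_cycles=int(rng.integers(1, 9)),
        annual_incidence=u(0.02, 0.25),
        recovery_prob_6m=u(0.15, 0.85),
        screening=ScreeningPerformance(
            threshold_label=round(u(0.05, 0.30), 3),
            sensitivity=u(0.30, 0.95),
            specificity=u(0.30, 0.95),
        ),
        or_targeted=float(np.exp(rng.normal(np.log(0.7), 0.25))),
        or_universal=float(np.exp(rng.normal(np.log(0.9), 0.15))),
        utility_well=utility_well,
        utility_depressed=utility_depressed,
        utility_recovered=utility_recovered,
        annual_treatment_cost=u(50.0, 1500.0),
        programme_cost_per_patient=u(5.0, 300.0),
        nurse_minutes_per_patient=u(5.0, 30.0),
        nurse_cost_per_hour=u(20.0, 80.0),
        training_cost=u(0.0, 5000.0),
        universal_uptake=u(0.0, 1.0),
        wtp=u(10000.0, 40000.0),
        half_cycle_correction=bool(rng.integers(0, 2)),
        or_application="risk",
    )

    def beta_spec(mean: float) -> DistributionSpec:
        se = 0.2 * float(np.sqrt(mean * (1.0 - mean)))
        return DistributionSpec(family="beta", mean=mean, se=se, assumed=True)

    def lognormal_spec(mean: float) -> DistributionSpec:
        return DistributionSpec(
            family="lognormal", mean=mean, ci_low=mean * 0.7,
            ci_high=mean / 0.7, assumed=True,
        )

    dists = {
        "annual_incidence": beta_spec(point.annual_incidence),
        "recovery_prob_6m": beta_spec(point.recovery_prob_6m),
        "sensitivity": beta_spec(point.screening.sensitivity),
        "specificity": beta_spec(point.screening.specificity),
        "or_targeted": lognormal_spec(point.or_targeted),
        "or_universal": lognormal_spec(point.or_universal),
        "utility_well": beta_spec(point.utility_well),
        "utility_depressed": beta_spec(point.utility_depressed),
        "utility_recovered": beta_spec(point.utility_recovered),
        "annual_treatment_cost": DistributionSpec(
            family="gamma", mean=point.annual_treatment_cost,
            se=point.annual_treatment_cost / 2.0, assumed=True,
        ),
        "programme_cost_per_patient": DistributionSpec(
            family="gamma", mean=point.programme_cost_per_patient,
            se=point.programme_cost_per_patient / 2.0, assumed=True,
        ),
    }
    return ParameterSetWithUncertainty(point=point, dists=dists)


class ParameterFileError(ValueError):
    """Raised when a parameter file is missing, malformed or out of range."""


def to_dict(pset: ParameterSetWithUncertainty) -> dict:
    """Plain-dict form of a parameter set for serialization."""
    point = pset.point
    doc: dict = {
        "settings": {k: getattr(point, k) for k in _SETTINGS_FIELDS},
        "screening": {"threshold_label": point.screening.threshold_label},
        "parameters": {},
    }
    for name in UNCERTAIN_FIELDS:
        if name not in pset.dists:
            continue
        spec = pset.dists[name]
        entry: dict = {"value": _point_value(point, name), "family": spec.family}
        if spec.se is not None:
            entry["se"] = spec.se
        if spec.ci_low is not None:
            entry["ci_low"] = spec.ci_low
            entry["ci_high"] = spec.ci_high
        entry["assumed"] = spec.assumed
        if spec.source is not None:
            entry["source"] = spec.source
        doc["parameters"][name] = entry
    return doc


def from_dict(doc: dict) -> ParameterSetWithUncertainty:
    """Inverse of :func:`to_dict`, with errors naming the offending field."""
    try:
        settings = dict(doc["settings"])
        screening_doc = dict(doc.get("screening", {}))
        params_doc = dict(doc["parameters"])
    except (KeyError, TypeError) as exc:
        raise ParameterFileError(f"missing top-level section: {exc}") from exc

    dists: dict[str, DistributionSpec] = {}
    values: dict[str, float] = {}
    for name, entry in params_doc.items():
        if name not in UNCERTAIN_FIELDS:
            raise ParameterFileError(f"unknown parameter {name!r}")
        try:
            spec = DistributionSpec(
                family=entry.get("family", "fixed"),
                mean=entry["value"],
                se=entry.get("se"),
                ci_low=entry.get("ci_low"),
                ci_high=entry.get("ci_high"),
                assumed=entry.get("assumed", False),
                source=entry.get("source"),
            )
        except KeyError as exc:
            raise ParameterFileError(f"parameter {name!r}: missing field {exc}") from exc
        except ValidationError as exc:
            raise ParameterFileError(f"parameter {name!r}: {exc}") from exc
        dists[name] = spec
        values[name] = entry["value"]

    missing = [n for n in UNCERTAIN_FIELDS if n not in values]
    if missing:
        raise ParameterFileError(f"missing parameters: {missing}")
    try:
        point = ModelParameters(
            screening=ScreeningPerformance(
                threshold_label=screening_doc.get("threshold_label", 0.0),
                sensitivity=values["sensitivity"],
                specificity=values["specificity"],
            ),
            **{k: values[k] for k in values if k not in ("sensitivity", "specificity")},
            **settings,
        )
    except (ValidationError, TypeError) as exc:
        raise ParameterFileError(str(exc)) from exc
    return ParameterSetWithUncertainty(point=point, dists=dists)


def serialize(pset: ParameterSetWithUncertainty) -> str:
    return yaml.safe_dump(to_dict(pset), sort_keys=True)


def save_parameters(pset: ParameterSetWithUncertainty, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize(pset))


def load_parameters(path) -> ParameterSetWithUncertainty:
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ParameterFileError(f"parameter file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ParameterFileError(f"could not parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParameterFileError(f"{path} does not contain a parameter document")
    return from_dict(doc)
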