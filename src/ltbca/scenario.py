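"""Scenario configuration: validation, model assembly, and the pipeline.

A scenario YAML names the three input tables (incidence, screening,
weights), the study windows, the sojourn distribution, the screening
policy, and every model switch. Validation is strict — unknown keys are
rejected and all violations are reported at once — and each run logs the
resolved configuration together with a content hash of every input file.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import io as ltbca_io
from .core import (
    AgeStratum,
    BiasResult,
    ModelOptions,
    StudyWindow,
    compute_bias,
)
from .duration import (
    DurationSpec,
    lognormal_from_mode_sd,
    overdiagnosis_mixture,
)
from .incidence import IncidenceCurve, fit_incidence_curve, shift_to_preclinical
from .screening import ScreeningBehavior, ScreeningPolicy

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "ScenarioError",
    "load_scenario",
    "build_model",
    "ModelInputs",
    "run_pipeline",
    "default_scenario_dict",
]


class ScenarioError(ValueError):
    """Raised with all validation problems of a scenario file at once."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputsConfig(_Strict):
    incidence: str
    screening: str
    weights: str


class StrataConfig(_Strict):
    exposed: str = "smoker"
    reference: str = "nonsmoker"


class AgeStratumConfig(_Strict):
    label: str
    a0: float = Field(ge=0)
    aE: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.a0 < self.aE:
            raise ValueError(f"age stratum {self.label!r}: need a0 < aE")
        return self


class StudyConfig(_Strict):
    age_strata: list[AgeStratumConfig] = Field(min_length=1)
    screenage: float = Field(default=40.0, ge=0)
    maxage: float = Field(default=100.0, gt=0)


class DurationConfig(_Strict):
    mode_years: float = Field(gt=0)
    sd_years: float = Field(gt=0)
    overdiagnosis_weight: float = Field(default=0.0, ge=0.0, lt=1.0)
    overdiagnosis_mode_years: float = Field(default=20.0, gt=0)
    overdiagnosis_sd_years: float = Field(default=3.0, gt=0)


class ScreeningConfig(_Strict):
    sensitivity: float = Field(ge=0.0, le=1.0)
    detection_form: Literal["geometric", "linear"] = "geometric"
    line1_form: Literal["coupled", "product"] = "coupled"
    two_plus_value: float = Field(default=2.0, gt=0)


class IncidenceFitConfig(_Strict):
    family: Literal["logcubic", "logquad", "spline"] = "logcubic"
    scale: Literal["log", "rate"] = "log"


class ModelConfig(_Strict):
    gs_includes_baseline: bool = True
    shared_weights: bool = True


class QuadratureConfig(_Strict):
    step: float = Field(default=0.05, gt=0)
    refinement_check: bool = False
    refinement_rtol: float = Field(default=1e-6, gt=0)


class MicrosimConfig(_Strict):
    screen_process: Literal["expected_count", "poisson"] = "expected_count"
    n: int = Field(default=200_000, ge=1)
    seed: int = Field(default=1, ge=0)


class Scenario(_Strict):
    inputs: InputsConfig
    strata: StrataConfig = StrataConfig()
    study: StudyConfig
    duration: DurationConfig
    screening: ScreeningConfig
    incidence_fit: IncidenceFitConfig = IncidenceFitConfig()
    model: ModelConfig = ModelConfig()
    quadrature: QuadratureConfig = QuadratureConfig()
    microsim: MicrosimConfig = MicrosimConfig()
    base_dir: Path | None = Field(default=None, exclude=True)

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p


def load_scenario(path: str | Path) -> Scenario:
    """Parse and validate a scenario YAML; all errors are reported together."""
    path = Path(path)
    data = ltbca_io.read_yaml(path)
    try:
        scenario = Scenario.model_validate(data)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ScenarioError(f"{path}: {problems}") from exc
    object.__setattr__(scenario, "base_dir", path.parent)
    return scenario


def default_scenario_dict(config) -> dict:
    """A complete scenario mapping for a generated fixture set."""
    return {
        "inputs": {
            "incidence": "incidence.csv",
            "screening": "screening.csv",
            "weights": "weights.csv",
        },
        "strata": {"exposed": config.exposed, "reference": config.reference},
        "study": {
            "age_strata": [
                {"label": label, "a0": a0, "aE": aE}
                for label, a0, aE in config.age_strata
            ],
            "screenage": config.screenage,
            "maxage": config.maxage,
        },
        "duration": {
            "mode_years": 5.0,
            "sd_years": 3.0,
            "overdiagnosis_weight": 0.0,
            "overdiagnosis_mode_years": 20.0,
            "overdiagnosis_sd_years": 3.0,
        },
        "screening": {"sensitivity": 0.46},
        "model": {
            "gs_includes_baseline": True,
            "shared_weights": config.weights_mode != "stratum-specific",
        },
    }


def duration_from_config(cfg: DurationConfig) -> DurationSpec:
    base = lognormal_from_mode_sd(cfg.mode_years, cfg.sd_years)
    if cfg.overdiagnosis_weight > 0:
        return overdiagnosis_mixture(
            base,
            weight=cfg.overdiagnosis_weight,
            long_mode=cfg.overdiagnosis_mode_years,
            long_sd=cfg.overdiagnosis_sd_years,
        )
    return base


@dataclass(frozen=True)
class ModelInputs:
    """Everything the integrator and the microsimulation consume."""

    scenario: Scenario
    clinical_before: IncidenceCurve
    clinical_during: IncidenceCurve
    duration: DurationSpec
    w_b: IncidenceCurve
    w_d: IncidenceCurve
    behaviors: dict[tuple[str, str], ScreeningBehavior]
    policy: ScreeningPolicy
    window: StudyWindow
    options: ModelOptions

    @property
    def exposed(self) -> str:
        return self.scenario.strata.exposed

    @property
    def reference(self) -> str:
        return self.scenario.strata.reference

    def with_duration(self, duration: DurationSpec) -> "ModelInputs":
        """Same scenario with another sojourn spec (curves re-shifted)."""
        mean = duration.mean()
        return ModelInputs(
            scenario=self.scenario,
            clinical_before=self.clinical_before,
            clinical_during=self.clinical_during,
            duration=duration,
            w_b=shift_to_preclinical(self.clinical_before, mean),
            w_d=shift_to_preclinical(self.clinical_during, mean),
            behaviors=self.behaviors,
            policy=self.policy,
            window=self.window,
            options=self.options,
        )

    def with_policy(self, policy: ScreeningPolicy) -> "ModelInputs":
        return ModelInputs(
            scenario=self.scenario,
            clinical_before=self.clinical_before,
            clinical_during=self.clinical_during,
            duration=self.duration,
            w_b=self.w_b, w_d=self.w_d,
            behaviors=self.behaviors, policy=policy,
            window=self.window, options=self.options,
        )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _weights_table(
    raw: dict[str, dict[str, float]],
    labels: list[str],
    shared: bool,
    strata: StrataConfig,
) -> dict[str, tuple[float, ...]]:
    problems = []
    out: dict[str, tuple[float, ...]] = {}
    wanted = ["all"] if shared else [strata.exposed, strata.reference]
    for key in wanted:
        if key not in raw:
            problems.append(f"weights: missing entry for stratum {key!r}")
            continue
        per_label = raw[key]
        missing = [lb for lb in labels if lb not in per_label]
        if missing:
            problems.append(f"weights[{key!r}]: missing age strata {missing}")
            continue
        out[key] = tuple(per_label[lb] for lb in labels)
    if problems:
        raise ScenarioError("; ".join(problems))
    return out


def build_model(scenario: Scenario) -> ModelInputs:
    """Read inputs, fit and shift curves, and assemble all model objects."""
    paths = {
        name: scenario.resolve(getattr(scenario.inputs, name))
        for name in ("incidence", "screening", "weights")
    }
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise ScenarioError(f"missing input files: {missing}")
    for name, p in paths.items():
        logger.info("input %s: %s (sha256 %s)", name, p, _hash_file(p))
    logger.info("resolved scenario: %s", scenario.model_dump())

    points = ltbca_io.read_incidence_csv(paths["incidence"])
    fit = scenario.incidence_fit
    clinical = {
        period: fit_incidence_curve(
            points, period, family=fit.family, scale=fit.scale,
            maxage=scenario.study.maxage,
        )
        for period in ("before", "during")
    }
    duration = duration_from_config(scenario.duration)
    mean = duration.mean()

    behaviors = ltbca_io.read_screening_csv(paths["screening"])
    for stratum in (scenario.strata.exposed, scenario.strata.reference):
        for period in ("before", "during"):
            if (stratum, period) not in behaviors:
                raise ScenarioError(
                    f"screening table lacks (stratum={stratum!r}, period={period!r})"
                )

    labels = [s.label for s in scenario.study.age_strata]
    weights = _weights_table(
        ltbca_io.read_weights_csv(paths["weights"]), labels,
        scenario.model.shared_weights, scenario.strata,
    )
    window = StudyWindow(
        strata=tuple(
            AgeStratum(label=s.label, a0=s.a0, aE=s.aE)
            for s in scenario.study.age_strata
        ),
        weights=weights,
        screenage=scenario.study.screenage,
        maxage=scenario.study.maxage,
    )
    policy = ScreeningPolicy(
        sensitivity=scenario.screening.sensitivity,
        screenage=scenario.study.screenage,
        detection_form=scenario.screening.detection_form,
    )
    options = ModelOptions(
        step=scenario.quadrature.step,
        line1_form=scenario.screening.line1_form,
        gs_includes_baseline=scenario.model.gs_includes_baseline,
        refinement_check=scenario.quadrature.refinement_check,
        refinement_rtol=scenario.quadrature.refinement_rtol,
    )
    return ModelInputs(
        scenario=scenario,
        clinical_before=clinical["before"],
        clinical_during=clinical["during"],
        duration=duration,
        w_b=shift_to_preclinical(clinical["before"], mean),
        w_d=shift_to_preclinical(clinical["during"], mean),
        behaviors=behaviors,
        policy=policy,
        window=window,
        options=options,
    )


def compute_bias_for(inputs: ModelInputs) -> BiasResult:
    return compute_bias(
        inputs.w_b, inputs.w_d, inputs.duration, inputs.behaviors,
        inputs.policy, inputs.window, inputs.exposed, inputs.reference,
        inputs.options,
    )


def run_pipeline(scenario_path: str | Path, out_path: str | Path) -> BiasResult:
    """fit -> shift -> integrate -> aggregate -> RR; writes bias_result.csv.

    Partial output is removed if any stage fails.
    """
    out_path = Path(out_path)
    scenario = load_scenario(scenario_path)
    try:
        inputs = build_model(scenario)
        result = compute_bias_for(inputs)
        result.to_frame().to_csv(out_path, index=False)
    except Exception:
        if out_path.exists():
            out_path.unlink()
        raise
    return result
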