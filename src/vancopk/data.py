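"""Population dataset containers and model specification.

A :class:`PopulationDataset` is a list of :class:`SubjectRecord`s, each with
fixed covariates, dose events and timed concentration observations (times in
hours since the subject's first dose).  A :class:`ModelSpec` describes the
structural/statistical model being estimated: number of compartments,
residual-error model, and the covariate terms enabled on clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .model import (
    ERROR_MODELS,
    DoseEvent,
    PatientCovariates,
    PKParameters,
)

__all__ = [
    "Observation",
    "SubjectRecord",
    "PopulationDataset",
    "CovariateTerm",
    "ModelSpec",
    "FINAL_MODEL_SPEC",
    "BASE_MODEL_SPEC",
    "param_names",
    "params_to_dict",
    "dict_to_pkparams",
]

COVARIATE_RELATIONS = ("power", "inverse-power", "additive")


@dataclass(frozen=True)
class Observation:
    """One observed concentration (mg/L) at a time (h) since first dose."""

    time: float
    conc: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.conc < 0:
            raise ValueError("conc must be >= 0")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    covariates: PatientCovariates
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if len(self.doses) == 0:
            raise ValueError(f"subject {self.subject_id}: at least one dose required")
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))


@dataclass(frozen=True)
class PopulationDataset:
    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if len(self.subjects) == 0:
            raise ValueError("dataset must contain at least one subject")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate effect on clearance.

    relation:
      * ``"power"``          CL *= (x / reference) ** theta
      * ``"inverse-power"``  CL *= (reference / x) ** theta   (albumin form)
      * ``"additive"``       CL += theta * x                  (UFR form)
    """

    covariate: str
    relation: str
    reference: float = 1.0

    def __post_init__(self) -> None:
        if self.relation not in COVARIATE_RELATIONS:
            raise ValueError(f"relation must be one of {COVARIATE_RELATIONS}")
        if not self.reference > 0:
            raise ValueError("reference must be > 0")

    @property
    def param_name(self) -> str:
        suffix = "slope" if self.relation == "additive" else "exponent"
        return f"{self.covariate}_{suffix}"


@dataclass(frozen=True)
class ModelSpec:
    """Structural + statistical model specification for estimation."""

    n_compartments: int = 2
    error_model: str = "proportional"
    covariate_terms: tuple[CovariateTerm, ...] = ()
    allometric: bool = True  # WT^0.75 on CL and WT^1 on Vc, fixed a priori
    wt_ref: float = 70.0

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(f"error_model must be one of {ERROR_MODELS}")
        object.__setattr__(self, "covariate_terms", tuple(self.covariate_terms))
        names = [t.param_name for t in self.covariate_terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate terms")

    def with_term(self, term: CovariateTerm) -> "ModelSpec":
        return ModelSpec(
            self.n_compartments,
            self.error_model,
            self.covariate_terms + (term,),
            self.allometric,
            self.wt_ref,
        )

    def without_term(self, term: CovariateTerm) -> "ModelSpec":
        return ModelSpec(
            self.n_compartments,
            self.error_model,
            tuple(t for t in self.covariate_terms if t != term),
            self.allometric,
            self.wt_ref,
        )


ALBUMIN_POWER_TERM = CovariateTerm("albumin", "inverse-power", 29.0)
UFR_ADDITIVE_TERM = CovariateTerm("ufr", "additive", 1.0)

#: Covariate-free (weight-allometric only) two-compartment base model.
BASE_MODEL_SPEC = ModelSpec(n_compartments=2, error_model="proportional")

#: The published final model: albumin inverse-power + additive UFR on CL.
FINAL_MODEL_SPEC = ModelSpec(
    n_compartments=2,
    error_model="proportional",
    covariate_terms=(ALBUMIN_POWER_TERM, UFR_ADDITIVE_TERM),
)


def param_names(spec: ModelSpec) -> list[str]:
    """Ordered names of the parameters estimated under ``spec``."""
    names = ["cl_pop", "vc_pop"]
    if spec.n_compartments == 2:
        names += ["vp_pop", "q_pop"]
    names += [t.param_name for t in spec.covariate_terms]
    names += ["omega2_cl", "sigma2"]
    if spec.error_model == "combined":
        names += ["sigma2_add"]
    return names


def params_to_dict(params: PKParameters, spec: ModelSpec) -> dict[str, float]:
    """Map a PKParameters container onto the named vector for ``spec``.

    The albumin exponent maps to ``alpha`` and the additive UFR slope to
    ``beta``; any other enabled covariate term starts at 0 (no effect).
    """
    d: dict[str, float] = {
        "cl_pop": params.cl_pop,
        "vc_pop": params.vc_pop,
        "omega2_cl": params.omega2_cl,
        "sigma2": params.sigma2,
    }
    if spec.n_compartments == 2:
        d["vp_pop"] = params.vp_pop
        d["q_pop"] = params.q_pop
    if spec.error_model == "combined":
        d["sigma2_add"] = params.sigma2_add
    for term in spec.covariate_terms:
        if term.covariate == "albumin" and term.relation == "inverse-power":
            d[term.param_name] = params.alpha
        elif term.covariate == "ufr" and term.relation == "additive":
            d[term.param_name] = params.beta
        else:
            d[term.param_name] = 0.0
    return d


def dict_to_pkparams(d: dict[str, float], spec: ModelSpec) -> PKParameters | None:
    """Inverse of :func:`params_to_dict` when the spec's terms map onto the
    final-model fields; returns None for specs with other covariate terms or
    a one-compartment structure (no Vp/Q to report)."""
    if spec.n_compartments != 2:
        return None
    alpha = beta = 0.0
    alb_ref = 29.0
    for term in spec.covariate_terms:
        if term.covariate == "albumin" and term.relation == "inverse-power":
            alpha = d[term.param_name]
            alb_ref = term.reference
        elif term.covariate == "ufr" and term.relation == "additive":
            beta = d[term.param_name]
        else:
            return None
    return PKParameters(
        cl_pop=d["cl_pop"],
        vc_pop=d["vc_pop"],
        vp_pop=d.get("vp_pop", d["vc_pop"]),
        q_pop=d.get("q_pop", 1.0),
        alpha=alpha,
        beta=beta,
        omega2_cl=d["omega2_cl"],
        sigma2=d["sigma2"],
        sigma2_add=d.get("sigma2_add", 0.0),
        error_model=spec.error_model,
        alb_ref=alb_ref,
        wt_ref=spec.wt_ref,
    )
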