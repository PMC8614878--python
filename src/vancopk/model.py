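"""Structural and covariate PK model for vancomycin during CVVH.

Two-compartment disposition with zero-order intravenous infusion input and
linear elimination.  Individual clearance is driven by three covariates:
allometrically scaled body weight (fixed exponent 0.75), serum albumin as an
inverse power term (hypoalbuminemia raises the free fraction available for
convective removal, hence clearance), and the CVVH ultrafiltration rate as an
additive linear term (extracorporeal convective clearance).  Between-subject
variability enters as a single log-normal random effect on clearance:

    CL_i = [ CL_pop (WT/70)^0.75 (29/ALB)^alpha + UFR * beta ] * exp(eta)
    Vc_i = Vc_pop (WT/70),   Vp_i = Vp_pop,   Q_i = Q_pop

Units are fixed throughout: hours, mg, L, mg/L for concentrations, g/L for
albumin, mL/kg/h for ultrafiltration rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PKParameters",
    "PatientCovariates",
    "DoseEvent",
    "IndividualParameters",
    "Regimen",
    "VANCOMYCIN_CVVH_ESTIMATES",
    "individual_parameters",
    "concentration_profile",
    "steady_state_auc24",
]

ERROR_MODELS = ("additive", "proportional", "combined", "exponential")

#: relative floor applied to the discriminant of the disposition quadratic to
#: keep the two macro rate constants separated (repeated-root guard)
_DISC_FLOOR = 1e-12


@dataclass(frozen=True)
class PKParameters:
    """Population fixed effects plus variance components of the final model.

    ``alpha`` is the exponent of the (alb_ref/ALB) albumin term and ``beta``
    the additive ultrafiltration-rate slope (L/h per mL/kg/h) on clearance.
    ``omega2_cl`` is the variance of the log-scale random effect on CL and
    ``sigma2`` the residual-error variance (units depend on ``error_model``;
    dimensionless for proportional/exponential, (mg/L)^2 for additive).
    ``sigma2_add`` is the additive component of the combined model only.
    """

    cl_pop: float
    vc_pop: float
    vp_pop: float
    q_pop: float
    alpha: float = 0.0
    beta: float = 0.0
    omega2_cl: float = 0.0
    sigma2: float = 0.0
    sigma2_add: float = 0.0
    error_model: str = "proportional"
    alb_ref: float = 29.0
    wt_ref: float = 70.0

    def __post_init__(self) -> None:
        for name in ("cl_pop", "vc_pop", "vp_pop", "q_pop", "alb_ref", "wt_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("omega2_cl", "sigma2", "sigma2_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(f"error_model must be one of {ERROR_MODELS}")


#: Published population estimates for vancomycin in critically ill adults on
#: CVVH (proportional residual error).  Used as simulation truth and as the
#: default parameter set for dose optimization.
VANCOMYCIN_CVVH_ESTIMATES = PKParameters(
    cl_pop=1.15,
    vc_pop=16.9,
    vp_pop=25.9,
    q_pop=7.72,
    alpha=5.52,
    beta=0.0377,
    omega2_cl=0.0647,
    sigma2=0.0507,
    error_model="proportional",
)


@dataclass(frozen=True)
class PatientCovariates:
    """Weight (kg), serum albumin (g/L) and ultrafiltration rate (mL/kg/h).

    ``extra`` carries additional named covariates (used by the covariate
    screening / stepwise machinery, e.g. dummy candidates); it is not part of
    the final structural model.
    """

    weight: float
    albumin: float
    ufr: float
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError("weight must be > 0")
        if not self.albumin > 0:
            raise ValueError("albumin must be > 0")
        if self.ufr < 0:
            raise ValueError("ufr must be >= 0")

    def value(self, name: str) -> float:
        if name in ("weight", "albumin", "ufr"):
            return getattr(self, name)
        return self.extra[name]


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order IV infusion: start time (h), amount (mg), duration (h)."""

    time: float
    amount: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.time < 0:
            raise ValueError("time must be >= 0")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass(frozen=True)
class IndividualParameters:
    """Individual-level disposition parameters (post covariates and eta)."""

    cl: float
    vc: float
    vp: float
    q: float

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "vp", "q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Regimen:
    """Weight-normalized maintenance regimen: mg/kg per dose, every `interval` h."""

    dose_per_kg: float
    interval: float
    infusion_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.dose_per_kg < 0:
            raise ValueError("dose_per_kg must be >= 0")
        if not self.interval > 0:
            raise ValueError("interval must be > 0")
        if not self.infusion_duration > 0:
            raise ValueError("infusion_duration must be > 0")

    @property
    def daily_dose_per_kg(self) -> float:
        return self.dose_per_kg * 24.0 / self.interval

    @property
    def administrations_per_day(self) -> float:
        return 24.0 / self.interval

    def label(self) -> str:
        names = {24.0: "qd", 12.0: "q12h", 8.0: "q8h", 6.0: "q6h"}
        iv = names.get(float(self.interval), f"q{self.interval:g}h")
        return f"{self.dose_per_kg:g} mg/kg {iv}"


def typical_clearance(
    params: PKParameters, weight, albumin, ufr
) -> np.ndarray | float:
    """Typical-value clearance (L/h) at eta = 0; accepts scalars or arrays."""
    return (
        params.cl_pop
        * (np.asarray(weight) / params.wt_ref) ** 0.75
        * (params.alb_ref / np.asarray(albumin)) ** params.alpha
        + np.asarray(ufr) * params.beta
    )


def individual_parameters(
    params: PKParameters, cov: PatientCovariates, eta_cl: float = 0.0
) -> IndividualParameters:
    """Individual PK parameters from population values, covariates and eta.

    The random effect multiplies the whole clearance expression (covariate
    terms included); volumes and intercompartmental clearance carry no
    random effect.
    """
    cl_typ = typical_clearance(params, cov.weight, cov.albumin, cov.ufr)
    if not cl_typ > 0:
        raise ValueError("typical clearance is nonpositive under these covariates")
    return IndividualParameters(
        cl=float(cl_typ * np.exp(eta_cl)),
        vc=params.vc_pop * (cov.weight / params.wt_ref),
        vp=params.vp_pop,
        q=params.q_pop,
    )


def _disposition(cl, vc, vp, q):
    """Macro rate constants and central-compartment coefficients.

    Roots of  lam^2 - (k10+k12+k21) lam + k10 k21 = 0.  A relative floor on
    the discriminant keeps the roots separated when they would coincide
    (documented perturbation instead of a division by zero).
    Broadcasts over array-valued ``cl``.
    """
    cl = np.asarray(cl, dtype=float)
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.maximum(s * s - 4.0 * k10 * k21, _DISC_FLOOR * s * s)
    root = np.sqrt(disc)
    lam1 = 0.5 * (s + root)
    lam2 = 0.5 * (s - root)
    c1 = (lam1 - k21) / (lam1 - lam2)
    c2 = (k21 - lam2) / (lam1 - lam2)
    return lam1, lam2, c1, c2


def _profile_matrix(
    cl,
    vc: float,
    vp: float | None,
    q: float | None,
    dose_t: np.ndarray,
    dose_rate: np.ndarray,
    dose_dur: np.ndarray,
    times: np.ndarray,
    n_compartments: int = 2,
) -> np.ndarray:
    """Central concentrations, vectorized over a batch of clearances.

    Returns shape (len(cl), len(times)).  Superposition over dose events of
    the closed-form zero-order-infusion solution; the response of one
    exponential mode lam with coefficient c is

        (R / (Vc lam)) * c * (1 - e^{-lam * min(tau, T)}) * e^{-lam * max(tau - T, 0)}

    which is continuous at the end of infusion tau = T and zero for tau <= 0.
    """
    cl = np.atleast_1d(np.asarray(cl, dtype=float))
    times = np.asarray(times, dtype=float)
    m = cl.shape[0]
    tau = times[None, :] - dose_t[:, None]          # (d, t)
    active = tau > 0.0
    tau = np.where(active, tau, 0.0)
    dur = dose_dur[:, None]
    up = np.minimum(tau, dur)                        # time infusing
    down = np.maximum(tau - dur, 0.0)                # time since infusion end

    out = np.zeros((m, times.shape[0]))
    if n_compartments == 1:
        lam = (cl / vc)[:, None, None]               # (m,1,1)
        contrib = (1.0 - np.exp(-lam * up)) * np.exp(-lam * down) / (vc * lam)
        out = np.sum(contrib * (dose_rate[:, None] * active), axis=1)
    else:
        lam1, lam2, c1, c2 = _disposition(cl, vc, vp, q)
        for lam, c in ((lam1, c1), (lam2, c2)):
            lamb = lam[:, None, None]
            cb = c[:, None, None]
            contrib = (
                cb * (1.0 - np.exp(-lamb * up)) * np.exp(-lamb * down) / (vc * lamb)
            )
            out = out + np.sum(contrib * (dose_rate[:, None] * active), axis=1)
    return out


def concentration_profile(
    ind: IndividualParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    n_compartments: int = 2,
) -> np.ndarray:
    """Central-compartment concentration (mg/L) at the requested times.

    Superposition over dose events of the closed-form two-compartment
    zero-order-infusion solution (micro constants k10 = CL/Vc, k12 = Q/Vc,
    k21 = Q/Vp).  Times strictly before the first infusion return 0.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    dose_t = np.array([d.time for d in doses], dtype=float)
    dose_rate = np.array([d.rate for d in doses], dtype=float)
    dose_dur = np.array([d.duration for d in doses], dtype=float)
    if dose_t.size == 0:
        return np.zeros_like(times)
    return _profile_matrix(
        ind.cl, ind.vc, ind.vp, ind.q, dose_t, dose_rate, dose_dur, times,
        n_compartments=n_compartments,
    )[0]


def steady_state_auc24(
    ind: IndividualParameters, regimen: Regimen, weight: float
) -> float:
    """Steady-state 24-h AUC (mg.h/L): daily dose divided by clearance.

    Exact for linear PK; with MIC fixed at 1 mg/L this equals AUC24/MIC.
    Requires the dosing interval to divide 24 h evenly.
    """
    if not weight > 0:
        raise ValueError("weight must be > 0")
    n_per_day = 24.0 / regimen.interval
    if abs(n_per_day - round(n_per_day)) > 1e-9:
        raise ValueError("regimen interval must divide 24 h evenly")
    return n_per_day * regimen.dose_per_kg * weight / ind.cl
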