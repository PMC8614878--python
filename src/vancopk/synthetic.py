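"""Virtual CVVH study generator.

Emulates the sampling design of the source trial: ~11 critically ill adults
on continuous venovenous hemofiltration receiving 0.5 g vancomycin infusions
(qd, q12h or q8h; 1-h infusions), with blood samples at baseline and 0.5, 1,
2, 4, 6, 8, 10 and 12 h after the first dose, and the same schedule repeated
on day 3 while dosing continues.  Covariates are drawn from truncated
distributions whose medians and ranges follow the observed cohort:

* weight — log-normal, median 70 kg, log-SD 0.24 (from the observed IQR of
  22.5 kg), truncated to [52, 90] kg;
* albumin — normal, location 28.6 g/L, SD 3.8 (IQR 5.1), truncated to
  [26, 39] g/L;
* ultrafiltration rate — normal, location 33.3, SD 4.8 (IQR 6.5), truncated
  to [18, 39] mL/kg/h.

The day-1 baseline sample is pre-dose (zero concentration); the day-3
baseline is a trough under continued dosing.  An optional per-sample dropout
probability emulates the missingness implied by 131 observations from a
nominal 11 x 18 schedule.  CVVH circuit downtime and within-subject
covariate drift are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import Observation, PopulationDataset, SubjectRecord
from .model import DoseEvent, PatientCovariates, PKParameters
from .model import _profile_matrix

__all__ = ["StudyDesign", "generate_covariates", "generate_study", "apply_residual_error"]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of one virtual study."""

    n_subjects: int = 11
    sampling_times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    repeat_day: int = 3
    #: (dose mg, interval h, infusion duration h) options assigned per subject
    regimen_pool: tuple[tuple[float, float, float], ...] = (
        (500.0, 24.0, 1.0),
        (500.0, 12.0, 1.0),
        (500.0, 8.0, 1.0),
    )
    missingness: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        t = np.asarray(self.sampling_times)
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValueError("sampling_times must be sorted and nonnegative")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")


_WT_MEDIAN, _WT_LOGSD, _WT_LO, _WT_HI = 70.0, 0.24, 52.0, 90.0
_ALB_LOC, _ALB_SD, _ALB_LO, _ALB_HI = 28.6, 3.8, 26.0, 39.0
_UFR_LOC, _UFR_SD, _UFR_LO, _UFR_HI = 33.3, 4.8, 18.0, 39.0


def _truncnorm(rng: np.random.Generator, loc, sd, lo, hi, n: int) -> np.ndarray:
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def generate_covariates(n: int, seed=None) -> list[PatientCovariates]:
    """Draw n covariate sets from the documented truncated distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    logwt = _truncnorm(
        rng, np.log(_WT_MEDIAN), _WT_LOGSD, np.log(_WT_LO), np.log(_WT_HI), n
    )
    wt = np.exp(logwt)
    alb = _truncnorm(rng, _ALB_LOC, _ALB_SD, _ALB_LO, _ALB_HI, n)
    ufr = _truncnorm(rng, _UFR_LOC, _UFR_SD, _UFR_LO, _UFR_HI, n)
    return [
        PatientCovariates(weight=float(w), albumin=float(a), ufr=float(u))
        for w, a, u in zip(wt, alb, ufr)
    ]


def apply_residual_error(
    rng: np.random.Generator,
    conc: np.ndarray,
    error_model: str,
    sigma2: float,
    sigma2_add: float = 0.0,
) -> np.ndarray:
    """Perturb true concentrations by the configured residual model,
    truncating at zero (concentrations cannot be negative)."""
    conc = np.asarray(conc, dtype=float)
    if error_model == "additive":
        out = conc + rng.normal(0.0, np.sqrt(sigma2), conc.shape)
    elif error_model == "proportional":
        out = conc * (1.0 + rng.normal(0.0, np.sqrt(sigma2), conc.shape))
    elif error_model == "combined":
        out = conc * (1.0 + rng.normal(0.0, np.sqrt(sigma2), conc.shape))
        out = out + rng.normal(0.0, np.sqrt(sigma2_add), conc.shape)
    elif error_model == "exponential":
        out = conc * np.exp(rng.normal(0.0, np.sqrt(sigma2), conc.shape))
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return np.maximum(out, 0.0)


def generate_study(
    design: StudyDesign,
    params: PKParameters,
    seed=None,
) -> PopulationDataset:
    """Simulate one study: covariates, regimen assignment, eta draws, the
    true two-compartment profiles and residual-perturbed observations.

    Observation times are hours since the subject's first dose; the day-1
    baseline (time 0) is pre-dose and reported as 0 mg/L.  Reproducible
    given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covs = generate_covariates(design.n_subjects, rng)
    offsets = np.asarray(design.sampling_times, dtype=float)
    day3_start = 24.0 * (design.repeat_day - 1)
    subjects = []
    for i, cov in enumerate(covs):
        amt, interval, dur = design.regimen_pool[
            rng.integers(0, len(design.regimen_pool))
        ]
        eta = rng.normal(0.0, np.sqrt(params.omega2_cl)) if params.omega2_cl > 0 else 0.0
        sample_times = np.concatenate([offsets, day3_start + offsets])
        last = sample_times[-1]
        dose_times = np.arange(0.0, last + 1e-9, interval)
        doses = tuple(DoseEvent(float(t), amt, dur) for t in dose_times)

        cl_typ = (
            params.cl_pop
            * (cov.weight / params.wt_ref) ** 0.75
            * (params.alb_ref / cov.albumin) ** params.alpha
            + cov.ufr * params.beta
        )
        true = _profile_matrix(
            cl_typ * np.exp(eta),
            params.vc_pop * cov.weight / params.wt_ref,
            params.vp_pop,
            params.q_pop,
            np.array([d.time for d in doses]),
            np.array([d.rate for d in doses]),
            np.array([d.duration for d in doses]),
            sample_times,
        )[0]
        obs_conc = apply_residual_error(
            rng, true, params.error_model, params.sigma2, params.sigma2_add
        )
        obs_conc[sample_times <= 0.0] = 0.0  # pre-dose baseline
        keep = np.ones(sample_times.shape, dtype=bool)
        if design.missingness > 0:
            keep = rng.random(sample_times.shape) >= design.missingness
            keep[0] = True  # never drop the whole record's anchor sample
        observations = tuple(
            Observation(float(t), float(c))
            for t, c, k in zip(sample_times, obs_conc, keep)
            if k
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                covariates=cov,
                doses=doses,
                observations=observations,
            )
        )
    return PopulationDataset(tuple(subjects))
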