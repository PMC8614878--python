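"""Final-model evaluation: nonparametric bootstrap and numerical predictive check.

The bootstrap resamples subjects with replacement (same number of subjects),
refits each replicate starting from the final estimates, and summarizes the
successful replicates by median and 2.5th-97.5th percentile CI per parameter.

The numerical predictive check (NPC) simulates replicate datasets under the
fitted model (same design and covariates, fresh eta and epsilon draws) and,
for each observation and prediction-interval level L, forms the
((100-L)/2, (100+L)/2) percentile band of that observation's simulated
values (level 0 is the median split).  It then counts real observations
below/above their bands; the 95% CI for each count is the 2.5th-97.5th
percentile of the same count computed replicate-wise, treating each
simulated dataset as pseudo-observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ModelSpec, PopulationDataset, SubjectRecord
from . import estimation
from .estimation import FitResult, _make_works, _predict
from .synthetic import apply_residual_error

__all__ = ["BootstrapResult", "NPCResult", "bootstrap", "npc", "DEFAULT_PI_LEVELS"]

DEFAULT_PI_LEVELS = (0, 20, 40, 50, 60, 80, 90, 95)


@dataclass
class BootstrapResult:
    """Per-parameter median and 95% percentile CI over converged replicates."""

    median: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    n_requested: int
    n_converged: int
    estimates: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Summary table mirroring the usual estimate/median/95% CI layout."""
        rows = [
            {
                "parameter": k,
                "median": self.median[k],
                "ci95_lower": self.ci_lower[k],
                "ci95_upper": self.ci_upper[k],
            }
            for k in self.median
        ]
        return pd.DataFrame(rows)


def bootstrap(
    dataset: PopulationDataset,
    spec: ModelSpec,
    init,
    b: int = 2000,
    seed=None,
    **fit_kwargs,
) -> BootstrapResult:
    """Nonparametric (subject-resampling) bootstrap of the population fit.

    Each of ``b`` replicate datasets draws n_subjects subjects with
    replacement and is refitted from ``init`` (typically the final-model
    estimates, which speeds convergence).  Non-converged replicates are
    excluded and counted.  Reproducible given ``seed``.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    fit_kwargs.setdefault("compute_rse", False)
    rng = np.random.default_rng(seed)
    subjects = dataset.subjects
    n = len(subjects)
    rows = []
    n_converged = 0
    for rep in range(b):
        idx = rng.integers(0, n, n)
        resampled = tuple(
            SubjectRecord(
                subject_id=f"bs{rep}_{k}",
                covariates=subjects[i].covariates,
                doses=subjects[i].doses,
                observations=subjects[i].observations,
            )
            for k, i in enumerate(idx)
        )
        try:
            res = estimation.fit(
                PopulationDataset(resampled), init=init, spec=spec, **fit_kwargs
            )
        except Exception as exc:  # noqa: BLE001 - replicate failure is counted
            warnings.warn(f"bootstrap replicate {rep} failed: {exc}")
            continue
        if not np.isfinite(res.ofv):
            continue
        n_converged += 1
        rows.append(dict(res.estimates, _converged=res.converged))
    if not rows:
        raise RuntimeError("all bootstrap replicates failed to fit")
    frame = pd.DataFrame(rows)
    params = [c for c in frame.columns if c != "_converged"]
    med = {p: float(frame[p].median()) for p in params}
    lo = {p: float(frame[p].quantile(0.025)) for p in params}
    hi = {p: float(frame[p].quantile(0.975)) for p in params}
    return BootstrapResult(
        median=med,
        ci_lower=lo,
        ci_upper=hi,
        n_requested=b,
        n_converged=n_converged,
        estimates=frame,
    )


@dataclass
class NPCResult:
    """NPC counts per prediction-interval level."""

    table: pd.DataFrame
    n_obs: int
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def npc(
    dataset: PopulationDataset,
    fit_result: FitResult,
    spec: ModelSpec | None = None,
    n_sim: int = 1000,
    levels=DEFAULT_PI_LEVELS,
    seed=None,
) -> NPCResult:
    """Numerical predictive check of a fitted model against its dataset.

    Simulates ``n_sim`` replicates of the study under the fitted parameters
    (same subjects, doses and sampling times; new random effects and residual
    errors) and counts observations below/above the per-observation
    prediction-interval bands at each level.
    """
    spec = spec or fit_result.spec
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives unstable prediction-interval percentiles")
    d = fit_result.estimates
    omega2 = d["omega2_cl"]
    sigma2 = d["sigma2"]
    sigma2_add = d.get("sigma2_add", 0.0)
    rng = np.random.default_rng(seed)
    works = [w for w in _make_works(dataset, spec) if w.n_obs > 0]

    obs = np.concatenate([w.y for w in works])
    sims = []
    for w in works:
        etas = rng.normal(0.0, np.sqrt(omega2), n_sim) if omega2 > 0 else np.zeros(n_sim)
        f = _predict(w, d, spec, etas)  # (n_sim, n_obs)
        if f is None:
            raise RuntimeError("invalid parameters in NPC simulation")
        sims.append(
            apply_residual_error(rng, f, spec.error_model, sigma2, sigma2_add)
        )
    sim = np.concatenate(sims, axis=1)  # (n_sim, n_obs_total)
    n_obs = obs.shape[0]

    rows = []
    for level in levels:
        lo_q = (100.0 - level) / 2.0
        hi_q = (100.0 + level) / 2.0
        lo = np.percentile(sim, lo_q, axis=0)
        hi = np.percentile(sim, hi_q, axis=0)
        below = int(np.sum(obs < lo))
        above = int(np.sum(obs > hi))
        # replicate-wise counts: each simulated dataset as pseudo-observed
        below_rep = np.sum(sim < lo[None, :], axis=1)
        above_rep = np.sum(sim > hi[None, :], axis=1)
        b_lo, b_hi = np.percentile(below_rep, [2.5, 97.5])
        a_lo, a_hi = np.percentile(above_rep, [2.5, 97.5])
        rows.append(
            {
                "pi_level": level,
                "below_count": below,
                "below_pct": 100.0 * below / n_obs,
                "below_ci_lower_pct": 100.0 * b_lo / n_obs,
                "below_ci_upper_pct": 100.0 * b_hi / n_obs,
                "above_count": above,
                "above_pct": 100.0 * above / n_obs,
                "above_ci_lower_pct": 100.0 * a_lo / n_obs,
                "above_ci_upper_pct": 100.0 * a_hi / n_obs,
            }
        )
    return NPCResult(table=pd.DataFrame(rows), n_obs=n_obs, n_sim=n_sim)
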