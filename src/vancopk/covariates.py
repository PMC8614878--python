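"""Covariate pre-screening and stepwise selection on the OFV.

Screening is advisory: pairwise association tests among candidate covariates
(Pearson when both columns pass a Shapiro-Wilk normality test, Kendall's tau
otherwise; two-sample t-test for discrete-vs-continuous pairs) flag
correlated pairs for the analyst.  Which member of a correlated pair to keep
is a configuration choice, not an algorithm.

Stepwise selection uses the likelihood-ratio heuristic on the FOCE-I
objective: forward inclusion admits, one at a time, the candidate with the
largest OFV drop provided the drop strictly exceeds 3.84 (chi-square(1),
p < 0.05); backward elimination then removes any included covariate whose
removal raises the OFV by 10.83 or less (retention requires > 10.83,
p < 0.001).  A retained covariate whose effect-parameter 95% CI includes
zero is also removed.  Allometric weight scaling is part of the base model
and never tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CovariateTerm, ModelSpec, PopulationDataset
from . import estimation

__all__ = [
    "CovariateCandidate",
    "StepwiseStep",
    "StepwiseTrace",
    "covariate_table",
    "screen_covariates",
    "stepwise_select",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
]

FORWARD_THRESHOLD = 3.84   # chi-square(1) at p = 0.05
BACKWARD_THRESHOLD = 10.83  # chi-square(1) at p = 0.001


@dataclass(frozen=True)
class CovariateCandidate:
    """A candidate covariate effect on clearance.

    ``relation`` is one of ``power`` ((x/ref)^theta), ``inverse-power``
    ((ref/x)^theta, the albumin form) or ``additive`` (theta * x, the
    ultrafiltration-rate form).  ``reference`` normalizes continuous
    covariates (population mean or a published reference value).
    """

    name: str
    relation: str
    reference: float = 1.0

    def term(self) -> CovariateTerm:
        return CovariateTerm(self.name, self.relation, self.reference)


@dataclass(frozen=True)
class StepwiseStep:
    phase: str          # "forward" | "backward" | "ci-check"
    candidate: str
    delta_ofv: float
    threshold: float
    decision: str       # "include" | "exclude" | "retain" | "remove" | "skip"
    ofv: float = float("nan")


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def covariate_table(dataset: PopulationDataset, extra: Sequence[str] = ()) -> pd.DataFrame:
    """One row per subject with weight/albumin/ufr plus named extras."""
    rows = []
    for s in dataset.subjects:
        row = {
            "subject_id": s.subject_id,
            "weight": s.covariates.weight,
            "albumin": s.covariates.albumin,
            "ufr": s.covariates.ufr,
        }
        for name in extra:
            row[name] = s.covariates.value(name)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def _is_discrete(col: pd.Series) -> bool:
    return col.nunique() <= 2


def screen_covariates(
    table: pd.DataFrame,
    discrete: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise association screen over the columns of ``table``.

    Continuous pairs: Shapiro-Wilk decides normality per column; Pearson if
    both normal, Kendall's tau otherwise.  Discrete-vs-continuous pairs: a
    two-sample t-test of the continuous variable across the two levels.
    Returns one row per pair with the method, coefficient, p-value and a
    ``flagged`` column (p < alpha).  Constant columns yield an undefined
    coefficient with a note instead of a number.
    """
    if len(table) < 3:
        raise ValueError("screening needs at least 3 subjects")
    cols = list(table.columns)
    if discrete is None:
        discrete = [c for c in cols if _is_discrete(table[c])]
    discrete = set(discrete)
    normal: dict[str, bool] = {}
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        if c in discrete or np.ptp(x) == 0:
            normal[c] = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal[c] = stats.shapiro(x).pvalue > alpha
    rows = []
    for a, b in combinations(cols, 2):
        xa = table[a].to_numpy(dtype=float)
        xb = table[b].to_numpy(dtype=float)
        note = ""
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            method, coef, p = "undefined", float("nan"), float("nan")
            note = "constant column"
        elif (a in discrete) != (b in discrete):
            d, c = (a, b) if a in discrete else (b, a)
            levels = np.unique(table[d])
            groups = [
                table.loc[table[d] == lev, c].to_numpy(dtype=float) for lev in levels
            ]
            method = "t-test"
            res = stats.ttest_ind(*groups)
            coef, p = float(res.statistic), float(res.pvalue)
        elif a in discrete and b in discrete:
            method = "kendall"
            res = stats.kendalltau(xa, xb)
            coef, p = float(res.statistic), float(res.pvalue)
        elif normal[a] and normal[b]:
            method = "pearson"
            res = stats.pearsonr(xa, xb)
            coef, p = float(res.statistic), float(res.pvalue)
        else:
            method = "kendall"
            res = stats.kendalltau(xa, xb)
            coef, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "var1": a,
                "var2": b,
                "method": method,
                "normal1": normal.get(a, False),
                "normal2": normal.get(b, False),
                "coefficient": coef,
                "p_value": p,
                "flagged": bool(p < alpha) if math.isfinite(p) else False,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def _default_fit(dataset, spec, init, **kwargs):
    return estimation.fit(dataset, init=init, spec=spec, **kwargs)


def stepwise_select(
    dataset: PopulationDataset,
    base_spec: ModelSpec,
    candidates: Sequence[CovariateCandidate],
    init=None,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    ci_criterion: bool = True,
    fit_func: Callable | None = None,
    **fit_kwargs,
) -> tuple[ModelSpec, StepwiseTrace]:
    """Forward-inclusion / backward-elimination covariate selection.

    Forward phase: at each step every remaining candidate is added to the
    current model and refitted; the candidate with the largest OFV drop is
    included if the drop strictly exceeds ``forward_threshold`` (exact ties
    broken by candidate list order).  Backward phase: each included
    covariate is removed in turn and retained only if its removal raises the
    OFV by more than ``backward_threshold``.  Finally (``ci_criterion``), a
    covariate whose effect-parameter 95% CI (estimate +/- 1.96 SE) includes
    zero is removed.  Candidate fits that fail to converge are skipped for
    that step and recorded in the trace.

    Returns the selected ModelSpec and the full decision trace; each later
    fit starts from the previous accepted fit's estimates.
    """
    do_fit = fit_func or _default_fit
    trace = StepwiseTrace()
    base_fit = do_fit(dataset, base_spec, init, **fit_kwargs)
    if not base_fit.converged:
        warnings.warn("base model fit did not converge; proceeding with its OFV")
    current_spec = base_spec
    current_fit = base_fit
    remaining = list(candidates)
    included: list[CovariateCandidate] = []

    # ---- forward inclusion
    while remaining:
        results = []
        for cand in remaining:
            spec_c = current_spec.with_term(cand.term())
            init_c = dict(current_fit.estimates)
            init_c[cand.term().param_name] = 0.0
            try:
                fit_c = do_fit(dataset, spec_c, init_c, **fit_kwargs)
            except Exception as exc:  # noqa: BLE001 - candidate failure is data
                trace.steps.append(
                    StepwiseStep("forward", cand.name, float("nan"),
                                 forward_threshold, "skip"))
                warnings.warn(f"candidate {cand.name} failed: {exc}")
                continue
            if not fit_c.converged and not np.isfinite(fit_c.ofv):
                trace.steps.append(
                    StepwiseStep("forward", cand.name, float("nan"),
                                 forward_threshold, "skip"))
                continue
            results.append((cand, fit_c, current_fit.ofv - fit_c.ofv))
        if not results:
            break
        best_cand, best_fit, best_drop = max(
            results, key=lambda r: (r[2], -list(remaining).index(r[0]))
        )
        for cand, _, drop in results:
            if cand is not best_cand:
                trace.steps.append(
                    StepwiseStep("forward", cand.name, -drop, forward_threshold,
                                 "exclude", float("nan")))
        if best_drop > forward_threshold:
            trace.steps.append(
                StepwiseStep("forward", best_cand.name, -best_drop,
                             forward_threshold, "include", best_fit.ofv))
            included.append(best_cand)
            remaining.remove(best_cand)
            current_spec = current_spec.with_term(best_cand.term())
            current_fit = best_fit
        else:
            trace.steps.append(
                StepwiseStep("forward", best_cand.name, -best_drop,
                             forward_threshold, "exclude", float("nan")))
            break

    # ---- backward elimination
    changed = True
    while changed and included:
        changed = False
        for cand in list(included):
            spec_r = current_spec.without_term(cand.term())
            init_r = {
                k: v for k, v in current_fit.estimates.items()
                if k != cand.term().param_name
            }
            fit_r = do_fit(dataset, spec_r, init_r, **fit_kwargs)
            rise = fit_r.ofv - current_fit.ofv
            if rise > backward_threshold:
                trace.steps.append(
                    StepwiseStep("backward", cand.name, rise, backward_threshold,
                                 "retain", current_fit.ofv))
            else:
                trace.steps.append(
                    StepwiseStep("backward", cand.name, rise, backward_threshold,
                                 "remove", fit_r.ofv))
                included.remove(cand)
                current_spec = spec_r
                current_fit = fit_r
                changed = True

    # ---- effect-parameter 95% CI must exclude zero
    if ci_criterion and included:
        rse = current_fit.rse
        for cand in list(included):
            pname = cand.term().param_name
            est = current_fit.estimates[pname]
            if rse is None or not math.isfinite(rse.get(pname, float("nan"))):
                warnings.warn(
                    f"no standard error for {pname}; CI criterion not applied")
                continue
            se = abs(est) * rse[pname] / 100.0
            lo, hi = est - 1.96 * se, est + 1.96 * se
            if lo <= 0.0 <= hi:
                spec_r = current_spec.without_term(cand.term())
                init_r = {
                    k: v for k, v in current_fit.estimates.items() if k != pname
                }
                current_fit = do_fit(dataset, spec_r, init_r, **fit_kwargs)
                current_spec = spec_r
                included.remove(cand)
                trace.steps.append(
                    StepwiseStep("ci-check", cand.name, float("nan"), 0.0,
                                 "remove", current_fit.ofv))
            else:
                trace.steps.append(
                    StepwiseStep("ci-check", cand.name, float("nan"), 0.0,
                                 "retain", current_fit.ofv))

    return current_spec, trace
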