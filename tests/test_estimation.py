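"""FOCE-I engine: conditional modes, objective function, fitting, diagnostics."""

import dataclasses

import numpy as np
import pytest

import vancopk as v
from vancopk.data import (
    FINAL_MODEL_SPEC,
    ModelSpec,
    Observation,
    PopulationDataset,
    SubjectRecord,
    params_to_dict,
)
from vancopk.estimation import (
    FOCEI,
    FitResult,
    _data_neg2ll,
    _joint_neg2,
    _make_works,
    conditional_eta,
    diagnostics_table,
)
from vancopk.model import DoseEvent, PatientCovariates, _profile_matrix

from conftest import ONECPT_INIT, ONECPT_SPEC, make_onecpt_dataset


def make_subject(params, cov, eta, times, doses, subject_id="X", noise=None):
    """Noise-free (or perturbed) subject simulated at a known eta."""
    cl_typ = (
        params.cl_pop
        * (cov.weight / 70.0) ** 0.75
        * (29.0 / cov.albumin) ** params.alpha
        + cov.ufr * params.beta
    )
    times = np.asarray(times, dtype=float)
    f = _profile_matrix(
        cl_typ * np.exp(eta),
        params.vc_pop * cov.weight / 70.0,
        params.vp_pop,
        params.q_pop,
        np.array([d.time for d in doses]),
        np.array([d.rate for d in doses]),
        np.array([d.duration for d in doses]),
        times,
    )[0]
    if noise is not None:
        f = f * (1.0 + noise)
    return SubjectRecord(
        subject_id, cov, tuple(doses),
        tuple(Observation(float(t), float(c)) for t, c in zip(times, f)),
    )


TIMES = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
DOSES = (DoseEvent(0.0, 500.0, 1.0),)
COV = PatientCovariates(70.0, 29.0, 30.0)


class TestConditionalEta:
    def test_shrinks_to_zero_as_omega_vanishes(self, published_params):
        subj = make_subject(published_params, COV, 0.4, TIMES, DOSES)
        p = dataclasses.replace(published_params, omega2_cl=1e-12)
        assert abs(conditional_eta(subj, p)) < 1e-4

    def test_recovers_known_eta_from_noise_free_data(self, published_params):
        subj = make_subject(published_params, COV, 0.3, TIMES, DOSES)
        p = dataclasses.replace(published_params, sigma2=1e-8, omega2_cl=4.0)
        assert conditional_eta(subj, p) == pytest.approx(0.3, abs=1e-3)

    def test_matches_exhaustive_grid_search(self, published_params):
        rng = np.random.default_rng(8)
        subj = make_subject(
            published_params, COV, 0.25, TIMES, DOSES,
            noise=rng.normal(0.0, 0.2, len(TIMES)),
        )
        d = params_to_dict(published_params, FINAL_MODEL_SPEC)
        work = _make_works(PopulationDataset((subj,)), FINAL_MODEL_SPEC)[0]
        grid = np.arange(-3.0, 3.0, 1e-4)
        vals = _joint_neg2(work, d, FINAL_MODEL_SPEC, grid)
        brute = grid[np.argmin(vals)]
        assert conditional_eta(subj, published_params) == pytest.approx(
            brute, abs=1e-4
        )


def agq_neg2ll(dataset, params, spec, nodes=61):
    """Oracle: exact marginal -2 log-likelihood by adaptive Gauss-Hermite
    quadrature centered at each subject's conditional mode."""
    from numpy.polynomial.hermite import hermgauss
    from vancopk.estimation import _eta_mode

    d = params_to_dict(params, spec) if isinstance(params, v.PKParameters) else params
    x, w = hermgauss(nodes)
    total = 0.0
    for work in _make_works(dataset, spec):
        lfun = lambda e: _joint_neg2(work, d, spec, e)
        mode = _eta_mode(lfun, 0.0)
        h = 1e-3
        lm, l0, lp = lfun(np.array([mode - h, mode, mode + h]))
        curv = max((lp - 2 * l0 + lm) / h**2, 1e-6)
        sig = np.sqrt(2.0 / curv)
        etas = mode + np.sqrt(2.0) * sig * x
        lv = lfun(etas)
        logterms = np.log(w) + x**2 + 0.5 * np.log(2.0) + np.log(sig) - lv / 2.0
        m = logterms.max()
        total += -2.0 * (m + np.log(np.sum(np.exp(logterms - m))))
    return total


class TestOFV:
    def test_degenerate_omega_equals_fixed_effects_likelihood(self, small_study,
                                                              published_params):
        spec = FINAL_MODEL_SPEC
        d = params_to_dict(published_params, spec)
        d["omega2_cl"] = 0.0
        closed = sum(
            float(_data_neg2ll(w, d, spec, np.zeros(1))[0])
            for w in _make_works(small_study, spec)
        )
        assert v.ofv(small_study, d, spec) == pytest.approx(closed, rel=1e-12)

    @pytest.mark.parametrize("error_model", ["proportional", "additive",
                                             "exponential", "combined"])
    def test_matches_gauss_hermite_quadrature(self, published_params, error_model):
        p = dataclasses.replace(
            published_params,
            error_model=error_model,
            sigma2={"proportional": 0.05, "additive": 1.0,
                    "exponential": 0.05, "combined": 0.03}[error_model],
            sigma2_add=0.5 if error_model == "combined" else 0.0,
        )
        spec = ModelSpec(2, error_model, FINAL_MODEL_SPEC.covariate_terms)
        ds = v.generate_study(
            v.StudyDesign(n_subjects=2, regimen_pool=((500.0, 12.0, 1.0),)),
            p, seed=11,
        )
        exact = agq_neg2ll(ds, p, spec)
        approx = v.ofv(ds, p, spec)
        assert approx == pytest.approx(exact, rel=5e-3)

    def test_additive_over_subjects(self, small_study, published_params):
        one = PopulationDataset((small_study.subjects[0],))
        dup = PopulationDataset(
            (
                small_study.subjects[0],
                dataclasses.replace(small_study.subjects[1], subject_id="dup"),
                small_study.subjects[1],
            )
        )
        two = PopulationDataset(small_study.subjects[:2])
        contribution = v.ofv(dup, published_params) - v.ofv(two, published_params)
        second = v.ofv(two, published_params) - v.ofv(one, published_params)
        assert contribution == pytest.approx(second, abs=1e-6)

    def test_invalid_parameters_rejected(self, small_study, published_params):
        d = params_to_dict(published_params, FINAL_MODEL_SPEC)
        del d["sigma2"]
        with pytest.raises(ValueError):
            v.ofv(small_study, d, FINAL_MODEL_SPEC)


class TestFit:
    def test_noise_free_single_subject_recovers_fixed_effects(self, published_params):
        subj = make_subject(
            published_params, COV, 0.0,
            (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0),
            (DoseEvent(0.0, 500.0, 1.0), DoseEvent(12.0, 500.0, 1.0)),
        )
        ds = PopulationDataset((subj,))
        init = {"cl_pop": 2.0, "vc_pop": 12.0, "vp_pop": 20.0, "q_pop": 5.0,
                "omega2_cl": 0.0, "sigma2": 1e-4}
        spec = ModelSpec(n_compartments=2, error_model="additive")
        res = v.fit(ds, init=init, spec=spec,
                    fixed={"omega2_cl": 0.0, "sigma2": 1e-4},
                    compute_rse=False, tol=1e-10)
        ind_truth = v.individual_parameters(published_params, COV)
        assert res.estimates["cl_pop"] * (70 / 70) ** 0.75 == pytest.approx(
            ind_truth.cl, rel=1e-3
        )
        assert res.estimates["vc_pop"] == pytest.approx(ind_truth.vc, rel=1e-3)
        assert res.estimates["vp_pop"] == pytest.approx(ind_truth.vp, rel=1e-2)
        assert res.estimates["q_pop"] == pytest.approx(ind_truth.q, rel=1e-2)

    def test_reproducible_bit_for_bit(self, onecpt_dataset):
        a = v.fit(onecpt_dataset, init=dict(ONECPT_INIT), spec=ONECPT_SPEC,
                  compute_rse=False)
        b = v.fit(onecpt_dataset, init=dict(ONECPT_INIT), spec=ONECPT_SPEC,
                  compute_rse=False)
        assert a.estimates == b.estimates
        assert a.ofv == b.ofv

    def test_aic_consistent_with_ofv(self, onecpt_fit):
        assert onecpt_fit.aic == pytest.approx(
            onecpt_fit.ofv + 2 * onecpt_fit.n_params
        )
        assert onecpt_fit.n_params == 4

    def test_aic_prefers_true_compartment_count(self):
        """Data simulated from a one-compartment model: the 1-cpt fit should
        win on AIC in most replicates (2-cpt adds two unsupported params)."""
        wins = 0
        for seed in (101, 202, 303):
            ds = make_onecpt_dataset(seed=seed, n_subjects=16, sigma2=0.16)
            one = v.fit(ds, init=dict(ONECPT_INIT), spec=ONECPT_SPEC,
                        compute_rse=False, tol=1e-4, max_fev=600)
            init2 = dict(ONECPT_INIT, vp_pop=20.0, q_pop=2.0)
            two = v.fit(ds, init=init2,
                        spec=ModelSpec(n_compartments=2, error_model="additive"),
                        compute_rse=False, tol=1e-4, max_fev=800)
            wins += one.aic < two.aic
        assert wins >= 2

    def test_estimator_class_interface(self, onecpt_dataset):
        est = FOCEI(spec=ONECPT_SPEC, init=dict(ONECPT_INIT), compute_rse=False)
        assert est.get_params()["spec"] is ONECPT_SPEC
        est.set_params(tol=1e-5)
        assert est.tol == 1e-5
        est.fit(onecpt_dataset)
        assert est.converged_
        assert est.ofv_ == est.result_.ofv
        assert set(est.etas_) == {s.subject_id for s in onecpt_dataset.subjects}
        table = est.predict(onecpt_dataset)
        assert {"pred", "ipred", "cwres"} <= set(table.columns)
        with pytest.raises(ValueError):
            est.set_params(bogus=1)


class TestStandardErrors:
    def test_rse_positive_and_finite_on_regular_problem(self, onecpt_dataset,
                                                        onecpt_fit):
        rse = v.standard_errors(onecpt_dataset, onecpt_fit)
        assert set(rse) == {"cl_pop", "vc_pop", "omega2_cl", "sigma2"}
        assert all(np.isfinite(x) and x > 0 for x in rse.values())

    def test_se_scales_inversely_with_sqrt_n(self):
        """Quadrupling the number of subjects should roughly halve the SE of
        the population clearance."""
        small = make_onecpt_dataset(seed=21, n_subjects=10)
        large = make_onecpt_dataset(seed=21, n_subjects=40)
        fits = {}
        for name, ds in (("small", small), ("large", large)):
            res = v.fit(ds, init=dict(ONECPT_INIT), spec=ONECPT_SPEC,
                        compute_rse=True, tol=1e-5)
            fits[name] = res.rse["cl_pop"] * res.estimates["cl_pop"] / 100.0
        ratio = fits["small"] / fits["large"]
        assert 1.3 < ratio < 3.0


class TestDiagnostics:
    def _truth_fit_result(self, dataset, params, spec):
        d = params_to_dict(params, spec)
        etas = {
            s.subject_id: conditional_eta(s, params, spec) for s in dataset.subjects
        }
        return FitResult(
            estimates=d, params=params, ofv=v.ofv(dataset, d, spec),
            aic=float("nan"), rse=None, etas=etas, converged=True,
            n_obs=dataset.n_observations, n_subjects=dataset.n_subjects,
            n_params=len(d), n_excluded_obs=0, spec=spec,
        )

    def test_noise_free_data_has_null_residuals(self, published_params):
        subj = make_subject(published_params, COV, 0.0, TIMES, DOSES)
        ds = PopulationDataset((subj,))
        fr = self._truth_fit_result(ds, published_params, FINAL_MODEL_SPEC)
        table = diagnostics_table(ds, fr)
        # with a proportional error model the log-variance ("interaction")
        # term pulls the conditional mode a hair off zero even on noise-free
        # data, so CWRES is only approximately zero (in SD units)
        np.testing.assert_allclose(table["cwres"], 0.0, atol=5e-3)
        np.testing.assert_allclose(table["pred"], table["dv"], rtol=1e-8)

    def test_pred_identical_for_identical_covariates_and_doses(self,
                                                               published_params):
        rng = np.random.default_rng(9)
        subs = tuple(
            make_subject(published_params, COV, eta, TIMES, DOSES, subject_id=sid,
                         noise=rng.normal(0, 0.2, len(TIMES)))
            for sid, eta in (("A", 0.2), ("B", -0.3))
        )
        ds = PopulationDataset(subs)
        fr = self._truth_fit_result(ds, published_params, FINAL_MODEL_SPEC)
        table = diagnostics_table(ds, fr)
        a = table[table.subject_id == "A"]["pred"].to_numpy()
        b = table[table.subject_id == "B"]["pred"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_cwres_mostly_within_two(self, published_params):
        """Under the generating model ~95% of CWRES lie in [-2, 2]."""
        design = v.StudyDesign(n_subjects=30, regimen_pool=((500.0, 12.0, 1.0),))
        ds = v.generate_study(design, published_params, seed=77)
        fr = self._truth_fit_result(ds, published_params, FINAL_MODEL_SPEC)
        table = diagnostics_table(ds, fr)
        frac = np.mean(np.abs(table["cwres"]) <= 2.0)
        assert 0.88 <= frac <= 1.0
        assert "tad" in table.columns and (table["tad"] >= 0).all()
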