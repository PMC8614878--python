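import numpy as np
import pytest

import vancopk as v
from vancopk.data import ModelSpec, Observation, PopulationDataset, SubjectRecord
from vancopk.model import DoseEvent, PatientCovariates
from vancopk.model import _profile_matrix


@pytest.fixture(scope="session")
def published_params():
    return v.VANCOMYCIN_CVVH_ESTIMATES


@pytest.fixture(scope="session")
def small_study(published_params):
    """An 11-subject virtual study on the trial design (500 mg q12h only)."""
    design = v.StudyDesign(n_subjects=11, regimen_pool=((500.0, 12.0, 1.0),))
    return v.generate_study(design, published_params, seed=42)


def make_onecpt_dataset(
    seed,
    n_subjects=12,
    cl_pop=2.0,
    vc_pop=30.0,
    omega2=0.05,
    sigma2=0.25,
    ufr_slope=0.0,
    extra_covariate=None,
    times=(1.0, 2.0, 4.0, 8.0, 12.0),
):
    """Small one-compartment IV-infusion dataset with additive error.

    Fast fixture for the estimation/selection/bootstrap machinery; clearance
    is allometric weight plus an optional additive UFR term, and an optional
    extra covariate column (pure noise unless wired into the model) supports
    null-candidate tests.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    subjects = []
    for i in range(n_subjects):
        wt = rng.uniform(52.0, 90.0)
        ufr = rng.uniform(18.0, 39.0)
        extra = {extra_covariate: float(rng.uniform(0.0, 1.0))} if extra_covariate else {}
        cov = PatientCovariates(wt, 29.0, ufr, extra=extra)
        cl = cl_pop * (wt / 70.0) ** 0.75 + ufr_slope * ufr
        eta = rng.normal(0.0, np.sqrt(omega2)) if omega2 > 0 else 0.0
        f = _profile_matrix(
            cl * np.exp(eta), vc_pop * wt / 70.0, None, None,
            np.array([0.0]), np.array([500.0]), np.array([1.0]), times, 1,
        )[0]
        y = np.maximum(f + rng.normal(0.0, np.sqrt(sigma2), f.shape), 1e-3)
        subjects.append(
            SubjectRecord(
                f"S{i:02d}", cov, (DoseEvent(0.0, 500.0, 1.0),),
                tuple(Observation(float(t), float(c)) for t, c in zip(times, y)),
            )
        )
    return PopulationDataset(tuple(subjects))


ONECPT_SPEC = ModelSpec(n_compartments=1, error_model="additive")
ONECPT_INIT = {"cl_pop": 2.0, "vc_pop": 30.0, "omega2_cl": 0.05, "sigma2": 0.25}


@pytest.fixture(scope="session")
def onecpt_dataset():
    return make_onecpt_dataset(seed=5)


@pytest.fixture(scope="session")
def onecpt_fit(onecpt_dataset):
    return v.fit(onecpt_dataset, init=dict(ONECPT_INIT), spec=ONECPT_SPEC,
                 compute_rse=False)
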