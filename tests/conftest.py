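"""Shared fixtures: donor surrogate mesh, its four-edge protocol run, and
coarse-pixel synthetic cohorts.

Simulations in the suite use a 1-us operator-splitting step with
Rush-Larsen gate updates (the package's documented stable-coarser option);
the step-halving test below demonstrates that conduction velocities are
converged at this resolution.  Synthetic images use 2-um pixels so that a
1 mm^2 image is 500 x 500 pixels.
"""

import warnings

import numpy as np
import pytest

from fibrocv import bidomain, cv, mesh as fmesh, synthetic

FAST_DT = 1e-6  # s
DONOR_FRACTIONS = {"v_e": 0.201, "v_f": 0.010, "v_mf": 0.010}
COARSE_PIXEL_NM = 2000.0


def eval_params():
    return fmesh.ConductivityParams.preset("evaluation")


@pytest.fixture(scope="session")
def donor_mesh():
    """Homogeneous 1-mm (20x20) mesh at donor-mean volume fractions."""
    return fmesh.homogeneous_mesh(20, 20, **DONOR_FRACTIONS, params=eval_params())


@pytest.fixture(scope="session")
def donor_recordings(donor_mesh):
    """Four-edge stimulus protocol on the donor surrogate mesh."""
    return bidomain.run_protocol(
        donor_mesh, bidomain.SimulationConfig(dt=FAST_DT)
    )


@pytest.fixture(scope="session")
def donor_cv(donor_recordings):
    """CV measurements at the standard triplets for each stimulus edge."""
    return {
        edge: cv.cv_vectors(cv.activation_map(rec))
        for edge, rec in donor_recordings.items()
    }


def median_magnitude(measurements):
    vals = [m.magnitude_m_s for m in measurements if m.valid]
    assert vals, "all sampling triplets blocked"
    return float(np.median(vals))


@pytest.fixture(scope="session")
def small_cohort():
    """2 donor + 2 NIC + 2 IC coarse-pixel images for conduction studies."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.generate_cohort(
            2, 2, 2, seed=42, pixel_size_nm=COARSE_PIXEL_NM
        )


@pytest.fixture(scope="session")
def full_cohort():
    """Study-sized cohort (5 donor, 8 NIC, 8 IC) at coarse pixels."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.generate_cohort(
            5, 8, 8, seed=7, pixel_size_nm=COARSE_PIXEL_NM
        )
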