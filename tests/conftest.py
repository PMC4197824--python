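import numpy as np
import pytest

from polpause import bimodal_fit as bf
from polpause import workflows as wf
from polpause.synthetic_cohort import CohortConfig

# Parameter set of the high-quality single-gene worked example: initiation
# peak 2 bp downstream of the annotated TSS, pausing peak 113 bp further,
# widths 48/18 bp, maxima ratio 2.16.
WORKED_EXAMPLE = dict(mu_u=2.0, d=113.0, sigma_u=48.0, sigma_d=18.0,
                      r=2.16, amplitude=100.0)


@pytest.fixture(scope="session")
def worked_profile():
    params = bf.BimodalParams(**WORKED_EXAMPLE)
    return bf.render_model(params, (-300, 400))


@pytest.fixture(scope="session")
def worked_fit(worked_profile):
    return bf.fit_bimodal(worked_profile)


@pytest.fixture(scope="session")
def small_cohort():
    """40 isolated genes with full PolII + RNA simulation."""
    cfg = CohortConfig(n_genes=40, seed=7, fraction_bidirectional=0.0)
    return wf.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    positions, half = wf.centered_positions(small_cohort)
    profiles = wf.promoter_profiles(positions, small_cohort.annotation)
    fits = wf.fit_cohort(profiles, small_cohort.annotation,
                         positions=positions)
    return {"positions": positions, "half_fragment": half,
            "profiles": profiles, "fits": fits}


@pytest.fixture(scope="session")
def mixed_cohort():
    """Cohort with bidirectional pairs, annotation only (no tag simulation)."""
    cfg = CohortConfig(n_genes=400, seed=13, fraction_bidirectional=0.3,
                       annotation_err_sd=0.0)
    from polpause.synthetic_cohort import generate_cohort
    truths, annot = generate_cohort(cfg)
    return truths, annot
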