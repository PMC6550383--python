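import numpy as np
import pytest

import lurepoint as lp


@pytest.fixture(scope="session")
def true_params():
    """Generator defaults: effective areas ~0.045 (large) / 0.030 km2 (small)."""
    return lp.TrueDetectionParams()


@pytest.fixture(scope="session")
def fitted_model(true_params):
    """Detection function fitted on a large seeded trial set (tight coefficients)."""
    trials = lp.simulate_trials(true_params, n_groups=400, seed=11)
    return lp.fit_detection(trials, ("distance", "fragment_class"))


@pytest.fixture(scope="session")
def reference_estimates():
    return lp.load_reference_estimates()


def make_quadrat(mu, qid, n_points, detected_last=False, size=5):
    """A quadrat with n_points surveyed points, optionally ending in a detection."""
    pts = []
    for i in range(1, n_points + 1):
        det = 1 if (detected_last and i == n_points) else 0
        pts.append(
            lp.SurveyPoint(
                mu_name=mu,
                quadrat_id=qid,
                point_index=i,
                detected=det,
                n_individuals=size if det else None,
            )
        )
    return lp.Quadrat(mu_name=mu, quadrat_id=qid, points=tuple(pts))
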