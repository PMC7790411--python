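import numpy as np
import pytest
from hypothesis import settings

import implantsurv as im

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from implantsurv.cohort import Cohort, CovariateSpec, TimeToEventRecord


@pytest.fixture(scope="session")
def two_level_spec():
    return CovariateSpec(
        categories={"g": ("A", "B")},
        references={"g": "A"},
    )


@pytest.fixture(scope="session")
def km_toy(two_level_spec):
    """4 subjects: events at 2 and 4, censored at 3 and 5.

    Hand product-limit: S(2) = 3/4; at t=4 risk set {4, 5} so
    S(4) = 3/4 * 1/2 = 0.375.
    """
    rows = [(2, 1), (3, 0), (4, 1), (5, 0)]
    recs = [
        TimeToEventRecord(f"s{i}", f"s{i}", 0.0, t, e, {"g": "A"})
        for i, (t, e) in enumerate(rows)
    ]
    return Cohort(recs, two_level_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient cohort, no frailty, default margins and effect sizes."""
    cfg = im.SyntheticConfig(n_patients=300, frailty_theta=0.0, seed=101)
    cohort, truth = im.generate(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def clustered_cohort():
    """Implant-level cohort with shared gamma frailty (theta = 0.5)."""
    cfg = im.SyntheticConfig(n_patients=150, implant_level=True,
                             frailty_theta=0.5, seed=77)
    cohort, truth = im.generate(cfg)
    return cohort, truth


def brute_force_breslow(entry, exit_, event, X, beta):
    """Term-by-term Breslow partial log-likelihood over ordered failure times."""
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, int)
    X = np.asarray(X, float)
    ll = 0.0
    for t in np.unique(exit_[event == 1]):
        fail = (exit_ == t) & (event == 1)
        risk = (entry < t) & (exit_ >= t)
        ll += float(np.sum(X[fail] @ beta))
        ll -= fail.sum() * np.log(np.sum(np.exp(X[risk] @ beta)))
    return ll
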