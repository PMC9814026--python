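import numpy as np
import pandas as pd
import pytest

from coxagq.design import FrailtyTerm, LinearTerm, ModelSpec, SmoothTerm
from coxagq.priors import exponential_prior
from coxagq.survdata import dataset_from_frame


def random_dataset(rng, n=40, n_groups=8, censor_frac=0.25, with_ties=False):
    """Small random survival dataset with one covariate and groups."""
    times = rng.exponential(scale=5.0, size=n) + 0.1
    if with_ties:
        times = np.round(times, 0) + 1.0
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[0] = 1
    df = pd.DataFrame({
        "group": rng.integers(0, n_groups, size=n),
        "time": times,
        "status": events,
        "x": rng.normal(size=n),
    })
    # ensure every group label 0..k-1 appears densely via dataset mapping
    return dataset_from_frame(df)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def frailty_toy():
    """6 records in 3 groups, distinct times: the standard small testbed."""
    df = pd.DataFrame({
        "group": [0, 0, 1, 1, 2, 2],
        "time": [3.0, 1.0, 2.0, 5.0, 4.0, 6.0],
        "status": [1, 1, 1, 0, 1, 1],
        "x": [0.5, -1.2, 0.3, 0.9, -0.4, 1.1],
    })
    return dataset_from_frame(df)


def frailty_spec(data, prior_median=1.0, prior_variance=1000.0, with_linear=True):
    linear = None
    if with_linear:
        linear = LinearTerm(data.covariate("x")[:, None], ["x"],
                            prior_variance=prior_variance)
    return ModelSpec(
        linear=linear,
        frailty=FrailtyTerm(data.group_codes, data.n_groups,
                            prior=exponential_prior(median=prior_median)),
    )


def smooth_spec(data, n_knots=10, tail=(2.0, 0.5)):
    return ModelSpec(smooths=[SmoothTerm(
        name="u", covariate=data.covariate("u"), n_knots=n_knots,
        prior=exponential_prior(tail=tail),
    )])
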