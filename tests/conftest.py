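"""Shared fixtures: tiny hand-sized panels and simulated truths."""

import numpy as np
import pytest

import latentrules as lr

RUM_ATTRS = ("grade_steep", "traffic_heavy", "mean_exposure",
             "travel_time", "segregation_exclusive")
RRM_ATTRS = ("grade_steep", "traffic_heavy", "mean_exposure", "travel_time")


def make_panel(C=3, K=2, I=3, M=2, seed=0, attribute_names=None, full_avail=True):
    """Small dense panel with random attribute values and choices."""
    rng = np.random.default_rng(seed)
    names = attribute_names or [f"a{m}" for m in range(M)]
    x = rng.normal(size=(C, K, I, len(names)))
    avail = np.ones((C, K, len(names)), dtype=bool)
    if not full_avail:
        avail[:, :, -1] = rng.random((C, K)) < 0.5
        x[~np.broadcast_to(avail[:, :, None, :], x.shape)] = 0.0
    chosen = rng.integers(0, I, size=(C, K))
    z = np.column_stack([np.ones(C), rng.integers(0, 2, C).astype(float)])
    return lr.ChoicePanel(x=x, chosen=chosen, z=z, attribute_names=list(names),
                          covariate_names=["intercept", "female"],
                          availability=avail)


@pytest.fixture
def small_panel():
    return make_panel(C=3, K=2, I=3, M=2, seed=1)


@pytest.fixture
def masked_panel():
    return make_panel(C=4, K=3, I=3, M=3, seed=2, full_avail=False)


@pytest.fixture(scope="session")
def two_class_truth():
    """Well-separated 1 RRM + 1 RUM generating model."""
    spec = lr.ModelSpec(
        segments=(lr.SegmentSpec("RRM", RRM_ATTRS),
                  lr.SegmentSpec("RUM", RUM_ATTRS)),
        membership_covariates=("intercept", "female"))
    params = lr.ParameterSet(
        gamma={1: np.array([0.4, 0.9])},
        beta=[np.array([-2.1, -1.1, -0.07, -0.25]),
              np.array([-1.8, -1.6, -0.06, -0.05, 1.9])],
        log_spread=[np.array([]), np.array([])])
    return lr.TruthConfig(spec=spec, params=params, seed=11)


@pytest.fixture(scope="session")
def two_class_panel(two_class_truth):
    return lr.simulate_panel(lr.DesignConfig(n_respondents=2000, seed=3),
                             two_class_truth)
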