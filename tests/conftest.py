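"""Shared fixtures: toy models and small synthetic datasets.

The one-parameter exponential-decay model gives fast, fully checkable
fits (the likelihood surface can be scanned densely in 1-D); the
three-compartment fixtures exercise the production forward model at
small population sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from npag import (
    ControlParams,
    ErrorModel,
    NPMLModel,
    Observation,
    ParameterDomain,
    PKModelSpec,
    Subject,
    default_spec,
    simulate_population,
)

TOY_TIMES = (1.0, 2.0, 4.0)
TOY_AMPLITUDE = 100.0


def toy_predict(theta, doses, obs_points):
    """y(t) = A * exp(-theta * t); strictly monotone in theta at each t."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    t = np.asarray([tp for tp, _ in obs_points])
    return TOY_AMPLITUDE * np.exp(-theta[:, [0]] * t[None, :])


TOY_MODEL = PKModelSpec(
    name="toy_decay", parameter_names=("kel",), n_outputs=1, predict=toy_predict
)

TOY_DOMAIN = ParameterDomain(("kel",), (0.05,), (2.0,))


def make_toy_subject(theta, sid="s1", noise_sd=0.0, sigma=1.0, rng=None,
                     times=TOY_TIMES):
    clean = toy_predict(np.array([[theta]]), [], [(t, 0) for t in times])[0]
    noise = rng.normal(0, noise_sd, len(times)) if noise_sd else 0.0
    obs = [Observation(t, v, 0) for t, v in zip(times, clean + noise)]
    return Subject(sid, [], obs, {0: (sigma, 0.0, 0.0, 0.0)})


@pytest.fixture(scope="session")
def toy_noiseless_fit():
    """Converged 1-subject noiseless 1-D fit; truth kel = 0.7."""
    subj = make_toy_subject(0.7)
    model = NPMLModel([subj], TOY_DOMAIN, TOY_MODEL, ErrorModel("constant", gamma=1.0))
    res = model.fit(101, controls=ControlParams(max_cycles=500))
    return model, res


@pytest.fixture(scope="session")
def toy_three_subject_fit():
    """Converged 3-subject tiny-noise 1-D fit; truths 0.3, 0.8, 1.4."""
    rng = np.random.default_rng(7)
    truths = (0.3, 0.8, 1.4)
    subjects = [
        make_toy_subject(th, f"s{i}", noise_sd=0.01, sigma=0.01, rng=rng)
        for i, th in enumerate(truths)
    ]
    model = NPMLModel(subjects, TOY_DOMAIN, TOY_MODEL,
                      ErrorModel("constant", gamma=0.01))
    res = model.fit(101, controls=ControlParams(max_cycles=500))
    return model, res, truths


@pytest.fixture(scope="session")
def small_pk_dataset():
    """Eight subjects from the reference simulation design."""
    spec = default_spec(8)
    subjects, truth = simulate_population(spec, seed=11)
    return spec, subjects, truth


@pytest.fixture(scope="session")
def small_pk_fit(small_pk_dataset):
    """A short (cycle-capped) adaptive-grid run on the 8-subject dataset."""
    spec, subjects, _ = small_pk_dataset
    model = NPMLModel(subjects, spec.domain, "threecomp",
                      ErrorModel("constant", gamma=5.5))
    res = model.fit(301, controls=ControlParams(max_cycles=30))
    return model, res
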