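"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cephorient import CohortConfig, LandmarkSet, generate_cohort
from cephorient.simulate import AXIS_DISTANCE_TARGETS_MM


#: Axis-aligned reference quadruple: canonical frame by construction.
AXIS_ALIGNED_REFS = {
    "Na": np.array([0.0, 60.0, 0.0]),
    "S": np.array([0.0, 0.0, 0.0]),
    "Ba": np.array([0.0, -10.0, -30.0]),
    "MLWS": np.array([0.0, 2.0, 0.0]),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def axis_aligned_trial():
    return LandmarkSet("p1", "T1", dict(AXIS_ALIGNED_REFS))


def random_reference_trial(rng, patient="p1", trial="T1", spread=50.0):
    """Random non-degenerate reference quadruple (plus one target point)."""
    while True:
        pts = {n: rng.uniform(-spread, spread, 3)
               for n in ("MLWS", "Na", "S", "Ba")}
        ns = pts["Na"] - pts["S"]
        if np.linalg.norm(ns) < 1.0:
            continue
        y = ns / np.linalg.norm(ns)
        off = (pts["Ba"] - pts["S"]) - ((pts["Ba"] - pts["S"]) @ y) * y
        if np.linalg.norm(off) < 1.0:
            continue
        pts["Me"] = rng.uniform(-spread, spread, 3)
        return LandmarkSet(patient, trial, pts)


@pytest.fixture
def default_cohort():
    """One default 20-patient, 3-trial cohort at a fixed seed."""
    return generate_cohort(CohortConfig(seed=1))


def simulate_regression_rows(n, rng, coefs=None, intercept=0.5, noise_sd=1.0,
                             n_decoys=3):
    """Rows drawn from the linear error model with realistic predictor
    ranges: Db as the norm of 3D placement-difference noise, DX from the
    template's axis distances, A3r gamma-distributed around 1 degree."""
    if coefs is None:
        coefs = {"Db": 0.758, "DX": 0.018, "A3r": 0.545}
    db = np.linalg.norm(rng.normal(0.0, 0.45, size=(n, 3)), axis=1)
    dx = rng.choice(list(AXIS_DISTANCE_TARGETS_MM.values()), size=n)
    dx = dx + rng.normal(0.0, 4.0, size=n)
    a3r = rng.gamma(shape=5.0, scale=0.2, size=n)
    y = (intercept + coefs["Db"] * db + coefs["DX"] * dx
         + coefs["A3r"] * a3r + rng.normal(0.0, noise_sd, size=n))
    data = {"pair": "T1-T2", "Y": y, "Db": db, "DX": dx, "A3r": a3r}
    for k in range(n_decoys):
        data[f"noise{k + 1}"] = rng.normal(size=n)
    return pd.DataFrame(data)
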