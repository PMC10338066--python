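"""Shared fixtures: small synthetic problems with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import rdcfit as rf


@pytest.fixture(scope="session")
def truth_tensor() -> rf.AlignmentTensor:
    return rf.AlignmentTensor.from_parameters(10.0, 0.3, (0.4, 1.1, 2.3))


@pytest.fixture(scope="session")
def mixture_problem(truth_tensor):
    """10 discrete conformers, measurements from members 2 and 5 at 0.3/0.7.

    Noise is 2% of the alignment strength.  Returns (d_members, d_meas,
    tensor, w_true, sigma).
    """
    spec = rf.SyntheticSpec(
        n_residues=30,
        n_members=10,
        motion={r: rf.Scatter() for r in range(1, 31)},
        seed=3,
    )
    vs, _ = rf.generate_vector_ensemble(spec)
    w_true = np.zeros(10)
    w_true[2], w_true[5] = 0.3, 0.7
    sigma = 0.02 * spec.da
    table = rf.generate_rdc_table(vs, truth_tensor, w_true, sigma=sigma, seed=4)
    d_members = rf.predict_members(vs, truth_tensor)
    d_meas = table.df["value_hz"].to_numpy()
    return d_members, d_meas, truth_tensor, w_true, sigma


@pytest.fixture(scope="session")
def rigid_vectors():
    spec = rf.SyntheticSpec(n_residues=40, n_members=8, seed=10)
    vs, _ = rf.generate_vector_ensemble(spec)
    return vs


@pytest.fixture(scope="session")
def random_unit_vectors():
    rng = np.random.default_rng(1)
    v = rng.normal(size=(1, 100, 3))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    return rf.BondVectorSet("NH", np.arange(1, 101), v)
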