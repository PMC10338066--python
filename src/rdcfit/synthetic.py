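"""Synthetic fixtures with known ground truth.

Every generator is a pure function of its specification and seed.  The module
emulates the ingredients of an RDC-vs-ensemble analysis without any external
data: sets of unit bond vectors with controlled angular disorder (rigid bonds,
uniform wobble in a cone, discrete two-state jumps, fully scattered
per-member orientations), noisy RDC tables generated from a known alignment
tensor and known mixture weights, and idealized multi-MODEL PDB files that
realize a requested vector ensemble so the full file -> vectors -> fit path
can be exercised end to end.

For cone wobble of semi-angle theta0 (uniform over the enclosed solid angle)
the generalized order parameter has the closed form
S = cos(theta0) (1 + cos(theta0)) / 2, which serves as the analytic oracle for
the Monte-Carlo estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .couplings import get_coupling
from .rdc_core import AlignmentTensor, RDCTable, predict_members
from .structure_io import BondVectorSet, Conformer, ConformerEnsemble, write_ensemble_pdb

# ---------------------------------------------------------------------------
# motion models


@dataclass(frozen=True)
class Rigid:
    """Identical orientation in every member."""


@dataclass(frozen=True)
class Cone:
    """Uniform wobble within a cone of semi-angle ``theta0_deg`` about the base vector."""

    theta0_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0_deg < 90.0:
            raise ValueError("cone semi-angle must lie in (0, 90) degrees")

    @property
    def analytic_s(self) -> float:
        c = math.cos(math.radians(self.theta0_deg))
        return c * (1.0 + c) / 2.0


@dataclass(frozen=True)
class TwoState:
    """Discrete jump between two orientations separated by ``angle_deg``.

    ``p1`` is the population of the first state; members are assigned
    deterministically (the first round(p1*n) members take state 1).
    """

    angle_deg: float
    p1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError("population must lie on [0, 1]")


@dataclass(frozen=True)
class Scatter:
    """Independent uniform random orientation per member (discrete conformers)."""


MotionModel = Rigid | Cone | TwoState | Scatter


@dataclass
class SyntheticSpec:
    """Specification of a synthetic vector ensemble.

    ``motion`` maps residue index -> motion model; residues not listed are
    rigid.  The truth tensor defaults to Da = 10 Hz, Rh = 0.3 at a fixed
    generic orientation, and noise to 2% of Da per coupling, matching a
    realistic alignment strength and measurement precision for backbone amide
    couplings.
    """

    n_residues: int = 20
    n_members: int = 10
    motion: Mapping[int, MotionModel] = field(default_factory=dict)
    da: float = 10.0
    rh: float = 0.3
    euler: tuple[float, float, float] = (0.4, 1.1, 2.3)
    noise_hz: float = 0.2
    coupling_type: str = "NH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_members < 1:
            raise ValueError("need >=1 residue and >=1 member")
        if self.noise_hz < 0:
            raise ValueError("noise must be >= 0")
        for resid in self.motion:
            if not 1 <= resid <= self.n_residues:
                raise ValueError(f"motion residue {resid} outside 1..{self.n_residues}")
        get_coupling(self.coupling_type)

    @property
    def tensor(self) -> AlignmentTensor:
        return AlignmentTensor.from_parameters(self.da, self.rh, self.euler)


# ---------------------------------------------------------------------------
# sampling helpers


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _frame_about(axis: np.ndarray) -> np.ndarray:
    """Orthonormal frame with the given unit vector as third column."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.column_stack([e1, e2, axis])


def sample_cone(
    rng: np.random.Generator, axis: np.ndarray, theta0_deg: float, n: int
) -> np.ndarray:
    """Unit vectors uniform over the solid angle of a cone about ``axis``."""
    cos0 = math.cos(math.radians(theta0_deg))
    cos_t = rng.uniform(cos0, 1.0, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return local @ _frame_about(axis).T


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    return (
        v * math.cos(angle_rad)
        + np.cross(axis, v) * math.sin(angle_rad)
        + axis * (axis @ v) * (1.0 - math.cos(angle_rad))
    )


# ---------------------------------------------------------------------------
# generators


def generate_vector_ensemble(spec: SyntheticSpec) -> tuple[BondVectorSet, dict]:
    """Vector ensemble realizing the requested per-residue motion models.

    Returns the BondVectorSet and a ground-truth record with the base
    orientations, the per-residue analytic order parameter where a closed form
    exists (rigid, cone, two-state), and the truth tensor parameters.
    """
    rng = np.random.default_rng(spec.seed)
    resids = np.arange(1, spec.n_residues + 1)
    base = _random_unit(rng, spec.n_residues)
    vectors = np.empty((spec.n_members, spec.n_residues, 3))
    truth_s: dict[int, float | None] = {}
    for ri, resid in enumerate(resids):
        model = spec.motion.get(int(resid), Rigid())
        axis = base[ri]
        if isinstance(model, Rigid):
            vectors[:, ri, :] = axis
            truth_s[int(resid)] = 1.0
        elif isinstance(model, Cone):
            vectors[:, ri, :] = sample_cone(rng, axis, model.theta0_deg, spec.n_members)
            truth_s[int(resid)] = model.analytic_s
        elif isinstance(model, TwoState):
            perp = _frame_about(axis)[:, 0]
            u1 = axis
            u2 = _rotate_about(axis, perp, math.radians(model.angle_deg))
            k = int(round(model.p1 * spec.n_members))
            vectors[:k, ri, :] = u1
            vectors[k:, ri, :] = u2
            p1 = k / spec.n_members
            mean = p1 * u1 + (1 - p1) * u2
            mean /= np.linalg.norm(mean)
            s = p1 * _p2(u1 @ mean) + (1 - p1) * _p2(u2 @ mean)
            truth_s[int(resid)] = float(s)
        elif isinstance(model, Scatter):
            vectors[:, ri, :] = _random_unit(rng, spec.n_members)
            truth_s[int(resid)] = None
        else:  # pragma: no cover - guarded by the union type
            raise TypeError(f"unknown motion model {model!r}")
    vset = BondVectorSet(
        spec.coupling_type,
        resids,
        vectors,
        [f"synthetic:{i}" for i in range(spec.n_members)],
    )
    truth = {
        "base_vectors": base,
        "analytic_s": truth_s,
        "da": spec.da,
        "rh": spec.rh,
        "euler": spec.euler,
        "saupe": spec.tensor.saupe,
        "seed": spec.seed,
    }
    return vset, truth


def _p2(x: float) -> float:
    return (3.0 * x * x - 1.0) / 2.0


def generate_rdc_table(
    vectors: BondVectorSet,
    tensor: AlignmentTensor,
    weights: np.ndarray | None = None,
    sigma: float = 0.2,
    seed: int = 0,
    medium: str = "syn1",
    chain: str = "A",
) -> RDCTable:
    """Noisy measured couplings from the ensemble-averaged prediction.

    D_meas = sum_i w_i D_i^pred + Gaussian(0, sigma); the table's uncertainty
    column is set to sigma (floored at 1e-9 Hz for the noiseless case).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    m = vectors.n_members
    weights = np.full(m, 1.0 / m) if weights is None else np.asarray(weights, float)
    if weights.shape != (m,):
        raise ValueError("weight/member count mismatch")
    rng = np.random.default_rng(seed)
    d = weights @ predict_members(vectors, tensor)
    if sigma > 0:
        d = d + rng.normal(0.0, sigma, d.size)
    ct = get_coupling(vectors.coupling_type)
    records = [
        {
            "medium": medium,
            "chain": chain,
            "resid_i": int(r),
            "atom_i": ct.atom_i,
            "resid_j": int(r) + ct.offset_j,
            "atom_j": ct.atom_j,
            "type": ct.name,
            "value_hz": float(v),
            "sigma_hz": max(sigma, 1e-9),
        }
        for r, v in zip(vectors.residues, d)
    ]
    return RDCTable.from_records(records)


# ---------------------------------------------------------------------------
# PDB fixtures

# idealized local geometry (Angstrom / degrees): each residue is an internally
# rigid peptide unit placed on a regular lattice; exact N-H directions take
# priority over chain closure, so units are intentionally not bonded.
_N_CA = 1.458
_CA_C = 1.525
_C_O = 1.231
_H_N_CA_ANGLE = 119.0
_SPACING = 6.0


def _residue_atoms(n_pos: np.ndarray, nh: np.ndarray) -> dict[str, np.ndarray]:
    frame = _frame_about(nh)
    perp = frame[:, 0]
    ang = math.radians(_H_N_CA_ANGLE)
    ca_dir = math.cos(ang) * nh + math.sin(ang) * perp
    ca = n_pos + _N_CA * ca_dir
    c_dir = _rotate_about(ca_dir, frame[:, 1], math.radians(70.0))
    c = ca + _CA_C * c_dir
    o = c + _C_O * nh
    return {
        "N": n_pos,
        "H": n_pos + 1.02 * nh,
        "CA": ca,
        "C": c,
        "O": o,
    }


def generate_pdb_fixture(
    spec: SyntheticSpec, path: str | Path | None = None
) -> tuple[ConformerEnsemble, BondVectorSet, dict]:
    """Poly-alanine multi-MODEL ensemble realizing the spec's N-H vectors.

    Residue *i* of every model sits at (6*i, 0, 0) with idealized local
    geometry oriented so that the N->H unit vector equals the generated one.
    When ``path`` is given the ensemble is also written as a multi-MODEL PDB
    file (synthetic fixture; readable by any PDB parser).
    """
    if spec.coupling_type != "NH":
        raise ValueError("PDB fixtures realize NH vector ensembles")
    vset, truth = generate_vector_ensemble(spec)
    members = []
    for mi in range(spec.n_members):
        residues = {}
        for ri, resid in enumerate(vset.residues):
            n_pos = np.array([_SPACING * ri, 0.0, 0.0])
            residues[int(resid)] = ("ALA", _residue_atoms(n_pos, vset.vectors[mi, ri]))
        members.append(Conformer(f"synthetic:{mi}", residues))
    ensemble = ConformerEnsemble(members)
    if path is not None:
        write_ensemble_pdb(ensemble, path)
    return ensemble, vset, truth
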