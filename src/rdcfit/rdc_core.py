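"""Alignment tensors, RDC prediction, SVD fitting and Q-factor scoring.

The residual dipolar coupling of a bond with unit vector *u* under a Saupe
alignment matrix *S* (symmetric, traceless, in Hz on the reference coupling
scale) is D = u^T S u.  For a weighted ensemble the observed coupling is the
population-weighted average of the per-member predictions, which is what makes
RDCs sensitive to the *distribution* of bond orientations rather than only to
the mean orientation.

The tensor is characterized by its alignment strength Da = lambda_z/2 and
rhombicity Rh = 2(lambda_x - lambda_y)/(3 lambda_z), with eigenvalues ordered
|lambda_z| >= |lambda_y| >= |lambda_x| (which pins Rh into [0, 2/3]).  In the
principal frame D(theta, phi) = Da[(3 cos^2 theta - 1)
+ (3/2) Rh sin^2 theta cos 2 phi].

Agreement between measured and predicted couplings is expressed as the quality
factor Q = rms(D_pred - D_meas) / sqrt(Da^2 (4 + 3 Rh^2) / 5), a normalized
rms deviation that is comparable across alignment media of different strength.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .couplings import REGISTRY, coupling_from_atom_pair, get_coupling, nh_scale_factor
from .errors import (
    EmptySelectionError,
    FormatError,
    IllConditionedWarning,
    UndefinedNormalizationError,
    UnderDeterminedError,
)
from .structure_io import BondVectorSet

logger = logging.getLogger("rdcfit")


# ---------------------------------------------------------------------------
# alignment tensor


@dataclass
class AlignmentTensor:
    """Symmetric traceless Saupe-like alignment matrix (Hz, NH scale).

    Derived quantities (computed at construction):

    - ``da``: alignment strength, half the largest-magnitude eigenvalue (Hz);
    - ``rh``: rhombicity in [0, 2/3];
    - ``euler``: z-y-z Euler angles (radians) of the principal-axis frame.
    """

    saupe: np.ndarray
    da: float = field(init=False)
    rh: float = field(init=False)
    euler: tuple[float, float, float] = field(init=False)
    eigenvalues: np.ndarray = field(init=False)  # ordered (x, y, z)
    principal_axes: np.ndarray = field(init=False)  # columns x, y, z

    def __post_init__(self) -> None:
        s = np.asarray(self.saupe, dtype=float)
        if s.shape != (3, 3):
            raise ValueError("saupe must be 3x3")
        if not np.allclose(s, s.T, atol=1e-9):
            raise ValueError("saupe must be symmetric")
        if abs(np.trace(s)) > 1e-9 * max(1.0, np.abs(s).max()):
            raise ValueError("saupe must be traceless")
        self.saupe = s
        w, v = np.linalg.eigh(s)
        order = np.argsort(np.abs(w))  # ascending magnitude -> (x, y, z)
        w, v = w[order], v[:, order]
        self.eigenvalues = w
        if np.linalg.det(v) < 0:
            v[:, 0] = -v[:, 0]
        self.principal_axes = v
        lz = w[2]
        self.da = float(lz / 2.0)
        self.rh = float(2.0 * (w[0] - w[1]) / (3.0 * lz)) if lz != 0 else 0.0
        with warnings.catch_warnings():
            # axially symmetric tensors have a degenerate azimuth (gimbal lock)
            warnings.simplefilter("ignore", UserWarning)
            self.euler = tuple(Rotation.from_matrix(v).as_euler("ZYZ"))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_elements(cls, elements: np.ndarray) -> "AlignmentTensor":
        """Build from the 5 independent elements (Sxx, Syy, Sxy, Sxz, Syz)."""
        sxx, syy, sxy, sxz, syz = np.asarray(elements, dtype=float)
        return cls(
            np.array(
                [
                    [sxx, sxy, sxz],
                    [sxy, syy, syz],
                    [sxz, syz, -sxx - syy],
                ]
            )
        )

    @classmethod
    def from_parameters(
        cls, da: float, rh: float, euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ) -> "AlignmentTensor":
        """Build from alignment strength, rhombicity and principal-axis Euler angles."""
        if not 0.0 <= rh <= 2.0 / 3.0:
            raise ValueError("rhombicity must lie in [0, 2/3]")
        lz = 2.0 * da
        lx = -da * (1.0 - 1.5 * rh)
        ly = -da * (1.0 + 1.5 * rh)
        rot = Rotation.from_euler("ZYZ", euler).as_matrix()
        return cls(rot @ np.diag([lx, ly, lz]) @ rot.T)

    @property
    def elements(self) -> np.ndarray:
        s = self.saupe
        return np.array([s[0, 0], s[1, 1], s[0, 1], s[0, 2], s[1, 2]])

    def to_dict(self) -> dict:
        return {
            "saupe": self.saupe.tolist(),
            "da_hz": self.da,
            "rh": self.rh,
            "euler_zyz_rad": list(self.euler),
        }


# ---------------------------------------------------------------------------
# RDC tables


TABLE_COLUMNS = [
    "medium",
    "chain",
    "resid_i",
    "atom_i",
    "resid_j",
    "atom_j",
    "type",
    "value_hz",
    "sigma_hz",
]


@dataclass
class RDCTable:
    """Measured couplings keyed by (medium, chain, residue, coupling type)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"RDC table missing columns: {missing}")
        self.df = self.df[TABLE_COLUMNS].reset_index(drop=True)
        self.df["resid_i"] = self.df["resid_i"].astype(int)
        self.df["resid_j"] = self.df["resid_j"].astype(int)
        for t in self.df["type"].unique():
            get_coupling(t)
        if (self.df["sigma_hz"] <= 0).any():
            raise FormatError("sigma_hz must be positive")
        dup = self.df.duplicated(subset=["medium", "chain", "resid_i", "type"])
        if dup.any():
            raise FormatError(
                "duplicate (medium, chain, residue, type) records: "
                f"{self.df.loc[dup, ['medium', 'resid_i', 'type']].to_dict('records')}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def media(self) -> list[str]:
        return sorted(self.df["medium"].unique())

    @property
    def types(self) -> list[str]:
        return sorted(self.df["type"].unique())

    def select(
        self,
        type: str | Sequence[str] | None = None,
        medium: str | None = None,
        resids: Sequence[int] | None = None,
    ) -> "RDCTable":
        df = self.df
        if type is not None:
            types = [type] if isinstance(type, str) else list(type)
            df = df[df["type"].isin(types)]
        if medium is not None:
            df = df[df["medium"] == medium]
        if resids is not None:
            df = df[df["resid_i"].isin(set(resids))]
        return RDCTable(df.reset_index(drop=True))

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "RDCTable":
        return cls(pd.DataFrame.from_records(list(records)))

    @classmethod
    def read(cls, path: str | Path, dialect: str = "native") -> "RDCTable":
        if dialect == "native":
            df = pd.read_csv(path, sep=r"\s+", comment="#", names=TABLE_COLUMNS, header=None)
            # tolerate a header row repeating the column names
            if str(df.iloc[0]["resid_i"]) == "resid_i":
                df = df.iloc[1:].reset_index(drop=True)
            return cls(df)
        if dialect == "pales":
            return cls(_read_pales(path))
        raise FormatError(f"unknown RDC table dialect {dialect!r}")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# " + " ".join(TABLE_COLUMNS) + "\n")
            self.df.to_csv(fh, sep="\t", header=False, index=False)


def _read_pales(path: str | Path) -> pd.DataFrame:
    """Read a PALES/DC-style table (VARS/FORMAT header, DATA-free records)."""
    columns: list[str] | None = None
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "REMARK", "FORMAT", "DATA")):
            continue
        if line.startswith("VARS"):
            columns = line.split()[1:]
            continue
        if columns is None:
            raise FormatError(f"{path}: PALES table has no VARS header")
        parts = line.split()
        if len(parts) != len(columns):
            raise FormatError(f"{path}: bad PALES record {line!r}")
        rec = dict(zip(columns, parts))
        ct = coupling_from_atom_pair(rec["ATOMNAME_I"], rec["ATOMNAME_J"])
        rows.append(
            {
                "medium": rec.get("MEDIUM", "m1"),
                "chain": rec.get("CHAIN", "A"),
                "resid_i": int(rec["RESID_I"]),
                "atom_i": rec["ATOMNAME_I"],
                "resid_j": int(rec["RESID_J"]),
                "atom_j": rec["ATOMNAME_J"],
                "type": ct,
                "value_hz": float(rec["D"]),
                "sigma_hz": float(rec.get("DD", 1.0)),
            }
        )
    if not rows:
        raise EmptySelectionError(f"{path}: no records")
    return pd.DataFrame(rows)


def normalize_coupling_types(
    table: RDCTable, scale_overrides: Mapping[str, float] | None = None
) -> RDCTable:
    """Rescale all coupling types onto the amide N-H scale.

    Default factors come from gyromagnetic ratios and standard internuclear
    distances (signed, so a single tensor fits all types jointly); explicit
    ``scale_overrides`` take precedence and are applied literally (logged).
    """
    overrides = dict(scale_overrides or {})
    for t in overrides:
        get_coupling(t)
    df = table.df.copy()
    for t in df["type"].unique():
        factor = overrides.get(t, nh_scale_factor(t))
        if t in overrides:
            logger.info("coupling type %s: override scale factor %.4g", t, factor)
        mask = df["type"] == t
        df.loc[mask, "value_hz"] *= factor
        df.loc[mask, "sigma_hz"] *= abs(factor)
    return RDCTable(df)


# ---------------------------------------------------------------------------
# prediction and fitting


def _quadratic_rows(u: np.ndarray) -> np.ndarray:
    """Design-matrix rows [ux^2-uz^2, uy^2-uz^2, 2uxuy, 2uxuz, 2uyuz].

    ``u`` has shape (..., 3); the result has shape (..., 5).  With the Saupe
    elements (Sxx, Syy, Sxy, Sxz, Syz) and Szz = -Sxx - Syy this reproduces
    u^T S u exactly.
    """
    ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
    return np.stack(
        [ux**2 - uz**2, uy**2 - uz**2, 2 * ux * uy, 2 * ux * uz, 2 * uy * uz],
        axis=-1,
    )


def predict_members(vectors: BondVectorSet, tensor: AlignmentTensor) -> np.ndarray:
    """Per-member predicted couplings, shape (n_members, n_residues), Hz."""
    return np.einsum("mri,ij,mrj->mr", vectors.vectors, tensor.saupe, vectors.vectors)


def predict_rdc(
    vectors: BondVectorSet,
    tensor: AlignmentTensor,
    weights: np.ndarray | None = None,
) -> dict[int, float]:
    """Ensemble-weighted predicted couplings, residue -> Hz.

    For a single-member set with weight 1 this is the static prediction.
    """
    if weights is None:
        weights = np.full(vectors.n_members, 1.0 / vectors.n_members)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (vectors.n_members,):
        raise ValueError(
            f"{weights.size} weights for {vectors.n_members} ensemble members"
        )
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    per_member = predict_members(vectors, tensor)
    d = weights @ per_member
    return {int(r): float(v) for r, v in zip(vectors.residues, d)}


def q_factor(
    d_pred: Mapping[int, float] | np.ndarray,
    d_meas: Mapping[int, float] | np.ndarray,
    da: float,
    rh: float,
) -> float:
    """Quality factor: rms(D_pred - D_meas) / sqrt(Da^2 (4 + 3 Rh^2) / 5)."""
    if isinstance(d_pred, Mapping):
        keys = sorted(d_pred)
        if isinstance(d_meas, Mapping):
            keys = sorted(set(d_pred) & set(d_meas))
            d_meas = np.array([d_meas[k] for k in keys])
        d_pred = np.array([d_pred[k] for k in keys])
    d_pred = np.asarray(d_pred, dtype=float)
    d_meas = np.asarray(d_meas, dtype=float)
    if d_pred.size == 0:
        raise EmptySelectionError("no couplings to score")
    if da == 0:
        raise UndefinedNormalizationError("Q undefined: Da is zero")
    rms = np.sqrt(np.mean((d_pred - d_meas) ** 2))
    return float(rms / np.sqrt(da**2 * (4.0 + 3.0 * rh**2) / 5.0))


@dataclass
class FitResult:
    """Outcome of an SVD tensor fit to one alignment medium."""

    tensor: AlignmentTensor
    resids: np.ndarray  # residue key per record (aligned with d_pred/d_meas)
    types: np.ndarray  # coupling type per record
    d_pred: np.ndarray  # Hz
    d_meas: np.ndarray  # Hz
    q: float
    rmsd: float  # Hz
    n_used: int
    condition_number: float
    warnings: list[str] = field(default_factory=list)

    @property
    def per_residue_residuals(self) -> dict[tuple[str, int], float]:
        return {
            (t, int(r)): float(p - m)
            for t, r, p, m in zip(self.types, self.resids, self.d_pred, self.d_meas)
        }

    def to_dict(self) -> dict:
        return {
            "tensor": self.tensor.to_dict(),
            "q": self.q,
            "rmsd_hz": self.rmsd,
            "n_used": self.n_used,
            "condition_number": self.condition_number,
            "warnings": self.warnings,
        }


def _as_vector_sets(
    vectors: BondVectorSet | Sequence[BondVectorSet],
) -> list[BondVectorSet]:
    if isinstance(vectors, BondVectorSet):
        return [vectors]
    return list(vectors)


def svd_fit_tensor(
    vectors: BondVectorSet | Sequence[BondVectorSet],
    table: RDCTable,
    weights: np.ndarray | None = None,
    sigma_weighting: bool = False,
    condition_threshold: float = 1e6,
) -> FitResult:
    """Least-squares Saupe tensor fit to measured couplings.

    ``vectors`` may be one BondVectorSet or several (one per coupling type);
    for an ensemble the design-matrix rows are the weight-averaged quadratic
    vector terms, so a single-member set reproduces the static fit bitwise.
    The table must contain a single alignment medium (media are fit
    independently; see :func:`fit_media`) and should be on a common scale
    (see :func:`normalize_coupling_types`) when mixing coupling types.
    """
    vsets = _as_vector_sets(vectors)
    if len(table.media) > 1:
        raise ValueError("table has multiple media; fit each separately (fit_media)")
    n_members = vsets[0].n_members
    if weights is None:
        weights = np.full(n_members, 1.0 / n_members)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_members,):
        raise ValueError("weight/member count mismatch")

    rows, meas, sig, resids, types = [], [], [], [], []
    for vs in vsets:
        if vs.n_members != n_members:
            raise ValueError("all vector sets must have the same member count")
        sub = table.df[table.df["type"] == vs.coupling_type]
        have = set(int(r) for r in vs.residues)
        for rec in sub.itertuples():
            if rec.resid_i not in have:
                logger.info(
                    "record %s %d dropped: no vector in ensemble", rec.type, rec.resid_i
                )
                continue
            u = vs.vectors[:, vs.residue_index(rec.resid_i), :]  # (m, 3)
            rows.append(weights @ _quadratic_rows(u))
            meas.append(rec.value_hz)
            sig.append(rec.sigma_hz)
            resids.append(rec.resid_i)
            types.append(rec.type)
    n_used = len(rows)
    if n_used < 5:
        raise UnderDeterminedError(
            f"{n_used} usable records; >=5 required for a full tensor fit"
        )
    a = np.asarray(rows)
    b = np.asarray(meas)
    if sigma_weighting:
        w = 1.0 / np.asarray(sig)
        sol, *_ = np.linalg.lstsq(a * w[:, None], b * w, rcond=None)
    else:
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cond = float(np.linalg.cond(a))
    warns: list[str] = []
    if cond > condition_threshold:
        msg = f"ill-conditioned design matrix (cond={cond:.3g})"
        warns.append(msg)
        warnings.warn(msg, IllConditionedWarning, stacklevel=2)
    tensor = AlignmentTensor.from_elements(sol)
    d_pred = a @ sol
    rmsd = float(np.sqrt(np.mean((d_pred - b) ** 2)))
    if tensor.da == 0:
        q = float("nan")
        warns.append("Da = 0: Q undefined")
    else:
        q = q_factor(d_pred, b, tensor.da, tensor.rh)
    return FitResult(
        tensor,
        np.asarray(resids),
        np.asarray(types),
        d_pred,
        b,
        q,
        rmsd,
        n_used,
        cond,
        warns,
    )


def fit_media(
    vectors: BondVectorSet | Sequence[BondVectorSet],
    table: RDCTable,
    weights: np.ndarray | None = None,
    **fit_kwargs,
) -> tuple[dict[str, FitResult], float]:
    """Independent tensor fit per alignment medium.

    Returns the per-medium results and the rms Q over media.
    """
    fits = {
        medium: svd_fit_tensor(
            vectors, table.select(medium=medium), weights, **fit_kwargs
        )
        for medium in table.media
    }
    qs = np.array([f.q for f in fits.values()])
    return fits, float(np.sqrt(np.mean(qs**2)))
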