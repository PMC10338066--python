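"""Per-residue disorder of a structural ensemble and its RDC diagnostics.

Given unit bond vectors over a superposed ensemble, each residue's angular
excursion in member *n* is beta_{i,n} = arccos(u_{i,n} . ubar_i), the angle to
the renormalized ensemble-averaged orientation ubar_i.  The generalized order
parameter is the weighted ensemble mean

    S_i = < (3 cos^2 beta_{i,n} - 1) / 2 >_n,

which is 1 for a rigid bond and decreases with motional amplitude (NMR
relaxation reports S^2).  Ranking residues by rms excursion and fitting the
most- and least-disordered halves (H50%/L50%) separately provides a
consistency check: if the ensemble's motional amplitudes match the couplings,
both halves yield the same alignment strength Da, whereas exaggerated
amplitudes inflate Da for the disordered half.  Comparing the ensemble fit
with a fit to the single averaged-orientation model separates genuine
dynamic-distribution effects from mere orientation averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySelectionError, UnderDeterminedError
from .rdc_core import FitResult, RDCTable, svd_fit_tensor
from .structure_io import BondVectorSet

logger = logging.getLogger("rdcfit")


@dataclass
class OrderParameterResult:
    """Per-residue mean orientations, angular excursions and order parameters."""

    coupling_type: str
    residues: np.ndarray  # (r,)
    mean_vectors: np.ndarray  # (r, 3) unit vectors; NaN where undefined
    beta: np.ndarray  # (m, r) radians
    s: np.ndarray  # (r,) generalized order parameter
    s2: np.ndarray  # (r,)
    rms_beta: np.ndarray  # (r,) radians
    valid: np.ndarray  # (r,) bool; False for undefined (antipodal) residues
    weights: np.ndarray  # (m,)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "resid": self.residues,
                "S": self.s,
                "S2": self.s2,
                "rms_beta_deg": np.degrees(self.rms_beta),
                "n_members": np.where(self.valid, len(self.weights), 0),
            }
        )


def order_parameters(
    vectors: BondVectorSet,
    weights: np.ndarray | None = None,
    superposed: bool = True,
) -> OrderParameterResult:
    """Generalized order parameters from inter-member angular excursions.

    The ensemble must already be superposed in a common frame (pass
    ``superposed=False`` to acknowledge an un-superposed input; a warning is
    logged).  Residues whose weighted mean vector has zero norm (antipodal
    members) are flagged invalid and excluded from downstream ranking.
    """
    if not superposed:
        logger.warning("order parameters computed on an ensemble not marked superposed")
    m = vectors.n_members
    if weights is None:
        weights = np.full(m, 1.0 / m)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (m,):
        raise ValueError("weight/member count mismatch")
    u = vectors.vectors  # (m, r, 3)
    mean = np.einsum("m,mri->ri", weights, u)
    norms = np.linalg.norm(mean, axis=-1)
    valid = norms > 1e-9
    if not valid.all():
        logger.warning(
            "residues %s have undefined mean orientation (antipodal members)",
            vectors.residues[~valid].tolist(),
        )
    mean_unit = np.full_like(mean, np.nan)
    mean_unit[valid] = mean[valid] / norms[valid, None]
    cosb = np.clip(np.einsum("mri,ri->mr", u, mean_unit), -1.0, 1.0)
    beta = np.arccos(cosb)  # (m, r); NaN propagates for invalid residues
    s = np.einsum("m,mr->r", weights, (3.0 * cosb**2 - 1.0) / 2.0)
    rms_beta = np.sqrt(np.einsum("m,mr->r", weights, beta**2))
    return OrderParameterResult(
        vectors.coupling_type,
        vectors.residues,
        mean_unit,
        beta,
        s,
        s**2,
        rms_beta,
        valid,
        weights,
    )


def mean_orientation_model(
    vectors: BondVectorSet, weights: np.ndarray | None = None
) -> BondVectorSet:
    """Single-member vector set holding the renormalized mean orientations.

    This is the averaged-orientation comparison model: every bond adopts its
    ensemble-averaged direction, discarding the distribution around it.
    Residues with undefined means are dropped.
    """
    result = order_parameters(vectors, weights)
    keep = result.valid
    return BondVectorSet(
        vectors.coupling_type,
        vectors.residues[keep],
        result.mean_vectors[None, keep, :],
        ["<mean>"],
    )


@dataclass
class SplitFitReport:
    """H50%/L50% disorder split and (after fitting) the per-set comparison."""

    metric: dict[int, float]  # residue -> rms beta (radians)
    l50: list[int]
    h50: list[int]
    fit_l50: FitResult | None = None
    fit_h50: FitResult | None = None
    da_ratio: float | None = None  # Da(H50) / Da(L50)
    q_l50: float | None = None
    q_h50: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "l50": self.l50,
            "h50": self.h50,
            "da_l50_hz": self.fit_l50.tensor.da if self.fit_l50 else None,
            "da_h50_hz": self.fit_h50.tensor.da if self.fit_h50 else None,
            "da_ratio_h50_over_l50": self.da_ratio,
            "q_l50": self.q_l50,
            "q_h50": self.q_h50,
            "notes": self.notes,
        }


def rank_and_split(result: OrderParameterResult, metric: str = "rms_beta") -> SplitFitReport:
    """Rank residues by disorder and split at the median into H50%/L50%.

    ``metric`` is ``"rms_beta"`` (default) or ``"one_minus_s"``.  Ties are
    broken by residue number, the lower residue going to L50; with an odd
    count the extra residue goes to L50.
    """
    resids = result.residues[result.valid]
    if metric == "rms_beta":
        values = result.rms_beta[result.valid]
    elif metric == "one_minus_s":
        values = 1.0 - result.s[result.valid]
    else:
        raise ValueError("metric must be 'rms_beta' or 'one_minus_s'")
    if resids.size < 2:
        raise EmptySelectionError("need >=2 scored residues to split")
    lookup = {int(r): float(v) for r, v in zip(resids, values)}
    # descending disorder; among ties the higher residue number ranks first,
    # so the lower residue number falls into L50
    ranked = sorted(lookup, key=lambda r: (-lookup[r], -r))
    n_h = len(ranked) // 2
    h50 = sorted(ranked[:n_h])
    l50 = sorted(ranked[n_h:])
    return SplitFitReport(lookup, l50, h50)


def split_fit_compare(
    vectors: BondVectorSet | list[BondVectorSet],
    table: RDCTable,
    report: SplitFitReport,
    weights: np.ndarray | None = None,
    **fit_kwargs,
) -> SplitFitReport:
    """Independent tensor fits to the L50% and H50% residue sets.

    A Da(H50)/Da(L50) ratio far from 1 signals motional amplitudes in the
    ensemble that are inconsistent with the measured couplings (too large when
    the ratio exceeds 1).
    """
    vsets = vectors if isinstance(vectors, list) else [vectors]
    fits = {}
    for name, resids in (("L50", report.l50), ("H50", report.h50)):
        sub = table.select(resids=resids)
        if len(sub) < 5:
            raise UnderDeterminedError(
                f"{name} set has {len(sub)} records; >=5 required"
            )
        subsets = [vs.subset(resids) for vs in vsets]
        fits[name] = svd_fit_tensor(subsets, sub, weights, **fit_kwargs)
    report.fit_l50 = fits["L50"]
    report.fit_h50 = fits["H50"]
    report.da_ratio = float(fits["H50"].tensor.da / fits["L50"].tensor.da)
    report.q_l50 = fits["L50"].q
    report.q_h50 = fits["H50"].q
    if abs(report.da_ratio - 1.0) > 0.05:
        report.notes.append(
            f"Da(H50)/Da(L50) = {report.da_ratio:.3f}: motional amplitudes of the "
            "disordered half look inconsistent with the couplings"
        )
    return report


def averaged_model_fit(
    vectors: BondVectorSet,
    table: RDCTable,
    weights: np.ndarray | None = None,
    **fit_kwargs,
) -> FitResult:
    """Fit couplings to the single averaged-orientation model.

    Each bond vector is replaced by its renormalized ensemble mean before
    fitting; comparing this Q with the ensemble-fit Q separates
    orientation-averaging gains from genuine distribution (dynamics) gains.
    """
    model = mean_orientation_model(vectors, weights)
    return svd_fit_tensor(model, table, np.array([1.0]), **fit_kwargs)
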