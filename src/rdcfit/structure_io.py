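"""Coordinate input/output and geometric preparation of conformer ensembles.

Reads PDB/mmCIF files (optionally gzipped) into :class:`Conformer` objects,
normalizes same-sequence chains into a :class:`ConformerEnsemble`, builds
missing amide hydrogens with idealized planar geometry, extracts unit
internuclear bond vectors for the supported coupling types, and superposes
ensemble members with the Kabsch algorithm (proper rotations only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .couplings import get_coupling
from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    FormatError,
)

logger = logging.getLogger("rdcfit")

NH_BOND_LENGTH = 1.02  # Angstrom; fixed for reproducibility


@dataclass
class Conformer:
    """A single protein chain (or model) with author residue numbering.

    ``residues`` maps residue index -> (3-letter residue name,
    {atom name -> position [Angstrom]}).
    """

    id: str
    residues: dict[int, tuple[str, dict[str, np.ndarray]]]
    resolution: float | None = None
    space_group: str | None = None

    def __post_init__(self) -> None:
        for resid, (_, atoms) in self.residues.items():
            for name, pos in atoms.items():
                if not np.all(np.isfinite(pos)):
                    raise FormatError(
                        f"{self.id}: non-finite position for {resid}:{name}"
                    )

    @property
    def resids(self) -> list[int]:
        return sorted(self.residues)

    def resname(self, resid: int) -> str | None:
        entry = self.residues.get(resid)
        return entry[0] if entry else None

    def position(self, resid: int, atom: str) -> np.ndarray | None:
        entry = self.residues.get(resid)
        if entry is None:
            return None
        return entry[1].get(atom)

    def has_atom(self, resid: int, atom: str) -> bool:
        return self.position(resid, atom) is not None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        """Return a copy with every position mapped to R @ x + t."""
        new = {}
        for resid, (rname, atoms) in self.residues.items():
            new[resid] = (
                rname,
                {a: rotation @ p + translation for a, p in atoms.items()},
            )
        return Conformer(self.id, new, self.resolution, self.space_group)


@dataclass
class ConformerEnsemble:
    """Same-sequence conformers with per-member weights summing to 1."""

    members: list[Conformer]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.members:
            raise EmptySelectionError("ensemble needs at least one member")
        if self.weights is None:
            self.weights = np.full(len(self.members), 1.0 / len(self.members))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.members),):
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    def __len__(self) -> int:
        return len(self.members)

    def common_resids(self) -> list[int]:
        """Residue indices present in every member with matching residue names."""
        common = set(self.members[0].resids)
        for m in self.members[1:]:
            common &= set(m.resids)
        keep = []
        for resid in sorted(common):
            names = {m.resname(resid) for m in self.members}
            if len(names) == 1:
                keep.append(resid)
            else:
                logger.warning(
                    "residue %d excluded: name mismatch across members (%s)",
                    resid,
                    sorted(n for n in names if n),
                )
        return keep


@dataclass
class BondVectorSet:
    """Unit internuclear vectors for one coupling type over an ensemble.

    ``vectors`` has shape (n_members, n_residues, 3); rows of the last axis
    are unit vectors from the first-named registry atom to the second.
    Residue keys follow the first atom's residue index.
    """

    coupling_type: str
    residues: np.ndarray  # (n_residues,) int
    vectors: np.ndarray  # (n_members, n_residues, 3)
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[1] != len(self.residues):
            raise ValueError("vectors must have shape (members, residues, 3)")
        norms = np.linalg.norm(self.vectors, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("bond vectors must be unit length")
        get_coupling(self.coupling_type)

    @property
    def n_members(self) -> int:
        return self.vectors.shape[0]

    def residue_index(self, resid: int) -> int:
        idx = np.flatnonzero(self.residues == resid)
        if idx.size == 0:
            raise KeyError(resid)
        return int(idx[0])

    def subset(self, resids: Iterable[int]) -> "BondVectorSet":
        wanted = [r for r in self.residues if r in set(resids)]
        cols = [self.residue_index(r) for r in wanted]
        return BondVectorSet(
            self.coupling_type,
            np.asarray(wanted),
            self.vectors[:, cols, :],
            self.member_ids,
        )

    def single_member(self, index: int) -> "BondVectorSet":
        ids = [self.member_ids[index]] if self.member_ids else []
        return BondVectorSet(
            self.coupling_type, self.residues, self.vectors[index : index + 1], ids
        )


# ---------------------------------------------------------------------------
# loading


def _resolve_altlocs(res: gemmi.Residue) -> dict[str, np.ndarray]:
    """Pick one position per atom name: highest occupancy, tie -> altloc 'A'."""
    best: dict[str, tuple[float, str, np.ndarray]] = {}
    for atom in res:
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        key = (-(atom.occ if atom.occ else 1.0), atom.altloc or "")
        cur = best.get(atom.name)
        if cur is None or key < (cur[0], cur[1]):
            best[atom.name] = (key[0], key[1], pos)
    return {name: pos for name, (_, _, pos) in best.items()}


def load_conformers(
    paths: Sequence[str | Path],
    chain_selector: str = "A",
    resolution_cutoff: float | None = None,
) -> list[Conformer]:
    """Read coordinate files into one Conformer per matching chain (and model).

    Parameters
    ----------
    paths:
        PDB or mmCIF files; ``.gz`` accepted.
    chain_selector:
        Comma-separated chain names, or ``"*"`` for all chains.
    resolution_cutoff:
        Drop conformers whose entry resolution exceeds this value (Angstrom);
        entries with unknown resolution are kept.
    """
    wanted = None if chain_selector == "*" else set(chain_selector.split(","))
    out: list[Conformer] = []
    for path in paths:
        path = Path(path)
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        resolution = st.resolution if st.resolution > 0 else None
        if (
            resolution_cutoff is not None
            and resolution is not None
            and resolution > resolution_cutoff
        ):
            logger.info("%s: resolution %.2f above cutoff, skipped", path, resolution)
            continue
        space_group = st.spacegroup_hm or None
        matched = False
        multi_model = len(st) > 1
        for model in st:
            for chain in model:
                if wanted is not None and chain.name not in wanted:
                    continue
                residues: dict[int, tuple[str, dict[str, np.ndarray]]] = {}
                last = None
                for res in chain:
                    info = gemmi.find_tabulated_residue(res.name)
                    if info is None or not info.is_amino_acid():
                        continue
                    num = res.seqid.num
                    if last is not None and num <= last:
                        logger.warning(
                            "%s chain %s: residue %d out of order/duplicated, skipped",
                            path,
                            chain.name,
                            num,
                        )
                        continue
                    residues[num] = (res.name, _resolve_altlocs(res))
                    last = num
                if not residues:
                    continue
                cid = f"{path.stem.removesuffix('.pdb')}:{chain.name}"
                if multi_model:
                    cid += f":model{model.num}"
                out.append(Conformer(cid, residues, resolution, space_group))
                matched = True
        if not matched:
            logger.warning("%s: no chain matched selector %r", path, chain_selector)
    if not out:
        raise EmptySelectionError("no conformers left after chain/resolution filters")
    return out


# ---------------------------------------------------------------------------
# amide hydrogen building


def build_amide_hydrogens(conformer: Conformer) -> Conformer:
    """Add missing backbone amide hydrogens with idealized planar geometry.

    H is placed in the C'(i-1)-N(i)-CA(i) plane, opposite the bisector of the
    C'->N and CA->N directions, at 1.02 A from N.  Prolines, the first residue
    and residues lacking a preceding carbonyl carbon are skipped; experimental
    hydrogens already present are kept untouched.
    """
    residues = {r: (n, dict(a)) for r, (n, a) in conformer.residues.items()}
    resids = sorted(residues)
    for resid in resids:
        rname, atoms = residues[resid]
        if rname == "PRO" or "H" in atoms:
            continue
        n_pos = atoms.get("N")
        ca_pos = atoms.get("CA")
        prev = residues.get(resid - 1)
        if resid - 1 not in residues or resid == resids[0]:
            continue
        c_prev = prev[1].get("C") if prev else None
        if n_pos is None or ca_pos is None or c_prev is None:
            logger.warning(
                "%s: residue %d skipped for H building (missing N/CA/C')",
                conformer.id,
                resid,
            )
            continue
        u1 = c_prev - n_pos
        u2 = ca_pos - n_pos
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bisector = u1 + u2
        norm = np.linalg.norm(bisector)
        if norm < 1e-9:
            logger.warning(
                "%s: residue %d skipped for H building (collinear C'-N-CA)",
                conformer.id,
                resid,
            )
            continue
        atoms["H"] = n_pos - NH_BOND_LENGTH * bisector / norm
    return Conformer(conformer.id, residues, conformer.resolution, conformer.space_group)


# ---------------------------------------------------------------------------
# bond vectors


def extract_bond_vectors(
    ensemble: ConformerEnsemble, coupling_type: str
) -> BondVectorSet:
    """Unit bond vectors for one coupling type over the common residue set.

    Residues missing either atom in any member are excluded (logged); the
    vector points from the registry's first atom to its second.  For couplings
    spanning the peptide bond the key residue is that of the first atom.
    """
    ct = get_coupling(coupling_type)
    common = ensemble.common_resids()
    usable = []
    for resid in common:
        resid_j = resid + ct.offset_j
        if ct.offset_j and resid_j not in common:
            continue
        ok = all(
            m.has_atom(resid, ct.atom_i) and m.has_atom(resid_j, ct.atom_j)
            for m in ensemble.members
        )
        if ok:
            usable.append(resid)
        else:
            logger.info(
                "residue %d excluded from %s vectors (missing atoms)", resid, ct.name
            )
    if not usable:
        raise EmptySelectionError(f"no residues with complete {ct.name} atoms")
    vectors = np.empty((len(ensemble), len(usable), 3))
    for mi, member in enumerate(ensemble.members):
        for ri, resid in enumerate(usable):
            a = member.position(resid, ct.atom_i)
            b = member.position(resid + ct.offset_j, ct.atom_j)
            v = b - a
            vectors[mi, ri] = v / np.linalg.norm(v)
    return BondVectorSet(
        ct.name, np.asarray(usable), vectors, [m.id for m in ensemble.members]
    )


# ---------------------------------------------------------------------------
# superposition


@dataclass
class SuperpositionResult:
    ensemble: ConformerEnsemble
    per_member_rmsd: np.ndarray  # Angstrom, vs reference over the fit selection
    pooled_rmsd: float
    rotations: list[np.ndarray]
    translations: list[np.ndarray]


def _kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det=+1) minimizing RMSD of centered point sets."""
    cov = moving.T @ target
    u, s, vt = np.linalg.svd(cov)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "superposition selection is rank-deficient (collinear atoms)"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def kabsch_superpose(
    ensemble: ConformerEnsemble,
    fit_range: tuple[int, int] | None = None,
    exclude: Iterable[int] = (),
    reference: str = "first",
) -> SuperpositionResult:
    """Superpose all members on C-alpha atoms of ``fit_range`` minus ``exclude``.

    ``reference="first"`` fits to member 1; ``reference="mean"`` runs a second
    pass against the unweighted mean structure of the first-pass result.
    Internal geometry of every member is preserved exactly (rigid-body moves).
    """
    excl = set(exclude)
    common = ensemble.common_resids()
    sel = [
        r
        for r in common
        if (fit_range is None or fit_range[0] <= r <= fit_range[1])
        and r not in excl
        and all(m.has_atom(r, "CA") for m in ensemble.members)
    ]
    if len(sel) < 3:
        raise DegenerateGeometryError(
            f"need >=3 shared C-alpha atoms in fit selection, have {len(sel)}"
        )

    def coords(member: Conformer) -> np.ndarray:
        return np.array([member.position(r, "CA") for r in sel])

    def fit_to(
        members_in: list[Conformer], target: np.ndarray
    ) -> tuple[list[Conformer], list, list, np.ndarray]:
        t_cent = target.mean(axis=0)
        members, rots, trans, rmsds = [], [], [], []
        for member in members_in:
            x = coords(member)
            x_cent = x.mean(axis=0)
            rot = _kabsch_rotation(x - x_cent, target - t_cent)
            shift = t_cent - rot @ x_cent
            members.append(member.transformed(rot, shift))
            rots.append(rot)
            trans.append(shift)
            fitted = (x - x_cent) @ rot.T + t_cent
            rmsds.append(float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1)))))
        return members, rots, trans, np.array(rmsds)

    target = coords(ensemble.members[0])
    members, rots, trans, rmsds = fit_to(ensemble.members, target)
    if reference == "mean":
        mean_coords = np.mean([coords(m) for m in members], axis=0)
        members, rots2, trans2, rmsds = fit_to(members, mean_coords)
        rots = [r2 @ r1 for r1, r2 in zip(rots, rots2)]
        trans = [r2 @ t1 + t2 for t1, t2, r2 in zip(trans, trans2, rots2)]
    elif reference != "first":
        raise ValueError("reference must be 'first' or 'mean'")
    # pooled rmsd: spread of all members about their mean over the selection
    stack = np.array([[m.position(r, "CA") for r in sel] for m in members])
    pooled = float(np.sqrt(np.mean(np.sum((stack - stack.mean(axis=0)) ** 2, axis=2))))
    return SuperpositionResult(
        ConformerEnsemble(members, ensemble.weights), rmsds, pooled, rots, trans
    )


# ---------------------------------------------------------------------------
# PDB writing


def write_ensemble_pdb(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write the ensemble as a fixed-column multi-MODEL PDB file."""
    lines = []
    for mi, member in enumerate(ensemble.members, start=1):
        lines.append(f"MODEL     {mi:4d}")
        serial = 0
        for resid in member.resids:
            rname, atoms = member.residues[resid]
            for aname in sorted(atoms, key=_atom_sort_key):
                serial += 1
                x, y, z = atoms[aname]
                name_field = aname if len(aname) == 4 else f" {aname:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name_field}"
                    f" {rname:>3s} A{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {aname[0]:>2s}"
                )
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_BACKBONE_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4, "H": 5, "HA": 6}


def _atom_sort_key(name: str) -> tuple[int, str]:
    return (_BACKBONE_ORDER.get(name, 99), name)
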