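"""Registry of supported backbone coupling types.

Each one-bond (or two-bond) dipolar coupling connects two backbone atoms,
possibly across a peptide bond.  The registry records which atoms define the
internuclear vector, the gyromagnetic ratios of the two nuclei and a standard
internuclear distance, from which per-type scale factors onto the amide N-H
reference scale are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError

# Gyromagnetic ratios, rad s^-1 T^-1 (1H, 15N, 13C).
GAMMA = {
    "H": 26.7522128e7,
    "N": -2.71261804e7,
    "C": 6.728284e7,
}


@dataclass(frozen=True)
class CouplingType:
    """A dipolar coupling between two named backbone atoms.

    ``offset_j`` is the residue offset of the second atom relative to the
    first (1 for couplings that span the peptide bond, e.g. C'(i)-N(i+1)).
    ``r_ab`` is the standard internuclear distance in Angstrom.
    """

    name: str
    atom_i: str
    atom_j: str
    offset_j: int
    nucleus_i: str
    nucleus_j: str
    r_ab: float

    @property
    def dipolar_strength(self) -> float:
        """Signed gamma_i * gamma_j / r^3 (arbitrary common units)."""
        return GAMMA[self.nucleus_i] * GAMMA[self.nucleus_j] / self.r_ab**3


#: Supported coupling types.  NH is the reference scale.
REGISTRY: dict[str, CouplingType] = {
    "NH": CouplingType("NH", "N", "H", 0, "N", "H", 1.02),
    "CaHa": CouplingType("CaHa", "CA", "HA", 0, "C", "H", 1.09),
    "C'N": CouplingType("C'N", "C", "N", 1, "C", "N", 1.329),
    "C'Ca": CouplingType("C'Ca", "C", "CA", 0, "C", "C", 1.525),
    # two-bond C'(i)-HN(i+1); distance for a trans peptide plane
    "C'H": CouplingType("C'H", "C", "H", 1, "C", "H", 2.05),
}

_ATOM_PAIR_TO_TYPE = {(t.atom_i, t.atom_j): t.name for t in REGISTRY.values()}


def get_coupling(name: str) -> CouplingType:
    try:
        return REGISTRY[name]
    except KeyError:
        raise FormatError(
            f"unknown coupling type {name!r}; supported: {sorted(REGISTRY)}"
        ) from None


def coupling_from_atom_pair(atom_i: str, atom_j: str) -> str:
    """Infer the coupling-type name from the two atom names (PALES/DC tables)."""
    key = (atom_i.upper(), atom_j.upper().replace("HN", "H"))
    if key in _ATOM_PAIR_TO_TYPE:
        return _ATOM_PAIR_TO_TYPE[key]
    raise FormatError(f"no coupling type for atom pair {atom_i}-{atom_j}")


def nh_scale_factor(name: str) -> float:
    """Signed factor that maps a coupling of this type onto the NH scale.

    Multiplying a measured coupling by this factor expresses it in the units
    of an amide N-H coupling experiencing the same alignment:
    (gammaN*gammaH/rNH^3) / (gammaA*gammaB/rAB^3).  Exactly 1 for NH.
    """
    ct = get_coupling(name)
    return REGISTRY["NH"].dipolar_strength / ct.dipolar_strength
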