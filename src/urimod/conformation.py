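"""Per-residue ribose pucker (pseudorotation) and glycosidic-angle
classification.

The five endocyclic ribose torsions nu0..nu4 are reduced to the
Altona-Sundaralingam pseudorotation phase P and puckering amplitude
nu_max; P is then binned into the ten canonical envelope/twist classes
(36-degree bins centred on C3'-endo = 18 degrees).  The glycosidic
torsion chi is classified syn for chi in [-90, +90] (inclusive at both
boundaries) and anti otherwise.  Pseudouridine's C-glycosidic bond is
handled by measuring chi over O4'-C1'-C5-C4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import components
from .geometry import UndefinedTorsionError, torsion_angle

__all__ = [
    "ConformationCall", "PUCKER_CLASSES", "pseudorotation_from_torsions",
    "torsions_from_pseudorotation", "ring_torsions", "pseudorotation_pucker",
    "chi", "classify_residue", "MissingAtomsError",
]

#: Canonical pucker classes in pseudorotation order; class k spans
#: P in [36k, 36(k+1)) with ideal phase 18 + 36k.
PUCKER_CLASSES: tuple[str, ...] = (
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
)

UNSPECIFIED = "UNSPECIFIED"

#: Amplitude below which the ring is too flat to classify.
AMPLITUDE_FLOOR = 5.0

#: Torsion atom quadruples for nu0..nu4 in ring order
#: (O4', C1', C2', C3', C4'); nu_j is the torsion about the bond between
#: ring atoms j+1 and j+2 (mod 5) starting from nu0 about O4'-C1'.
NU_ATOMS: tuple[tuple[str, str, str, str], ...] = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

_SIN36 = math.sin(math.radians(36.0))
_SIN72 = math.sin(math.radians(72.0))


class MissingAtomsError(KeyError):
    """A required atom is absent from the residue."""


@dataclass(frozen=True)
class ConformationCall:
    """Pucker and glycosidic classification for one residue."""

    P: float | None = None
    nu_max: float | None = None
    pucker_class: str = UNSPECIFIED
    chi: float | None = None
    chi_class: str = "unspecified"
    chi_atoms: tuple[str, str, str, str] | None = None


def pseudorotation_from_torsions(nu) -> tuple[float, float]:
    """(P, nu_max) from the five endocyclic torsions (degrees).

    Uses the Altona-Sundaralingam relation
    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72)),
    evaluated with atan2 so the full [0, 360) range is recovered; nu_max
    is the amplitude nu2 / cos P.
    """
    nu0, nu1, nu2, nu3, nu4 = (float(v) for v in nu)
    num = (nu4 + nu1) - (nu3 + nu0)
    den = 2.0 * nu2 * (_SIN36 + _SIN72)
    if num == 0.0 and den == 0.0:
        return 0.0, 0.0
    p = math.degrees(math.atan2(num, den)) % 360.0
    cos_p = math.cos(math.radians(p))
    if abs(cos_p) > 1e-8:
        nu_max = nu2 / cos_p
    else:
        nu_max = num / (2.0 * (_SIN36 + _SIN72) * math.sin(math.radians(p)))
    return p, abs(nu_max)


def torsions_from_pseudorotation(P: float, nu_max: float) -> tuple[float, ...]:
    """Closed-form endocyclic torsions nu_j = nu_max cos(P + 144(j - 2))."""
    return tuple(nu_max * math.cos(math.radians(P + 144.0 * (j - 2)))
                 for j in range(5))


def classify_phase(P: float, nu_max: float,
                   amplitude_floor: float = AMPLITUDE_FLOOR) -> str:
    """Canonical pucker class with the nearest ideal phase (36-degree bins)."""
    if nu_max < amplitude_floor:
        return UNSPECIFIED
    return PUCKER_CLASSES[int((P % 360.0) // 36.0) % 10]


def _atom_pos(residue, name: str):
    atom = residue.get_atom(name)
    if atom is None:
        raise MissingAtomsError(name)
    return atom.pos


def ring_torsions(residue) -> tuple[float, ...]:
    """nu0..nu4 measured from the residue's ribose ring atoms."""
    return tuple(torsion_angle(*(_atom_pos(residue, n) for n in quad))
                 for quad in NU_ATOMS)


def pseudorotation_pucker(residue,
                          amplitude_floor: float = AMPLITUDE_FLOOR) -> ConformationCall:
    """Pucker classification of a screened residue.

    Raises :class:`MissingAtomsError` if a ring atom is absent.
    """
    nu = ring_torsions(residue)
    p, nu_max = pseudorotation_from_torsions(nu)
    return ConformationCall(P=p, nu_max=nu_max,
                            pucker_class=classify_phase(p, nu_max, amplitude_floor))


def chi(residue, comp_id: str | None = None) -> ConformationCall:
    """Glycosidic torsion and syn/anti classification.

    ``comp_id`` defaults to the residue's own component code; unknown
    components or missing atoms degrade to an unspecified call rather
    than raising (mirroring annotation tools that report 'unspecified'
    glycosidic angles they cannot assign).
    """
    comp_id = (comp_id or residue.comp_id).upper()
    atoms = components.chi_atom_chain(comp_id)
    if atoms is None:
        return ConformationCall()
    try:
        pos = [_atom_pos(residue, n) for n in atoms]
        angle = torsion_angle(*pos)
    except (MissingAtomsError, UndefinedTorsionError):
        return ConformationCall(chi_atoms=atoms)
    cls = "syn" if -90.0 <= angle <= 90.0 else "anti"
    return ConformationCall(chi=angle, chi_class=cls, chi_atoms=atoms)


def classify_residue(residue, amplitude_floor: float = AMPLITUDE_FLOOR) -> ConformationCall:
    """Combined pucker + chi call for one screened residue.

    Missing ring atoms leave the pucker fields unspecified instead of
    raising, so whole-structure tabulation never aborts on a damaged
    residue.
    """
    try:
        pucker = pseudorotation_pucker(residue, amplitude_floor)
    except (MissingAtomsError, UndefinedTorsionError):
        pucker = ConformationCall()
    chi_call = chi(residue)
    return ConformationCall(P=pucker.P, nu_max=pucker.nu_max,
                            pucker_class=pucker.pucker_class,
                            chi=chi_call.chi, chi_class=chi_call.chi_class,
                            chi_atoms=chi_call.chi_atoms)
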