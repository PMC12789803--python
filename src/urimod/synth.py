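"""Synthetic RNA structure generator with ground-truth manifests.

Builds idealized hairpins (A-form stems closed by smooth-arc loops),
places the six uridine modifications by local chemistry edits, wraps
entries into NMR-like ensembles with a planted representative, and emits
whole labelled datasets as mmCIF files -- so every pipeline stage can be
exercised against known answers without any external structure files.

Construction notes
------------------
* Each nucleotide is built from internal coordinates (NeRF chain
  extension).  The ribose ring is solved numerically so its
  Altona-Sundaralingam phase and amplitude hit the requested values; the
  base is planar and the glycosidic torsion chi is set exactly.
* Stems use fibre-diffraction A-form parameters (rise 2.81 A, twist
  32.7 deg); Watson-Crick-Franklin partners are placed by least-squares
  anchor fitting so donor-acceptor distances land near 2.85 A.
* Loops fan nucleotides along a semicircular arc bridging the closing
  pair, bases pointing outward, which keeps loop residues unpaired.
* All randomness is seeded; identical specs give identical coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.optimize import fsolve

from . import components
from .conformation import pseudorotation_from_torsions
from .geometry import kabsch_superpose, CoordinateSet, torsion_angle
from .structure_io import (Atom, Model, Residue, StructureEntry,
                           EM, NMR, OTHER, XRAY, write_structure)

__all__ = [
    "GeneratorSpec", "Manifest", "GenerationError", "build_hairpin",
    "apply_modification", "make_ensemble", "DatasetPlan", "EntryPlan",
    "generate_dataset", "default_study_plan",
]

RISE = 2.81      # A-form helical rise, Angstrom
TWIST = 32.7     # A-form helical twist, degrees
HBOND_LEN = 2.85  # target donor-acceptor distance in built pairs


class GenerationError(ValueError):
    """Requested geometry cannot be built."""


# ---------------------------------------------------------------------------
# NeRF primitives

def _nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion (degrees, IUPAC sign)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


# ---------------------------------------------------------------------------
# ribose ring with prescribed pseudorotation

_RING_NAMES = ("O4'", "C1'", "C2'", "C3'", "C4'")


@lru_cache(maxsize=256)
def _ring_template(P: float, nu_max: float) -> tuple[tuple[float, float, float], ...]:
    """Five ribose ring atom positions whose Altona-Sundaralingam phase
    and amplitude equal (P, nu_max).

    The ring is parametrized as a pentagon with out-of-plane puckering
    displacements z_j = sqrt(2/5) q cos(phi + 4 pi j / 5); (phi, q) are
    solved so the measured torsion-space phase hits the target.
    """
    radius = 1.53 / (2.0 * math.sin(math.pi / 5.0)) * 0.985

    def ring_coords(phi_deg: float, q: float) -> np.ndarray:
        pts = []
        for j in range(5):
            theta = math.radians(72.0 * j)
            z = math.sqrt(0.4) * q * math.cos(math.radians(phi_deg) + 0.8 * math.pi * j)
            pts.append([radius * math.cos(theta), radius * math.sin(theta), z])
        return np.asarray(pts)

    def measured(phi_deg: float, q: float) -> tuple[float, float]:
        pts = ring_coords(phi_deg, q)
        nu = [torsion_angle(pts[(1 + j) % 5], pts[(2 + j) % 5],
                            pts[(3 + j) % 5], pts[(4 + j) % 5])
              for j in range(5)]
        # nu0 is C4'-O4'-C1'-C2' = atoms (4,0,1,2) -> j offset 3
        nu = nu[3:] + nu[:3]
        return pseudorotation_from_torsions(nu)

    if nu_max < 1e-6:
        return tuple(map(tuple, ring_coords(0.0, 0.0)))

    def residual(x):
        phi, q = x
        p_m, nm_m = measured(phi, abs(q))
        dp = ((p_m - P + 180.0) % 360.0) - 180.0
        return [dp, nm_m - nu_max]

    sol = None
    for phi0 in (P + 90.0, P - 90.0, P, P + 180.0):
        x, info, ier, _ = fsolve(residual, x0=[phi0, 0.4 * nu_max / 38.0],
                                 full_output=True)
        if ier == 1:
            sol = x
            break
    if sol is None:
        raise GenerationError(f"ring solve failed for P={P}, nu_max={nu_max}")
    return tuple(map(tuple, ring_coords(sol[0], abs(sol[1]))))


# ---------------------------------------------------------------------------
# whole-nucleotide construction

def _build_base(atoms: dict[str, np.ndarray], comp_id: str, chi: float) -> None:
    """Attach a planar base to the sugar in ``atoms`` (modified in place).

    For N-glycosides the ring runs N1(C2..) / N9(C4..); pseudouridine
    attaches through C5 and its chi is measured over O4'-C1'-C5-C4.
    """
    c4p, o4p, c1p = atoms["C4'"], atoms["O4'"], atoms["C1'"]
    nu0 = torsion_angle(c4p, o4p, c1p, atoms["C2'"])
    comp = components.component(comp_id)
    purine = comp is not None and comp.purine

    def put(name, a, b, c, bond, angle, tor):
        atoms[name] = _nerf(atoms[a] if isinstance(a, str) else a,
                            atoms[b] if isinstance(b, str) else b,
                            atoms[c] if isinstance(c, str) else c,
                            bond, angle, tor)

    glyco_tor = nu0 - 120.0
    if comp_id == "PSU":
        put("C5", c4p, o4p, c1p, 1.50, 110.0, glyco_tor)
        put("C4", "O4'", "C1'", "C5", 1.44, 117.0, chi)
        put("N3", "C1'", "C5", "C4", 1.38, 120.0, 180.0)
        put("C2", "C5", "C4", "N3", 1.38, 120.0, 0.0)
        put("N1", "C4", "N3", "C2", 1.38, 120.0, 0.0)
        put("C6", "N3", "C2", "N1", 1.38, 120.0, 0.0)
        put("O4", "C1'", "C5", "C4", 1.23, 120.0, 0.0)
        put("O2", "C4", "N3", "C2", 1.23, 120.0, 180.0)
        return
    if purine:
        put("N9", c4p, o4p, c1p, 1.46, 108.0, glyco_tor)
        put("C4", "O4'", "C1'", "N9", 1.37, 127.0, chi)
        put("C5", "C1'", "N9", "C4", 1.38, 132.0, 180.0)
        put("C6", "N9", "C4", "C5", 1.41, 120.0, 180.0)
        put("N1", "C4", "C5", "C6", 1.36, 120.0, 0.0)
        put("C2", "C5", "C6", "N1", 1.33, 120.0, 0.0)
        put("N3", "C6", "N1", "C2", 1.33, 120.0, 0.0)
        put("N7", "N9", "C4", "C5", 1.39, 110.0, 0.0)
        put("C8", "C4", "C5", "N7", 1.33, 104.0, 0.0)
        if comp_id == "A":
            put("N6", "C4", "C5", "C6", 1.34, 120.0, 180.0)
        else:  # G
            put("O6", "C4", "C5", "C6", 1.23, 120.0, 180.0)
            put("N2", "C6", "N1", "C2", 1.34, 120.0, 180.0)
        return
    # pyrimidines (U-like, C)
    put("N1", c4p, o4p, c1p, 1.48, 108.0, glyco_tor)
    put("C2", "O4'", "C1'", "N1", 1.37, 117.0, chi)
    put("N3", "C1'", "N1", "C2", 1.38, 120.0, 180.0)
    put("C4", "N1", "C2", "N3", 1.38, 120.0, 0.0)
    put("C5", "C2", "N3", "C4", 1.38, 120.0, 0.0)
    put("C6", "N3", "C4", "C5", 1.38, 120.0, 0.0)
    put("O2", "C1'", "N1", "C2", 1.23, 120.0, 0.0)
    if comp_id == "C":
        put("N4", "C2", "N3", "C4", 1.34, 120.0, 180.0)
    else:
        put("O4", "C2", "N3", "C4", 1.23, 120.0, 180.0)


_ELEMENTS = {"P": "P", "S": "S", "O": "O", "N": "N", "C": "C"}


def _element_of(name: str) -> str:
    return _ELEMENTS.get(name[0], "C")


def build_nucleotide(comp_id: str, pucker_P: float = 18.0,
                     nu_max: float = 38.0, chi: float = -160.0) -> dict[str, np.ndarray]:
    """Full heavy-atom nucleotide in a local frame.

    Sugar pucker (phase, amplitude) and glycosidic torsion are built in
    exactly; backbone substituents use idealized internal coordinates.
    """
    comp_id = comp_id.upper()
    ring = _ring_template(round(pucker_P, 3), round(nu_max, 3))
    atoms: dict[str, np.ndarray] = {
        name: np.asarray(pos) for name, pos in zip(_RING_NAMES, ring)}
    nu1 = torsion_angle(atoms["O4'"], atoms["C1'"], atoms["C2'"], atoms["C3'"])
    nu2 = torsion_angle(atoms["C1'"], atoms["C2'"], atoms["C3'"], atoms["C4'"])
    nu3 = torsion_angle(atoms["C2'"], atoms["C3'"], atoms["C4'"], atoms["O4'"])
    atoms["O2'"] = _nerf(atoms["O4'"], atoms["C1'"], atoms["C2'"], 1.41, 110.0,
                         nu1 + 120.0)
    atoms["O3'"] = _nerf(atoms["C1'"], atoms["C2'"], atoms["C3'"], 1.42, 110.0,
                         nu2 + 120.0)
    atoms["C5'"] = _nerf(atoms["C2'"], atoms["C3'"], atoms["C4'"], 1.51, 116.0,
                         nu3 - 120.0)
    atoms["O5'"] = _nerf(atoms["C3'"], atoms["C4'"], atoms["C5'"], 1.42, 111.0,
                         -60.0)
    atoms["P"] = _nerf(atoms["C4'"], atoms["C5'"], atoms["O5'"], 1.60, 120.0,
                       180.0)
    atoms["OP1"] = _nerf(atoms["C5'"], atoms["O5'"], atoms["P"], 1.49, 110.0,
                         60.0)
    atoms["OP2"] = _nerf(atoms["C5'"], atoms["O5'"], atoms["P"], 1.49, 110.0,
                         -60.0)
    base_parent = comp_id
    if comp_id in components.MODIFICATIONS and comp_id != "PSU":
        base_parent = "U"  # built as U, then chemically edited
    _build_base(atoms, base_parent if comp_id != "PSU" else "PSU", chi)
    return atoms


def _residue_from_atoms(atoms: dict[str, np.ndarray], comp_id: str,
                        chain_id: str, seq_num: int) -> Residue:
    order = list(components.BACKBONE_ATOMS)
    order += [n for n in atoms if n not in order]
    return Residue(comp_id=comp_id, chain_id=chain_id, seq_num=seq_num,
                   atoms=[Atom(name=n, element=_element_of(n), pos=atoms[n])
                          for n in order if n in atoms])


# ---------------------------------------------------------------------------
# base-pair and helix assembly

def _base_frame(atoms: dict[str, np.ndarray], comp_id: str):
    """(centroid, normal, transform-to-canonical-pose) of the base.

    Canonical pose: base centroid at origin, plane -> z = 0, the
    C1'->centroid direction along +x.
    """
    comp = components.component(comp_id)
    ring_names = comp.rings[0]
    pts = np.array([atoms[n] for n in ring_names])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    # deterministic sign: normal follows the ring winding (listed atom
    # order counterclockwise), so "up" is chemically consistent
    winding = np.sum(np.cross(pts - centroid, np.roll(pts, -1, axis=0) - centroid),
                     axis=0)
    if np.dot(normal, winding) < 0:
        normal = -normal
    inward = centroid - atoms["C1'"]
    inward -= np.dot(inward, normal) * normal
    x_axis = inward / np.linalg.norm(inward)
    y_axis = np.cross(normal, x_axis)
    rot = np.array([x_axis, y_axis, normal])  # rows: world -> canonical
    return centroid, normal, rot


def _to_canonical(atoms: dict[str, np.ndarray], comp_id: str) -> dict[str, np.ndarray]:
    centroid, _, rot = _base_frame(atoms, comp_id)
    return {n: rot @ (p - centroid) for n, p in atoms.items()}


_PAIR_ANCHORS: dict[frozenset, list[tuple[str, str]]] = {
    # matched (pyrimidine-side atom, partner-side atom) donor/acceptor pairs
    frozenset(("G", "C")): [("N3", "N1"), ("O2", "N2"), ("N4", "O6")],
    frozenset(("A", "U")): [("N3", "N1"), ("O4", "N6")],
    frozenset(("G", "U")): [("O2", "N1"), ("N3", "O6")],
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _pair_bonds(placed_comp: str, partner_comp: str) -> list[tuple[str, str]]:
    """Canonical (placed-side atom, partner-side atom) H-bond pairs."""
    canon_a = components.canonical_letter(placed_comp)
    canon_b = components.canonical_letter(partner_comp)
    anchors = _PAIR_ANCHORS.get(frozenset((canon_a, canon_b)))
    if anchors is None:
        raise GenerationError(f"no pair template for {placed_comp}-{partner_comp}")
    pyr_first = canon_a in ("U", "C")
    return [(a, b) if pyr_first else (b, a) for a, b in anchors]


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # proper 180-degree rotation about x


def _place_partner(placed: dict[str, np.ndarray], placed_comp: str,
                   partner: dict[str, np.ndarray], partner_comp: str,
                   hbond_len: float | None = None) -> dict[str, np.ndarray]:
    """Rigidly place ``partner`` so it forms a WCF (or wobble) pair with
    the already-placed residue.

    Both bases are put exactly in the pair plane (the partner flipped by
    a proper rotation, as the antiparallel strand requires); the
    partner's in-plane pose (two translations + rotation) is found by a
    deterministic global grid search over the rotation followed by least
    squares that drives every canonical donor-acceptor distance to
    ``hbond_len`` while penalizing non-bonded clashes.
    """
    from scipy.optimize import least_squares

    length = hbond_len if hbond_len is not None else HBOND_LEN
    bonds = _pair_bonds(placed_comp, partner_comp)
    centroid_a, normal_a, rot_a = _base_frame(placed, placed_comp)
    # work in the placed base's canonical frame (base plane = z 0)
    placed_c = {n: rot_a @ (p - centroid_a) for n, p in placed.items()}
    partner_canon = _to_canonical(partner, partner_comp)

    base_a = set(_base_atom_names_for(placed_comp)) & set(placed_c)
    base_b = set(_base_atom_names_for(partner_comp)) & set(partner_canon)
    pts_a = {n: placed_c[n] for n in base_a}
    bond_pairs = set(bonds)

    names_a = [a for a, _ in bonds]
    mid = np.mean([placed_c[n] for n in names_a], axis=0)
    u = mid.copy()
    u[2] = 0.0
    u /= np.linalg.norm(u)

    # expected C1'-C1' separation: ~10.4 A for canonical geometry, grown
    # by any interface stretch beyond the standard bond length
    c1_c1 = 10.4 + (length - 2.85)

    def make_posed(template):
        def posed(params):
            tx, ty, theta = params
            c, s = math.cos(theta), math.sin(theta)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            shift = np.array([tx, ty, 0.0])
            return {n: rot @ p + shift for n, p in template.items()}
        return posed

    def make_residuals(posed):
        def residuals(params):
            atoms = posed(params)
            res = [3.0 * (np.linalg.norm(placed_c[a] - atoms[b]) - length)
                   for a, b in bonds]
            res.append(0.5 * (np.linalg.norm(placed_c["C1'"] - atoms["C1'"])
                              - c1_c1))
            clash_a = dict(pts_a)
            clash_a["C1'"] = placed_c["C1'"]
            clash_b = set(base_b) | {"C1'"}
            for na, pa in clash_a.items():
                for nb in clash_b:
                    if (na, nb) in bond_pairs:
                        continue
                    d = np.linalg.norm(pa - atoms[nb])
                    res.append(max(0.0, 2.9 - d))
            return res
        return residuals

    # which face the partner shows (sugar above or below the pair plane)
    # interacts with the in-plane edge order; search both
    best, best_posed = None, None
    for flip in (_FLIP_X, np.eye(3)):
        template = {n: flip @ p for n, p in partner_canon.items()}
        posed = make_posed(template)
        residuals = make_residuals(posed)
        for theta_deg in range(0, 360, 30):
            theta = math.radians(theta_deg)
            c, s = math.cos(theta), math.sin(theta)
            rot2 = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            src_mid = np.mean([rot2 @ template[b] for _, b in bonds], axis=0)
            t0 = mid + length * u - src_mid
            sol = least_squares(residuals, x0=[t0[0], t0[1], theta],
                                xtol=1e-10, ftol=1e-10)
            if best is None or sol.cost < best.cost:
                best, best_posed = sol, posed
    # final polish: drive the bonds parallel and perpendicular to the
    # edge (vector targets) so cross-edge contacts keep physical lengths
    if len(bonds) >= 2:
        pts = np.array([placed_c[a] for a, _ in bonds])
        d_edge = pts[-1] - pts[0]
        d_edge[2] = 0.0
        d_edge /= np.linalg.norm(d_edge)
        axis_pair = np.array([d_edge[1], -d_edge[0], 0.0])
    else:
        axis_pair = u.copy()
    if np.dot(axis_pair, u) < 0:
        axis_pair = -axis_pair

    def vector_residuals(params):
        atoms = best_posed(params)
        res = []
        for a, b in bonds:
            res.extend(placed_c[a] + length * axis_pair - atoms[b])
        return res

    sol = least_squares(vector_residuals, x0=best.x, xtol=1e-12, ftol=1e-12)
    final = best_posed(sol.x)
    inv = rot_a.T
    return {n: inv @ p + centroid_a for n, p in final.items()}


def _base_atom_names_for(comp_id: str) -> tuple[str, ...]:
    comp = components.component(comp_id)
    names = set()
    for ring in comp.rings:
        names.update(ring)
    names.update(comp.wcf_edge)
    names.update(comp.hoogsteen_edge)
    return tuple(names)


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_STEM_CACHE: dict = {}


def _stem_pair_template(comp5: str, comp3: str, conf5: tuple, conf3: tuple):
    """Cached placed (5'-residue, 3'-partner) atom dictionaries for one
    stem pair in the pair-local frame."""
    key = (comp5, comp3, conf5, conf3)
    if key not in _STEM_CACHE:
        P5, nm5, chi5 = conf5
        P3, nm3, chi3 = conf3
        nt5 = _to_canonical(build_nucleotide(comp5, P5, nm5, chi5), comp5)
        # 5' residue in canonical pose, centred off the helix axis
        nt5 = {nme: p + np.array([-2.2, 0.0, 0.0]) for nme, p in nt5.items()}
        nt3 = _place_partner(nt5, comp5, build_nucleotide(comp3, P3, nm3, chi3),
                             comp3)
        _STEM_CACHE[key] = (nt5, nt3)
    nt5, nt3 = _STEM_CACHE[key]
    return dict(nt5), dict(nt3)


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic hairpin entry."""

    seed: int = 0
    entry_id: str = "SYN1"
    chain_id: str = "A"
    start_seq_num: int = 1
    stem_bp: int = 2
    loop_sequence: str = "UUCAAAG"
    stem_seq5: str | None = None
    modifications: tuple = ()   # (position_in_chain, comp_id) pairs, 0-based
    pucker_overrides: dict[int, tuple[float, float]] = field(default_factory=dict)
    chi_overrides: dict[int, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    n_models: int = 1
    planted_model: int = 0
    method: str = XRAY
    resolution: float | None = 2.0
    description: str = "synthetic RNA hairpin"
    organism: str | None = None

    def full_sequence(self) -> str:
        stem5 = self.stem_seq5 or ("GCGCGCGCGC"[: self.stem_bp])
        stem3 = "".join(_COMPLEMENT[c] for c in reversed(stem5))
        return stem5 + self.loop_sequence.upper() + stem3


@dataclass
class Manifest:
    """Ground truth for one generated entry."""

    entry_id: str
    chain_id: str
    start_seq_num: int
    sequence: str                  # display string (modifications lowercased)
    canonical_sequence: str
    stem_bp: int
    loop_size: int
    pairing: list = field(default_factory=list)   # (seq_num_i, seq_num_j)
    modifications: list = field(default_factory=list)  # (seq_num, comp_id)
    pucker_classes: dict = field(default_factory=dict)  # seq_num -> class
    chi_classes: dict = field(default_factory=dict)     # seq_num -> syn/anti
    representative_model: int | None = None             # 0-based, ensembles
    method: str = XRAY
    resolution: float | None = None
    defects: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _pucker_class_of(P: float) -> str:
    from .conformation import classify_phase
    return classify_phase(P, 99.0)


def build_hairpin(spec: GeneratorSpec) -> tuple[StructureEntry, Manifest]:
    """Construct a single-chain hairpin entry plus its manifest."""
    seq = spec.full_sequence()
    n = len(seq)
    loop_len = len(spec.loop_sequence)
    if not (4 <= loop_len <= 10):
        raise GenerationError("loop length must be 4-10 nt")
    if spec.stem_bp < 2:
        raise GenerationError("need at least 2 stem base pairs")

    placements: dict[int, dict[str, np.ndarray]] = {}   # chain index -> atoms
    comp_ids = {i: seq[i] for i in range(n)}

    def conf(i: int) -> tuple[float, float, float]:
        P, nm = spec.pucker_overrides.get(i, (18.0, 38.0))
        chi = spec.chi_overrides.get(i, -160.0)
        return P, nm, chi

    # --- stem: pair k occupies chain indices (k, n-1-k)
    for k in range(spec.stem_bp):
        i5, i3 = k, n - 1 - k
        nt5, nt3 = _stem_pair_template(seq[i5], seq[i3], conf(i5), conf(i3))
        rot = _rot_z(TWIST * k)
        shift = np.array([0.0, 0.0, RISE * k])
        placements[i5] = {nme: rot @ p + shift for nme, p in nt5.items()}
        placements[i3] = {nme: rot @ p + shift for nme, p in nt3.items()}

    # --- loop on a semicircular arc bridging the closing pair
    top5, top3 = spec.stem_bp - 1, n - spec.stem_bp
    p_a = placements[top5]["C1'"]
    p_b = placements[top3]["C1'"]
    centre = 0.5 * (p_a + p_b)
    x_arc = p_b - p_a
    span = np.linalg.norm(x_arc)
    x_arc /= span
    z_hat = np.array([0.0, 0.0, 1.0])
    z_arc = z_hat - np.dot(z_hat, x_arc) * x_arc
    z_arc /= np.linalg.norm(z_arc)
    radius = span / 2.0 + 1.5
    for j in range(1, loop_len + 1):
        i = top5 + j
        theta = math.pi - j * math.pi / (loop_len + 1)
        u = math.cos(theta) * x_arc + math.sin(theta) * z_arc  # radial, outward
        t = math.sin(theta) * x_arc - math.cos(theta) * z_arc  # tangent
        pos = centre + radius * u
        P, nm, chi = conf(i)
        tmpl = _to_canonical(build_nucleotide(seq[i], P, nm, chi), seq[i])
        c1 = tmpl["C1'"]
        w = np.cross(t, u)
        rot = np.column_stack([u, w, t])   # maps ex->u, ey->w, ez->t
        placements[i] = {nme: rot @ (p - c1) + pos for nme, p in tmpl.items()}

    residues = []
    for i in range(n):
        residues.append(_residue_from_atoms(
            placements[i], comp_ids[i], spec.chain_id, spec.start_seq_num + i))
    entry = StructureEntry(
        entry_id=spec.entry_id, method=spec.method,
        resolution=spec.resolution if spec.method in (XRAY, EM) else None,
        models=[Model(chains={spec.chain_id: residues})],
        molecule_descriptions={spec.chain_id: spec.description},
        organism=spec.organism)

    manifest = Manifest(
        entry_id=spec.entry_id, chain_id=spec.chain_id,
        start_seq_num=spec.start_seq_num, sequence=seq,
        canonical_sequence=seq, stem_bp=spec.stem_bp, loop_size=loop_len,
        pairing=[(spec.start_seq_num + k, spec.start_seq_num + n - 1 - k)
                 for k in range(spec.stem_bp)],
        method=spec.method,
        resolution=spec.resolution if spec.method in (XRAY, EM) else None)
    for i in range(n):
        P, nm, chi = conf(i)
        num = spec.start_seq_num + i
        manifest.pucker_classes[num] = _pucker_class_of(P)
        manifest.chi_classes[num] = "syn" if -90.0 <= chi <= 90.0 else "anti"

    # --- modifications
    display = list(seq)
    for pos, comp_id in spec.modifications:
        apply_modification(entry, pos, comp_id, chain_id=spec.chain_id)
        manifest.modifications.append((spec.start_seq_num + pos, comp_id.upper()))
        display[pos] = components.display_char(comp_id) or "u"
    manifest.sequence = "".join(display)

    # --- ensemble / noise
    if spec.n_models > 1 or spec.noise_sigma > 0:
        entry, rep = make_ensemble(entry, spec.n_models, spec.noise_sigma,
                                   spec.seed, spec.planted_model)
        manifest.representative_model = rep
        manifest.method = entry.method
        manifest.resolution = None
    return entry, manifest


def apply_modification(entry: StructureEntry, position: int, comp_id: str,
                       chain_id: str | None = None) -> None:
    """Convert the U residue at chain ``position`` (0-based) into the
    requested modification, editing every model in place.

    PSU swaps base atom names across the pseudo-dyad (N1<->C5, C2<->C4,
    O2<->O4), turning the bond to C1' into the C-glycoside while leaving
    the base footprint (and any pairing) intact.  Methylations add the
    methyl carbon; 4SU turns O4 into S4 at a C=S bond length; H2U
    puckers C5/C6 out of the base plane to mimic the saturated ring.
    """
    comp_id = comp_id.upper()
    if comp_id not in components.MODIFICATIONS:
        raise GenerationError(f"unknown modification {comp_id}")
    for model in entry.models:
        chain = model.chains[chain_id] if chain_id else next(iter(model.chains.values()))
        res = chain[position]
        if components.canonical_letter(res.comp_id) != "U":
            raise GenerationError(
                f"target at position {position} is {res.comp_id}, not U-like")
        atoms = {a.name: a.pos.copy() for a in res.atoms}
        if comp_id == "PSU":
            swap = {"N1": "C5", "C5": "N1", "C2": "C4", "C4": "C2",
                    "O2": "O4", "O4": "O2"}
            atoms = {swap.get(nme, nme): p for nme, p in atoms.items()}
        elif comp_id == "5MU":
            atoms["C5M"] = _nerf(atoms["N3"], atoms["C4"], atoms["C5"],
                                 1.50, 120.0, 180.0)
        elif comp_id == "UR3":
            atoms["C3U"] = _nerf(atoms["N1"], atoms["C2"], atoms["N3"],
                                 1.47, 120.0, 180.0)
        elif comp_id == "OMU":
            atoms["CM2"] = _nerf(atoms["C1'"], atoms["C2'"], atoms["O2'"],
                                 1.43, 114.0, -70.0)
        elif comp_id == "4SU":
            direction = atoms["O4"] - atoms["C4"]
            direction /= np.linalg.norm(direction)
            atoms["S4"] = atoms["C4"] + 1.68 * direction
            del atoms["O4"]
        elif comp_id == "H2U":
            ring = np.array([atoms[nme] for nme in
                             ("N1", "C2", "N3", "C4", "C5", "C6")])
            centroid = ring.mean(axis=0)
            _, _, vt = np.linalg.svd(ring - centroid)
            normal = vt[2]
            atoms["C5"] = atoms["C5"] + 0.25 * normal
            atoms["C6"] = atoms["C6"] - 0.25 * normal
        order = [a.name for a in res.atoms]
        if comp_id == "5MU":
            order.append("C5M")
        elif comp_id == "UR3":
            order.append("C3U")
        elif comp_id == "OMU":
            order.append("CM2")
        elif comp_id == "4SU":
            order = [("S4" if nme == "O4" else nme) for nme in order]
        res.atoms = [Atom(name=nme, element=_element_of(nme), pos=atoms[nme])
                     for nme in order if nme in atoms]
        res.comp_id = comp_id


def make_ensemble(entry: StructureEntry, n_models: int, noise_sigma: float,
                  seed: int, planted_representative: int = 0
                  ) -> tuple[StructureEntry, int]:
    """NMR-style ensemble: each model is the base coordinates plus i.i.d.
    Gaussian noise of scale ``noise_sigma`` (Angstrom); the planted model
    gets sigma/10, making it the expected representative.

    Returns (entry, planted index).
    """
    rng = np.random.default_rng(seed)
    base = entry.models[0]
    models = []
    for k in range(n_models):
        sigma = noise_sigma / 10.0 if k == planted_representative else noise_sigma
        model = Model()
        for ch, residues in base.chains.items():
            out = []
            for r in residues:
                noisy = [Atom(name=a.name, element=a.element,
                              pos=a.pos + rng.normal(0.0, sigma, 3)
                              if sigma > 0 else a.pos.copy(),
                              occupancy=a.occupancy, alt_id=a.alt_id)
                         for a in r.atoms]
                out.append(replace(r, atoms=noisy))
            model.chains[ch] = out
        models.append(model)
    new = replace(entry, method=NMR, resolution=None, models=models)
    return new, planted_representative


# ---------------------------------------------------------------------------
# labelled datasets

@dataclass
class EntryPlan:
    """One planned dataset entry (plus optional unmodified counterpart)."""

    entry_id: str
    modification: str | None          # None -> unmodified library entry
    loop_sequence: str
    mod_loop_positions: tuple = (2,)  # loop-relative indices to modify
    stem_bp: int = 2
    method: str = XRAY
    resolution: float | None = 2.0
    rna_type_text: str = "synthetic RNA hairpin construct"
    counterpart: bool = False         # also emit an unmodified library copy
    defect: str | None = None         # None | "resolution" | "missing_atom"
    planted_distinct: bool = False    # loop conformation differs from library
    n_models: int = 1
    noise_sigma: float = 0.0
    chain_id: str = "A"
    start_seq_num: int = 1
    pucker_overrides: dict = field(default_factory=dict)
    chi_overrides: dict = field(default_factory=dict)


@dataclass
class DatasetPlan:
    seed: int = 0
    entries: list = field(default_factory=list)


def _spec_from_plan(plan: EntryPlan, seed: int) -> GeneratorSpec:
    mods = ()
    if plan.modification:
        mods = tuple((plan.stem_bp + p, plan.modification)
                     for p in plan.mod_loop_positions)
    resolution = plan.resolution
    if plan.defect == "resolution":
        resolution = 3.5
    return GeneratorSpec(
        seed=seed, entry_id=plan.entry_id, chain_id=plan.chain_id,
        start_seq_num=plan.start_seq_num, stem_bp=plan.stem_bp,
        loop_sequence=plan.loop_sequence, modifications=mods,
        pucker_overrides=plan.pucker_overrides,
        chi_overrides=plan.chi_overrides,
        noise_sigma=plan.noise_sigma, n_models=plan.n_models,
        method=plan.method, resolution=resolution,
        description=plan.rna_type_text)


def generate_dataset(plan: DatasetPlan, out_dir) -> dict:
    """Emit a labelled corpus: modified entries under ``modified/``,
    unmodified counterparts under ``library/``, and a global manifest
    (JSON) recording every planted ground truth."""
    out_dir = Path(out_dir)
    mod_dir = out_dir / "modified"
    lib_dir = out_dir / "library"
    mod_dir.mkdir(parents=True, exist_ok=True)
    lib_dir.mkdir(parents=True, exist_ok=True)
    manifests = {}
    rng = np.random.default_rng(plan.seed)
    for k, ep in enumerate(plan.entries):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = _spec_from_plan(ep, sub_seed)
        entry, manifest = build_hairpin(spec)
        if ep.defect == "missing_atom":
            # delete O2' from the first loop residue in every model
            for model in entry.models:
                res = model.chains[spec.chain_id][ep.stem_bp]
                res.atoms = [a for a in res.atoms if a.name != "O2'"]
            manifest.defects.append("missing_atom")
        if ep.defect == "resolution":
            manifest.defects.append("resolution")
        if ep.planted_distinct:
            manifest.defects.append("planted_distinct")
        target = lib_dir if ep.modification is None else mod_dir
        write_structure(entry, target / f"{ep.entry_id}.cif")
        manifests[ep.entry_id] = manifest.to_dict()
        if ep.counterpart and ep.modification is not None:
            lib_plan = replace(ep, entry_id=ep.entry_id + "L",
                               modification=None, counterpart=False,
                               defect=None, planted_distinct=False,
                               n_models=1, noise_sigma=0.0,
                               method=XRAY, resolution=2.0,
                               pucker_overrides={}, chi_overrides={})
            lib_spec = _spec_from_plan(lib_plan, sub_seed + 1)
            lib_entry, lib_manifest = build_hairpin(lib_spec)
            write_structure(lib_entry, lib_dir / f"{lib_plan.entry_id}.cif")
            manifests[lib_plan.entry_id] = lib_manifest.to_dict()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifests, fh, indent=1, default=str)
    return manifests


#: Per-modification loop sequences (A: redundant group, B: group with a
#: planted conformational difference, C: NMR-solved group, D: extras
#: without library counterparts).  Loops are unique per modification so
#: display sequences never collide across the shared lowercase-u codes.
_MOD_LOOPS: dict[str, tuple[str, str, str, str]] = {
    "PSU": ("UUCG", "AUUCGA", "UUCAAAG", "GCUAA"),
    "5MU": ("GAUC", "AUCCG", "UUCAAAGG", "CGUAA"),
    "UR3": ("UAAC", "CAUGG", "AUCAAAGGA", "GGUAA"),
    "OMU": ("GUAA", "ACUGG", "CAAAGGAAU", "AAUCG"),
    "4SU": ("UGCA", "GGUAC", "AACAAGGUAU", "CCUGA"),
    "H2U": ("CUGA", "AGUCC", "UUCAAAGGAA", "GAUGC"),
}

_RNA_TYPE_TEXTS = ("23S ribosomal RNA", "transfer RNA-Phe",
                   "messenger RNA fragment", "synthetic RNA hairpin construct")

# pseudorotation/chi used for the planted conformational difference:
# C2'-endo sugars with syn bases, far from the A-form default
_DISTINCT_CONF = ((162.0, 38.0), 30.0)


def default_study_plan(seed: int = 0, n_entries: int = 60,
                       stem_bp: int = 2) -> DatasetPlan:
    """A corpus emulating the survey conditions at desk scale.

    Ten entries per modification (60 total): a redundant three-member
    motif group with an unmodified library counterpart, a two-member
    group whose loop is built in a deliberately different conformation
    (C2'-endo / syn) from its counterpart so the comparison crosses the
    similarity threshold, one NMR ensemble entry with counterpart, one
    entry planted to fail the resolution filter, one with a missing
    atom so clipping fails, and two extras with no counterpart.
    ``n_entries`` truncates the plan for smaller tests.
    """
    entries = []
    for mod, loops in _MOD_LOOPS.items():
        loop_a, loop_b, loop_c, loop_d = loops
        rna_type = _RNA_TYPE_TEXTS[len(entries) % len(_RNA_TYPE_TEXTS)]
        base_id = f"{mod[0]}{len(entries):02d}"

        def plan(tag, loop, **kw):
            pos = loop.index("U")
            defaults = dict(modification=mod, loop_sequence=loop,
                            mod_loop_positions=(pos,), stem_bp=stem_bp,
                            rna_type_text=rna_type)
            defaults.update(kw)
            return EntryPlan(entry_id=f"{base_id}{tag}", **defaults)

        # redundant group (3 members, one counterpart)
        entries.append(plan("A0", loop_a, counterpart=True))
        entries.append(plan("A1", loop_a, method=EM, resolution=2.8))
        entries.append(plan("A2", loop_a, resolution=2.5))
        # planted-distinct group (2 members, one counterpart)
        distinct_overrides = {
            "pucker_overrides": {stem_bp + j: _DISTINCT_CONF[0]
                                 for j in range(len(loop_b))},
            "chi_overrides": {stem_bp + j: _DISTINCT_CONF[1]
                              for j in range(len(loop_b))},
        }
        entries.append(plan("B0", loop_b, counterpart=True,
                            planted_distinct=True, **distinct_overrides))
        entries.append(plan("B1", loop_b, planted_distinct=True,
                            **distinct_overrides))
        # NMR ensemble with counterpart
        entries.append(plan("C0", loop_c, counterpart=True, method=NMR,
                            resolution=None, n_models=6, noise_sigma=0.3))
        # planted curation failures
        entries.append(plan("F0", loop_a, defect="resolution"))
        entries.append(plan("F1", loop_a, defect="missing_atom"))
        # extras without counterparts
        entries.append(plan("D0", loop_d))
        entries.append(plan("D1", loop_d, method=EM, resolution=2.9))
    return DatasetPlan(seed=seed, entries=entries[:n_entries])


# ---------------------------------------------------------------------------
# idealized pair fixtures and multi-arm topologies

def ideal_pair_fixture(kind: str = "GC", hbond_len: float = 3.4,
                       base_only: bool = True) -> Model:
    """Two residues forming one idealized planar base pair, for exercising
    hydrogen-bond and pair detection in isolation.

    ``hbond_len`` sets the donor-acceptor separations; the default keeps
    exactly the canonical contacts (3 for G-C, 2 for A-U and the G-U
    wobble) inside the 4.0 A cutoff while pushing every cross contact
    outside it.  ``base_only`` strips sugar/backbone atoms so sugar
    donors cannot add contacts.
    """
    kind = kind.upper()
    comp_a, comp_b = kind[0], kind[1]
    nt_a = _to_canonical(build_nucleotide(comp_a), comp_a)
    nt_b = _place_partner(nt_a, comp_a, build_nucleotide(comp_b), comp_b,
                          hbond_len=hbond_len)
    model = Model()
    residues = []
    for i, (comp, atoms) in enumerate(((comp_a, nt_a), (comp_b, nt_b)), start=1):
        res = _residue_from_atoms(atoms, comp, "A", i)
        if base_only:
            base_names = components.component(comp).base_atoms
            res.atoms = [a for a in res.atoms if a.name in base_names]
        residues.append(res)
    model.chains["A"] = residues
    return model


def build_cloverleaf(entry_id: str = "CLOV", chain_id: str = "A",
                     acceptor_bp: int = 3, arm_stem_bp: int = 2,
                     arm_loops: tuple = ("GAAAU", "UUCG", "UUCAAAG"),
                     ) -> tuple[StructureEntry, Manifest]:
    """A tRNA-like cloverleaf on one chain: an acceptor stem enclosing
    three hairpin arms separated by single-residue linkers.

    Arms are placed far apart so only the built pairing is detected;
    the expected annotation is one JUNCTION plus three HAIRPINs (and
    four helices), recorded in the manifest.
    """
    arm_offsets = (np.array([40.0, 0.0, 10.0]), np.array([0.0, 40.0, 10.0]),
                   np.array([-40.0, 0.0, 10.0]))
    seq_parts: list[str] = []
    residues: list[Residue] = []
    pairing: list[tuple[int, int]] = []
    seq_num = 0

    def add_residue(res: Residue, offset: np.ndarray) -> int:
        nonlocal seq_num
        seq_num += 1
        res = replace(res, chain_id=chain_id, seq_num=seq_num,
                      atoms=[Atom(a.name, a.element, a.pos + offset,
                                  a.occupancy, a.alt_id) for a in res.atoms])
        residues.append(res)
        return seq_num

    # acceptor stem as a plain duplex; 3' strand residues are buffered and
    # appended after the arms so the chain reads 5'strand-arms-3'strand.
    stem5 = "GCGCGCGCGC"[:acceptor_bp]
    stem3 = "".join(_COMPLEMENT[c] for c in reversed(stem5))
    placements5, placements3 = [], []
    for k in range(acceptor_bp):
        c5, c3 = stem5[k], stem3[acceptor_bp - 1 - k]
        default = (18.0, 38.0, -160.0)
        nt5, nt3 = _stem_pair_template(c5, c3, default, default)
        rot = _rot_z(TWIST * k)
        shift = np.array([0.0, 0.0, -RISE * k])  # grows downward, arms above
        placements5.append((c5, {nme: rot @ p + shift for nme, p in nt5.items()}))
        placements3.append((c3, {nme: rot @ p + shift for nme, p in nt3.items()}))
    pair_slots = []
    for c5, atoms in placements5:
        num = add_residue(_residue_from_atoms(atoms, c5, chain_id, 0),
                          np.zeros(3))
        pair_slots.append(num)
        seq_parts.append(c5)

    arm_hairpins = []
    for arm_idx, loop in enumerate(arm_loops):
        # linker residue, isolated below the stem
        linker = build_nucleotide("U")
        num = add_residue(_residue_from_atoms(linker, "U", chain_id, 0),
                          np.array([0.0, -30.0 - 12.0 * arm_idx, -20.0]))
        seq_parts.append("U")
        arm_spec = GeneratorSpec(entry_id="ARM", chain_id=chain_id,
                                 stem_bp=arm_stem_bp, loop_sequence=loop)
        arm_entry, arm_manifest = build_hairpin(arm_spec)
        arm_res = arm_entry.model.chains[chain_id]
        first = None
        for r in arm_res:
            num = add_residue(r, arm_offsets[arm_idx])
            first = first if first is not None else num
            seq_parts.append(components.display_char(r.comp_id) or "N")
        for i, j in arm_manifest.pairing:
            pairing.append((first + i - 1, first + j - 1))
        arm_hairpins.append((first + arm_stem_bp,
                             first + arm_stem_bp + len(loop) - 1))
    # trailing linker then the acceptor 3' strand
    linker = build_nucleotide("U")
    add_residue(_residue_from_atoms(linker, "U", chain_id, 0),
                np.array([0.0, -70.0, -20.0]))
    seq_parts.append("U")
    for k, (c3, atoms) in enumerate(reversed(placements3)):
        num = add_residue(_residue_from_atoms(atoms, c3, chain_id, 0),
                          np.zeros(3))
        pairing.append((pair_slots[acceptor_bp - 1 - k], num))
        seq_parts.append(c3)

    entry = StructureEntry(
        entry_id=entry_id, method=XRAY, resolution=2.0,
        models=[Model(chains={chain_id: residues})],
        molecule_descriptions={chain_id: "transfer RNA-like synthetic construct"})
    manifest = Manifest(
        entry_id=entry_id, chain_id=chain_id, start_seq_num=1,
        sequence="".join(seq_parts), canonical_sequence="".join(seq_parts),
        stem_bp=acceptor_bp, loop_size=0,
        pairing=sorted(pairing), method=XRAY, resolution=2.0)
    manifest.defects = [f"hairpin:{a}-{b}" for a, b in arm_hairpins]
    return entry, manifest
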