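"""Geometric annotation of RNA models: hydrogen bonds, base stacking,
base pairs, and secondary-structure elements (SSEs).

This is a self-contained reimplementation of the subset of annotations
the survey needs.  Hydrogen bonds are called on a donor/acceptor
heavy-atom distance criterion (default cutoff 4.0 A, boundary
inclusive); hydrogens are gone by the time annotation runs, so no
angular term is applied by default.  Stacking requires small inter-ring
atom distance, near-parallel base planes and close ring centroids.
Base pairs require at least two base-base hydrogen bonds between
near-coplanar bases and are classified WCF / WOBBLE / HOOGSTEEN / OTHER
from the participating edge atoms.  SSEs are derived from the nested
subset of WCF/wobble pairs: helices are runs of >= 2 consecutive pairs,
and the loops they enclose are classified hairpin / internal / bulge /
junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from . import components
from .structure_io import Model, Residue

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRef", "ResRef", "HBond", "StackContact", "BasePair", "SSE",
    "AnnotationConfig", "detect_hbonds", "detect_stacks",
    "detect_base_pairs", "assign_sses", "annotate", "Annotation",
]

HAIRPIN, HELIX, INTERNAL, BULGE, JUNCTION, MISC = (
    "HAIRPIN", "HELIX", "INTERNAL", "BULGE", "JUNCTION", "MISC")

WCF, WOBBLE, HOOGSTEEN, OTHER_PAIR = "WCF", "WOBBLE", "HOOGSTEEN", "OTHER"


class ResRef(NamedTuple):
    chain_id: str
    seq_num: int
    icode: str
    comp_id: str


class AtomRef(NamedTuple):
    chain_id: str
    seq_num: int
    icode: str
    comp_id: str
    atom: str

    @property
    def residue(self) -> ResRef:
        return ResRef(self.chain_id, self.seq_num, self.icode, self.comp_id)


def res_ref(r: Residue) -> ResRef:
    return ResRef(r.chain_id, r.seq_num, r.icode, r.comp_id)


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float


@dataclass(frozen=True)
class StackContact:
    res_a: ResRef
    res_b: ResRef
    min_ring_dist: float
    centroid_dist: float
    normal_angle: float
    saturated: bool = False  # H2U's non-aromatic ring treated geometrically


@dataclass(frozen=True)
class BasePair:
    res_a: ResRef
    res_b: ResRef
    n_hbonds: int
    pair_type: str
    hbonds: tuple = ()


@dataclass
class SSE:
    sse_type: str
    residues: list  # ordered ResRef, loop residues for loop types
    loop_size: int | None = None
    closing_pair: BasePair | None = None


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable geometric criteria (defaults follow the survey settings)."""

    contact_cutoff: float = 4.0        # H-bond and stacking atom distance, A
    stack_normal_max: float = 30.0     # max angle between base normals, deg
    stack_centroid_max: float = 5.5    # max ring-centroid separation, A
    pair_coplanarity_max: float = 45.0  # max inter-plane angle for pairing, deg
    pair_plane_offset_max: float = 2.5  # max centroid offset from partner plane, A
    min_pair_hbonds: int = 2


# ---------------------------------------------------------------------------
# hydrogen bonds

#: elements of generic (non-nucleotide, e.g. amino acid) residues treated
#: as both donors and acceptors.
_GENERIC_POLAR = {"N", "O", "S"}


def _donor_acceptor_atoms(residue: Residue):
    comp = components.component(residue.comp_id)
    donors, acceptors = [], []
    if comp is not None:
        for a in residue.atoms:
            if a.name in comp.donors:
                donors.append(a)
            if a.name in comp.acceptors:
                acceptors.append(a)
    else:
        for a in residue.atoms:
            if a.element in _GENERIC_POLAR:
                donors.append(a)
                acceptors.append(a)
    return donors, acceptors


def detect_hbonds(model: Model, cutoff: float = 4.0) -> list[HBond]:
    """All inter-residue donor-acceptor heavy-atom pairs within ``cutoff``
    (inclusive)."""
    donor_refs, donor_pos, acc_refs, acc_pos = [], [], [], []
    for r in model.residues():
        donors, acceptors = _donor_acceptor_atoms(r)
        ref = res_ref(r)
        for a in donors:
            donor_refs.append(AtomRef(*ref, a.name))
            donor_pos.append(a.pos)
        for a in acceptors:
            acc_refs.append(AtomRef(*ref, a.name))
            acc_pos.append(a.pos)
    if not donor_refs or not acc_refs:
        return []
    tree = cKDTree(np.asarray(acc_pos))
    out: list[HBond] = []
    # tiny epsilon keeps the boundary (= cutoff) inclusive under fp rounding
    for i, pos in enumerate(donor_pos):
        for j in tree.query_ball_point(pos, cutoff + 1e-9):
            d_ref, a_ref = donor_refs[i], acc_refs[j]
            if d_ref.residue == a_ref.residue:
                continue
            dist = float(np.linalg.norm(pos - np.asarray(acc_pos[j])))
            if dist <= cutoff:
                out.append(HBond(d_ref, a_ref, dist))
    out.sort(key=lambda h: (h.donor, h.acceptor))
    return out


# ---------------------------------------------------------------------------
# base geometry helpers

def _ring_coords(residue: Residue, ring: tuple[str, ...]) -> np.ndarray | None:
    pts = []
    for name in ring:
        a = residue.get_atom(name)
        if a is None:
            return None
        pts.append(a.pos)
    return np.asarray(pts)


def _plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit normal) of a least-squares plane fit."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]


def base_rings(residue: Residue) -> list[np.ndarray]:
    comp = components.component(residue.comp_id)
    if comp is None:
        return []
    rings = []
    for ring in comp.rings:
        pts = _ring_coords(residue, ring)
        if pts is not None:
            rings.append(pts)
    return rings


def base_plane(residue: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    """(centroid, normal) of the base, fitted over all ring atoms."""
    rings = base_rings(residue)
    if not rings:
        return None
    return _plane(np.vstack(rings))


def _normal_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosv = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return float(np.degrees(np.arccos(cosv)))


# ---------------------------------------------------------------------------
# stacking

def detect_stacks(model: Model, cutoff: float = 4.0,
                  config: AnnotationConfig | None = None) -> list[StackContact]:
    """Base-stacking contacts: min inter-ring atom distance <= cutoff,
    base-plane normals within ``stack_normal_max`` degrees, and ring
    centroids within ``stack_centroid_max`` A."""
    config = config or AnnotationConfig(contact_cutoff=cutoff)
    cutoff = config.contact_cutoff if config.contact_cutoff != 4.0 or cutoff == 4.0 else cutoff
    entries = []
    for r in model.residues():
        rings = base_rings(r)
        if not rings:
            continue
        plane = base_plane(r)
        entries.append((res_ref(r), rings, plane))
    out: list[StackContact] = []
    for i in range(len(entries)):
        ref_a, rings_a, (cen_a, nrm_a) = entries[i]
        for j in range(i + 1, len(entries)):
            ref_b, rings_b, (cen_b, nrm_b) = entries[j]
            angle = _normal_angle(nrm_a, nrm_b)
            if angle > config.stack_normal_max:
                continue
            cdist = min(float(np.linalg.norm(_plane(ra)[0] - _plane(rb)[0]))
                        for ra in rings_a for rb in rings_b)
            if cdist > config.stack_centroid_max:
                continue
            min_dist = min(
                float(np.min(np.linalg.norm(
                    ra[:, None, :] - rb[None, :, :], axis=2)))
                for ra in rings_a for rb in rings_b)
            if min_dist > cutoff + 1e-9:
                continue
            saturated = "H2U" in (ref_a.comp_id, ref_b.comp_id)
            out.append(StackContact(ref_a, ref_b, min_dist, cdist, angle,
                                    saturated=saturated))
    return out


# ---------------------------------------------------------------------------
# base pairs

def _base_atom_names(comp: components.ComponentDef) -> frozenset[str]:
    names = set()
    for ring in comp.rings:
        names.update(ring)
    names.update(comp.wcf_edge)
    names.update(comp.hoogsteen_edge)
    names.update(comp.extra_atoms)
    names.discard("O2'")
    return frozenset(names)


def _classify_pair(comp_a, comp_b, atoms_a: set[str], atoms_b: set[str]) -> str:
    for comp, atoms in ((comp_a, atoms_a), (comp_b, atoms_b)):
        if comp.purine and "N7" in atoms:
            return HOOGSTEEN
    if atoms_a <= comp_a.wcf_edge and atoms_b <= comp_b.wcf_edge:
        la = components.canonical_letter(comp_a.comp_id)
        lb = components.canonical_letter(comp_b.comp_id)
        combo = frozenset((la, lb))
        if combo in (frozenset("GC"), frozenset("AU")):
            return WCF
        if combo == frozenset("GU"):
            return WOBBLE
    return OTHER_PAIR


def detect_base_pairs(hbonds: list[HBond], model: Model,
                      config: AnnotationConfig | None = None) -> list[BasePair]:
    """Residue pairs joined by >= 2 base-base hydrogen bonds between
    near-coplanar bases (inter-plane angle and mutual plane offset both
    bounded), classified by the participating base edges."""
    config = config or AnnotationConfig()
    res_by_ref: dict[ResRef, Residue] = {res_ref(r): r for r in model.residues()}
    grouped: dict[tuple[ResRef, ResRef], list[HBond]] = {}
    for hb in hbonds:
        ra, rb = hb.donor.residue, hb.acceptor.residue
        comp_a = components.component(ra.comp_id)
        comp_b = components.component(rb.comp_id)
        if comp_a is None or comp_b is None:
            continue
        if (hb.donor.atom not in _base_atom_names(comp_a)
                or hb.acceptor.atom not in _base_atom_names(comp_b)):
            continue
        key = (ra, rb) if (ra <= rb) else (rb, ra)
        grouped.setdefault(key, []).append(hb)
    out: list[BasePair] = []
    for (ra, rb), bonds in sorted(grouped.items()):
        if len(bonds) < config.min_pair_hbonds:
            continue
        plane_a = base_plane(res_by_ref[ra])
        plane_b = base_plane(res_by_ref[rb])
        if plane_a is None or plane_b is None:
            continue
        (cen_a, nrm_a), (cen_b, nrm_b) = plane_a, plane_b
        if _normal_angle(nrm_a, nrm_b) > config.pair_coplanarity_max:
            continue
        offset = max(abs(float(np.dot(cen_b - cen_a, nrm_a))),
                     abs(float(np.dot(cen_a - cen_b, nrm_b))))
        if offset > config.pair_plane_offset_max:
            continue
        atoms_a = {hb.donor.atom for hb in bonds if hb.donor.residue == ra}
        atoms_a |= {hb.acceptor.atom for hb in bonds if hb.acceptor.residue == ra}
        atoms_b = {hb.donor.atom for hb in bonds if hb.donor.residue == rb}
        atoms_b |= {hb.acceptor.atom for hb in bonds if hb.acceptor.residue == rb}
        ptype = _classify_pair(components.component(ra.comp_id),
                               components.component(rb.comp_id),
                               atoms_a, atoms_b)
        out.append(BasePair(ra, rb, len(bonds), ptype, tuple(bonds)))
    return out


# ---------------------------------------------------------------------------
# secondary structure

def _residue_order(model: Model) -> dict[ResRef, int]:
    order = {}
    for r in model.residues():
        order[res_ref(r)] = len(order)
    return order


def _select_partners(pairs: list[BasePair], order) -> dict[int, int]:
    """One pairing partner per residue: prefer more hydrogen bonds, then
    the 5'-most pair."""
    ranked = sorted(
        pairs,
        key=lambda p: (-p.n_hbonds, min(order[p.res_a], order[p.res_b]),
                       max(order[p.res_a], order[p.res_b])))
    partner: dict[int, int] = {}
    for p in ranked:
        ia, ib = order[p.res_a], order[p.res_b]
        if ia in partner or ib in partner:
            continue
        partner[ia] = ib
        partner[ib] = ia
    return partner


def _helices(partner: dict[int, int]) -> list[list[tuple[int, int]]]:
    """Runs of consecutive nested pairs (i,j),(i+1,j-1),..., length >= 2."""
    pairs = sorted((i, j) for i, j in partner.items() if i < j)
    helices, used = [], set()
    pair_set = set(pairs)
    for i, j in pairs:
        if (i, j) in used:
            continue
        run = [(i, j)]
        used.add((i, j))
        while (run[-1][0] + 1, run[-1][1] - 1) in pair_set:
            nxt = (run[-1][0] + 1, run[-1][1] - 1)
            run.append(nxt)
            used.add(nxt)
        if len(run) >= 2:
            helices.append(run)
    return helices


def _nested_subset(helices):
    """Maximal nested (non-crossing) subset of helices, greedy by helix
    length, ties broken by 5' position; discards pseudoknotted helices."""
    chosen: list[list[tuple[int, int]]] = []

    def crosses(h1, h2) -> bool:
        a1, a2 = h1[0][0], h1[0][1]
        b1, b2 = h2[0][0], h2[0][1]
        return (a1 < b1 < a2 < b2) or (b1 < a1 < b2 < a2)

    for h in sorted(helices, key=lambda h: (-len(h), h[0][0])):
        if all(not crosses(h, c) for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h[0][0])
    return chosen


def assign_sses(pairs: list[BasePair], model: Model) -> list[SSE]:
    """Secondary-structure elements from WCF/wobble pairs.

    Helices are runs of >= 2 consecutive pairs; every helix contributes a
    HELIX element, and the loop enclosed by its innermost pair is
    classified HAIRPIN (no nested helix, one chain, contiguous
    numbering), INTERNAL/BULGE (one nested helix) or JUNCTION (several).
    Pseudoknotted helices are excluded by a greedy maximal nested subset.
    Unpaired runs outside every helix are reported as MISC.
    """
    order = _residue_order(model)
    refs = sorted(order, key=order.get)
    pairing = [p for p in pairs if p.pair_type in (WCF, WOBBLE)]
    pair_lookup = {}
    for p in pairing:
        key = tuple(sorted((order[p.res_a], order[p.res_b])))
        pair_lookup[key] = p
    partner = _select_partners(pairing, order)
    helices = _nested_subset(_helices(partner))
    helix_pairs = {pr for h in helices for pr in h}
    paired_idx = {i for pr in helix_pairs for i in pr}

    sses: list[SSE] = []
    for h in helices:
        residues = sorted({i for pr in h for i in pr})
        sses.append(SSE(HELIX, [refs[i] for i in residues]))

    def contiguous_one_chain(idx_list) -> bool:
        rs = [refs[i] for i in idx_list]
        if len({r.chain_id for r in rs}) > 1:
            return False
        nums = [r.seq_num for r in rs]
        return all(b - a == 1 for a, b in zip(nums, nums[1:]))

    for h in helices:
        i_in, j_in = h[-1]  # innermost pair
        enclosed = list(range(i_in + 1, j_in))
        children = [c for c in helices
                    if c is not h and i_in < c[0][0] and c[0][1] < j_in]
        # only direct children (not nested inside another child)
        children = [c for c in children
                    if not any(d is not c and d[0][0] < c[0][0] and c[0][1] < d[0][1]
                               for d in children)]
        unpaired = [i for i in enclosed if i not in paired_idx]
        closing = pair_lookup.get((i_in, j_in))
        if not children:
            if not unpaired:
                continue  # blunt helix end, no loop element
            loop = [refs[i] for i in unpaired]
            stype = HAIRPIN if contiguous_one_chain(
                [i_in] + unpaired + [j_in]) else MISC
            sses.append(SSE(stype, loop, loop_size=len(unpaired),
                            closing_pair=closing))
        elif len(children) == 1:
            if not unpaired:
                continue  # coaxial helices, no loop element
            c = children[0]
            left = [i for i in unpaired if i < c[0][0]]
            right = [i for i in unpaired if i > c[0][1]]
            stype = INTERNAL if (left and right) else BULGE
            sses.append(SSE(stype, [refs[i] for i in unpaired],
                            loop_size=len(unpaired), closing_pair=closing))
        else:
            sses.append(SSE(JUNCTION, [refs[i] for i in unpaired],
                            loop_size=len(unpaired), closing_pair=closing))

    # residues outside every helix span: dangling ends / linkers -> MISC
    in_loop = {order[r] for s in sses if s.sse_type != HELIX for r in s.residues}
    outside = [i for i in range(len(refs))
               if i not in paired_idx and i not in in_loop]
    run: list[int] = []
    for i in outside + [None]:
        if run and (i is None or i != run[-1] + 1):
            sses.append(SSE(MISC, [refs[k] for k in run], loop_size=len(run)))
            run = []
        if i is not None:
            run.append(i)
    return sses


def residue_sse_map(sses: list[SSE]) -> dict[ResRef, str]:
    """Per-residue SSE label for survey tabulation.

    Loop residues take their loop type; helix residues take HELIX, except
    that the residues of a hairpin's closing pair count with the hairpin
    (the clipped motif includes them).
    """
    out: dict[ResRef, str] = {}
    for s in sses:
        if s.sse_type == HELIX:
            for r in s.residues:
                out.setdefault(r, HELIX)
    for s in sses:
        if s.sse_type == HELIX:
            continue
        for r in s.residues:
            out[r] = s.sse_type
        if s.sse_type == HAIRPIN and s.closing_pair is not None:
            out[s.closing_pair.res_a] = HAIRPIN
            out[s.closing_pair.res_b] = HAIRPIN
    return out


@dataclass
class Annotation:
    """Full annotation of one model."""

    hbonds: list[HBond] = field(default_factory=list)
    stacks: list[StackContact] = field(default_factory=list)
    pairs: list[BasePair] = field(default_factory=list)
    sses: list[SSE] = field(default_factory=list)


def annotate(model: Model, config: AnnotationConfig | None = None) -> Annotation:
    """Run the full annotation stack on one model."""
    config = config or AnnotationConfig()
    hbonds = detect_hbonds(model, cutoff=config.contact_cutoff)
    stacks = detect_stacks(model, cutoff=config.contact_cutoff, config=config)
    pairs = detect_base_pairs(hbonds, model, config=config)
    sses = assign_sses(pairs, model)
    return Annotation(hbonds=hbonds, stacks=stacks, pairs=pairs, sses=sses)


# ---------------------------------------------------------------------------
# optional external-annotation reader (cross-checking only; never required)

def _parse_nt_id(nt: str) -> ResRef:
    """Parse a DSSR-style nucleotide id like 'A.PSU13' or 'B.U5^A'."""
    chain, _, rest = nt.partition(".")
    icode = ""
    if "^" in rest:
        rest, icode = rest.split("^", 1)
    comp = rest.rstrip("-0123456789")
    num = int(rest[len(comp):])
    return ResRef(chain, num, icode, comp.upper())


def load_external_annotation(path) -> Annotation:
    """Read a DSSR-style JSON document into an :class:`Annotation`.

    Understands the ``hbonds`` (atom1_id/atom2_id/distance) and ``pairs``
    (nt1/nt2/name) lists.  Exists so external annotations can be compared
    against this package's output; nothing in the pipeline depends on it.
    """
    import json

    with open(path) as fh:
        doc = json.load(fh)
    ann = Annotation()
    for rec in doc.get("hbonds", []):
        refs = []
        for key in ("atom1_id", "atom2_id"):
            atom, _, nt = rec[key].partition("@")
            ref = _parse_nt_id(nt)
            refs.append(AtomRef(*ref, atom))
        ann.hbonds.append(HBond(refs[0], refs[1],
                                float(rec.get("distance", 0.0))))
    name_map = {"WC": WCF, "Wobble": WOBBLE, "Hoogsteen": HOOGSTEEN}
    for rec in doc.get("pairs", []):
        ann.pairs.append(BasePair(
            _parse_nt_id(rec["nt1"]), _parse_nt_id(rec["nt2"]),
            n_hbonds=int(rec.get("hbonds_num", 0)),
            pair_type=name_map.get(rec.get("name", ""), OTHER_PAIR)))
    return ann
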