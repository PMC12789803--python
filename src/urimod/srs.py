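"""Sequence-representative structures (SRS) and modified-vs-unmodified
comparison.

Motifs sharing (SSE type, sequence) form a group; the group member with
the lowest all-atom RMSD to the group's iterative mean structure is its
SRS.  A modified SRS is compared to the unmodified SRS of the same
canonical sequence by superposing the name-matched heavy atoms
(chemistry differences such as added methyls are dropped from the
correspondence and reported) and testing the RMSD against the
similarity threshold (1.0 Angstrom, boundary inclusive).  Interaction
differencing reports, per motif position, the hydrogen bonds, stacks
and pairs gained or lost relative to the unmodified counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import components
from .annotation import Annotation, ResRef
from .curation import MotifInstance
from .geometry import (CoordinateSet, CorrespondenceError, kabsch_superpose,
                       representative_to_mean)

__all__ = [
    "SRSRecord", "ComparisonResult", "InteractionDelta", "select_srs",
    "atom_correspondence", "compare_pair", "diff_interactions",
    "motif_interactions",
]


@dataclass
class SRSRecord:
    group_key: tuple  # (sse_type, sequence)
    member_ids: list[str]
    representative_id: str
    rmsd_to_mean: dict[str, float]

    @property
    def representative_index(self) -> int:
        return self.member_ids.index(self.representative_id)


def _motif_coordinate_set(motif: MotifInstance, labels=None) -> CoordinateSet:
    pairs = []
    for pos, r in enumerate(motif.residues):
        for a in r.atoms:
            pairs.append(((pos, a.name), a.pos))
    lookup = dict(pairs)
    if labels is None:
        labels = tuple(lab for lab, _ in pairs)
    return CoordinateSet(tuple(labels), [lookup[lab] for lab in labels])


def select_srs(group: list[MotifInstance]) -> SRSRecord:
    """SRS of a same-sequence motif group: lowest all-atom RMSD to the
    group mean (ties to the earliest member).  Atoms are matched by
    (motif position, atom name); members missing an atom shrink the
    shared label set."""
    if not group:
        raise ValueError("empty SRS group")
    key = (group[0].sse_type, group[0].sequence)
    ids = [m.motif_id for m in group]
    if len(group) == 1:
        return SRSRecord(key, ids, ids[0], {ids[0]: 0.0})
    label_lists = []
    for m in group:
        label_lists.append([(pos, a.name) for pos, r in enumerate(m.residues)
                            for a in r.atoms])
    shared = set(label_lists[0])
    for ls in label_lists[1:]:
        shared &= set(ls)
    labels = tuple(lab for lab in label_lists[0] if lab in shared)
    members = [_motif_coordinate_set(m, labels) for m in group]
    result = representative_to_mean(members)
    return SRSRecord(key, ids, ids[result.index],
                     {mid: r for mid, r in zip(ids, result.rmsds)})


@dataclass
class ComparisonResult:
    modified_id: str
    unmodified_id: str
    n_paired_atoms: int
    rmsd: float
    similar: bool
    dropped_atoms: dict  # position -> (dropped in modified, dropped in unmodified)


def atom_correspondence(modified: MotifInstance, unmodified: MotifInstance):
    """Position-by-position atom pairing by name.

    Atoms with no same-name counterpart at the aligned position (methyl
    carbons, O4 vs S4, ...) are dropped and reported.  Returns
    (ordered (position, atom name) labels, dropped_atoms dict).
    """
    if len(modified.residues) != len(unmodified.residues):
        raise CorrespondenceError("motif residue counts differ")
    if modified.canonical_sequence() != unmodified.canonical_sequence():
        raise CorrespondenceError("canonicalized sequences differ")
    labels, dropped = [], {}
    for pos, (rm, ru) in enumerate(zip(modified.residues, unmodified.residues)):
        names_m = [a.name for a in rm.atoms]
        names_u = {a.name for a in ru.atoms}
        common = [n for n in names_m if n in names_u]
        only_m = sorted(set(names_m) - names_u)
        only_u = sorted(names_u - set(names_m))
        if only_m or only_u:
            dropped[pos] = (only_m, only_u)
        labels.extend((pos, n) for n in common)
    if len(labels) < 3:
        raise CorrespondenceError("fewer than 3 paired atoms")
    return tuple(labels), dropped


def compare_pair(modified: MotifInstance, unmodified: MotifInstance,
                 threshold: float = 1.0) -> ComparisonResult:
    """Superpose the two motifs on their paired heavy atoms and call
    them similar iff RMSD <= threshold."""
    labels, dropped = atom_correspondence(modified, unmodified)
    sup = kabsch_superpose(_motif_coordinate_set(modified, labels),
                           _motif_coordinate_set(unmodified, labels))
    return ComparisonResult(
        modified_id=modified.motif_id, unmodified_id=unmodified.motif_id,
        n_paired_atoms=sup.n_atoms, rmsd=sup.rmsd,
        similar=sup.rmsd <= threshold, dropped_atoms=dropped)


# ---------------------------------------------------------------------------
# interaction differencing

@dataclass
class InteractionDelta:
    position: int
    gained: set = field(default_factory=set)
    lost: set = field(default_factory=set)
    shared: set = field(default_factory=set)


def _partner_descriptor(partner: ResRef, motif_index: dict) -> str:
    """Normalized partner identity: motif position for in-motif partners,
    component + author number + chain for tertiary partners (amino acids
    keep their 3-letter code, nucleotides their canonical letter)."""
    if partner in motif_index:
        return f"pos{motif_index[partner]}"
    comp = components.canonical_letter(partner.comp_id) or partner.comp_id
    return f"tert:{comp}{partner.seq_num}{partner.chain_id}"


def motif_interactions(motif: MotifInstance, annotation: Annotation
                       ) -> dict[int, set]:
    """Per-position interaction descriptor sets, computed in the parent
    structure's annotation (tertiary contacts included).

    Descriptors are (kind, partner) with distances omitted, so sets are
    comparable across entries.
    """
    motif_index = {(r.chain_id, r.seq_num, r.icode, r.comp_id): pos
                   for pos, r in enumerate(motif.residues)}

    def norm(ref: ResRef):
        return (ref.chain_id, ref.seq_num, ref.icode, ref.comp_id)

    out: dict[int, set] = {pos: set() for pos in range(len(motif.residues))}

    def add(ref_a: ResRef, ref_b: ResRef, kind: str):
        ka, kb = norm(ref_a), norm(ref_b)
        if ka in motif_index:
            out[motif_index[ka]].add((kind, _partner_descriptor(ref_b, motif_index)))
        if kb in motif_index:
            out[motif_index[kb]].add((kind, _partner_descriptor(ref_a, motif_index)))

    for hb in annotation.hbonds:
        add(hb.donor.residue, hb.acceptor.residue, "HBOND")
    for st in annotation.stacks:
        add(st.res_a, st.res_b, "STACK")
    for bp in annotation.pairs:
        add(bp.res_a, bp.res_b, "PAIR")
    return out


def diff_interactions(modified: MotifInstance, modified_ann: Annotation,
                      unmodified: MotifInstance, unmodified_ann: Annotation
                      ) -> list[InteractionDelta]:
    """Per-position set difference of interaction descriptors between a
    modified SRS and its unmodified counterpart."""
    im = motif_interactions(modified, modified_ann)
    iu = motif_interactions(unmodified, unmodified_ann)
    out = []
    for pos in range(len(modified.residues)):
        a, b = im.get(pos, set()), iu.get(pos, set())
        out.append(InteractionDelta(position=pos, gained=a - b, lost=b - a,
                                    shared=a & b))
    return out
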