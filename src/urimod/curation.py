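"""Dataset curation: the resolution filter, NMR ensemble representative
selection, sequence canonicalization, hairpin motif clipping and
local-library counterpart matching, plus keyword RNA-type classification.

The counterpart search replaces a web motif database with exact-sequence
matching over a user-supplied local library: a candidate must be a
hairpin of the same loop size whose full clipped sequence (closing pair
included) equals the canonicalized query sequence and which contains no
modified residues.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from . import components
from .annotation import HAIRPIN, SSE, Annotation, annotate
from .geometry import CoordinateSet, representative_to_mean
from .structure_io import (EM, NMR, XRAY, Model, Residue, ScreenResult,
                           StructureEntry, screen_residue)

logger = logging.getLogger(__name__)

__all__ = [
    "MotifInstance", "CurationLog", "CurationError", "filter_entries",
    "select_nmr_representative", "canonicalize_sequence", "clip_motif",
    "match_unmodified", "classify_rna_type", "clip_all_hairpins",
    "parse_motif_id",
]

RESOLUTION, MISSING_ATOMS, PROCESSING, INCOMPLETE_SSE, CLIP_FAIL = (
    "RESOLUTION", "MISSING_ATOMS", "PROCESSING", "INCOMPLETE_SSE", "CLIP_FAIL")


class CurationError(ValueError):
    pass


class UnknownComponentError(CurationError):
    pass


@dataclass
class MotifInstance:
    """A clipped hairpin: loop plus first closing pair.

    ``sequence`` is the display string (modified residues shown by their
    display character, e.g. P for pseudouridine); ``motif_id`` encodes
    provenance as ENTRYID_sequence_chain_startSeqNum.
    """

    entry_id: str
    chain_id: str
    start_seq_num: int
    sequence: str
    residues: list[Residue]
    sse_type: str = HAIRPIN
    loop_size: int = 0

    @property
    def motif_id(self) -> str:
        return f"{self.entry_id}_{self.sequence}_{self.chain_id}_{self.start_seq_num}"

    def canonical_sequence(self) -> str:
        return canonicalize_sequence(self.sequence)

    def is_modified(self) -> bool:
        return any(components.is_modified(r.comp_id) for r in self.residues)


def parse_motif_id(motif_id: str) -> tuple[str, str, str, int]:
    """(entry_id, sequence, chain, start) parsed back out of a motif id."""
    m = re.fullmatch(r"(.+?)_([A-Za-z]+)_(.+)_(-?\d+)", motif_id)
    if not m:
        raise CurationError(f"malformed motif id: {motif_id}")
    return m.group(1), m.group(2), m.group(3), int(m.group(4))


@dataclass
class CurationLog:
    entry_id: str
    decisions: list = field(default_factory=list)  # (filter, outcome, reason)

    def record(self, filter_name: str, outcome: str, reason: str = "") -> None:
        self.decisions.append((filter_name, outcome, reason))

    @property
    def excluded(self) -> bool:
        return any(outcome == "excluded" for _, outcome, _ in self.decisions)

    @property
    def reasons(self) -> list[str]:
        return [r for _, outcome, r in self.decisions if outcome == "excluded"]


def filter_entries(entries, max_resolution: float = 3.0):
    """Resolution filter: X-ray/EM entries pass iff resolution <=
    ``max_resolution`` (boundary inclusive); NMR entries always pass this
    filter (their ensemble is reduced separately).  X-ray/EM entries with
    no stated resolution are excluded.

    Returns (kept entries, {entry_id: CurationLog}).
    """
    kept, logs = [], {}
    for entry in entries:
        log = logs.setdefault(entry.entry_id, CurationLog(entry.entry_id))
        if entry.method in (XRAY, EM):
            if entry.resolution is None or entry.resolution > max_resolution:
                log.record("resolution", "excluded", RESOLUTION)
                continue
        log.record("resolution", "kept")
        kept.append(entry)
    return kept, logs


def _model_coordinate_set(model: Model, labels=None) -> CoordinateSet:
    pairs = []
    for r in model.residues():
        for a in r.atoms:
            if not a.is_hydrogen():
                pairs.append(((r.chain_id, r.seq_num, r.icode, a.name), a.pos))
    if labels is None:
        labels = tuple(lab for lab, _ in pairs)
    lookup = dict(pairs)
    return CoordinateSet(tuple(labels), [lookup[lab] for lab in labels])


def select_nmr_representative(entry: StructureEntry):
    """Reduce an NMR ensemble to the single model with the lowest
    all-atom RMSD to the ensemble's iterative mean structure.

    Models with unequal topology are intersected on their shared heavy
    atoms (with a warning).  Returns (single-model entry, result) where
    ``result`` carries the per-model RMSD table.
    """
    if entry.method != NMR:
        raise CurationError(f"{entry.entry_id}: not an NMR entry")
    if len(entry.models) == 1:
        single = StructureEntry(entry.entry_id, entry.method, None,
                                [entry.models[0]],
                                entry.molecule_descriptions, entry.organism)
        return single, representative_to_mean(
            [_model_coordinate_set(entry.models[0])])
    label_sets = []
    for model in entry.models:
        label_sets.append([
            (r.chain_id, r.seq_num, r.icode, a.name)
            for r in model.residues() for a in r.atoms if not a.is_hydrogen()])
    shared = set(label_sets[0])
    for ls in label_sets[1:]:
        shared &= set(ls)
    labels = tuple(lab for lab in label_sets[0] if lab in shared)
    if any(len(ls) != len(labels) for ls in label_sets):
        logger.warning("%s: models differ in topology; using %d shared atoms",
                       entry.entry_id, len(labels))
    members = [_model_coordinate_set(m, labels) for m in entry.models]
    result = representative_to_mean(members)
    single = StructureEntry(entry.entry_id, entry.method, None,
                            [entry.models[result.index]],
                            entry.molecule_descriptions, entry.organism)
    return single, result


def canonicalize_sequence(sequence: str, dictionary=None) -> str:
    """Replace each modification display character by its canonical base
    letter; canonical letters pass through unchanged."""
    table = dictionary if dictionary is not None else components.MODIFICATIONS
    by_char = {rec.display_char: rec.canonical for rec in table.values()}
    out = []
    for ch in sequence:
        if ch in "ACGU":
            out.append(ch)
        elif ch in by_char:
            out.append(by_char[ch])
        else:
            raise UnknownComponentError(f"unknown sequence character {ch!r}")
    return "".join(out)


def clip_motif(entry: StructureEntry, sse: SSE, model: Model | None = None) -> MotifInstance:
    """Clip a hairpin SSE (loop plus first closing pair) out of its
    parent entry.

    Every clipped residue must pass the quality screen (CLIP_FAIL
    otherwise); a numbering gap inside the span raises INCOMPLETE_SSE.
    """
    if sse.sse_type != HAIRPIN:
        raise CurationError(f"not a hairpin SSE: {sse.sse_type}")
    if sse.closing_pair is None:
        raise CurationError(INCOMPLETE_SSE + ": hairpin lacks a closing pair")
    model = model or entry.model
    ra, rb = sse.closing_pair.res_a, sse.closing_pair.res_b
    if ra.chain_id != rb.chain_id:
        raise CurationError(INCOMPLETE_SSE + ": closing pair spans two chains")
    lo, hi = sorted((ra.seq_num, rb.seq_num))
    chain = model.chains.get(ra.chain_id, [])
    span = [r for r in chain if lo <= r.seq_num <= hi]
    nums = [r.seq_num for r in span]
    if nums != list(range(lo, hi + 1)):
        raise CurationError(INCOMPLETE_SSE + f": numbering gap in {lo}-{hi}")
    screened: list[Residue] = []
    for r in span:
        result: ScreenResult = screen_residue(r)
        if not result.ok:
            raise CurationError(
                CLIP_FAIL + f": residue {r.chain_id}/{r.seq_num} {result.reason}")
        screened.append(result.residue)
    seq = []
    for r in screened:
        ch = components.display_char(r.comp_id)
        if ch is None:
            raise CurationError(CLIP_FAIL + f": unknown component {r.comp_id}")
        seq.append(ch)
    return MotifInstance(
        entry_id=entry.entry_id, chain_id=ra.chain_id, start_seq_num=lo,
        sequence="".join(seq), residues=screened, sse_type=HAIRPIN,
        loop_size=len(screened) - 2)


def clip_all_hairpins(entry: StructureEntry, annotation: Annotation | None = None,
                      model: Model | None = None) -> tuple[list[MotifInstance], list[str]]:
    """All clippable hairpins of an entry; returns (motifs, failure notes)."""
    model = model or entry.model
    ann = annotation or annotate(model)
    motifs, failures = [], []
    for sse in ann.sses:
        if sse.sse_type != HAIRPIN:
            continue
        try:
            motifs.append(clip_motif(entry, sse, model))
        except CurationError as exc:
            failures.append(str(exc))
    return motifs, failures


def match_unmodified(motif: MotifInstance, library_motifs) -> list[MotifInstance]:
    """Unmodified library hairpins matching the motif: same SSE type and
    loop size, full canonicalized sequence equal (closing pair included),
    and containing no modified residue at any position."""
    target = motif.canonical_sequence()
    out = []
    for cand in library_motifs:
        if cand.sse_type != motif.sse_type or cand.loop_size != motif.loop_size:
            continue
        if cand.is_modified():
            continue
        if cand.sequence != target:  # unmodified: display == canonical
            continue
        out.append(cand)
    return out


_RNA_TYPE_RULES = (
    ("rRNA", re.compile(r"ribosomal|16S|18S|23S|28S|5S", re.I)),
    ("tRNA", re.compile(r"transfer|tRNA", re.I)),
    ("mRNA", re.compile(r"messenger|mRNA", re.I)),
    ("snRNA", re.compile(r"snRNA|spliceosom", re.I)),
    ("synthetic", re.compile(r"synthetic|construct|aptamer", re.I)),
)


def classify_rna_type(entry: StructureEntry, chain_id: str) -> str:
    """Keyword classification of a chain's molecule description."""
    text = entry.molecule_descriptions.get(chain_id, "")
    if not text:
        return "other"
    for label, rule in _RNA_TYPE_RULES:
        if rule.search(text):
            return label
    return "other"
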