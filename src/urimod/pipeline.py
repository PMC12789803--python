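"""End-to-end survey pipeline and summary tables.

``run_pipeline`` executes the full workflow over a directory of
modified-RNA structure files and a local unmodified library:

    parse -> resolution filter -> NMR representative -> annotate ->
    per-residue conformation -> clip hairpin motifs -> match unmodified
    counterparts -> SRS selection -> modified-vs-unmodified comparison ->
    summary tabulation

Every exclusion is logged with a reason code; two runs on the same
inputs produce identical outputs (there is no unseeded randomness
anywhere in the pipeline).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import components
from .annotation import AnnotationConfig, annotate, residue_sse_map
from .conformation import classify_residue
from .curation import (CLIP_FAIL, INCOMPLETE_SSE, PROCESSING, CurationError,
                       MotifInstance, canonicalize_sequence, classify_rna_type,
                       clip_all_hairpins, filter_entries, match_unmodified,
                       select_nmr_representative)
from .srs import SRSRecord, compare_pair, diff_interactions, select_srs
from .structure_io import NMR, ParseError, parse_structure, screen_residue
from .srs import ComparisonResult

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SurveyReport", "run_pipeline", "tabulate",
           "load_config"]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; thresholds default to the survey's
    published settings."""

    modified_dir: str | Path = "modified"
    library_dir: str | Path | None = "library"
    out_dir: str | Path | None = None
    max_resolution: float = 3.0       # Angstrom, X-ray/EM filter
    contact_cutoff: float = 4.0       # Angstrom, H-bond/stacking
    similarity_threshold: float = 1.0  # Angstrom, SRS comparison
    amplitude_floor: float = 5.0      # degrees, pucker classifiability
    stack_normal_max: float = 30.0
    stack_centroid_max: float = 5.5
    pair_coplanarity_max: float = 45.0

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(
            contact_cutoff=self.contact_cutoff,
            stack_normal_max=self.stack_normal_max,
            stack_centroid_max=self.stack_centroid_max,
            pair_coplanarity_max=self.pair_coplanarity_max)


def load_config(path) -> PipelineConfig:
    """Read a flat ``key = value`` (or ``key: value``) config document."""
    cfg = PipelineConfig()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.replace(":", "=", 1).partition("=")
            key = key.strip()
            value = value.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
    return cfg


@dataclass
class SurveyReport:
    """Summary of one pipeline run (counts, distributions, comparisons)."""

    residue_records: pd.DataFrame = field(default_factory=pd.DataFrame)
    structure_counts: dict = field(default_factory=dict)   # mod -> method -> n
    residue_totals: dict = field(default_factory=dict)     # mod -> n residues
    sse_distribution: dict = field(default_factory=dict)   # mod -> {sse: pct}
    rna_type_distribution: dict = field(default_factory=dict)
    pucker_distribution: dict = field(default_factory=dict)
    chi_distribution: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)        # ComparisonResult
    interaction_deltas: dict = field(default_factory=dict)  # pair id -> deltas
    n_pairs: int = 0
    n_similar: int = 0
    exclusions: dict = field(default_factory=dict)         # entry -> [reasons]
    curation_rows: list = field(default_factory=list)
    srs_records: list = field(default_factory=list)

    @property
    def fraction_similar(self) -> float | None:
        return self.n_similar / self.n_pairs if self.n_pairs else None


def _collapse_misc(counts: dict[str, int], total: int) -> dict[str, float]:
    """Percentage distribution; categories individually < 1% collapse
    into MISC (strictly less than: a category at exactly 1.0% stays)."""
    if total == 0:
        return {}
    out: dict[str, float] = {}
    misc = 0.0
    for cat, n in sorted(counts.items()):
        pct = 100.0 * n / total
        if pct < 1.0:
            misc += pct
        else:
            out[cat] = out.get(cat, 0.0) + pct
    if misc > 0:
        out["MISC"] = out.get("MISC", 0.0) + misc
    return out


def tabulate(records: pd.DataFrame, comparisons=None) -> SurveyReport:
    """Build the survey report from per-residue records.

    ``records`` columns: entry_id, method, comp_id, chain, seq_num,
    sse, rna_type, pucker_class, chi_class.  Distributions are
    normalized per modification over its residues.
    """
    report = SurveyReport(residue_records=records)
    comparisons = comparisons or []
    if len(records):
        for mod, sub in records.groupby("comp_id", sort=True):
            mod = str(mod)
            report.residue_totals[mod] = int(len(sub))
            report.structure_counts[mod] = {
                str(m): int(n) for m, n in
                sub.groupby("method")["entry_id"].nunique().items()}
            total = len(sub)
            for col, dest in (("sse", report.sse_distribution),
                              ("rna_type", report.rna_type_distribution),
                              ("pucker_class", report.pucker_distribution),
                              ("chi_class", report.chi_distribution)):
                counts = {str(k): int(v) for k, v in
                          sub[col].value_counts().items()}
                dest[mod] = _collapse_misc(counts, total)
    report.comparisons = list(comparisons)
    report.n_pairs = len(report.comparisons)
    report.n_similar = sum(1 for c in report.comparisons if c.similar)
    return report


def _load_entries(directory, exclusions):
    entries = []
    for path in sorted(Path(directory).glob("*.cif")) + sorted(Path(directory).glob("*.pdb")):
        try:
            entries.append(parse_structure(path))
        except ParseError as exc:
            logger.warning("parse failure %s: %s", path, exc)
            exclusions.setdefault(path.stem.upper(), []).append(PROCESSING)
    return entries


def _prepare(entries, config, exclusions):
    """Filter + NMR-reduce; returns single-model working entries."""
    kept, logs = filter_entries(entries, max_resolution=config.max_resolution)
    for entry_id, log in logs.items():
        for reason in log.reasons:
            exclusions.setdefault(entry_id, []).append(reason)
    working = []
    for entry in kept:
        if entry.method == NMR and len(entry.models) > 1:
            try:
                entry, _ = select_nmr_representative(entry)
            except Exception as exc:  # quarantine, keep going
                logger.warning("representative selection failed %s: %s",
                               entry.entry_id, exc)
                exclusions.setdefault(entry.entry_id, []).append(PROCESSING)
                continue
        working.append(entry)
    return working


def _clip_motifs(working, config, exclusions):
    """Annotate entries and clip hairpins; returns (per-entry annotation,
    motifs)."""
    annotations, motifs = {}, []
    for entry in working:
        try:
            ann = annotate(entry.model, config.annotation_config())
        except Exception as exc:
            logger.warning("annotation failed %s: %s", entry.entry_id, exc)
            exclusions.setdefault(entry.entry_id, []).append(PROCESSING)
            continue
        annotations[entry.entry_id] = (entry, ann)
        clipped, failures = clip_all_hairpins(entry, ann)
        motifs.extend(clipped)
        for failure in failures:
            reason = CLIP_FAIL if CLIP_FAIL in failure else INCOMPLETE_SSE
            exclusions.setdefault(entry.entry_id, []).append(reason)
    return annotations, motifs


def _residue_records(annotations, config) -> pd.DataFrame:
    rows = []
    for entry_id in sorted(annotations):
        entry, ann = annotations[entry_id]
        sse_map = residue_sse_map(ann.sses)
        for chain_id, residues in entry.model.chains.items():
            rna_type = classify_rna_type(entry, chain_id)
            for r in residues:
                if not components.is_modified(r.comp_id):
                    continue
                screened = screen_residue(r)
                target = screened.residue if screened.ok else r
                call = classify_residue(target, config.amplitude_floor)
                key = (r.chain_id, r.seq_num, r.icode, r.comp_id)
                rows.append({
                    "entry_id": entry.entry_id, "method": entry.method,
                    "comp_id": r.comp_id, "chain": chain_id,
                    "seq_num": r.seq_num,
                    "sse": sse_map.get(key, "MISC"),
                    "rna_type": rna_type,
                    "pucker_class": call.pucker_class,
                    "chi_class": call.chi_class,
                    "P": call.P, "nu_max": call.nu_max, "chi": call.chi,
                })
    columns = ["entry_id", "method", "comp_id", "chain", "seq_num", "sse",
               "rna_type", "pucker_class", "chi_class", "P", "nu_max", "chi"]
    return pd.DataFrame(rows, columns=columns)


def _group_srs(motifs) -> dict[tuple, SRSRecord]:
    groups: dict[tuple, list[MotifInstance]] = {}
    for m in motifs:
        groups.setdefault((m.sse_type, m.sequence), []).append(m)
    out = {}
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda m: m.motif_id)
        out[key] = select_srs(members)
    return out


def run_pipeline(config: PipelineConfig) -> SurveyReport:
    """Execute the full survey and (optionally) write artifacts to
    ``config.out_dir``."""
    exclusions: dict[str, list[str]] = {}
    entries = _load_entries(config.modified_dir, exclusions)
    working = _prepare(entries, config, exclusions)
    annotations, motifs = _clip_motifs(working, config, exclusions)
    records = _residue_records(annotations, config)

    modified_motifs = [m for m in motifs if m.is_modified()]
    motif_lookup = {m.motif_id: m for m in motifs}
    srs_by_group = _group_srs(modified_motifs)

    library_srs: dict[tuple, SRSRecord] = {}
    library_lookup: dict[str, MotifInstance] = {}
    library_annotations = {}
    if config.library_dir and Path(config.library_dir).exists():
        lib_entries = _load_entries(config.library_dir, exclusions)
        lib_working = _prepare(lib_entries, config, exclusions)
        lib_ann, lib_motifs = _clip_motifs(lib_working, config, exclusions)
        lib_motifs = [m for m in lib_motifs if not m.is_modified()]
        library_lookup = {m.motif_id: m for m in lib_motifs}
        library_srs = _group_srs(lib_motifs)
        library_annotations = lib_ann

    comparisons: list[ComparisonResult] = []
    deltas = {}
    for key in sorted(srs_by_group):
        record = srs_by_group[key]
        motif = motif_lookup[record.representative_id]
        canonical = canonicalize_sequence(motif.sequence)
        counterparts = match_unmodified(
            motif, [library_lookup[r.representative_id]
                    for r in library_srs.values()])
        for cand in counterparts:
            result = compare_pair(motif, cand,
                                  threshold=config.similarity_threshold)
            comparisons.append(result)
            mod_ann = annotations[motif.entry_id][1]
            unmod_ann = library_annotations[cand.entry_id][1]
            deltas[(result.modified_id, result.unmodified_id)] = (
                diff_interactions(motif, mod_ann, cand, unmod_ann))

    report = tabulate(records, comparisons)
    report.exclusions = {k: sorted(v) for k, v in sorted(exclusions.items())}
    report.interaction_deltas = deltas
    report.srs_records = [srs_by_group[k] for k in sorted(srs_by_group)]
    report.srs_records += [library_srs[k] for k in sorted(library_srs)]
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: SurveyReport, out_dir) -> None:
    """Write the report as deterministic delimited-text artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.residue_records.to_csv(out_dir / "residues.tsv", sep="\t",
                                  index=False, float_format="%.3f")
    rows = [{"modified_id": c.modified_id, "unmodified_id": c.unmodified_id,
             "n_paired_atoms": c.n_paired_atoms, "rmsd": round(c.rmsd, 4),
             "similar": c.similar,
             "dropped": ";".join(
                 f"{pos}:{'|'.join(dm)}/{'|'.join(du)}"
                 for pos, (dm, du) in sorted(c.dropped_atoms.items()))}
            for c in report.comparisons]
    pd.DataFrame(rows, columns=["modified_id", "unmodified_id",
                                "n_paired_atoms", "rmsd", "similar",
                                "dropped"]).to_csv(
        out_dir / "comparisons.tsv", sep="\t", index=False)
    summary = {
        "structure_counts": report.structure_counts,
        "residue_totals": report.residue_totals,
        "sse_distribution": report.sse_distribution,
        "rna_type_distribution": report.rna_type_distribution,
        "pucker_distribution": report.pucker_distribution,
        "chi_distribution": report.chi_distribution,
        "n_pairs": report.n_pairs,
        "n_similar": report.n_similar,
        "fraction_similar": report.fraction_similar,
        "exclusions": report.exclusions,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out_dir / "curation_log.tsv", "w") as fh:
        fh.write("entry_id\treason\n")
        for entry_id, reasons in sorted(report.exclusions.items()):
            for reason in reasons:
                fh.write(f"{entry_id}\t{reason}\n")
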