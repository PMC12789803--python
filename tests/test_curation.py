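"""Dataset filters, NMR reduction, canonicalization, clipping and
counterpart matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from urimod import synth
from urimod.annotation import HAIRPIN, annotate
from urimod.curation import (CurationError, UnknownComponentError,
                             canonicalize_sequence, classify_rna_type,
                             clip_all_hairpins, clip_motif, filter_entries,
                             match_unmodified, parse_motif_id,
                             select_nmr_representative)
from urimod.geometry import CoordinateSet, kabsch_superpose
from urimod.structure_io import EM, NMR, OTHER, StructureEntry, XRAY


def _entry(method, resolution, entry_id="E1"):
    return StructureEntry(entry_id=entry_id, method=method,
                          resolution=resolution, models=[None])


class TestResolutionFilter:
    @pytest.mark.parametrize("method,res,kept", [
        (XRAY, 2.5, True), (EM, 3.2, False), (EM, 3.0, True),
        (XRAY, 3.01, False), (NMR, None, True), (XRAY, None, False),
        (EM, None, False),
    ])
    def test_boundary_semantics(self, method, res, kept):
        entries, logs = filter_entries([_entry(method, res)])
        assert (len(entries) == 1) is kept
        if not kept:
            assert "RESOLUTION" in logs["E1"].reasons

    @settings(max_examples=60, derandomize=True)
    @given(st.sampled_from([XRAY, EM, NMR, OTHER]),
           st.one_of(st.none(), st.floats(min_value=0.5, max_value=6.0)))
    def test_kept_iff_nmr_or_within_cutoff(self, method, res):
        if method in (NMR, OTHER):
            res = None
        kept, _ = filter_entries([_entry(method, res)])
        expected = method not in (XRAY, EM) or (res is not None and res <= 3.0)
        assert (len(kept) == 1) is expected


class TestNMRRepresentative:
    def test_planted_low_noise_model_selected(self):
        spec = synth.GeneratorSpec(loop_sequence="UUCAAAG", method=NMR,
                                   resolution=None, n_models=8,
                                   noise_sigma=0.5, planted_model=3, seed=21)
        entry, manifest = synth.build_hairpin(spec)
        single, result = select_nmr_representative(entry)
        assert result.index == manifest.representative_model == 3
        assert len(single.models) == 1

    def test_matches_brute_force_oracle(self):
        spec = synth.GeneratorSpec(loop_sequence="GAAAU", method=NMR,
                                   resolution=None, n_models=6,
                                   noise_sigma=0.4, planted_model=2, seed=5)
        entry, _ = synth.build_hairpin(spec)
        _, result = select_nmr_representative(entry)
        # oracle: per-model coordinate sets, iterate the mean by hand
        sets = []
        for model in entry.models:
            labels, coords = [], []
            for r in model.residues():
                for a in r.atoms:
                    labels.append((r.chain_id, r.seq_num, a.name))
                    coords.append(a.pos)
            sets.append(CoordinateSet(tuple(labels), np.array(coords)))
        mean = sets[0].coords.copy()
        for _ in range(50):
            aligned = []
            for s in sets:
                sup = kabsch_superpose(s, CoordinateSet(sets[0].labels, mean))
                aligned.append(sup.apply(s.coords))
            mean = np.mean(aligned, axis=0)
        rmsds = [kabsch_superpose(s, CoordinateSet(sets[0].labels, mean)).rmsd
                 for s in sets]
        assert result.index == int(np.argmin(rmsds))

    def test_single_model_entry_is_identity(self):
        spec = synth.GeneratorSpec(loop_sequence="GAAAU", method=NMR,
                                   resolution=None)
        entry, _ = synth.build_hairpin(spec)
        entry.method = NMR
        single, result = select_nmr_representative(entry)
        assert result.index == 0
        assert result.rmsds == (0.0,)

    def test_zero_noise_ties_to_first_model(self):
        spec = synth.GeneratorSpec(loop_sequence="GAAAU", method=NMR,
                                   resolution=None, n_models=4,
                                   noise_sigma=0.0, seed=1)
        entry, _ = synth.build_hairpin(spec)
        _, result = select_nmr_representative(entry)
        assert result.index == 0


class TestCanonicalize:
    @pytest.mark.parametrize("display,canonical", [
        ("GGuAAGC", "GGUAAGC"),
        ("UGPPCAAAG", "UGUUCAAAG"),
        ("ACGU", "ACGU"),
        ("GtPCAAGUC", "GUUCAAGUC"),
    ])
    def test_examples(self, display, canonical):
        assert canonicalize_sequence(display) == canonical

    def test_unknown_character_rejected(self):
        with pytest.raises(UnknownComponentError):
            canonicalize_sequence("GGxAAGC")

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGUPtu", min_size=0, max_size=30))
    def test_idempotent_and_length_preserving(self, seq):
        once = canonicalize_sequence(seq)
        assert len(once) == len(seq)
        assert canonicalize_sequence(once) == once


class TestClip:
    def test_clip_includes_closing_pair(self):
        spec = synth.GeneratorSpec(entry_id="SYN1", chain_id="9",
                                   start_seq_num=820, stem_bp=3,
                                   loop_sequence="UUCAAAG")
        entry, _ = synth.build_hairpin(spec)
        ann = annotate(entry.model)
        sse = next(s for s in ann.sses if s.sse_type == HAIRPIN)
        motif = clip_motif(entry, sse)
        assert len(motif.residues) == 9  # 7-nt loop + closing pair
        assert motif.loop_size == 7
        assert motif.motif_id == f"SYN1_{motif.sequence}_9_822"

    def test_motif_id_round_trip(self, simple_hairpin):
        entry, _ = simple_hairpin
        motifs, _ = clip_all_hairpins(entry)
        assert len(motifs) == 1
        entry_id, seq, chain, start = parse_motif_id(motifs[0].motif_id)
        assert (entry_id, chain, start) == (motifs[0].entry_id,
                                            motifs[0].chain_id,
                                            motifs[0].start_seq_num)
        assert seq == motifs[0].sequence

    def test_pentaloop_clip_is_seven_characters(self):
        spec = synth.GeneratorSpec(loop_sequence="GAAAU", stem_bp=2,
                                   modifications=((6, "UR3"),))
        entry, _ = synth.build_hairpin(spec)
        motifs, _ = clip_all_hairpins(entry)
        assert len(motifs[0].sequence) == 7
        assert motifs[0].loop_size == 5
        assert "u" in motifs[0].sequence

    def test_missing_atom_in_span_fails_clip(self, tmp_path):
        spec = synth.GeneratorSpec(loop_sequence="UUCAAAG")
        entry, _ = synth.build_hairpin(spec)
        res = entry.model.chains["A"][1]  # closing-pair residue
        res.atoms = [a for a in res.atoms if a.name != "O2'"]
        motifs, failures = clip_all_hairpins(entry)
        assert motifs == []
        assert any("CLIP_FAIL" in f for f in failures)

    def test_numbering_gap_is_incomplete_sse(self):
        spec = synth.GeneratorSpec(loop_sequence="UUCAAAG")
        entry, _ = synth.build_hairpin(spec)
        ann = annotate(entry.model)
        sse = next(s for s in ann.sses if s.sse_type == HAIRPIN)
        entry.model.chains["A"][5].seq_num = 99  # break contiguity
        with pytest.raises(CurationError, match="INCOMPLETE_SSE"):
            clip_motif(entry, sse)


class TestMatchUnmodified:
    def _motifs(self, *specs):
        out = []
        for spec in specs:
            entry, _ = synth.build_hairpin(spec)
            motifs, _ = clip_all_hairpins(entry)
            out.extend(motifs)
        return out

    def test_exact_canonical_match_returned(self):
        mod, lib = self._motifs(
            synth.GeneratorSpec(entry_id="M", loop_sequence="UUCAAAG",
                                modifications=((3, "PSU"),)),
            synth.GeneratorSpec(entry_id="L", loop_sequence="UUCAAAG"))
        matches = match_unmodified(mod, [lib])
        assert [m.entry_id for m in matches] == ["L"]

    def test_loop_mismatch_not_returned(self):
        mod, lib = self._motifs(
            synth.GeneratorSpec(entry_id="M", loop_sequence="UUCAAAG",
                                modifications=((3, "PSU"),)),
            synth.GeneratorSpec(entry_id="L", loop_sequence="UUCAAGG"))
        assert match_unmodified(mod, [lib]) == []

    def test_modified_library_entries_never_returned(self):
        mod, lib = self._motifs(
            synth.GeneratorSpec(entry_id="M", loop_sequence="UUCAAAG",
                                modifications=((3, "PSU"),)),
            synth.GeneratorSpec(entry_id="L", loop_sequence="UUCAAAG",
                                modifications=((2, "OMU"),)))
        assert match_unmodified(mod, [lib]) == []

    def test_conformers_both_returned(self):
        mod, lib1, lib2 = self._motifs(
            synth.GeneratorSpec(entry_id="M", loop_sequence="GAAAU",
                                modifications=((6, "4SU"),)),
            synth.GeneratorSpec(entry_id="L1", loop_sequence="GAAAU"),
            synth.GeneratorSpec(entry_id="L2", loop_sequence="GAAAU",
                                pucker_overrides={3: (162.0, 38.0)}))
        matches = match_unmodified(mod, [lib1, lib2])
        assert {m.entry_id for m in matches} == {"L1", "L2"}


class TestRNAType:
    @pytest.mark.parametrize("text,expected", [
        ("23S ribosomal RNA", "rRNA"),
        ("transfer RNA-Asp", "tRNA"),
        ("messenger RNA fragment", "mRNA"),
        ("U4 snRNA spliceosomal", "snRNA"),
        ("RNA (5'-R(*GP*AP*C)-3') synthetic construct", "synthetic"),
        ("ribozyme domain", "other"),
        ("", "other"),
    ])
    def test_keyword_rules(self, text, expected):
        entry = StructureEntry(entry_id="X", method=XRAY, resolution=2.0,
                               models=[None],
                               molecule_descriptions={"A": text} if text else {})
        assert classify_rna_type(entry, "A") == expected
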