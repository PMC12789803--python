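"""Hydrogen-bond, stacking, base-pair and SSE detection."""

import numpy as np
import pytest

from urimod import synth
from urimod.annotation import (HAIRPIN, HELIX, JUNCTION, WCF, WOBBLE,
                               annotate, detect_base_pairs, detect_hbonds,
                               detect_stacks, assign_sses, residue_sse_map)
from urimod.structure_io import Atom, Model, Residue


def _two_atom_model(distance):
    """An N donor and an O acceptor on separate single-atom residues."""
    r1 = Residue("U", "A", 1, atoms=[Atom("N3", "N", np.zeros(3))])
    r2 = Residue("U", "A", 2, atoms=[Atom("O4", "O",
                                          np.array([distance, 0.0, 0.0]))])
    return Model(chains={"A": [r1, r2]})


class TestHBonds:
    def test_contact_within_cutoff(self):
        hb = detect_hbonds(_two_atom_model(2.9))
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(2.9)

    def test_cutoff_boundary_inclusive(self):
        assert len(detect_hbonds(_two_atom_model(4.000))) == 1
        assert len(detect_hbonds(_two_atom_model(4.001))) == 0

    def test_intra_residue_pairs_excluded(self):
        r = Residue("U", "A", 1, atoms=[Atom("N3", "N", np.zeros(3)),
                                        Atom("O4", "O", np.array([1.2, 0, 0]))])
        assert detect_hbonds(Model(chains={"A": [r]})) == []

    @pytest.mark.parametrize("kind,bonds", [
        ("GC", {("N1", "N3"), ("N2", "O2"), ("N4", "O6")}),
        ("AU", {("N6", "O4"), ("N3", "N1")}),
        ("GU", {("N1", "O2"), ("N3", "O6")}),
    ])
    def test_ideal_fixture_canonical_bond_sets(self, kind, bonds):
        model = synth.ideal_pair_fixture(kind)
        hb = detect_hbonds(model)
        assert {(h.donor.atom, h.acceptor.atom) for h in hb} == bonds

    def test_omu_sugar_no_longer_donates(self):
        # 2'-O-methylation removes the O2' donor, not the acceptor role
        spec = synth.GeneratorSpec(loop_sequence="GUAA",
                                   modifications=((3, "OMU"),))
        entry, _ = synth.build_hairpin(spec)
        hb = detect_hbonds(entry.model)
        omu_donors = {h.donor.atom for h in hb
                      if h.donor.residue.comp_id == "OMU"}
        assert "O2'" not in omu_donors


class TestStacks:
    def _base_residue(self, seq_num, rot=np.eye(3), shift=(0.0, 0.0, 0.0)):
        atoms = synth.build_nucleotide("A")
        res = synth._residue_from_atoms(atoms, "A", "A", seq_num)
        res.atoms = [Atom(a.name, a.element, rot @ a.pos + np.asarray(shift))
                     for a in res.atoms
                     if a.name in ("N1", "C2", "N3", "C4", "C5", "C6",
                                   "N7", "C8", "N9")]
        return res

    def test_parallel_bases_stack(self):
        r1 = self._base_residue(1)
        r2 = self._base_residue(2, shift=(0.3, 0.0, 3.4))
        stacks = detect_stacks(Model(chains={"A": [r1, r2]}))
        assert len(stacks) == 1
        assert stacks[0].normal_angle == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_bases_do_not_stack(self):
        rot = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        r1 = self._base_residue(1)
        r2 = self._base_residue(2, rot=rot, shift=(0.0, 0.0, 3.4))
        assert detect_stacks(Model(chains={"A": [r1, r2]})) == []

    def test_coplanar_side_by_side_not_stacked(self):
        # paired-like geometry: parallel normals but rings far apart
        r1 = self._base_residue(1)
        r2 = self._base_residue(2, shift=(8.5, 0.0, 0.0))
        assert detect_stacks(Model(chains={"A": [r1, r2]})) == []

    def test_h2u_flagged_saturated(self):
        spec = synth.GeneratorSpec(loop_sequence="UUCAAAG",
                                   modifications=((0 + 2, "H2U"),))
        entry, _ = synth.build_hairpin(spec)
        stacks = detect_stacks(entry.model)
        h2u_stacks = [s for s in stacks
                      if "H2U" in (s.res_a.comp_id, s.res_b.comp_id)]
        assert h2u_stacks and all(s.saturated for s in h2u_stacks)


class TestBasePairs:
    @pytest.mark.parametrize("kind,expected", [
        ("GC", WCF), ("AU", WCF), ("GU", WOBBLE),
    ])
    def test_ideal_fixture_classification(self, kind, expected):
        model = synth.ideal_pair_fixture(kind)
        pairs = detect_base_pairs(detect_hbonds(model), model)
        assert len(pairs) == 1
        assert pairs[0].pair_type == expected

    def test_single_hbond_is_not_a_pair(self):
        model = _two_atom_model(2.9)
        assert detect_base_pairs(detect_hbonds(model), model) == []

    def test_output_symmetric_in_residue_order(self):
        model = synth.ideal_pair_fixture("GC")
        model.chains["A"] = list(reversed(model.chains["A"]))
        pairs = detect_base_pairs(detect_hbonds(model), model)
        assert len(pairs) == 1
        assert {pairs[0].res_a.seq_num, pairs[0].res_b.seq_num} == {1, 2}

    def test_stacked_neighbours_are_not_pairs(self, simple_hairpin):
        # parallel but vertically separated bases must not register
        entry, manifest = simple_hairpin
        pairs = detect_base_pairs(detect_hbonds(entry.model), entry.model)
        found = {tuple(sorted((p.res_a.seq_num, p.res_b.seq_num)))
                 for p in pairs if p.pair_type in (WCF, WOBBLE)}
        assert found == set(map(tuple, manifest.pairing))


class TestSSEs:
    @pytest.mark.parametrize("loop", ["UUCG", "GAAAU", "AAUUAA", "UUCAAAG",
                                      "UUCAAAGG", "CAAAGGAAU", "AACAAGGUAU"])
    def test_hairpin_loop_sizes_recovered(self, loop):
        spec = synth.GeneratorSpec(loop_sequence=loop)
        entry, manifest = synth.build_hairpin(spec)
        ann = annotate(entry.model)
        hairpins = [s for s in ann.sses if s.sse_type == HAIRPIN]
        assert len(hairpins) == 1
        assert hairpins[0].loop_size == len(loop) == manifest.loop_size

    def test_duplex_is_helix_only(self):
        # antiparallel two-chain duplex: A1-B3, A2-B2, A3-B1
        model = Model(chains={"A": [], "B": []})
        b_strand = {}
        for k, kind in enumerate(("GC", "AU", "GC")):
            pair = synth.ideal_pair_fixture(kind, base_only=False)
            r1, r2 = pair.chains["A"]
            shift = np.array([0.0, 0.0, 3.4 * k])
            model.chains["A"].append(Residue(
                r1.comp_id, "A", k + 1,
                atoms=[Atom(a.name, a.element, a.pos + shift)
                       for a in r1.atoms]))
            b_strand[3 - k] = Residue(
                r2.comp_id, "B", 3 - k,
                atoms=[Atom(a.name, a.element, a.pos + shift)
                       for a in r2.atoms])
        model.chains["B"] = [b_strand[n] for n in sorted(b_strand)]
        ann = annotate(model)
        types = {s.sse_type for s in ann.sses}
        assert HELIX in types
        assert HAIRPIN not in types

    def test_cloverleaf_recovers_junction_and_hairpins(self):
        entry, manifest = synth.build_cloverleaf()
        ann = annotate(entry.model)
        found = {tuple(sorted((p.res_a.seq_num, p.res_b.seq_num)))
                 for p in ann.pairs if p.pair_type in (WCF, WOBBLE)}
        assert found == set(map(tuple, manifest.pairing))
        types = [s.sse_type for s in ann.sses]
        assert types.count(JUNCTION) == 1
        assert types.count(HAIRPIN) == 3
        assert types.count(HELIX) == 4

    def test_loop_recovery_under_noise(self):
        # loop sizes recovered exactly at sigma = 0.25 A over seeded replicates
        failures = 0
        for seed in range(20):
            spec = synth.GeneratorSpec(loop_sequence="UUCAAAG", seed=seed,
                                       n_models=1, noise_sigma=0.0)
            entry, _ = synth.build_hairpin(spec)
            rng = np.random.default_rng(seed)
            for r in entry.model.residues():
                r.atoms = [Atom(a.name, a.element,
                                a.pos + rng.normal(0.0, 0.25, 3))
                           for a in r.atoms]
            ann = annotate(entry.model)
            hairpins = [s for s in ann.sses if s.sse_type == HAIRPIN]
            if len(hairpins) != 1 or hairpins[0].loop_size != 7:
                failures += 1
        assert failures == 0

    def test_residue_sse_map_includes_closing_pair_in_hairpin(self, simple_hairpin):
        entry, manifest = simple_hairpin
        ann = annotate(entry.model)
        smap = residue_sse_map(ann.sses)
        by_num = {ref.seq_num: sse for ref, sse in smap.items()}
        # closing pair (2, 10) counts with the hairpin; outer pair stays helix
        assert by_num[2] == HAIRPIN and by_num[10] == HAIRPIN
        assert by_num[1] == HELIX and by_num[11] == HELIX
        assert all(by_num[n] == HAIRPIN for n in range(3, 10))


class TestExternalReader:
    def test_dssr_style_json_round_trip(self, tmp_path):
        import json
        from urimod.annotation import load_external_annotation
        doc = {
            "hbonds": [{"atom1_id": "N1@A.G1", "atom2_id": "N3@A.C11",
                        "distance": 2.92}],
            "pairs": [{"nt1": "A.G1", "nt2": "A.C11", "name": "WC",
                       "hbonds_num": 3},
                      {"nt1": "A.PSU3", "nt2": "A.A7", "name": "Hoogsteen",
                       "hbonds_num": 2}],
        }
        path = tmp_path / "ext.json"
        path.write_text(json.dumps(doc))
        ann = load_external_annotation(path)
        assert ann.hbonds[0].distance == pytest.approx(2.92)
        assert ann.hbonds[0].donor.atom == "N1"
        assert ann.pairs[0].pair_type == "WCF"
        assert ann.pairs[1].res_a.comp_id == "PSU"
        assert ann.pairs[1].res_a.seq_num == 3
        assert ann.pairs[1].pair_type == "HOOGSTEEN"
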