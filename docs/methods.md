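# Methods

This note documents the models, conventions and numerical choices behind
the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Scope and data model

The pipeline operates on RNA-containing 3D structures (mmCIF preferred,
legacy PDB supported) and surveys six uridine modifications: PSU
(pseudouridine), 5MU (5-methyluridine), UR3 (3-methyluridine), OMU
(2′-O-methyluridine), 4SU (4-thiouridine) and H2U (5,6-dihydrouridine).
Author chain identifiers and author residue numbers are authoritative
throughout, because motif identifiers (`ENTRY_sequence_chain_start`)
are built from them. The modification dictionary maps each 3-character
component code to its canonical parent (U for all six), a display
character (P, t, and lowercase u for the remaining four — the shared
letter follows the motif-naming convention in the field), a
base/sugar class, and the base-side atoms of the glycosidic torsion.
The dictionary is an editable whitespace-delimited table
(`components.dump_modification_table`).

## Curation

* **Resolution filter.** X-ray and cryo-EM entries pass iff resolution
  ≤ 3.0 Å (inclusive). NMR entries carry no resolution and always pass
  this filter. X-ray/EM entries without a stated resolution are
  excluded (reason `RESOLUTION`): a missing number cannot demonstrate
  sufficient quality.
* **NMR reduction.** The ensemble mean is computed iteratively: all
  models are superposed onto the running mean (initialized from model
  1), the per-atom arithmetic mean of the aligned coordinates is taken,
  and the loop repeats until the mean moves < 10⁻⁴ Å (max per-atom
  displacement) or 20 iterations. The model with the lowest all-atom
  RMSD to this mean (each model re-superposed onto the mean before
  measuring) is the representative. Ties go to the lowest model index.
  Models with unequal topology are intersected on shared heavy atoms
  with a warning. Only this representative model enters the analysis.
* **Residue screen.** Hydrogens are removed (element field, else a
  leading-H-after-digits name pattern); alternate locations collapse to
  the highest-occupancy location, ties broken alphabetically by
  alternate-location id (the choice is logged — deposition practice
  varies and no single rule is standard); any missing reference heavy
  atom rejects the residue. The 5′-terminal phosphate group (P, OP1,
  OP2) is treated as optional so chain-terminal residues are not
  rejected wholesale. Missing occupancies default to 1.0.

## Conformational classification

* **Pucker.** The five endocyclic torsions ν0(C4′-O4′-C1′-C2′) …
  ν4(C3′-C4′-O4′-C1′) reduce to the Altona–Sundaralingam phase
  tan P = ((ν4+ν1) − (ν3+ν0)) / (2 ν2 (sin 36° + sin 72°)), evaluated
  with atan2 for the full [0°, 360°) range, with amplitude
  ν_max = ν2 / cos P. The class is the canonical pucker with the
  nearest ideal phase — ten 36°-wide bins starting at C3′-endo = 18°.
  Rings with ν_max below a 5° amplitude floor are UNSPECIFIED; the
  floor is configurable, since published annotation tools do not state
  their exact criterion.
* **Glycosidic angle.** χ is O4′-C1′-N1-C2 for pyrimidines,
  O4′-C1′-N9-C4 for purines, and O4′-C1′-C5-C4 for the C-glycoside PSU
  (mirroring the pyrimidine pattern across the carbon–carbon bond; the
  atoms used are recorded per residue for auditability). H2U keeps the
  standard pyrimidine atoms — saturation of C5=C6 does not remove N1.
  syn is χ ∈ [−90°, +90°] with both boundaries inclusive (the
  literature definition leaves the edges unstated; a closed interval is
  the simplest deterministic reading). Missing atoms degrade to an
  "unspecified" call rather than an error.
* Torsions follow the IUPAC sign convention (cis = 0°, range
  (−180°, 180°], verified against biotite). Note the IUPAC dihedral is
  invariant under full reversal of the atom chain and negated under
  coordinate mirroring.

## Annotation

* **Hydrogen bonds** are donor–acceptor heavy-atom pairs within 4.0 Å,
  boundary inclusive. No angular term is applied by default: the screen
  removed hydrogens, so donor geometry is not available without
  inference. Donor/acceptor tables are per-component: the N3 imino
  donor is lost in UR3 (methylated), the O2′ donor is lost in OMU (the
  methylated hydroxyl still accepts), PSU gains the free N1-H donor,
  4SU accepts on S4 instead of O4. Non-nucleotide residues (amino
  acids) fall back to treating every N/O/S atom as both donor and
  acceptor.
* **Stacking** requires minimum inter-ring atom distance ≤ 4.0 Å,
  base-plane normal angle ≤ 30°, and ring-centroid separation ≤ 5.5 Å.
  The distance cutoff is the published 4.0 Å default of DSSR-style
  annotation; the angular and centroid bounds are this package's own
  geometric closure of the underdocumented criterion, and all three are
  exposed in the configuration. H2U's saturated ring is treated
  geometrically as a ring and the contact flagged `saturated`.
* **Base pairs** need ≥ 2 base–base hydrogen bonds between
  near-coplanar bases. "Near-coplanar" means inter-plane normal angle
  ≤ 45° *and* mutual centroid-to-plane offset ≤ 2.5 Å; the offset bound
  is required because consecutive stacked bases are parallel (normal
  angle ≈ 0°) and would otherwise satisfy a normal-angle test alone.
  Classification is by participating edge atoms: any purine N7 contact
  → Hoogsteen; both sides confined to their Watson–Crick–Franklin edges
  → WCF for G·C / A·U combinations, wobble for G·U; anything else →
  OTHER.
* **SSEs.** Only WCF/wobble pairs define helices. Each residue keeps at
  most one partner (more hydrogen bonds preferred, then the 5′-most
  pair). Helices are runs of ≥ 2 consecutive nested pairs; a greedy
  maximal nested subset (longest helix first, ties by 5′ position)
  removes pseudoknots, which cannot participate in loop nesting. The
  region enclosed by a helix's innermost pair is classified by its
  nested children: none → hairpin (if single-chain and contiguous in
  author numbering, else MISC), one → internal loop or bulge, several →
  junction. Unpaired runs outside every helix are MISC. For per-residue
  survey tabulation, the residues of a hairpin's closing pair count
  with the hairpin — the clipped motif includes them.

## Motifs, SRS selection and comparison

A clipped hairpin comprises the loop plus the first closing base pair,
so clipped length = loop size + 2 (a pentaloop is a 7-character motif).
Every clipped residue must pass the screen (else `CLIP_FAIL`); a
numbering gap inside the span is `INCOMPLETE_SSE`.

Counterpart matching replaces a web motif database with exact-sequence
search over a local library: a candidate must match SSE type, loop
size, and the full canonicalized clipped sequence (closing pair
included — the figure-level pairing convention in this field matches
whole clipped sequences), and must contain no modified residue.

SRS groups share (SSE type, display sequence). The representative is
the member with the lowest all-atom RMSD to the group's iterative mean,
computed over the (position, atom-name) labels shared by all members;
ties go to the first member in sorted motif-id order.

Comparison pairs atoms position-by-position by name; atoms with no
same-name counterpart (5MU C5M, UR3 C3U, OMU CM2, 4SU S4 vs O4) are
dropped from the correspondence and reported. PSU pairs every base atom
— its heavy-atom name set equals uridine's. Superposition is Kabsch
with SVD sign correction: reflections are excluded because nucleic-acid
chirality must survive superposition. similar ⟺ RMSD ≤ 1.0 Å, boundary
inclusive. Superposition and RMSD use all clipped atoms (loop plus
closers), consistent with an all-atom comparison of the clipped
element. Interaction differencing normalizes each contact to
(kind, partner): in-motif partners by motif position, tertiary partners
(including amino acids) by component + author number + chain; distances
are not part of the identity. Interactions are computed in the parent
structure, so tertiary contacts count; a motif-only comparison is
available by annotating the clipped motif instead.

When several modified variants map to one canonical sequence they form
distinct display-sequence groups, each compared against the single
unmodified SRS of that canonical sequence.

## Numerical kernel

Kabsch superposition uses the SVD formulation with the determinant
correction and the minimized residual computed from the singular values
(numerically safer than re-measuring after transforming). The
quaternion (Horn) eigen method serves as an independent cross-check in
tests and in the acceptance script, never as the implementation. The
iterative mean is initialized from member 1; convergence is the maximum
per-atom displacement of the mean between iterations (< 10⁻⁴ Å,
max 20 iterations; non-convergence returns the last iterate flagged).
The representative choice is invariant to member order except through
the documented lowest-index tie-break.

## Synthetic-data generator

The generator builds every fixture from internal coordinates:

* **Nucleotides** are constructed by NeRF chain extension. The ribose
  ring is parametrized as a pentagon with Cremer–Pople-style
  out-of-plane displacements; the two ring parameters are solved
  numerically (scipy) so the measured Altona–Sundaralingam (P, ν_max)
  hit the requested values exactly, making pucker classes controllable
  per residue. Bases are idealized planar rings (regular-polygon
  internal coordinates); χ is built in exactly.
* **Stems** use fibre-diffraction A-form parameters (rise 2.81 Å,
  twist 32.7°). A pairing partner is placed by a deterministic global
  search over its in-plane pose (both base faces, 30° rotation grid,
  least squares on the canonical donor–acceptor distances with
  non-bonded clash penalties and a weak C1′–C1′ ≈ 10.4 Å term),
  followed by a polish that makes the hydrogen bonds parallel and
  perpendicular to the pairing edge. Stem templates are cached.
* **Loops** fan nucleotides along a semicircular arc bridging the
  closing pair, bases outward; this keeps loop residues unpaired while
  allowing natural loop stacking.
* **Modifications** are local chemistry edits: PSU renames base atoms
  across the ring pseudo-dyad (N1↔C5, C2↔C4, O2↔O4), which turns the
  glycosidic bond into the C1′–C5 C-glycoside while leaving the base
  footprint — and any pairing — in place; methylations add the methyl
  carbon by NeRF; 4SU repositions O4→S4 at a 1.68 Å C=S bond length;
  H2U puckers C5/C6 ± 0.25 Å out of the base plane.
* **Ensembles** add seeded isotropic Gaussian noise per model; the
  planted representative receives σ/10, which makes recovery
  unambiguous at test scale (σ = 0.5 Å, 10 models).
* **The default study corpus** (60 entries, 10 per modification)
  encodes the study conditions: a redundant 3-member motif group with a
  library counterpart, a 2-member group built C2′-endo/syn so its
  comparison exceeds the 1.0 Å threshold, one 6-model NMR ensemble
  (σ = 0.3 Å) with counterpart, one entry at 3.5 Å resolution (fails
  the filter), one with a deleted O2′ (fails clipping), and two extras
  without counterparts. Loops span sizes 4–10 and are unique per
  modification so the shared lowercase-u display codes never collide
  across modifications. Methods and RNA-type descriptions rotate over
  X-ray/EM/NMR and rRNA/tRNA/mRNA/synthetic texts.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: experimental coordinate error structure
(noise here is isotropic and i.i.d.), sequence-dependent helix
geometry, non-canonical pairs inside stems, multi-conformer loops,
crystal contacts, ligands and ions, and realistic protein partners
(tertiary-contact fixtures place single amino-acid residues). Real
deposited structures also carry annotation idiosyncrasies (partial
occupancies, microheterogeneity, legacy atom names) far richer than the
planted defects.

## Determinism and problem sizes

There is no unseeded randomness anywhere: generator specs carry seeds,
the pipeline is purely deterministic, and two runs on identical inputs
produce byte-identical artifacts. The test suite and the acceptance
script use desk-scale problem sizes chosen to exercise every code path
with clear margins: 100 random point sets for the superposition oracle,
1000 pseudorotation draws plus bin-edge probes, 100 ensembles for
representative recovery, hairpin loops 4–10, and the 60-entry survey
corpus.

## Known limitations

* The hydrogen-bond test is distance-only; a donor-angle option exists
  but defaults off, so borderline contacts may differ from
  hydrogen-aware annotators.
* Hoogsteen/edge classification is a heuristic on participating atoms
  and may disagree with reference annotators on borderline geometries;
  a reader interface for external DSSR-style JSON exists for
  cross-checking and is never required.
* Stacking criteria beyond the 4.0 Å distance are this package's
  closure of an underdocumented definition (configurable).
* RNA-type classification is keyword-based on entity descriptions;
  unusual descriptions fall into "other".
* The four accession-backed comparisons in the acceptance tests require
  deposited coordinate files that are not bundled; those tests fail
  until the files are supplied under `data/accessions/`.
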