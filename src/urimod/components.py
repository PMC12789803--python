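"""Chemical component tables for canonical ribonucleotides and the six
uridine modifications surveyed by this package (PSU, 5MU, UR3, OMU, 4SU, H2U).

All atom names follow the wwPDB chemical component dictionary conventions
for RNA residues (primes for sugar atoms, OP1/OP2 for phosphate oxygens).
Only heavy atoms are listed: the residue quality screen removes hydrogens
before any of these tables are consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Sugar-phosphate backbone heavy atoms shared by every ribonucleotide.
BACKBONE_ATOMS: tuple[str, ...] = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
)

#: Backbone atoms that may be absent on a 5'-terminal residue.
TERMINAL_OPTIONAL: frozenset[str] = frozenset({"P", "OP1", "OP2"})

#: Ribose ring atoms in Altona-Sundaralingam order (nu0 is about O4'-C1').
RIBOSE_RING: tuple[str, ...] = ("O4'", "C1'", "C2'", "C3'", "C4'")

_BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

#: Six-membered (pyrimidine or purine pyrimidine-moiety) ring used for
#: stacking geometry; five-membered imidazole ring of purines listed second.
BASE_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "A": (("N1", "C2", "N3", "C4", "C5", "C6"), ("C4", "C5", "N7", "C8", "N9")),
    "G": (("N1", "C2", "N3", "C4", "C5", "C6"), ("C4", "C5", "N7", "C8", "N9")),
    "C": (("N1", "C2", "N3", "C4", "C5", "C6"),),
    "U": (("N1", "C2", "N3", "C4", "C5", "C6"),),
}


@dataclass(frozen=True)
class ComponentDef:
    """Reference definition of one residue component.

    ``donors`` / ``acceptors`` are hydrogen-bond capable heavy atoms;
    ``wcf_edge`` lists the Watson-Crick-Franklin edge atoms and
    ``hoogsteen_edge`` the major-groove edge atoms used for base-pair
    classification.
    """

    comp_id: str
    one_letter: str
    base_atoms: tuple[str, ...]
    donors: frozenset[str]
    acceptors: frozenset[str]
    wcf_edge: frozenset[str]
    hoogsteen_edge: frozenset[str]
    rings: tuple[tuple[str, ...], ...]
    purine: bool = False
    extra_atoms: tuple[str, ...] = ()
    removed_atoms: frozenset[str] = frozenset()
    renamed_atoms: dict[str, str] = field(default_factory=dict)

    @property
    def heavy_atoms(self) -> tuple[str, ...]:
        """All expected heavy-atom names for a non-terminal residue."""
        base = tuple(self.renamed_atoms.get(a, a) for a in self.base_atoms
                     if a not in self.removed_atoms)
        return BACKBONE_ATOMS + base + self.extra_atoms


_BACKBONE_ACCEPTORS = frozenset({"OP1", "OP2", "O3'", "O5'", "O4'"})


def _comp(comp_id: str, one_letter: str, parent: str, *, donors: set[str],
          acceptors: set[str], wcf: set[str], hoog: set[str],
          extra: tuple[str, ...] = (), removed: set[str] | None = None,
          renamed: dict[str, str] | None = None,
          sugar_donor: bool = True) -> ComponentDef:
    d = set(donors)
    if sugar_donor:
        d.add("O2'")
    a = set(acceptors) | _BACKBONE_ACCEPTORS | {"O2'"}
    renamed = renamed or {}
    return ComponentDef(
        comp_id=comp_id,
        one_letter=one_letter,
        base_atoms=_BASE_ATOMS[parent],
        donors=frozenset(d),
        acceptors=frozenset(a),
        wcf_edge=frozenset(renamed.get(x, x) for x in wcf),
        hoogsteen_edge=frozenset(renamed.get(x, x) for x in hoog),
        rings=tuple(tuple(renamed.get(x, x) for x in ring)
                    for ring in BASE_RINGS[parent]),
        purine=parent in ("A", "G"),
        extra_atoms=extra,
        removed_atoms=frozenset(removed or set()),
        renamed_atoms=renamed,
    )


COMPONENTS: dict[str, ComponentDef] = {
    "A": _comp("A", "A", "A", donors={"N6"}, acceptors={"N1", "N3", "N7"},
               wcf={"N1", "C2", "N6"}, hoog={"N7", "N6"}),
    "G": _comp("G", "G", "G", donors={"N1", "N2"}, acceptors={"O6", "N3", "N7"},
               wcf={"N1", "N2", "O6"}, hoog={"N7", "O6"}),
    "C": _comp("C", "C", "C", donors={"N4"}, acceptors={"O2", "N3"},
               wcf={"N3", "O2", "N4"}, hoog={"N4", "C5"}),
    "U": _comp("U", "U", "U", donors={"N3"}, acceptors={"O2", "O4"},
               wcf={"N3", "O2", "O4"}, hoog={"O4", "C5"}),
    # Pseudouridine: C-glycoside (base bonded through C5); N1-H becomes an
    # additional donor. Heavy-atom names are identical to U.
    "PSU": _comp("PSU", "U", "U", donors={"N1", "N3"}, acceptors={"O2", "O4"},
                 wcf={"N3", "O2", "O4"}, hoog={"O4", "C5"}),
    # 5-methyluridine (ribothymidine): methyl carbon C5M on C5.
    "5MU": _comp("5MU", "U", "U", donors={"N3"}, acceptors={"O2", "O4"},
                 wcf={"N3", "O2", "O4"}, hoog={"O4", "C5"}, extra=("C5M",)),
    # 3-methyluridine: methyl C3U on N3 abolishes the N3 imino donor.
    "UR3": _comp("UR3", "U", "U", donors=set(), acceptors={"O2", "O4"},
                 wcf={"O2", "O4"}, hoog={"O4", "C5"}, extra=("C3U",)),
    # 2'-O-methyluridine: methyl CM2 on O2'; O2' stays an acceptor but can
    # no longer donate.
    "OMU": _comp("OMU", "U", "U", donors={"N3"}, acceptors={"O2", "O4"},
                 wcf={"N3", "O2", "O4"}, hoog={"O4", "C5"}, extra=("CM2",),
                 sugar_donor=False),
    # 4-thiouridine: O4 replaced by S4.
    "4SU": _comp("4SU", "U", "U", donors={"N3"}, acceptors={"O2", "S4"},
                 wcf={"N3", "O2", "O4"}, hoog={"O4", "C5"},
                 renamed={"O4": "S4"}),
    # 5,6-dihydrouridine: saturated C5-C6; same heavy-atom names as U.
    "H2U": _comp("H2U", "U", "U", donors={"N3"}, acceptors={"O2", "O4"},
                 wcf={"N3", "O2", "O4"}, hoog={"O4", "C5"}),
}

CANONICAL_BASES: frozenset[str] = frozenset({"A", "C", "G", "U"})


@dataclass(frozen=True)
class ModificationRecord:
    """One surveyed modification: 3-char code, canonical parent, the single
    character used in motif display sequences, whether the base, the sugar
    or both are altered, and the two base-side atoms that terminate the
    glycosidic torsion chi (O4'-C1'-X-Y)."""

    comp_id: str
    canonical: str
    display_char: str
    mod_class: str  # BASE | SUGAR | BOTH
    glycosidic_atoms: tuple[str, str]


#: Display characters follow the motif-naming convention in which
#: pseudouridine is P, ribothymidine is t, and the remaining uridine
#: modifications share lowercase u.
MODIFICATIONS: dict[str, ModificationRecord] = {
    "PSU": ModificationRecord("PSU", "U", "P", "BASE", ("C5", "C4")),
    "5MU": ModificationRecord("5MU", "U", "t", "BASE", ("N1", "C2")),
    "UR3": ModificationRecord("UR3", "U", "u", "BASE", ("N1", "C2")),
    "OMU": ModificationRecord("OMU", "U", "u", "SUGAR", ("N1", "C2")),
    "4SU": ModificationRecord("4SU", "U", "u", "BASE", ("N1", "C2")),
    "H2U": ModificationRecord("H2U", "U", "u", "BASE", ("N1", "C2")),
}

#: chi torsion base-side atoms for the canonical nucleotides.
CHI_ATOMS: dict[str, tuple[str, str]] = {
    "A": ("N9", "C4"), "G": ("N9", "C4"),
    "C": ("N1", "C2"), "U": ("N1", "C2"),
}


def component(comp_id: str) -> ComponentDef | None:
    return COMPONENTS.get(comp_id.upper())


def is_modified(comp_id: str) -> bool:
    return comp_id.upper() in MODIFICATIONS


def is_nucleotide(comp_id: str) -> bool:
    return comp_id.upper() in COMPONENTS


def chi_atom_chain(comp_id: str) -> tuple[str, str, str, str] | None:
    """The four atoms defining chi for ``comp_id`` (None if unknown)."""
    comp_id = comp_id.upper()
    if comp_id in MODIFICATIONS:
        x, y = MODIFICATIONS[comp_id].glycosidic_atoms
    elif comp_id in CHI_ATOMS:
        x, y = CHI_ATOMS[comp_id]
    else:
        return None
    return ("O4'", "C1'", x, y)


def canonical_letter(comp_id: str) -> str | None:
    """Canonical one-letter base for a component code, or None."""
    comp_id = comp_id.upper()
    if comp_id in MODIFICATIONS:
        return MODIFICATIONS[comp_id].canonical
    if comp_id in CANONICAL_BASES:
        return comp_id
    return None


def display_char(comp_id: str) -> str | None:
    """Character used for this component in motif display sequences."""
    comp_id = comp_id.upper()
    if comp_id in MODIFICATIONS:
        return MODIFICATIONS[comp_id].display_char
    if comp_id in CANONICAL_BASES:
        return comp_id
    return None


def load_modification_table(path) -> dict[str, ModificationRecord]:
    """Read an editable whitespace-delimited modification table.

    Columns: comp_id canonical display_char mod_class glyco_atom1 glyco_atom2.
    Lines starting with ``#`` are ignored.
    """
    table: dict[str, ModificationRecord] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"malformed modification row: {line!r}")
            cid, canon, disp, mcl, g1, g2 = parts
            table[cid.upper()] = ModificationRecord(
                cid.upper(), canon.upper(), disp, mcl.upper(), (g1, g2))
    return table


def dump_modification_table(path, table: dict[str, ModificationRecord] | None = None) -> None:
    table = table if table is not None else MODIFICATIONS
    with open(path, "w") as fh:
        fh.write("# comp_id canonical display_char mod_class glyco_atom1 glyco_atom2\n")
        for rec in table.values():
            fh.write(f"{rec.comp_id} {rec.canonical} {rec.display_char} "
                     f"{rec.mod_class} {rec.glycosidic_atoms[0]} {rec.glycosidic_atoms[1]}\n")
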