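"""Structure reading/writing and the residue quality screen.

Coordinates are read with gemmi (mmCIF/PDBx preferred, legacy PDB
supported) into a small uniform model: ``StructureEntry`` -> models ->
chains -> ``Residue`` -> ``Atom``.  Author chain identifiers and author
residue numbers are authoritative throughout, because motif identifiers
(ENTRYID_sequence_chain_start) are built from them.

The quality screen enforces, per residue: all reference heavy atoms
present, a single coordinate per atom (alternate locations resolved to
the highest-occupancy location, ties broken alphabetically), and all
hydrogens removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from . import components

logger = logging.getLogger(__name__)

__all__ = [
    "Atom", "Residue", "Model", "StructureEntry", "ScreenResult",
    "ParseError", "parse_structure", "screen_residue", "write_motif",
]

XRAY, EM, NMR, OTHER = "XRAY", "EM", "NMR", "OTHER"


class ParseError(ValueError):
    """File could not be parsed into a non-empty structure."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    alt_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))

    def is_hydrogen(self) -> bool:
        if self.element in ("H", "D"):
            return True
        if self.element:
            return False
        # no element field: name pattern, leading H after any digits
        stripped = self.name.lstrip("0123456789")
        return stripped[:1] in ("H", "D")


@dataclass
class Residue:
    comp_id: str
    chain_id: str
    seq_num: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)


@dataclass
class Model:
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def find_residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, ()):
            if r.seq_num == seq_num and r.icode == icode:
                return r
        return None


@dataclass
class StructureEntry:
    entry_id: str
    method: str = OTHER
    resolution: float | None = None
    models: list[Model] = field(default_factory=list)
    molecule_descriptions: dict[str, str] = field(default_factory=dict)
    organism: str | None = None

    @property
    def model(self) -> Model:
        """First model; the working model for X-ray/EM entries."""
        return self.models[0]


def _method_from_text(text: str) -> str:
    text = (text or "").upper()
    if "NMR" in text:
        return NMR
    if "X-RAY" in text or "DIFFRACTION" in text:
        return XRAY
    if "MICROSCOPY" in text or "CRYO" in text:
        return EM
    return OTHER


_RES_TAGS = (
    ("_refine.", "ls_d_res_high"),
    ("_em_3d_reconstruction.", "resolution"),
    ("_reflns.", "d_resolution_high"),
)


def _cif_metadata(path: Path):
    """(method, resolution, chain->description, organism) from a CIF file."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    method = block.find_value("_exptl.method")
    if method:
        method = gemmi.cif.as_string(method)
    resolution = None
    for prefix, tag in _RES_TAGS:
        val = block.find_value(prefix + tag)
        if val not in (None, "?", "."):
            try:
                resolution = float(gemmi.cif.as_string(val))
                break
            except ValueError:
                continue
    # entity descriptions mapped onto auth chain ids via _entity_poly
    descriptions: dict[str, str] = {}
    ent_desc: dict[str, str] = {}
    for row in block.find("_entity.", ["id", "?pdbx_description"]):
        if row.has(1):
            ent_desc[row.str(0)] = row.str(1)
    for row in block.find("_entity_poly.", ["entity_id", "?pdbx_strand_id"]):
        desc = ent_desc.get(row.str(0))
        if desc and row.has(1):
            for ch in row.str(1).split(","):
                descriptions[ch.strip()] = desc
    organism = None
    for cat in ("_entity_src_nat.", "_entity_src_gen."):
        for tag in ("pdbx_organism_scientific", "pdbx_gene_src_scientific_name"):
            val = block.find_value(cat + tag)
            if val not in (None, "?", "."):
                organism = gemmi.cif.as_string(val)
                break
        if organism:
            break
    return method, resolution, descriptions, organism


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # sniff: CIF files start with data_
    with open(path) as fh:
        head = fh.read(64)
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def parse_structure(path, fmt: str = "auto") -> StructureEntry:
    """Parse an mmCIF or PDB file into a :class:`StructureEntry`.

    All models are kept; atoms, author numbering, occupancies and
    alternate-location tags are preserved in file order.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = _detect_format(path, fmt)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    models: list[Model] = []
    for gm in st:
        model = Model()
        for gch in gm:
            residues = model.chains.setdefault(gch.name, [])
            for gr in gch:
                res = Residue(
                    comp_id=gr.name.upper(),
                    chain_id=gch.name,
                    seq_num=gr.seqid.num,
                    icode=gr.seqid.icode.strip(),
                )
                for ga in gr:
                    alt = "" if ga.altloc in ("\x00", " ", "") else ga.altloc
                    res.atoms.append(Atom(
                        name=ga.name,
                        element=ga.element.name if ga.element else "",
                        pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        alt_id=alt,
                    ))
                residues.append(res)
        models.append(model)
    if not models or all(m.n_atoms() == 0 for m in models):
        raise ParseError(f"empty structure (no coordinate records): {path}")

    info = dict(st.info) if st.info else {}
    method_text = info.get("_exptl.method", "")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    descriptions: dict[str, str] = {}
    organism = None
    if fmt == "mmcif":
        try:
            cif_method, cif_res, descriptions, organism = _cif_metadata(path)
        except (RuntimeError, ValueError):
            cif_method, cif_res = None, None
        method_text = method_text or (cif_method or "")
        resolution = resolution if resolution is not None else cif_res
    method = _method_from_text(method_text)
    if method in (NMR, OTHER):
        resolution = None
    entry_id = (st.name or path.stem).strip().upper() or path.stem.upper()
    return StructureEntry(entry_id=entry_id, method=method, resolution=resolution,
                          models=models, molecule_descriptions=descriptions,
                          organism=organism)


# ---------------------------------------------------------------------------
# residue quality screen

MISSING_ATOMS = "MISSING_ATOMS"
MULTI_COORD_UNRESOLVED = "MULTI_COORD_UNRESOLVED"
UNKNOWN_COMPONENT = "UNKNOWN_COMPONENT"


@dataclass(frozen=True)
class ScreenResult:
    ok: bool
    residue: Residue | None = None
    reason: str | None = None
    detail: str = ""


def _resolve_altlocs(atoms: list[Atom]) -> tuple[list[Atom] | None, str]:
    """One coordinate per atom name: keep the highest-occupancy alternate
    location (ties alphabetical by alt_id).  Duplicate names without
    alternate-location tags are unresolvable."""
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    out: list[Atom] = []
    seen: set[str] = set()
    for a in atoms:
        if a.name in seen:
            continue
        seen.add(a.name)
        group = by_name[a.name]
        if len(group) == 1:
            chosen = group[0]
        else:
            if any(g.alt_id == "" for g in group):
                return None, a.name
            chosen = sorted(group, key=lambda g: (-g.occupancy, g.alt_id))[0]
            logger.debug("altloc %s:%s resolved to %r (occ %.2f)",
                         a.name, [g.alt_id for g in group],
                         chosen.alt_id, chosen.occupancy)
        out.append(replace(chosen, alt_id=""))
    return out, ""


def screen_residue(residue: Residue, reference_atoms=None,
                   optional_atoms=components.TERMINAL_OPTIONAL) -> ScreenResult:
    """Apply the quality screen to one residue.

    Hydrogens are stripped, alternate locations are collapsed to a single
    coordinate, and the residue is rejected if any reference heavy atom
    (from the component dictionary unless ``reference_atoms`` is given)
    is absent.  Atoms in ``optional_atoms`` (by default the 5'-terminal
    phosphate group) are allowed to be missing.
    """
    if reference_atoms is None:
        comp = components.component(residue.comp_id)
        if comp is None:
            return ScreenResult(False, reason=UNKNOWN_COMPONENT,
                                detail=residue.comp_id)
        reference_atoms = comp.heavy_atoms
    heavy = [a for a in residue.atoms if not a.is_hydrogen()]
    resolved, clash = _resolve_altlocs(heavy)
    if resolved is None:
        return ScreenResult(False, reason=MULTI_COORD_UNRESOLVED, detail=clash)
    present = {a.name for a in resolved}
    missing = [n for n in reference_atoms
               if n not in present and n not in optional_atoms]
    if missing:
        return ScreenResult(False, reason=MISSING_ATOMS,
                            detail=",".join(missing))
    return ScreenResult(True, residue=replace(residue, atoms=resolved))


# ---------------------------------------------------------------------------
# motif output

_PDB_CHAIN_POOL = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_motif(motif, path, fmt: str = "mmcif") -> dict[str, str]:
    """Write a clipped motif to mmCIF or PDB.

    Returns the chain-id remap table (identity unless the PDB format
    forced multi-character author chains onto single letters; the remap
    is also recorded in the output header).  The written file re-parses
    to the same atoms and coordinates within format precision (1e-3 A).
    """
    residues = list(motif.residues)
    if not residues:
        raise ValueError("cannot write an empty motif")
    st = gemmi.Structure()
    st.name = getattr(motif, "motif_id", "MOTIF")[:78]
    remap: dict[str, str] = {}
    chain_order = []
    for r in residues:
        if r.chain_id not in remap:
            remap[r.chain_id] = r.chain_id
            chain_order.append(r.chain_id)
    if fmt == "pdb":
        used = set()
        for cid in chain_order:
            if len(cid) == 1 and cid not in used:
                remap[cid] = cid
            else:
                remap[cid] = next(c for c in _PDB_CHAIN_POOL if c not in used)
            used.add(remap[cid])
    gm = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for r in residues:
        cid = remap[r.chain_id]
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        gr = gemmi.Residue()
        gr.name = r.comp_id
        gr.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element or a.name[0])
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            gr.add_atom(ga)
        chains[cid].add_residue(gr)
    for cid in chains:
        gm.add_chain(chains[cid])
    st.add_model(gm)
    st.setup_entities()
    path = str(path)
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(path)
    elif fmt == "pdb":
        remark = "".join(f"REMARK 999 CHAIN REMAP {old} -> {new}\n"
                         for old, new in remap.items() if old != new)
        with open(path, "w") as fh:
            fh.write(remark)
            fh.write(st.make_pdb_string())
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return remap


def write_structure(entry: StructureEntry, path) -> None:
    """Write a full StructureEntry (all models, metadata) as mmCIF.

    Emits _exptl.method, a resolution record appropriate to the method,
    per-chain _entity descriptions and a standard atom_site loop, so the
    file round-trips through :func:`parse_structure`.
    """
    method_text = {
        XRAY: "X-RAY DIFFRACTION",
        EM: "ELECTRON MICROSCOPY",
        NMR: "SOLUTION NMR",
        OTHER: "OTHER",
    }[entry.method]
    lines = [f"data_{entry.entry_id}", "#",
             f"_entry.id {entry.entry_id}", "#",
             f"_exptl.method '{method_text}'", "#"]
    if entry.resolution is not None:
        tag = ("_em_3d_reconstruction.resolution" if entry.method == EM
               else "_refine.ls_d_res_high")
        lines += [f"{tag} {entry.resolution:.2f}", "#"]
    chains = list(entry.models[0].chains)
    ent_ids = {ch: str(i + 1) for i, ch in enumerate(chains)}
    if entry.molecule_descriptions:
        lines += ["loop_", "_entity.id", "_entity.pdbx_description"]
        for ch in chains:
            desc = entry.molecule_descriptions.get(ch, "RNA")
            lines.append(f"{ent_ids[ch]} '{desc}'")
        lines += ["#", "loop_", "_entity_poly.entity_id",
                  "_entity_poly.pdbx_strand_id"]
        for ch in chains:
            lines.append(f"{ent_ids[ch]} {ch}")
        lines.append("#")
    if entry.organism:
        lines += [f"_entity_src_nat.pdbx_organism_scientific '{entry.organism}'", "#"]
    lines += ["loop_"] + [
        "_atom_site." + t for t in (
            "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
            "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
            "pdbx_PDB_ins_code", "Cartn_x", "Cartn_y", "Cartn_z", "occupancy",
            "B_iso_or_equiv", "auth_seq_id", "auth_asym_id",
            "pdbx_PDB_model_num")]
    serial = 0
    for imodel, model in enumerate(entry.models, start=1):
        for ch, residues in model.chains.items():
            for ir, r in enumerate(residues, start=1):
                for a in r.atoms:
                    serial += 1
                    name = f'"{a.name}"' if "'" in a.name else a.name
                    alt = a.alt_id or "."
                    icode = r.icode or "?"
                    lines.append(
                        f"ATOM {serial} {a.element or '.'} {name} {alt} "
                        f"{r.comp_id} {ch} {ent_ids[ch]} {ir} {icode} "
                        f"{a.pos[0]:.3f} {a.pos[1]:.3f} {a.pos[2]:.3f} "
                        f"{a.occupancy:.2f} 0.00 {r.seq_num} {ch} {imodel}")
    lines.append("#")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
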