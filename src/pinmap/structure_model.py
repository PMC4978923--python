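"""Internal structure model built from PDB files.

A :class:`StructureModel` is a light, chain-ordered view of the heavy atoms
of a single model of a PDB entry: one :class:`Residue` per resolved residue
(with author numbering and insertion codes preserved), one :class:`Atom` per
heavy atom with a van der Waals radius attached at load time.  Gaps in the
author numbering of a chain are recorded as *missing-density segments* so
that downstream region classification can label those residues as
unresolved/disordered.

Parsing and writing of the fixed-width PDB layout is delegated to ``gemmi``;
this module only applies the filtering policy (hydrogens and waters dropped,
one conformer per alternate-location group, first NMR model only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "StructureError",
    "DEFAULT_VDW_RADII",
    "read_structure",
    "write_structure",
    "chain_sequence",
    "load_radius_table",
]

#: Van der Waals radii in Angstrom used for SASA; overridable via a
#: two-column TSV (element, radius).  Unlisted elements fall back to
#: ``DEFAULT_VDW_RADII["*"]``.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "*": 1.70,
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


@dataclass
class Atom:
    element: str
    name: str
    coord: tuple[float, float, float]
    occupancy: float
    altloc: str
    radius: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if self.radius <= 0:
            raise ValueError(f"non-positive radius for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, seq_num, icode) — the residue identifier used package-wide."""
        return (self.chain_id, self.seq_num, self.icode)


@dataclass
class StructureModel:
    id: str
    chains: dict[str, list[Residue]]
    missing_segments: dict[str, list[tuple[int, int]]]

    @property
    def n_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())

    def residues(self):
        for residues in self.chains.values():
            yield from residues

    def residue_map(self) -> dict[tuple[str, int, str], Residue]:
        return {r.key: r for r in self.residues()}


def load_radius_table(path: str | Path) -> dict[str, float]:
    """Read a (element, radius_A) TSV into a radius table."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        elem, radius = line.split("\t")[:2]
        table[elem.strip()] = float(radius)
    table.setdefault("*", DEFAULT_VDW_RADII["*"])
    return table


def _validate_pdb_lines(path: Path) -> None:
    # gemmi is forgiving; pre-scan coordinate records so a corrupt line is
    # reported with its line number.
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise StructureError(f"{path}: unparseable record at line {lineno}: too short")
        try:
            float(line[30:38]); float(line[38:46]); float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise StructureError(f"{path}: unparseable record at line {lineno}: {exc}") from exc


def _pick_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc code."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
            continue
        key_new = (-a.occ, a.altloc or "~")
        key_old = (-prev.occ, prev.altloc or "~")
        if key_new < key_old:
            by_name[a.name] = a
    return list(by_name.values())


def read_structure(
    path: str | Path,
    keep_het: bool = False,
    radii: dict[str, float] | None = None,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Hydrogens and waters are always discarded; non-water heteroatom residues
    are kept only when ``keep_het``.  For alternate-location groups the
    highest-occupancy conformer is retained (ties broken by the
    lexicographically smallest altloc code).  Only the first MODEL of a
    multi-model file is read.  Missing-density segments are inferred from
    gaps in consecutive author numbering within each chain.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    radii = radii or DEFAULT_VDW_RADII
    _validate_pdb_lines(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"empty structure: no coordinate records in {path}")

    chains: dict[str, list[Residue]] = {}
    n_atom_records = 0
    for ch in st[0]:
        residues: list[Residue] = []
        for res in ch:
            if res.is_water():
                continue
            is_het = res.het_flag == "H"
            if not is_het:
                n_atom_records += 1
            if is_het and not keep_het:
                continue
            atoms: list[Atom] = []
            for a in _pick_altloc([a for a in res if not a.is_hydrogen()]):
                elem = a.element.name.upper()
                atoms.append(
                    Atom(
                        element=elem,
                        name=a.name,
                        coord=(a.pos.x, a.pos.y, a.pos.z),
                        occupancy=min(max(a.occ, 0.0), 1.0),
                        altloc=(a.altloc or "").strip("\x00"),
                        radius=radii.get(elem, radii.get("*", 1.70)),
                    )
                )
            if not atoms:
                continue
            icode = (res.seqid.icode or "").strip()
            residues.append(
                Residue(
                    chain_id=ch.name,
                    seq_num=res.seqid.num,
                    icode=icode,
                    aa=_THREE_TO_ONE.get(res.name, "X"),
                    atoms=atoms,
                )
            )
        if residues:
            # insertion codes sort after their base number, alphabetically
            residues.sort(key=lambda r: (r.seq_num, r.icode))
            seen = set()
            for r in residues:
                if (r.seq_num, r.icode) in seen:
                    raise StructureError(
                        f"{path}: duplicate residue {r.seq_num}{r.icode} in chain {ch.name}"
                    )
                seen.add((r.seq_num, r.icode))
            chains[ch.name] = residues

    if n_atom_records == 0:
        raise StructureError(f"empty structure: no ATOM records in {path}")
    if not chains:
        raise StructureError(f"empty structure: no residues retained from {path}")

    missing: dict[str, list[tuple[int, int]]] = {}
    for cid, residues in chains.items():
        gaps: list[tuple[int, int]] = []
        nums = sorted({r.seq_num for r in residues})
        for prev, nxt in zip(nums, nums[1:]):
            if nxt > prev + 1:
                gaps.append((prev + 1, nxt - 1))
        missing[cid] = gaps

    return StructureModel(id=path.stem, chains=chains, missing_segments=missing)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model back out as a PDB file (ATOM/TER/END records)."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = _ONE_TO_THREE.get(r.aa, "UNK")
            gr.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
            gr.het_flag = "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                if a.altloc:
                    ga.altloc = a.altloc
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def chain_sequence(
    model: StructureModel, chain_id: str
) -> tuple[str, list[tuple[int, int, str]]]:
    """One-letter sequence of a chain's resolved residues plus an index map.

    Returns ``(sequence, index_map)`` where ``index_map[k] = (pos, seq_num,
    icode)`` with ``pos`` the 1-based position in ``sequence``; the map is a
    bijection between sequence positions and residues.
    """
    if chain_id not in model.chains:
        raise KeyError(
            f"chain {chain_id!r} not in structure {model.id}; "
            f"available: {sorted(model.chains)}"
        )
    seq = []
    index_map: list[tuple[int, int, str]] = []
    for pos, r in enumerate(model.chains[chain_id], start=1):
        seq.append(r.aa)
        index_map.append((pos, r.seq_num, r.icode))
    return "".join(seq), index_map
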