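"""Sequence-to-structure mapping.

Query protein sequences are aligned globally (Needleman–Wunsch with affine
gaps, BLOSUM62 by default) against structure-derived chain sequences.  A
candidate structure is accepted for homology transfer when the alignment
has strictly more than 30% sequence identity and covers strictly more than
80% of the query domain interval; a cognate structure (a structure of the
query protein itself) is always accepted.  Variants are then mapped through
the highest-ranked accepted alignment covering their position and inherit
the region label of the target residue.

Conventions (recorded in output metadata): identity is computed over
aligned residue–residue pairs (gap columns excluded); coverage is computed
over the domain-interval length; 'X' scores 0 against everything and never
counts as identical; a gap of length k costs open + (k−1)·extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .regions import RegionLabel

__all__ = [
    "DomainInterval",
    "AlignmentMap",
    "HomologMatch",
    "VariantRecord",
    "MappedVariant",
    "MapStatus",
    "ChainRegions",
    "align_pair",
    "accept_homolog",
    "map_variants",
    "rank_matches",
    "read_variant_table",
    "mapped_variant_table",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

#: DP cell cap guarding against accidental quadratic blow-ups.
DEFAULT_CELL_CAP = 25_000_000

IDENTITY_CONVENTION = (
    "identity = 100 * identical aligned pairs / aligned pairs (gaps excluded); "
    "coverage = 100 * aligned query positions in domain interval / interval length"
)


@dataclass(frozen=True)
class DomainInterval:
    protein: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain interval {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AlignmentMap:
    pairs: list[tuple[int, int]]  # (query_pos, target_pos), 1-based, monotone
    identity: float  # percent
    coverage: float  # percent of the query domain interval
    score: float

    def target_for(self, query_pos: int) -> int | None:
        for q, t in self.pairs:
            if q == query_pos:
                return t
        return None


@dataclass
class HomologMatch:
    alignment: AlignmentMap
    structure_id: str
    chain_id: str
    cognate: bool
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        self.accepted = accept_homolog(self.alignment, self.cognate)


@dataclass(frozen=True)
class VariantRecord:
    protein: str
    position: int
    ref_aa: str
    alt_aa: str
    source: str = ""
    id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant {self.id or '?'}: position must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"variant {self.id or '?'}: ref and alt are identical")


class MapStatus(str, Enum):
    MAPPED = "mapped"
    UNALIGNED_POSITION = "unaligned_position"
    NO_ACCEPTED_STRUCTURE = "no_accepted_structure"
    REF_MISMATCH = "ref_mismatch"


@dataclass
class MappedVariant:
    variant: VariantRecord
    match: HomologMatch | None
    residue: tuple[str, int, str] | None
    region: RegionLabel | None
    status: MapStatus


@dataclass
class ChainRegions:
    """Region labels of one structure chain, indexed by chain-sequence position."""

    structure_id: str
    chain_id: str
    sequence: str
    index_map: list[tuple[int, int, str]]  # (pos, seq_num, icode)
    labels: dict[tuple[str, int, str], RegionLabel]

    def residue_at(self, pos: int) -> tuple[str, int, str]:
        _, seq_num, icode = self.index_map[pos - 1]
        return (self.chain_id, seq_num, icode)

    def label_at(self, pos: int) -> RegionLabel | None:
        return self.labels.get(self.residue_at(pos))


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    m = substitution_matrices.load(matrix).copy()
    if "X" in m.alphabet:
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    aligner.substitution_matrix = m
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_pair(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    domain: DomainInterval | None = None,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> AlignmentMap:
    """Optimal global alignment of ``query`` against ``target``.

    ``pairs`` lists aligned residue–residue columns only; gap columns are
    omitted.  Coverage is measured over ``domain`` when given, else over
    the whole query.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    for name, seq in (("query", query), ("target", target)):
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"{name} contains invalid residues: {sorted(bad)}")
    if len(query) * len(target) > cell_cap:
        raise ValueError(
            f"alignment matrix {len(query)}x{len(target)} exceeds the cell cap "
            f"({cell_cap}); align domains separately"
        )
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(query, target)[0]
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, _te) in zip(aln.aligned[0], aln.aligned[1]):
        for k in range(qe - qs):
            pairs.append((int(qs + k + 1), int(ts + k + 1)))

    identical = sum(
        1 for q, t in pairs if query[q - 1] == target[t - 1] and query[q - 1] != "X"
    )
    identity = 100.0 * identical / len(pairs) if pairs else 0.0
    if domain is None:
        interval = (1, len(query))
    else:
        interval = (domain.start, domain.end)
    in_interval = sum(1 for q, _ in pairs if interval[0] <= q <= interval[1])
    coverage = 100.0 * in_interval / (interval[1] - interval[0] + 1)
    return AlignmentMap(
        pairs=pairs, identity=identity, coverage=coverage, score=float(aln.score)
    )


def accept_homolog(alignment: AlignmentMap, cognate: bool) -> bool:
    """Homology-transfer gate: cognate structures always pass; homologs need
    strictly more than 30% identity and strictly more than 80% coverage."""
    if cognate:
        return True
    return alignment.identity > 30.0 and alignment.coverage > 80.0


def rank_matches(matches: list[HomologMatch]) -> list[HomologMatch]:
    """Deterministic ranking: cognate first, then identity, coverage, ids."""
    return sorted(
        matches,
        key=lambda m: (
            not m.cognate,
            -m.alignment.identity,
            -m.alignment.coverage,
            m.structure_id,
            m.chain_id,
        ),
    )


def map_variants(
    variants: list[VariantRecord],
    protein_seq: str,
    matches: list[HomologMatch],
    regions_by_structure: dict[tuple[str, str], ChainRegions],
) -> list[MappedVariant]:
    """Join each variant to a structure residue and its region label.

    Every input variant appears exactly once in the output with a definite
    status.  The reference amino acid is checked against ``protein_seq``
    before any structural assignment.
    """
    ranked = [m for m in rank_matches(matches) if m.accepted]
    out: list[MappedVariant] = []
    for v in variants:
        if v.position > len(protein_seq):
            raise ValueError(
                f"variant {v.id or v.protein}: position {v.position} beyond "
                f"protein length {len(protein_seq)}"
            )
        if protein_seq[v.position - 1] != v.ref_aa:
            out.append(MappedVariant(v, None, None, None, MapStatus.REF_MISMATCH))
            continue
        if not ranked:
            out.append(MappedVariant(v, None, None, None, MapStatus.NO_ACCEPTED_STRUCTURE))
            continue
        placed = False
        for m in ranked:
            target_pos = m.alignment.target_for(v.position)
            if target_pos is None:
                continue
            chain_regions = regions_by_structure[(m.structure_id, m.chain_id)]
            residue = chain_regions.residue_at(target_pos)
            region = chain_regions.labels.get(residue)
            out.append(MappedVariant(v, m, residue, region, MapStatus.MAPPED))
            placed = True
            break
        if not placed:
            out.append(MappedVariant(v, None, None, None, MapStatus.UNALIGNED_POSITION))
    return out


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV with header protein/position/ref_aa/alt_aa/source/id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein", "position", "ref_aa", "alt_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: variant table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                protein=row.protein,
                position=int(row.position),
                ref_aa=row.ref_aa,
                alt_aa=row.alt_aa,
                source=getattr(row, "source", "") or "",
                id=getattr(row, "id", "") or "",
            )
        )
    return records


def mapped_variant_table(mapped: list[MappedVariant]) -> pd.DataFrame:
    """Flatten mapped variants for TSV export."""
    rows = []
    for mv in mapped:
        v = mv.variant
        m = mv.match
        rows.append(
            {
                "protein": v.protein,
                "position": v.position,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "source": v.source,
                "id": v.id,
                "status": mv.status.value,
                "structure_id": m.structure_id if m else "",
                "chain": m.chain_id if m else "",
                "cognate": int(m.cognate) if m else "",
                "identity": round(m.alignment.identity, 2) if m else "",
                "coverage": round(m.alignment.coverage, 2) if m else "",
                "seq_num": mv.residue[1] if mv.residue else "",
                "icode": mv.residue[2] if mv.residue else "",
                "region": mv.region.region.value if mv.region else "",
                "disordered": int(mv.region.disordered) if mv.region else "",
            }
        )
    columns = [
        "protein", "position", "ref_aa", "alt_aa", "source", "id", "status",
        "structure_id", "chain", "cognate", "identity", "coverage",
        "seq_num", "icode", "region", "disordered",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.attrs["conventions"] = IDENTITY_CONVENTION
    return df
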