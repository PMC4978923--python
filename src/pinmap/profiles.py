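"""Per-protein sequence-annotated profiles.

A profile is a set of equal-length tracks over the protein sequence that
fingerprints everything known per position: the structural region the
position maps to (through the best accepted structure alignment), the
number of mapped variants, functional sites, PTMs, and disorder.

Track alphabets:
    region           I / C / S / U / '-'  ('-' = no accepted structural coverage)
    variant_density  integer count per position
    site, ptm        '*' marked / '.' unmarked
    disorder         '1' / '0'
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .seqmap import ChainRegions, HomologMatch, MapStatus, MappedVariant, rank_matches

__all__ = [
    "ProfileTrack",
    "SiteAnnotation",
    "build_profile",
    "profile_block",
    "parse_profile_block",
    "profile_long_table",
    "read_site_table",
]


@dataclass
class ProfileTrack:
    name: str
    values: list  # one symbol or count per protein position


@dataclass(frozen=True)
class SiteAnnotation:
    protein: str
    position: int
    kind: str  # e.g. active_site, binding, ptm_phospho
    source: str = ""


def _region_symbol(label) -> str:
    return label.region.symbol


def build_profile(
    protein_seq: str,
    mapped: list[MappedVariant],
    sites: list[SiteAnnotation],
    disorder: list[bool] | None = None,
    matches: list[HomologMatch] | None = None,
    regions_by_structure: dict[tuple[str, str], ChainRegions] | None = None,
) -> list[ProfileTrack]:
    """Merge structure, variant and annotation information into tracks.

    When ``matches``/``regions_by_structure`` are given, the region track is
    projected for *every* position covered by an accepted alignment (the
    highest-ranked accepted match wins per position); otherwise only the
    positions of mapped variants carry a region symbol.
    """
    n = len(protein_seq)
    region = ["-"] * n
    density = [0] * n
    site = ["."] * n
    ptm = ["."] * n

    if matches and regions_by_structure:
        for m in reversed([m for m in rank_matches(matches) if m.accepted]):
            for q, t in m.alignment.pairs:
                chain_regions = regions_by_structure[(m.structure_id, m.chain_id)]
                label = chain_regions.label_at(t)
                if label is not None:
                    region[q - 1] = _region_symbol(label)

    for mv in mapped:
        pos = mv.variant.position
        if pos > n:
            raise ValueError(f"variant {mv.variant.id or '?'} beyond sequence length {n}")
        if mv.status is MapStatus.MAPPED:
            density[pos - 1] += 1
            if mv.region is not None:
                region[pos - 1] = _region_symbol(mv.region)

    for s in sites:
        if not (1 <= s.position <= n):
            raise ValueError(
                f"site annotation {s.kind}@{s.position} on {s.protein} is outside "
                f"the sequence (length {n})"
            )
        if s.kind.lower().startswith("ptm"):
            ptm[s.position - 1] = "*"
        else:
            site[s.position - 1] = "*"

    tracks = [
        ProfileTrack("region", region),
        ProfileTrack("variant_density", density),
        ProfileTrack("site", site),
        ProfileTrack("ptm", ptm),
    ]
    if disorder is not None:
        if len(disorder) != n:
            raise ValueError("disorder track length differs from sequence length")
        tracks.append(ProfileTrack("disorder", ["1" if d else "0" for d in disorder]))
    return tracks


def profile_block(protein: str, protein_seq: str, tracks: list[ProfileTrack]) -> str:
    """Serialize a profile as a FASTA-like text block (lossless)."""
    lines = [f">{protein} length={len(protein_seq)}", f"sequence\t{protein_seq}"]
    for t in tracks:
        if t.name == "variant_density":
            lines.append(f"{t.name}\t{','.join(str(v) for v in t.values)}")
        else:
            lines.append(f"{t.name}\t{''.join(t.values)}")
    return "\n".join(lines) + "\n"


def parse_profile_block(text: str) -> tuple[str, str, list[ProfileTrack]]:
    """Inverse of :func:`profile_block`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError("profile block must start with a '>' header")
    protein = lines[0][1:].split()[0]
    seq = ""
    tracks: list[ProfileTrack] = []
    for ln in lines[1:]:
        name, _, payload = ln.partition("\t")
        if name == "sequence":
            seq = payload
        elif name == "variant_density":
            tracks.append(ProfileTrack(name, [int(x) for x in payload.split(",")]))
        else:
            tracks.append(ProfileTrack(name, list(payload)))
    return protein, seq, tracks


def profile_long_table(protein: str, tracks: list[ProfileTrack]) -> pd.DataFrame:
    """Long-form (protein, position, track, value) table for machine use."""
    rows = []
    for t in tracks:
        for pos, v in enumerate(t.values, start=1):
            rows.append((protein, pos, t.name, str(v)))
    return pd.DataFrame(rows, columns=["protein", "position", "track", "value"])


def read_site_table(path: str | Path) -> list[SiteAnnotation]:
    """Read a site/PTM TSV (protein, position, kind, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SiteAnnotation(
            protein=row.protein,
            position=int(row.position),
            kind=row.kind,
            source=getattr(row, "source", "") or "",
        )
        for row in df.itertuples(index=False)
    ]
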