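"""Batch pipeline wiring: structures -> SASA -> regions -> alignment -> profiles
-> variant mapping -> enrichment -> network.

This module is the programmatic counterpart of the CLI subcommands; every
stage reads and writes plain TSV/text so runs are diffable and rerunning a
stage with the same config and seed is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import enrichment as enr
from . import network as net
from .fixtures import demo_workspace
from .profiles import build_profile, profile_block, profile_long_table, read_site_table
from .regions import Region, RegionParams, classify_regions, region_census, region_table
from .seqmap import (
    ChainRegions,
    DomainInterval,
    HomologMatch,
    MapStatus,
    align_pair,
    map_variants,
    mapped_variant_table,
    rank_matches,
    read_variant_table,
)
from .structure_model import StructureModel, chain_sequence, read_structure

log = logging.getLogger("pinmap")

__all__ = ["RunConfig", "load_config", "annotate", "map_stage", "enrich", "network_stage", "run_all"]


@dataclass
class RunConfig:
    workdir: Path = Path(".")
    fasta: str = "proteins.fasta"
    homologs: str = "homologs.tsv"
    variants: str = "variants.tsv"
    sites: str = "sites.tsv"
    disorder: str = "disorder.tsv"
    edges: str = "edges.tsv"
    outdir: str = "out"
    probe: float = 1.4
    n_points: int = 960
    interface_min_dsasa: float = 0.1
    core_max_rasa: float = 0.15
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    n_perm: int = 10_000
    seed: int = 17
    log_level: str = "INFO"

    def path(self, name: str) -> Path:
        p = Path(getattr(self, name))
        return p if p.is_absolute() else self.workdir / p

    @property
    def out(self) -> Path:
        p = Path(self.outdir)
        out = p if p.is_absolute() else self.workdir / p
        out.mkdir(parents=True, exist_ok=True)
        return out

    def region_params(self) -> RegionParams:
        return RegionParams(
            interface_min_dsasa=self.interface_min_dsasa,
            core_max_rasa=self.core_max_rasa,
        )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a flat key=value config file; keyword overrides win."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    values: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    cfg = RunConfig(workdir=path.parent)
    for f in fields(RunConfig):
        raw = overrides.get(f.name, values.get(f.name))
        if raw is None:
            continue
        current = getattr(cfg, f.name)
        if isinstance(current, Path):
            setattr(cfg, f.name, Path(raw))
        elif isinstance(current, bool):
            setattr(cfg, f.name, str(raw).lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, f.name, int(raw))
        elif isinstance(current, float):
            setattr(cfg, f.name, float(raw))
        else:
            setattr(cfg, f.name, raw)
    return cfg


@dataclass
class AnnotationState:
    """In-memory artifacts shared between pipeline stages."""

    proteins: dict[str, str]
    structures: dict[str, StructureModel]
    labels: dict[str, dict]  # structure_id -> residue labels
    chain_regions: dict[tuple[str, str], ChainRegions]
    matches: dict[str, list[HomologMatch]] = field(default_factory=dict)
    match_meta: list[dict] = field(default_factory=list)


def _read_proteins(cfg: RunConfig) -> dict[str, str]:
    fasta = cfg.path("fasta")
    if not fasta.exists():
        raise FileNotFoundError(f"protein FASTA not found: {fasta}")
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}


def _annotate_structures(cfg: RunConfig) -> AnnotationState:
    t0 = time.perf_counter()
    proteins = _read_proteins(cfg)
    homolog_path = cfg.path("homologs")
    if not homolog_path.exists():
        raise FileNotFoundError(f"homolog candidate table not found: {homolog_path}")
    candidates = pd.read_csv(homolog_path, sep="\t", dtype=str)

    structures: dict[str, StructureModel] = {}
    labels: dict[str, dict] = {}
    chain_regions: dict[tuple[str, str], ChainRegions] = {}
    state = AnnotationState(proteins, structures, labels, chain_regions)

    for rel in sorted(candidates["structure_path"].unique()):
        spath = Path(rel)
        if not spath.is_absolute():
            spath = cfg.workdir / spath
        model = read_structure(spath)
        model.id = Path(rel).stem
        structures[model.id] = model
        labels[model.id] = classify_regions(
            model, cfg.region_params(), probe=cfg.probe, n_points=cfg.n_points
        )
        for cid in model.chains:
            seq, index_map = chain_sequence(model, cid)
            chain_regions[(model.id, cid)] = ChainRegions(
                structure_id=model.id,
                chain_id=cid,
                sequence=seq,
                index_map=index_map,
                labels=labels[model.id],
            )
    log.info("classified %d structures in %.2fs", len(structures), time.perf_counter() - t0)

    for row in candidates.itertuples(index=False):
        protein = row.protein
        if protein not in proteins:
            raise ValueError(f"candidate table references unknown protein {protein}")
        sid = Path(row.structure_path).stem
        cid = row.chain
        if (sid, cid) not in chain_regions:
            raise ValueError(f"structure {sid} has no chain {cid}")
        domain = DomainInterval(
            protein, int(row.domain_start), int(row.domain_end), name="input"
        )
        aln = align_pair(
            proteins[protein],
            chain_regions[(sid, cid)].sequence,
            matrix=cfg.matrix,
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
            domain=domain,
        )
        cognate = aln.identity == 100.0 and aln.coverage == 100.0
        match = HomologMatch(alignment=aln, structure_id=sid, chain_id=cid, cognate=cognate)
        state.matches.setdefault(protein, []).append(match)
        state.match_meta.append(
            {
                "protein": protein,
                "structure_id": sid,
                "chain": cid,
                "identity": round(aln.identity, 2),
                "coverage": round(aln.coverage, 2),
                "score": aln.score,
                "cognate": int(cognate),
                "accepted": int(match.accepted),
            }
        )
    return state


def _read_disorder(cfg: RunConfig) -> dict[str, dict[int, bool]]:
    path = cfg.path("disorder")
    if not path.exists():
        return {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    track: dict[str, dict[int, bool]] = {}
    for row in df.itertuples(index=False):
        track.setdefault(row.protein, {})[int(row.position)] = row.disordered == "1"
    return track


def annotate(cfg: RunConfig) -> AnnotationState:
    """Structure -> SASA -> regions -> alignments -> profiles, all written to outdir."""
    state = _annotate_structures(cfg)
    out = cfg.out

    region_frames = []
    for sid in sorted(state.structures):
        df = region_table(state.structures[sid], state.labels[sid])
        df.insert(0, "structure_id", sid)
        region_frames.append(df)
    pd.concat(region_frames, ignore_index=True).to_csv(
        out / "regions.tsv", sep="\t", index=False
    )
    pd.DataFrame(state.match_meta).to_csv(out / "matches.tsv", sep="\t", index=False)

    sites_path = cfg.path("sites")
    sites = read_site_table(sites_path) if sites_path.exists() else []
    disorder = _read_disorder(cfg)

    blocks = []
    long_frames = []
    for protein in sorted(state.proteins):
        seq = state.proteins[protein]
        dis_map = disorder.get(protein, {})
        dis_track = [dis_map.get(i + 1, False) for i in range(len(seq))] if dis_map else None
        tracks = build_profile(
            seq,
            mapped=[],
            sites=[s for s in sites if s.protein == protein],
            disorder=dis_track,
            matches=state.matches.get(protein),
            regions_by_structure=state.chain_regions,
        )
        blocks.append(profile_block(protein, seq, tracks))
        long_frames.append(profile_long_table(protein, tracks))
    (out / "profiles.txt").write_text("\n".join(blocks))
    pd.concat(long_frames, ignore_index=True).to_csv(
        out / "profiles.tsv", sep="\t", index=False
    )
    log.info("annotate: wrote regions.tsv, matches.tsv, profiles to %s", out)
    return state


def map_stage(cfg: RunConfig, state: AnnotationState | None = None) -> pd.DataFrame:
    """Map the variant table onto structures; write mapped.tsv and census.tsv."""
    state = state or _annotate_structures(cfg)
    out = cfg.out
    var_path = cfg.path("variants")
    if not var_path.exists():
        raise FileNotFoundError(f"variant table not found: {var_path}")
    variants = read_variant_table(var_path)

    mapped_all = []
    for protein in sorted({v.protein for v in variants}):
        if protein not in state.proteins:
            raise ValueError(f"variant table references unknown protein {protein}")
        mapped_all.extend(
            map_variants(
                [v for v in variants if v.protein == protein],
                state.proteins[protein],
                state.matches.get(protein, []),
                state.chain_regions,
            )
        )
    table = mapped_variant_table(mapped_all)
    table.to_csv(out / "mapped.tsv", sep="\t", index=False)

    # census universe: structure-covered positions of every protein with an
    # accepted match (the labelled residues variants could land on)
    census_counts: dict[str, int] = {r.value: 0 for r in Region}
    for protein in sorted(state.proteins):
        accepted = [m for m in rank_matches(state.matches.get(protein, [])) if m.accepted]
        if not accepted:
            continue
        best_by_pos: dict[int, str] = {}
        for m in reversed(accepted):
            for q, t in m.alignment.pairs:
                lab = state.chain_regions[(m.structure_id, m.chain_id)].label_at(t)
                if lab is not None:
                    best_by_pos[q] = lab.region.value
        for region in best_by_pos.values():
            census_counts[region] += 1
    census = pd.DataFrame(
        sorted(census_counts.items()), columns=["region", "count"]
    )
    census.to_csv(out / "census.tsv", sep="\t", index=False)
    n_mapped = int((table["status"] == MapStatus.MAPPED.value).sum()) if len(table) else 0
    log.info("map: %d/%d variants mapped", n_mapped, len(variants))
    return table


def enrich(cfg: RunConfig) -> pd.DataFrame:
    """Per-(class, region) enrichment report from mapped.tsv + census.tsv."""
    out = cfg.out
    mapped_path = out / "mapped.tsv"
    census_path = out / "census.tsv"
    for p in (mapped_path, census_path):
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline input {p}; run map-variants first")
    mapped = pd.read_csv(mapped_path, sep="\t", dtype=str)
    census = pd.read_csv(census_path, sep="\t")
    sizes = dict(zip(census["region"], census["count"].astype(int)))
    N = sum(v for k, v in sizes.items() if k != Region.UNRESOLVED.value)

    rows = []
    if len(mapped):
        ok = mapped[mapped["status"] == MapStatus.MAPPED.value]
        for source in sorted(ok["source"].fillna("").unique()):
            sub = ok[ok["source"].fillna("") == source]
            n = len(sub)
            for region in (Region.INTERFACE, Region.CORE, Region.SURFACE):
                N_r = sizes.get(region.value, 0)
                if N_r == 0:
                    continue
                n_r = int((sub["region"] == region.value).sum())
                rows.append(
                    {"source": source, "region": region.value, "n_r": n_r,
                     "n": n, "N_r": N_r, "N": N}
                )
    counts = pd.DataFrame(rows, columns=["source", "region", "n_r", "n", "N_r", "N"])
    report = enr.enrichment_report(counts, n_perm=cfg.n_perm, seed=cfg.seed)
    report.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    log.info("enrich: %d (class x region) pairs tested", len(report))
    return report


def network_stage(cfg: RunConfig, state: AnnotationState | None = None) -> pd.DataFrame:
    """Build the interaction network with structural evidence; write summary."""
    state = state or _annotate_structures(cfg)
    out = cfg.out
    edge_path = cfg.path("edges")
    if not edge_path.exists():
        raise FileNotFoundError(f"edge list not found: {edge_path}")
    edges = net.read_edge_list(edge_path)

    complexes = []
    for sid in sorted(state.structures):
        chain_proteins: dict[str, str] = {}
        all_cognate = True
        for protein in sorted(state.matches):
            for m in state.matches[protein]:
                if m.accepted and m.structure_id == sid:
                    chain_proteins.setdefault(m.chain_id, protein)
                    if chain_proteins[m.chain_id] == protein and not m.cognate:
                        all_cognate = False
        if len(chain_proteins) >= 2 or (
            len(chain_proteins) == 1 and len(state.structures[sid].chains) >= 2
        ):
            complexes.append(
                net.ComplexCoverage(
                    structure_id=sid,
                    chain_proteins=chain_proteins,
                    labels=state.labels[sid],
                    homology=not all_cognate,
                )
            )

    network = net.build_network(edges, matches=state.matches, complexes=complexes)
    net.write_network(network, out / "network_nodes.tsv", out / "network_edges.tsv")
    summary = net.network_summary(network)
    summary.to_csv(out / "network_summary.tsv", sep="\t", index=False)
    log.info("network: %d nodes, %d edges", network.graph.number_of_nodes(),
             network.graph.number_of_edges())
    return summary


def run_all(cfg: RunConfig) -> None:
    """annotate -> map-variants -> enrich -> network with shared state."""
    state = annotate(cfg)
    map_stage(cfg, state)
    enrich(cfg)
    network_stage(cfg, state)


def simulate(outdir: str | Path, seed: int = 17) -> dict[str, Path]:
    """Emit the demo workspace (delegates to the fixtures generator)."""
    return demo_workspace(outdir, seed=seed)
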