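"""Structural coverage of protein–protein interaction networks.

Nodes (proteins) are classified by the best structural evidence available
for them — a cognate resolved structure, an accepted homologous structure,
or none — and edges by whether a complex structure (cognate or homology
model) covers both interaction partners.  Interface residues from the
region classification of the covering complex are attached to structurally
covered edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx
import pandas as pd

from .regions import Region, RegionLabel
from .seqmap import HomologMatch

__all__ = [
    "Evidence",
    "NodeStatus",
    "InteractionEdge",
    "ComplexCoverage",
    "Network",
    "build_network",
    "network_summary",
    "read_edge_list",
    "write_network",
    "read_network",
]


class NodeStatus(str, Enum):
    RESOLVED = "resolved"
    HOMOLOG = "homolog"
    NONE = "none"


class Evidence(str, Enum):
    RESOLVED_STRUCTURE = "resolved_structure"
    HOMOLOGY_MODEL = "homology_model"
    SEQUENCE_ONLY = "sequence_only"


@dataclass
class InteractionEdge:
    a: str
    b: str
    evidence: Evidence
    interface_residues: dict[str, set[tuple[str, int, str]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        # canonical unordered orientation
        if self.b < self.a:
            self.a, self.b = self.b, self.a
        if self.evidence is Evidence.SEQUENCE_ONLY and self.interface_residues:
            raise ValueError("sequence-only edges carry no interface residues")


@dataclass
class ComplexCoverage:
    """A multi-chain structure annotated with which protein each chain models."""

    structure_id: str
    chain_proteins: dict[str, str]  # chain_id -> protein accession
    labels: dict[tuple[str, int, str], RegionLabel]
    homology: bool = False  # True when chains model the proteins via homologs

    def interface_for(self, protein: str) -> set[tuple[str, int, str]]:
        chains = {c for c, p in self.chain_proteins.items() if p == protein}
        return {
            key
            for key, lab in self.labels.items()
            if key[0] in chains and lab.region is Region.INTERFACE
        }


@dataclass
class Network:
    graph: nx.Graph

    @property
    def nodes(self) -> dict[str, NodeStatus]:
        return {n: d["status"] for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> list[InteractionEdge]:
        out = []
        for a, b, d in self.graph.edges(data=True):
            x, y = sorted((a, b))
            out.append(
                InteractionEdge(
                    x, y, d["evidence"], d.get("interface_residues", {}) or {}
                )
            )
        return sorted(out, key=lambda e: (e.a, e.b))


def build_network(
    edge_list: list[tuple[str, str]],
    matches: dict[str, list[HomologMatch]] | None = None,
    complexes: list[ComplexCoverage] | None = None,
    allow_self: bool = True,
) -> Network:
    """Assemble a non-redundant network with structural evidence labels.

    Duplicate and reversed-duplicate edges are collapsed.  Node status is
    ``resolved`` if the protein has any accepted cognate match, ``homolog``
    if it has only accepted homologous matches, else ``none``.  Edge
    evidence is ``resolved_structure`` when a cognate complex covers both
    partners, ``homology_model`` when only homolog complexes do, else
    ``sequence_only``.
    """
    matches = matches or {}
    complexes = complexes or []
    g = nx.Graph()

    seen_nodes: set[str] = set()
    for a, b in edge_list:
        if not a or not b:
            raise ValueError(f"edge with empty accession: {(a, b)!r}")
        if a == b and not allow_self:
            continue
        seen_nodes.update((a, b))
    for p in matches:
        seen_nodes.add(p)

    for p in sorted(seen_nodes):
        accepted = [m for m in matches.get(p, []) if m.accepted]
        if any(m.cognate for m in accepted):
            status = NodeStatus.RESOLVED
        elif accepted:
            status = NodeStatus.HOMOLOG
        else:
            status = NodeStatus.NONE
        g.add_node(p, status=status)

    for a, b in edge_list:
        if a == b and not allow_self:
            continue
        x, y = sorted((a, b))
        if g.has_edge(x, y):
            continue
        evidence = Evidence.SEQUENCE_ONLY
        interface: dict[str, set] = {}
        covering = [
            c
            for c in complexes
            if x in c.chain_proteins.values() and y in c.chain_proteins.values()
            # self-interactions need two chains of the same protein
            and (x != y or sum(1 for p in c.chain_proteins.values() if p == x) >= 2)
        ]
        cognate_cov = [c for c in covering if not c.homology]
        chosen = cognate_cov[0] if cognate_cov else (covering[0] if covering else None)
        if chosen is not None:
            evidence = (
                Evidence.HOMOLOGY_MODEL if chosen.homology else Evidence.RESOLVED_STRUCTURE
            )
            interface = {p: chosen.interface_for(p) for p in {x, y}}
        g.add_edge(x, y, evidence=evidence, interface_residues=interface)

    return Network(graph=g)


def network_summary(net: Network) -> pd.DataFrame:
    """Coverage table: node counts per structure status, edge counts per evidence."""
    rows = []
    nodes = net.nodes
    for status in NodeStatus:
        rows.append(("node", status.value, sum(1 for s in nodes.values() if s is status)))
    edges = net.edges
    for ev in Evidence:
        rows.append(("edge", ev.value, sum(1 for e in edges if e.evidence is ev)))
    rows.append(("node", "total", len(nodes)))
    rows.append(("edge", "total", len(edges)))
    return pd.DataFrame(rows, columns=["kind", "category", "count"])


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a (protein_a, protein_b[, source]) TSV; header optional."""
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() in ("protein_a", "a", "source_node"):
            continue
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}: malformed edge at line {lineno}: {line!r}")
        edges.append((fields[0], fields[1]))
    return edges


def write_network(net: Network, node_path: str | Path, edge_path: str | Path) -> None:
    nodes = net.nodes
    node_df = pd.DataFrame(
        sorted((p, s.value) for p, s in nodes.items()), columns=["protein", "status"]
    )
    node_df.to_csv(node_path, sep="\t", index=False)
    edge_rows = []
    for e in net.edges:
        iface = ";".join(
            f"{p}:" + ",".join(f"{c}/{n}{i}" for c, n, i in sorted(res))
            for p, res in sorted(e.interface_residues.items())
            if res
        )
        edge_rows.append((e.a, e.b, e.evidence.value, iface))
    pd.DataFrame(
        edge_rows, columns=["protein_a", "protein_b", "evidence", "interface_residues"]
    ).to_csv(edge_path, sep="\t", index=False)


def read_network(node_path: str | Path, edge_path: str | Path) -> Network:
    """Rebuild a Network from its serialized node/edge tables."""
    g = nx.Graph()
    nodes = pd.read_csv(node_path, sep="\t", dtype=str)
    for row in nodes.itertuples(index=False):
        g.add_node(row.protein, status=NodeStatus(row.status))
    edges = pd.read_csv(edge_path, sep="\t", dtype=str).fillna("")
    for row in edges.itertuples(index=False):
        interface: dict[str, set] = {}
        if row.interface_residues:
            for part in row.interface_residues.split(";"):
                prot, _, res = part.partition(":")
                keys = set()
                for item in res.split(","):
                    if not item:
                        continue
                    chain, _, numic = item.partition("/")
                    num = "".join(ch for ch in numic if ch.isdigit() or ch == "-")
                    icode = numic[len(num):]
                    keys.add((chain, int(num), icode))
                interface[prot] = keys
        g.add_edge(
            row.protein_a,
            row.protein_b,
            evidence=Evidence(row.evidence),
            interface_residues=interface,
        )
    return Network(graph=g)
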