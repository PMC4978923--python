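"""Deterministic synthetic structures, variants and demo workspaces.

Every generator is a pure function of its spec (including the seed), so
fixtures are reproducible bit-for-bit and ship with *exact* ground truth:

* geometry is built from pseudo-residues of single carbon atoms placed on
  lattices or helix paths, with inter-atom distances chosen so that each
  residue's region label is forced by construction (an atom whose nearest
  partner-chain atom sits closer than the burial margin must lose SASA; an
  atom beyond the solvent-expanded reach 2(r+probe) cannot lose any);
* residues whose label geometry leaves ambiguous are returned as ``None``
  in the truth map and excluded from ground-truth comparisons;
* planted variant sets multiply the *fraction* of variants expected in the
  target region, so the planted factor is directly the expected value of
  the enrichment score estimator.

No attempt is made to mimic real amino-acid packing; the point is exact,
download-free ground truth for every pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .regions import Region
from .structure_model import Atom, Residue, StructureModel, write_structure

__all__ = [
    "FixtureSpec",
    "PlantedVariantSpec",
    "make_structure",
    "make_variants",
    "demo_workspace",
    "FIXTURE_ALPHABET",
]

#: Residue types used by fixtures: max-ASA references <= 225 A^2, so a
#: single exposed carbon pseudo-atom is always safely above the core
#: threshold regardless of which letter it draws.
FIXTURE_ALPHABET = "ACDEGHILMNPQSTV"

_CARBON_RADIUS = 1.70
_PROBE = 1.4
#: two solvent-expanded carbon spheres interact iff centres are closer than this
_REACH = 2.0 * (_CARBON_RADIUS + _PROBE)
#: distances below this force a ΔSASA well above the interface noise floor
_CONTACT = 5.6
#: distances above this (with margin over _REACH = 6.2) force ΔSASA = 0
_CLEAR = 6.35


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # sphere_pair | two_slab_complex | globule | helix_dimer
    n_residues: int = 32  # per chain (total for globule / sphere_pair)
    separation: float = 2.0  # closest gap between partner chains, Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")


@dataclass(frozen=True)
class PlantedVariantSpec:
    n_variants: int
    target_region: Region = Region.INTERFACE
    enrichment_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _residue(chain_id: str, num: int, aa: str, xyz: tuple[float, float, float]) -> Residue:
    atom = Atom(
        element="C",
        name="CA",
        coord=(round(xyz[0], 3), round(xyz[1], 3), round(xyz[2], 3)),
        occupancy=1.0,
        altloc="",
        radius=_CARBON_RADIUS,
    )
    return Residue(chain_id=chain_id, seq_num=num, icode="", aa=aa, atoms=[atom])


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(FIXTURE_ALPHABET), size=n))


def _build_model(
    model_id: str, chain_coords: dict[str, list[tuple[float, float, float]]], seed: int
) -> StructureModel:
    rng = _rng(seed)
    chains: dict[str, list[Residue]] = {}
    for cid in sorted(chain_coords):
        seq = _random_sequence(rng, len(chain_coords[cid]))
        chains[cid] = [
            _residue(cid, i + 1, seq[i], xyz)
            for i, xyz in enumerate(chain_coords[cid])
        ]
    return StructureModel(
        id=model_id, chains=chains, missing_segments={c: [] for c in chains}
    )


def _distance_truth(model: StructureModel) -> dict[tuple[str, int, str], Region | None]:
    """Interface/surface truth from inter-chain distances with safety margins.

    ``None`` marks residues inside the ambiguous band (close enough that a
    small SASA loss is possible, too far to guarantee one).
    """
    coords = {
        cid: np.array([r.atoms[0].coord for r in residues])
        for cid, residues in model.chains.items()
    }
    truth: dict[tuple[str, int, str], Region | None] = {}
    for cid, residues in model.chains.items():
        partners = [c for c in model.chains if c != cid]
        if not partners:
            for r in residues:
                truth[r.key] = Region.SURFACE
            continue
        other = np.vstack([coords[c] for c in partners])
        for r in residues:
            d = float(np.min(np.linalg.norm(other - np.array(r.atoms[0].coord), axis=1)))
            if d <= _CONTACT:
                truth[r.key] = Region.INTERFACE
            elif d >= _CLEAR:
                truth[r.key] = Region.SURFACE
            else:
                truth[r.key] = None
    return truth


def _sphere_pair(spec: FixtureSpec):
    if spec.n_residues != 2:
        raise ValueError("sphere_pair needs n_residues = 2 (one atom per chain)")
    gap = spec.separation
    coords = {"A": [(0.0, 0.0, 0.0)], "B": [(gap, 0.0, 0.0)]}
    model = _build_model("sphere_pair", coords, spec.seed)
    return model, _distance_truth(model)


def _two_slab(spec: FixtureSpec):
    k = math.isqrt(spec.n_residues // 2)
    if 2 * k * k != spec.n_residues:
        raise ValueError(
            "two_slab_complex needs n_residues = 2*k^2 per chain (two k x k layers)"
        )
    s = 5.0  # lattice spacing: wide enough that back layers stay clearly exposed
    gap = spec.separation
    if gap + s <= _CLEAR:
        raise ValueError(
            f"two_slab_complex: back layer would sit within solvent reach "
            f"(need separation + {s} > {_CLEAR})"
        )
    layer = [(i * s, j * s) for i in range(k) for j in range(k)]
    coords = {
        # front layer first (residues 1..k^2), then back layer
        "A": [(x, y, 0.0) for x, y in layer] + [(x, y, -s) for x, y in layer],
        "B": [(x, y, gap) for x, y in layer] + [(x, y, gap + s) for x, y in layer],
    }
    model = _build_model("two_slab_complex", coords, spec.seed)
    truth = _distance_truth(model)
    if gap <= _CONTACT:
        # construction guarantee: contact layers are interface, back layers surface
        for cid in ("A", "B"):
            for idx, r in enumerate(model.chains[cid]):
                truth[r.key] = Region.INTERFACE if idx < k * k else Region.SURFACE
    return model, truth


def _globule(spec: FixtureSpec):
    m = round(spec.n_residues ** (1 / 3))
    if m ** 3 != spec.n_residues or m < 3 or m % 2 == 0:
        raise ValueError("globule needs n_residues = m^3 with odd m >= 3")
    s = 4.0
    coords = [
        (i * s, j * s, l * s)
        for i in range(m)
        for j in range(m)
        for l in range(m)
    ]
    model = _build_model("globule", {"A": coords}, spec.seed)
    truth: dict[tuple[str, int, str], Region | None] = {}
    centre = (m - 1) / 2
    for idx, r in enumerate(model.chains["A"]):
        i, j, l = idx // (m * m), (idx // m) % m, idx % m
        on_corner = all(c in (0, m - 1) for c in (i, j, l))
        interior = all(0 < c < m - 1 for c in (i, j, l))
        if (i, j, l) == (centre, centre, centre):
            truth[r.key] = Region.CORE
        elif on_corner:
            truth[r.key] = Region.SURFACE
        elif interior:
            truth[r.key] = Region.CORE
        else:
            truth[r.key] = None  # faces/edges: burial not guaranteed by construction
    return model, truth


def _helix_coords(n: int, axis_x: float, phase: float) -> list[tuple[float, float, float]]:
    radius, rise, twist = 2.3, 1.5, math.radians(100.0)
    return [
        (
            axis_x + radius * math.cos(phase + twist * i),
            radius * math.sin(phase + twist * i),
            rise * i,
        )
        for i in range(n)
    ]


def _helix_dimer(spec: FixtureSpec):
    if spec.n_residues % 2 != 0 or spec.n_residues < 8:
        raise ValueError("helix_dimer needs an even n_residues >= 8 (split over 2 chains)")
    n = spec.n_residues // 2
    axis_dist = 2 * 2.3 + spec.separation
    coords = {
        "A": _helix_coords(n, 0.0, 0.0),
        "B": _helix_coords(n, axis_dist, math.pi),
    }
    model = _build_model("helix_dimer", coords, spec.seed)
    truth = _distance_truth(model)
    # A helix trace occludes part of its own contact caps, so the generic
    # contact margin is not safe here: only very close partner contacts
    # (<= 4.6 A for this fixed helix geometry) force a SASA loss.  Far
    # residues may still be core-ish, so non-contacts stay open too.
    coords_arr = {
        cid: np.array([r.atoms[0].coord for r in rs]) for cid, rs in model.chains.items()
    }
    for cid, residues in model.chains.items():
        other = np.vstack([coords_arr[c] for c in model.chains if c != cid])
        for r in residues:
            d = float(np.min(np.linalg.norm(other - np.array(r.atoms[0].coord), axis=1)))
            truth[r.key] = Region.INTERFACE if d <= 4.6 else None
    return model, truth


_KINDS = {
    "sphere_pair": _sphere_pair,
    "two_slab_complex": _two_slab,
    "globule": _globule,
    "helix_dimer": _helix_dimer,
}


def make_structure(
    spec: FixtureSpec,
) -> tuple[StructureModel, dict[tuple[str, int, str], Region | None]]:
    """Build a synthetic structure plus its ground-truth region map.

    Truth values of ``None`` mark residues whose label is not forced by the
    geometry; all other entries must agree with :func:`~pinmap.regions.classify_regions`
    at default parameters.
    """
    if spec.kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[spec.kind](spec)


def make_variants(
    protein_len: int,
    truth_regions: dict[int, Region],
    spec: PlantedVariantSpec,
    protein_seq: str | None = None,
    source: str = "planted",
) -> tuple[list, dict]:
    """Sample variant positions with a planted regional enrichment.

    ``truth_regions`` maps 1-based protein positions to region labels; only
    labelled positions receive variants (the enrichment null is defined over
    the labelled universe).  The target region's total probability mass is
    ``enrichment_factor`` times its residue fraction, spread uniformly within
    the region, with the remaining mass uniform outside — so the expected
    enrichment score equals ``enrichment_factor`` exactly.  Positions are
    drawn independently (variants may co-occur at one position).

    Returns ``(variants, metadata)`` where metadata records the true factor,
    seed and realized counts.
    """
    from .seqmap import VariantRecord

    positions = sorted(p for p in truth_regions if 1 <= p <= protein_len)
    if not positions:
        raise ValueError("truth_regions covers no positions in 1..protein_len")
    if protein_seq is not None and len(protein_seq) < protein_len:
        raise ValueError("protein_seq shorter than protein_len")

    target = [p for p in positions if truth_regions[p] == spec.target_region]
    other = [p for p in positions if truth_regions[p] != spec.target_region]
    n_lab = len(positions)
    f = spec.enrichment_factor
    target_mass = f * len(target) / n_lab
    if target_mass > 1.0 + 1e-12:
        raise ValueError(
            f"enrichment_factor {f} infeasible: target region holds "
            f"{len(target)}/{n_lab} labelled positions (max factor {n_lab/len(target):.3g})"
        )
    if not other and (f == 0 or target_mass < 1.0 - 1e-12):
        raise ValueError("target region covers all labelled positions; factor must be 1")
    target_mass = min(target_mass, 1.0)

    probs = np.zeros(len(positions))
    pos_index = {p: i for i, p in enumerate(positions)}
    for p in target:
        probs[pos_index[p]] = target_mass / len(target) if target else 0.0
    for p in other:
        probs[pos_index[p]] = (1.0 - target_mass) / len(other)
    probs /= probs.sum()

    rng = _rng(spec.seed)
    drawn = rng.choice(positions, size=spec.n_variants, p=probs, replace=True)
    aa_list = list(FIXTURE_ALPHABET)
    variants = []
    for i, pos in enumerate(sorted(int(p) for p in drawn)):
        ref = protein_seq[pos - 1] if protein_seq else "A"
        alt_choices = [a for a in aa_list if a != ref]
        alt = alt_choices[int(rng.integers(0, len(alt_choices)))]
        variants.append(
            VariantRecord(
                protein="PROT", position=pos, ref_aa=ref, alt_aa=alt,
                source=source, id=f"v{i + 1}",
            )
        )
    n_in_target = sum(1 for v in variants if v.position in set(target))
    meta = {
        "true_factor": f,
        "seed": spec.seed,
        "n_variants": spec.n_variants,
        "n_in_target": n_in_target,
        "n_labelled": n_lab,
        "n_target_positions": len(target),
    }
    return variants, meta


def _mutate_sequence(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute a fixed fraction of positions (used to make homolog demo sequences)."""
    out = list(seq)
    n_mut = max(1, int(round(fraction * len(seq))))
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    for s in sites:
        choices = [a for a in FIXTURE_ALPHABET if a != out[s]]
        out[s] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def demo_workspace(outdir: str | Path, seed: int = 17) -> dict[str, Path]:
    """Write a complete, self-contained demo workspace.

    Contents: a two-slab complex (cognate structures of PROT_A/PROT_B), a
    helix dimer serving as homologous structure for PROT_C/PROT_D, an
    unstructured PROT_E, planted interface-enriched variants on PROT_A,
    background variants on PROT_C, site/PTM and disorder tracks, and a
    five-protein edge list (with a deliberate reversed duplicate).
    """
    from .seqmap import mapped_variant_table  # noqa: F401  (import check only)
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed + 101)

    slab, slab_truth = make_structure(FixtureSpec("two_slab_complex", 32, 2.0, seed))
    slab.id = "complex"
    write_structure(slab, outdir / "complex.pdb")
    helix, _ = make_structure(FixtureSpec("helix_dimer", 60, 2.0, seed + 1))
    helix.id = "homolog"
    write_structure(helix, outdir / "homolog.pdb")

    seq_a = "".join(r.aa for r in slab.chains["A"])
    seq_b = "".join(r.aa for r in slab.chains["B"])
    helix_a = "".join(r.aa for r in helix.chains["A"])
    helix_b = "".join(r.aa for r in helix.chains["B"])
    seq_c = _mutate_sequence(helix_a, 0.25, rng)
    seq_d = _mutate_sequence(helix_b, 0.25, rng)
    seq_e = _random_sequence(rng, 40)
    proteins = {
        "PROT_A": seq_a, "PROT_B": seq_b, "PROT_C": seq_c,
        "PROT_D": seq_d, "PROT_E": seq_e,
    }
    with open(outdir / "proteins.fasta", "w") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n{seq}\n")

    homolog_rows = [
        ("PROT_A", 1, len(seq_a), "complex.pdb", "A"),
        ("PROT_B", 1, len(seq_b), "complex.pdb", "B"),
        ("PROT_C", 1, len(seq_c), "homolog.pdb", "A"),
        ("PROT_D", 1, len(seq_d), "homolog.pdb", "B"),
    ]
    pd.DataFrame(
        homolog_rows,
        columns=["protein", "domain_start", "domain_end", "structure_path", "chain"],
    ).to_csv(outdir / "homologs.tsv", sep="\t", index=False)

    # planted interface enrichment on PROT_A; slab interface fraction is 1/2,
    # so 1.8 is close to the largest plantable fraction-multiplying factor
    truth_by_pos = {
        r.seq_num: slab_truth[r.key]
        for r in slab.chains["A"]
        if slab_truth[r.key] is not None
    }
    planted, meta = make_variants(
        len(seq_a),
        truth_by_pos,
        PlantedVariantSpec(25, Region.INTERFACE, 1.8, seed + 2),
        protein_seq=seq_a,
        source="planted",
    )
    background, _ = make_variants(
        len(seq_c),
        {i + 1: Region.SURFACE for i in range(len(seq_c))},
        PlantedVariantSpec(6, Region.SURFACE, 1.0, seed + 3),
        protein_seq=seq_c,
        source="background",
    )
    var_rows = [
        (("PROT_A" if v.source == "planted" else "PROT_C"), v.position, v.ref_aa,
         v.alt_aa, v.source, f"{v.source}_{i + 1}")
        for i, v in enumerate(planted + background)
    ]
    pd.DataFrame(
        var_rows, columns=["protein", "position", "ref_aa", "alt_aa", "source", "id"]
    ).to_csv(outdir / "variants.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            ("PROT_A", 3, "active_site", "demo"),
            ("PROT_A", 17, "ptm_phospho", "demo"),
            ("PROT_C", 5, "binding", "demo"),
        ],
        columns=["protein", "position", "kind", "source"],
    ).to_csv(outdir / "sites.tsv", sep="\t", index=False)

    pd.DataFrame(
        [("PROT_E", i + 1, 1) for i in range(10)],
        columns=["protein", "position", "disordered"],
    ).to_csv(outdir / "disorder.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            ("PROT_A", "PROT_B"),
            ("PROT_B", "PROT_A"),  # reversed duplicate, collapsed on load
            ("PROT_C", "PROT_D"),
            ("PROT_A", "PROT_C"),
            ("PROT_E", "PROT_A"),
        ],
        columns=["protein_a", "protein_b"],
    ).to_csv(outdir / "edges.tsv", sep="\t", index=False)

    config = "\n".join(
        [
            "# pinmap demo configuration (flat key=value; CLI flags override)",
            "structures_dir=.",
            "fasta=proteins.fasta",
            "homologs=homologs.tsv",
            "variants=variants.tsv",
            "sites=sites.tsv",
            "disorder=disorder.tsv",
            "edges=edges.tsv",
            "outdir=out",
            "probe=1.4",
            "n_points=960",
            "interface_min_dsasa=0.1",
            "core_max_rasa=0.15",
            "gap_open=10.0",
            "gap_extend=0.5",
            "matrix=BLOSUM62",
            "n_perm=10000",
            f"seed={seed}",
            "",
        ]
    )
    (outdir / "pinmap.cfg").write_text(config)
    return {p.name: p for p in sorted(outdir.iterdir())}
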