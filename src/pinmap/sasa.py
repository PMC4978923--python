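"""Shrake–Rupley solvent-accessible surface area.

Each atom's SASA is estimated by placing ``n_points`` quasi-uniform sample
points on its solvent-expanded sphere (radius r + probe) and counting the
points that fall outside every other included atom's expanded sphere:

    SASA_i = (exposed_i / n_points) * 4 * pi * (r_i + probe)^2

Sample points come from a deterministic Fibonacci (golden-spiral) lattice,
so the computation has no randomness.  A point lying exactly on a
neighbouring expanded sphere counts as buried; this makes two coincident
identical atoms score exactly zero.  Neighbour search uses a k-d tree with
a cutoff of r_i + r_j + 2*probe, which is exact — results are identical to
the all-pairs computation.

Relative SASA divides a residue's SASA by its maximum exposure in an
extended Gly-X-Gly tripeptide (theoretical values of Tien et al. style),
the standard reference for calling buried (core) residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import StructureModel

__all__ = [
    "SasaResult",
    "MAX_ASA_GXG",
    "NoReferenceArea",
    "sphere_points",
    "compute_sasa",
    "relative_sasa",
    "load_max_asa_table",
    "sasa_table",
]

#: Theoretical maximum accessible surface area (A^2) per residue in an
#: extended Gly-X-Gly tripeptide.
MAX_ASA_GXG: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


class NoReferenceArea(KeyError):
    """No maximum-ASA reference for this residue type (e.g. 'X')."""


@dataclass
class SasaResult:
    per_atom: dict[tuple[tuple[str, int, str], str], float]
    per_residue: dict[tuple[str, int, str], float]
    probe_radius: float
    n_points: int
    chain_subset: frozenset[str]


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _gather_atoms(model: StructureModel, chain_subset: frozenset[str]):
    coords, radii, keys = [], [], []
    for cid in chain_subset:
        for res in model.chains[cid]:
            for atom in res.atoms:
                coords.append(atom.coord)
                radii.append(atom.radius)
                keys.append((res.key, atom.name))
    return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float), keys


def compute_sasa(
    model: StructureModel,
    chain_subset: set[str] | frozenset[str] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Per-atom and per-residue SASA of the chains in ``chain_subset``.

    Atoms outside the subset are invisible to the computation, so computing
    a chain alone versus in complex yields the ΔSASA used for interface
    detection.
    """
    if chain_subset is None:
        chain_subset = set(model.chains)
    chain_subset = frozenset(chain_subset)
    if not chain_subset:
        raise ValueError("chain_subset must be non-empty")
    unknown = chain_subset - set(model.chains)
    if unknown:
        raise KeyError(f"chains {sorted(unknown)} not in structure {model.id}")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")

    coords, radii, keys = _gather_atoms(model, chain_subset)
    n_atoms = len(keys)
    expanded = radii + probe
    unit = sphere_points(n_points)

    per_atom_arr = np.empty(n_atoms)
    tree = cKDTree(coords)
    cutoff = 2.0 * expanded.max()
    neighbours = tree.query_ball_tree(tree, cutoff)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours[i]:
            if j == i:
                continue
            # exact pairwise cutoff; tree cutoff is only an upper bound
            d2 = np.sum((coords[i] - coords[j]) ** 2)
            if d2 > (expanded[i] + expanded[j]) ** 2:
                continue
            dist2 = np.sum((pts - coords[j]) ** 2, axis=1)
            # boundary counts as buried; the epsilon absorbs rounding so a
            # point lying exactly on the expanded sphere is buried reliably
            exposed &= dist2 > expanded[j] ** 2 + 1e-9
            if not exposed.any():
                break
        per_atom_arr[i] = exposed.sum() / n_points * 4.0 * np.pi * expanded[i] ** 2

    per_atom = {key: float(v) for key, v in zip(keys, per_atom_arr)}
    per_residue: dict[tuple[str, int, str], float] = {}
    for (res_key, _), v in per_atom.items():
        per_residue[res_key] = per_residue.get(res_key, 0.0) + v
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        probe_radius=probe,
        n_points=n_points,
        chain_subset=chain_subset,
    )


def relative_sasa(
    res_sasa: float, aa: str, table: dict[str, float] | None = None
) -> float:
    """Residue SASA divided by the reference maximum for its amino acid.

    May slightly exceed 1 for extended conformations; not clipped.  Raises
    :class:`NoReferenceArea` for residue types absent from the table (the
    caller must treat such residues as unclassifiable by burial).
    """
    table = table or MAX_ASA_GXG
    if aa not in table:
        raise NoReferenceArea(f"no reference area for residue type {aa!r}")
    return res_sasa / table[aa]


def load_max_asa_table(path: str | Path) -> dict[str, float]:
    """Read a (one-letter aa, max ASA A^2) TSV."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, area = line.split("\t")[:2]
        table[aa.strip()] = float(area)
    return table


def sasa_table(model: StructureModel, result: SasaResult) -> "pandas.DataFrame":
    """Per-residue SASA export table (chain, seq_num, icode, aa, sasa_A2, rel_sasa)."""
    import pandas as pd

    rows = []
    for cid in sorted(result.chain_subset):
        for res in model.chains[cid]:
            sasa = result.per_residue.get(res.key, 0.0)
            try:
                rel = relative_sasa(sasa, res.aa)
            except NoReferenceArea:
                rel = float("nan")
            rows.append((cid, res.seq_num, res.icode, res.aa, sasa, rel))
    return pd.DataFrame(
        rows, columns=["chain", "seq_num", "icode", "aa", "sasa_A2", "rel_sasa"]
    )
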