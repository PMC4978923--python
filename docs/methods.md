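# Methods

## Scope and model

`pinmap` annotates protein-level variants with structural context. The
chain of inference is: parse a PDB structure; compute solvent-accessible
surface area (SASA); classify residues into interface / core / surface /
unresolved; align protein sequences to structure chains and accept
homologous structures through an identity/coverage gate; transfer region
labels to variant positions; and test regional enrichment of variant
classes. A protein–protein interaction network layer summarizes, for an
edge list, how much of the network those structural annotations cover.

## Structure model

PDB files are parsed with gemmi and reduced to heavy atoms: hydrogens and
waters are always discarded, other heteroatoms only on request. For
alternate-location groups the highest-occupancy conformer is kept, ties
broken by the lexicographically smallest altloc code; only the first MODEL
of multi-model files is read. Author numbering is preserved, insertion
codes sort after their base number alphabetically, and gaps in consecutive
author numbering become *missing-density segments*, the basis of the
unresolved/disordered track. Van der Waals radii come from a small fixed
table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, default 1.70 Å),
overridable by TSV. Only the PDB dialect is supported; the file given is
the unit analysed (no assembly generation).

## SASA

Shrake–Rupley with a deterministic Fibonacci (golden-spiral) lattice —
there is no randomness anywhere in the SASA computation. Defaults: probe
1.4 Å, 960 sample points per atom (per-residue values at 960 vs 3,840
points differ by well under 1% on the bundled geometries, so 960 is kept
for speed). A sample point lying exactly on a neighbouring expanded sphere
counts as buried, with a 1e-9 Å² epsilon absorbing floating-point rounding;
this makes two coincident identical atoms score exactly zero. Neighbour
search uses a k-d tree with an exact per-pair cutoff r_i + r_j + 2·probe,
so results are identical to the all-pairs computation. Relative SASA
divides by theoretical Gly-X-Gly maxima (Tien-style values, 20 entries,
TSV-overridable); residue types without a reference (X) raise a
`NoReferenceArea` signal and are treated as unclassifiable by burial
(they can never be called core).

## Region classification

ΔSASA on complexation is computed chain-vs-rest: isolated-chain SASA minus
in-complex SASA, clamped at zero. Thresholds:

| parameter | default | meaning |
|---|---|---|
| `interface_min_dsasa` | 0.1 Å² | minimum ΔSASA for an interface call; suppresses point-sampling noise (one lattice point ≈ 0.13 Å²) while catching any real burial |
| `core_max_rasa` | 0.15 | maximum isolated-chain relative SASA for core; a common burial convention |

Interface takes precedence over core, so the four labels partition the
residues. Disorder is a flag orthogonal to the region: user tracks (e.g.
from an external disorder predictor) override; otherwise disordered ⇔
unresolved. The census reports the region × disordered cross-table so both
an exclusive and an additive reading of "disordered" are recoverable.

## Sequence mapping

Alignment is global Needleman–Wunsch with affine gaps, delegated to
Biopython's `PairwiseAligner` (BLOSUM62; gap open 10, extend 0.5, a gap of
length k costing open + (k−1)·extend, end gaps penalized). The test suite
holds it against an independently written Gotoh dynamic program. Chosen
conventions, recorded in output metadata: identity is the percentage of
identical residues among aligned residue–residue pairs (gap columns
excluded, X never identical and scoring 0 against everything); coverage is
the percentage of the query domain interval present in aligned pairs.
Alignments run on the full protein sequence; the domain interval only sets
the coverage denominator.

The homology-transfer gate is strict: identity > 30 **and** coverage > 80;
cognate structures (identity 100, coverage 100 in the pipeline's inference)
always pass. Matches are ranked cognate first, then identity, coverage, and
identifiers for deterministic ties. Variant mapping is total: every variant
gets exactly one status (`mapped`, `ref_mismatch` against the provided
sequence, `unaligned_position` when every accepted alignment gaps the
position, or `no_accepted_structure`). Candidate structures arrive as an
input table; no database search is performed.

## Profiles

A profile is a set of equal-length per-position tracks: region symbols
(I/C/S/U, '-' for positions without accepted structural coverage, best
accepted match winning where several overlap), mapped-variant counts, site
and PTM markers, and disorder. Serialization is a FASTA-like block format
plus a long-form TSV; both round-trip losslessly. The symbol vocabulary is
this package's own definition.

## Enrichment

The score is the ratio of observed to expected in-region variant fraction,
(n_r/n)/(N_r/N); an odds-ratio variant sits behind a flag. The exact test
is the one-sided upper-tail hypergeometric probability (depletion via
`alternative="less"`); the permutation test redraws the n variant positions
uniformly over the N *labelled* residues — never over the raw sequence, so
unresolved positions cannot absorb signal — with replacement by default
because several variants can hit one residue. p_perm = (1 + hits)/(1 +
n_perm) with n_perm = 10,000 by default; streams use the counter-based
Philox generator seeded per row, so results are independent of row order.
Benjamini–Hochberg q-values (statsmodels) are attached across all tested
(class × region) pairs. Note the exact test assumes n ≤ N and sampling
without replacement; with the default with-replacement null it is mildly
approximate, and the measured type-I error at α = 0.05 stays below 0.04–0.05
for the n ≪ N regimes exercised here.

## Synthetic data

Fixtures are pseudo-residues of single carbon atoms on exact geometries, so
ground truth is forced by construction rather than asserted empirically:

* **two_slab_complex** — two chains of two k×k layers (5 Å spacing), facing
  layers 2 Å apart. Contact-layer atoms must lose ≫ 0.1 Å² (the opposing
  sphere is 2 Å away); back-layer atoms sit beyond the 6.2 Å solvent-expanded
  reach of the partner and provably lose nothing, and stay above the core
  threshold at 5 Å lattice spacing. Interface ground truth is therefore the
  contact layer exactly.
* **globule** — an odd m³ cube (4 Å spacing); the centre (and any interior
  atom) is fully buried → core; corners are clearly exposed → surface; faces
  and edges are left unconstrained.
* **helix_dimer** — two ideal Cα-trace helices (radius 2.3 Å, rise 1.5 Å,
  100°/residue). Because a helix partially occludes its own contact caps,
  only close partner contacts (≤ 4.6 Å, where the forced cap is tens of Å²)
  are claimed as interface; the rest is unconstrained.
* **sphere_pair** — two single-atom chains at a chosen gap: both interface
  when within contact range, both surface when beyond reach.

Residue letters are drawn (seeded, Philox) from a 15-letter alphabet whose
Gly-X-Gly maxima are ≤ 225 Å², so a partially exposed carbon pseudo-atom
can never fall below the core threshold by the accident of drawing a large
reference residue. All generators are bit-reproducible from their spec.

The planted-variant sampler gives the target region a total probability
mass of `enrichment_factor ×` its residue fraction (uniform within the
region, remainder uniform outside), so the *expected enrichment score
equals the factor* and parameter-recovery tests compare like with like.
Factors above N/N_r are geometrically infeasible and rejected. Positions
are drawn independently (variants may co-occur).

What the fixtures do **not** emulate: real side-chain packing, atom
heterogeneity, B-factors, real amino-acid interface propensities, or
alignment ambiguity from repeats. Passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under the
stated geometric and sampling assumptions — not biological accuracy of any
particular threshold on real proteins.

## Pipeline and determinism

The census universe for enrichment is the set of structure-covered
positions of every protein with an accepted match, labels taken through the
best accepted alignment per position. The demo workspace plants a factor
1.8 interface enrichment on a slab protein (half of whose residues are
interface, capping the plantable factor at 2) over 25 variants, plus a
uniform background class. Chosen problem sizes throughout (32–64 residue
structures, 960-point SASA, 200-replicate recovery runs, 2,000-simulation
calibration) keep any single check in seconds while leaving Monte-Carlo
margins far from the asserted bounds.

All pipeline outputs are plain TSV/text written in sorted order; rerunning
any stage with the same config and seed is byte-identical. Exit codes: 0
ok, 1 internal error, 2 bad input.

## Known limitations

* PDB only (no mmCIF); first MODEL only; no biological-assembly generation.
* The exact test is approximate under with-replacement placement when n is
  an appreciable fraction of N (see above).
* Non-redundancy of input edge lists is exact-duplicate collapsing only.
* Disorder input in the bundled pipeline feeds the profile track; residue-
  keyed disorder for structure classification is available at the library
  level (`classify_regions(disorder_track=...)`).
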