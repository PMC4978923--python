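# pinmap

Map protein-level variants onto 3D structures, classify every residue into
**surface / interface / core** (with a disorder track), build per-protein
sequence-annotated *profiles*, and test whether a variant class is enriched
in a structural region — with exact and permutation statistics — plus a
structural-coverage summary for protein–protein interaction networks.

`pinmap` is for computational biologists who have protein-level variant
tables (e.g. germ-line disease SNPs or somatic cancer mutations), protein
sequences, and PDB structures (cognate or homologous), and want a
reproducible, desk-scale answer to questions like *"are these mutations
over-represented at protein–protein interfaces?"*.

## Method

**Regions.** Per-atom solvent-accessible surface area (SASA) is computed by
the Shrake–Rupley method: each atom's solvent-expanded sphere (radius
*r* + 1.4 Å) is sampled with a deterministic Fibonacci lattice (960 points
by default) and

&nbsp;&nbsp;SASA = (exposed points / total points) · 4π(r + probe)².

For every residue of chain *c* in a complex, ΔSASA = SASA(residue | chain
*c* alone) − SASA(residue | full complex). A residue is **interface** when
ΔSASA > 0.1 Å², else **core** when its isolated-chain relative SASA
(residue SASA over its Gly-X-Gly maximum) is ≤ 0.15, else **surface**;
residues without coordinates (missing density) are **unresolved** and
flagged disordered unless an explicit disorder track is supplied.

**Mapping.** Query sequences are aligned to structure-derived chain
sequences by global Needleman–Wunsch with affine gaps (BLOSUM62, open 10,
extend 0.5). A homologous structure is accepted for transfer when identity
> 30% (over aligned pairs) *and* coverage > 80% (of the domain interval);
cognate structures always win. Variants inherit the region label of the
residue their position aligns to, through the best accepted match.

**Enrichment.** For a variant class with *n* mapped variants, *n_r* of them
in region *r*, and a labelled-residue census (*N_r* of *N*):

&nbsp;&nbsp;score = (n_r / n) / (N_r / N),

with a one-sided hypergeometric exact p-value, a seeded permutation p-value
(positions redrawn uniformly over the *labelled* universe), and
Benjamini–Hochberg q-values across all tested (class × region) pairs.

## Worked example

Everything runs on a synthetic, fully self-contained demo workspace — two
structures with constructed interfaces, five proteins, planted
interface-enriched variants:

```bash
pinmap simulate demo --seed 17
pinmap all -c demo/pinmap.cfg
```

`demo/out/enrichment.tsv` (abridged):

| class | region | n_r | n | N_r | N | score | p_exact | q |
|---|---|---|---|---|---|---|---|---|
| planted | interface | 23 | 25 | 64 | 124 | 1.78 | 2.6e-06 | 1.1e-05 |
| planted | surface | 2 | 25 | 60 | 124 | 0.17 | 1.00 | 1.00 |
| background | interface | 2 | 6 | 64 | 124 | 0.65 | 0.91 | 1.00 |

The demo plants variants on PROT_A with 1.8× the interface's residue
fraction; the recovered score 1.78 matches the plant, and only the planted
(class, region) pair is significant after FDR. The background class placed
uniformly shows no enrichment. `demo/out/network_summary.tsv` reports the
structural coverage of the five-protein network: 2 proteins with a cognate
("resolved") structure, 2 covered by accepted homologs, 1 with none, and
edges split into resolved_structure / homology_model / sequence_only.

Per-protein profiles (`demo/out/profiles.txt`) line up one symbol per
position, e.g. for PROT_A the region track `IIIIIIIIIIIIIIIISSSSSSSSSSSSSSSS`
marks the 16 contact-layer residues of its slab structure as interface.

Subcommands can also run separately (`annotate`, `map-variants`, `enrich`,
`network`); all thresholds and paths live in the flat `pinmap.cfg` file and
can be overridden by flags.

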