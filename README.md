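# biaslens

A tested, reusable pipeline for locating structural determinants of
catalytic bias in paired [FeFe]-hydrogenases. Given two focal paralogs
(e.g., a hydrogen-evolving and a hydrogen-oxidizing enzyme), their homologs,
a phylogeny, and structures, it answers: *which residues differ between the
pair, sit near the FeS clusters, and carry phylogenetic signal?*

## Components

| module | what it does |
| --- | --- |
| `biaslens.core_io` | FASTA / aligned FASTA / newick / PDB-subset / TSV readers and writers; 1-based coordinate conventions; column↔residue maps |
| `biaslens.motifs` | H-cluster signature motif scanning (L1/L2/L3, P1B, [NiFe] CxxC), accessory-cluster cysteine inventory, group assignment (A2 / A3 / B2) |
| `biaslens.conserve` | global pairwise alignment (BLOSUM62, affine gaps), identity/similarity, L1→L3 catalytic-block trimming, per-column conservation profiling with focal-pair differencing |
| `biaslens.proximity` | Kabsch superposition, residue-to-cluster minimum heavy-atom distances, ≤5 Å candidate-site selection with region labels |
| `biaslens.phylosignal` | Blomberg's K (GLS formulation), tip-shuffle permutation p-values, p-distance + neighbor-joining fallback tree |
| `biaslens.qpcr` | efficiency-corrected relative expression ratios from replicate Ct tables, multi-control normalization |
| `biaslens.synthetic` | seeded generators (Yule trees, BM/Mk traits, MSAs with exact planted column frequencies, toy structures with exact planted cluster distances, Ct tables with known ratios) |

## CLI

```sh
biaslens simulate --out bundle/ --seed 0          # synthetic data + truth tables
biaslens classify --fasta seqs.fasta --ref-fasta ref.fasta \
    --ref-annotation ligands.tsv                  # type + group report
biaslens conserve --msa aln.fasta --focal-a CpI --focal-b CpII \
    --out profile.tsv                             # conservation profile
biaslens pair --fasta pair.fasta --a CpI --b CpII # identity / similarity
biaslens sites --ref ref.pdb --model model.pdb --profile profile.tsv \
    --clusters clusters.tsv --cutoff 5.0          # ≤5 Å differing residues
biaslens signal --tree tree.nwk --msa aln.fasta --profile profile.tsv \
    --focal-a CpI --focal-b CpII --n-perm 999 --seed 17  # appends K and p
biaslens qpcr --ct ct.tsv --eff eff.tsv --target CpII --controls 16S,nifD
```

`clusters.tsv` maps HETATM records to named cluster groups
(`label  resname  chain  number`); the ligand annotation is
`cluster  position` (1-based residue indices of cysteines in the
reference). Both are user-supplied inputs, not built-ins.

## Conventions

- alignment columns and residue numbers are 1-based; intervals closed
- gap character `-` (`.` normalized on read); newick branch lengths required
- PDB subset: ATOM/HETATM/TER only, insertion codes rejected
- gap penalties: a gap of length L scores −(open) − (L−1)·(extend);
  defaults open 10, extend 0.5, matrix BLOSUM62
- qPCR amplification base is (1 + E) with E the fractional primer efficiency
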