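# odirasim

A sequence-level simulator of **origin-dependent inverted-repeat
amplification (ODIRA)** — a replication-error mechanism that produces
interstitial, inverted DNA triplications — together with the in-silico
molecular assays used to verify each intermediate.

## The problem

Interstitial inverted triplications (three tandem copies of a
chromosomal segment with the central copy inverted, and no loss of distal
sequence) are a recurrent class of copy-number variant in yeast
adaptation experiments and in human genomic disorders
(DUP-TRP/INV-DUP).  ODIRA explains them through a replication error at
pre-existing short **interrupted inverted repeats** (IIRs): two ~7 bp
reverse-complementary arms separated by a short spacer.  The steps:

1. **Closed forks.** A replication fork regressing at an IIR can ligate
   its nascent leading 3′ end to the nascent lagging 5′ end, sealing the
   fork shut.  If the two forks diverging from an origin both close, the
   nascent strands form a self-complementary loop that is expelled as a
   linear duplex capped by single-stranded hairpin loops — a **dog
   bone** — whose loops are the IIR spacers and whose duplex retains the
   origin-proximal arm of each repeat.
2. **Inverted dimeric plasmid.** Because the dog bone contains the
   origin, it replicates in the next cell cycle into a circular plasmid
   `U + σR + rc(U) + σL`: the unit and its reverse complement joined
   through the former loops, with quasi-palindromic head-to-head and
   tail-to-tail junctions.
3. **Integration.** Homologous integration of the circle back into the
   locus yields the triplication (n tandem plasmid copies give `2n + 1`
   unit copies — always odd).  The ancestral `arm·spacer·arm` string is
   preserved verbatim at every inverted junction.

A secondary rearrangement is also modeled: repeats that were inverted
relative to each other in the ancestor lie in **direct** orientation
across a junction after the inversion, so intramolecular homologous
recombination can delete one palindrome arm, producing the
DUP-TRP/INV-DUP copy-number staircase (1 → 2 → 3).  Single closed forks
yield isochromosomes (telomere-proximal) or acentric inverted fragments
(centromere-proximal).

The package is for researchers who want to generate these structures as
explicit sequences, predict their experimental signatures (restriction
maps, snap-back/S1 palindrome assays, indirect end-labeling, junction
PCR, aCGH-like copy-number profiles, split-read signatures), or build
test data for structural-variant callers.

## Worked example

Everything runs on synthetic fixtures — no external data.  Build the
curated amplicon-locus fixture (24 kb ancestor, one active origin, a
2,300 bp unit bounded by IIRs with 3 and 4 nt spacers), simulate, and
profile copy number:

```bash
odirasim fixtures --seed 7 -o fx
#   fixture: 24000 bp, unit (10850, 13150)
odirasim scan --fasta fx/ancestor.fa --bed-out hits.bed --stats-out stats.json
#   149 hits in 1 record(s)
odirasim simulate --fasta fx/ancestor.fa --origins fx/origins.bed \
    --max-span 4000 --seed 3 --secondary-deletion off -o sim
#   product fixture_trp3: 28542 bp, 2 junction(s)
odirasim assay cnprofile --segments sim/product.json \
    --ancestor-fasta fx/ancestor.fa --window 50 --bedgraph-out cn.bedGraph
#   windows: 480, plateaus: [1.0, 1.36, 3.0, 2.12, 1.0]
```

The simulator scanned 149 IIRs, picked a pair flanking the origin within
the 4 kb span, extruded a 2,237 bp dog bone (9 and 59 nt loops),
replicated it to a 4,542 bp circular dimer and integrated it: the
copy-number profile steps 1 → 3 → 1 over ancestor coordinates (the 1.36
and 2.12 windows straddle the amplicon edges).  With
`--secondary-deletion auto` a direct-repeat pair flanking a junction may
recombine, and the profile steps 1 → 2 → 3 instead.

The artificial-fork construct (two fold-back oligos that assemble into a
replication fork with an Okazaki-gap IIR) is exercised the same way:

```bash
odirasim design-fork --seed 1 -o oligos
odirasim fork-assay --leading oligos/leading.fa --lagging oligos/lagging.fa \
    --report fork.json
```

```json
{"migratable_homology": 25, "n_states": 26, "paired_bases": 86,
 "n_ligatable": 12, "pcr_products_unligated": [],
 "junction_context": "GTCGCGTGCCTCGAGCAGGA",
 "pcr_products_ligated": [81], "xhoi_fragments": [47, 34]}
```

The fork has 25 bases of migratable homology (arm + spacer + arm =
7 + 11 + 7), every branch-migration state has the same number of paired
bases, PCR across the fork gives **no** product without ligation, and the
ligated molecule gives a single product cleaved by XhoI at the completed
junction site.

Coordinates in all emitted files are 0-based, half-open, top-strand.
Origins BED uses column 4 for the name and column 5 for an
`active`/`inactive` flag (anything other than `inactive` is active).

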