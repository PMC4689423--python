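# Methods

This note documents the model conventions, parameters, numerical choices
and limitations of `odirasim`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Repeat scanning (`irscan`)

An interrupted inverted repeat (IIR) at position *i* with spacer *s* and
arm length *a* satisfies `seq[i : i+a] == rc(seq[i+a+s : i+2a+s])` with
at most `max_mismatches` differences.  Defaults: `a = 7`,
`s ∈ [1, 69]` ("spacing of less than 70 bp" read as spacer length, with
spacer ≥ 1 because an *interrupted* repeat needs one), `0` mismatches.
Both bounds and the mismatch tolerance are parameters because the
published density estimate does not state them.

Every `(position, spacer)` combination is counted; overlapping and
nested hits are all reported.  Rationale: each arm pair independently
licenses a closed-fork event, and this convention gives the closed-form
density on uniform random sequence

    rate = S · 4⁻ᵃ per bp   (S = number of admissible spacers),

i.e. one hit per `4⁷/69 ≈ 237` bp for the defaults — the genome-wide
"about every 240 bp" figure.  The acceptance band (±10%, and hit count
within 3 standard errors of `n·S·4⁻ᵃ` using the binomial SE) treats the
weak dependence between overlapping windows as negligible, which holds
at 1 Mb.  N bases poison every window they fall in.  The scanner is
vectorized over positions per (spacer, arm-offset) pair; a brute-force
double-loop oracle checks exact equality on small inputs.

## Fork model (`fork_model`)

The artificial fork is assembled from two fold-back oligos (defaults
reproduce the published architecture: 100 and 99 nt, 30 nt complementary
tails, a 7 + 11 + 7 repeat behind the fork, an XhoI site split across
the nascent termini, HaeIII/NcoI sites in the parental tail duplex).
Geometry is annotated per oligo (template, tail, linker, nascent, gap),
so user-supplied oligos work as long as the annotations are present.

Branch migration is combinatorial, not thermodynamic: state *r* ∈
[0, R] re-anneals *r* parental bases and displaces *r* nascent leading
bases, where R is the length of the parental homology across the repeat
region (the longest common suffix of the nascent leading strand and the
gap).  The displaced bases and the single-stranded gap always form the
maximal repeat-arm stem, so every state has an identical paired-base
count (asserted, not assumed).  Because both extremes are counted, a
fork with R bases of homology has R + 1 states.

A state is *ligatable* when the lagging oligo carries a 5′-phosphate and
the whole displaced repeat arm is annealed onto the single-stranded
template copy of the repeat, which places the leading 3′-OH on the
template helix directly beside the lagging 5′-P (zero-gap nick; ligase
never fills gaps).  Several regression depths satisfy this; all yield
the same covalent product, the concatenation of the two oligos.  Linker
loops are unpaired and uncleavable.

PCR primers default to 16 nt with their 3′ ends in the linkers
(linker length 8), so a ≥15 nt primer fits; product and junction-digest
sizes are computed from the design at run time rather than asserted as
constants, because they are construct-specific.

## Amplification engine (`engine`)

Fold-point convention: a closed fork folds immediately after the
origin-proximal arm of its repeat.  The amplified unit U therefore runs
from the left IIR's right arm through the right IIR's left arm, and the
spacers become the hairpin loops.  This is the only rendering in which
the ancestral `arm·spacer·arm` string appears verbatim at every
inverted junction (`… U-end(=arm) σR rc(arm) …`), which the products
guarantee as an invariant.  Where the physical strand transition falls
*within* the spacer is not determined by junction sequences; the
convention is a documented rendering choice, not a mechanistic claim.

Replication and recombination are mutation-free.  Integration requires
the unit to occur exactly once in the host (no-homology and
multiple-homology cases are refused), inserts `n_copies` tandem circle
copies for `2n+1` unit copies, and is independent of the crossover
position because homology is exact — asserted as a property.  Products
are ordered lists of ancestral segments (strand-annotated) plus inserted
loop texts; rendering is lossless, and every novel adjacency carries a
junction record including a minimal product window absent from either
ancestor strand (used by the split-read labeler).

Direct-repeat discovery for the secondary rearrangement searches the two
palindrome arms around each inverted junction (their maximal
reverse-complementary extent), not the distal flanks; arm deletion
splices the piece list between the two copies, shortening the product by
exactly their separation and producing the 1→2→3 staircase over
ancestor coordinates.

The end-to-end driver draws the substrate pair, crossover and optional
deletion from `numpy.random.default_rng(seed)`; identical seeds give
byte-identical products.  Absence of a licensed substrate (no active
origin with flanking repeats in span) is an explicit outcome, not an
error.  Origin licensing is binary: inactive origins (the
origin-deletion analogue) never license extrusion.

## Assays (`assays`)

*Restriction digestion* recognizes sites (IUPAC, both strands) in duplex
regions only; single-stranded hairpin loops are immune, so dog-bone end
fragments keep their loops (total nucleotides `2·duplex + loop`, the
slight gel up-shift) and remain covalently closed when uncut.  Cut
coordinates are the top-strand offsets; fragment concatenation restores
the parent (rotation for circles).  Sizes are exact bp; no gel-mobility
model ("~" gel sizes are compared at 2 significant figures).

*Snap-back/S1* finds the maximal intramolecular stem
`t[a:a+k] == rc(t[b:b+k])` with an unpaired central loop (`b−a−k ≥ 0`)
and unpaired terminal overhangs, via binary search over k with rolling
hashes (O(n log n), verified matches only) — equivalent to the
quadratic center-enumeration oracle used in tests.  S1 removes loop and
overhangs: `s1_resistant_len = stem`, and for a palindrome with loop ℓ,
`stem = (L−ℓ)/2`.  Fold-back is intramolecular-first (infinite-dilution
approximation of boil/quick-cool); strands whose best stem is below
`min_duplex` (default 30 bp, far above the ~10 bp chance stems of
random kb-scale fragments) are reported non-foldback and S1-degraded.

*PCR* requires perfect-match annealing of ≥15 nt primers in convergent
orientation on one covalently continuous strand within `max_product` —
which is what makes the assay ligase-dependent on fork assemblies.
Quasi-palindromic templates can emit mirror-image products, as real PCR
does.

*Copy number* is the per-base count of derived segments over ancestor
coordinates, averaged in windows; *indirect end-labeling* reports
probe-containing fragment sizes in anchor + second-enzyme double
digests; *split reads* are tiled across the product and labeled `split`
when they fully cover a junction's minimal novel window, `flank` when
they touch none.

## Synthetic fixtures (`synthetic`)

The curated fixture emulates a selectable amplicon locus: 24 kb, GC
0.38 (yeast-like), a 2,300 bp unit centered on an active 150 bp origin,
IIRs with 3 and 4 nt spacers at the unit bounds, a planted inverted
12-mer word pair inside the unit (the future direct-repeat substrate),
and one blunt palindromic EcoRV site 1,348 bp from the unit end so the
inverted-dimer junction fragment digests to exactly
2·1348 + 4 = 2,700 bp and snaps back to a 1,348 bp (1.35 kb) duplex.
The unit size makes the replicated circle 4,607 bp (~4.6 kb).

The background is scrubbed to keep oracles unambiguous: stray copies of
the planted site, duplicate 15-mers genome-wide (direct or inverted)
and inverted duplicate 12-mers within the unit (including
self-palindromic 12-mers) are re-rolled, planted features excepted.
Hairpin loops shorter than 17 nt — the smallest loop observed in stably
inherited junctions — set a boolean `small_loop` warning; no instability
dynamics are simulated because no rate is available.

What the fixtures do **not** emulate: repeat families (Ty/LTR/tRNA),
replication timing, chromatin, selection.  Passing tests therefore show
the mechanism's sequence-level bookkeeping is correct, not that real
genomes lack confounding homologies.

## Problem sizes

The test suite runs on 1.5–50 kb fixtures (oracle comparisons), a
200 kb density check, and one 1 Mb scan in the acceptance path; the
acceptance script uses 1 Mb.  The suite completes in a few seconds on
one CPU.

## Known limitations

* Branch migration is isoenergetic bookkeeping; no ΔG, no kinetics.
* Ligation is nick-only; microhomology slippage and replication errors
  are not modeled.
* Mixed direct/inverted higher-order integrations are out of scope
  (tandem `n_copies` only); sequential re-integration is
  indistinguishable at the copy-number level and is not simulated
  separately.
* Centromere/telomere function is presence/absence of annotated
  intervals; no segregation model.
* Gel electrophoresis, probe thermodynamics and microarray noise are not
  simulated; assays report exact sizes.
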