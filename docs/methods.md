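# Methods

This note records the models, algorithmic conventions and design
choices behind `strainsort`, in the order the pipeline runs them.

## Marker-gene clustering

Pairwise strain similarity is percent identity of an optimal global
alignment (Needleman–Wunsch with affine gaps; defaults match +1,
mismatch −1, gap open −2, gap extend −0.5). Two conventions matter and
are fixed deliberately:

* **Terminal gap columns are excluded from the identity denominator.**
  Marker amplicons differ in trimmed length; counting terminal gaps
  would conflate read length with divergence.
* **Ties are resolved deterministically**: the reported alignment is
  reconstructed front-to-back, preferring diagonal, then up, then left
  whenever co-optimal continuations exist. `N` never counts as a match
  anywhere in the package.

OTUs are built by agglomerative clustering on similarity, merging the
best pair while its linkage similarity stays at or above the threshold
(default ≥ 98%). Complete linkage is the default because it is the
strictest reading of an identity-threshold OTU definition — every
within-OTU pair is guaranteed to meet the threshold; single and average
linkage are available. Merge ties go to the lexicographically smallest
member pair, making the partition independent of input order. Because
the merge sequence does not depend on the threshold, raising the
threshold always refines the partition. OTU labels are assigned by
decreasing cluster size (OTU1, OTU2, …; ties by smallest member id);
singletons are labelled `ST`. The numbering is this package's
convention — thresholds define the partition, not the names.

Trees are Saitou–Nei neighbor joining on d = (100 − identity)/100, with
Q-matrix ties broken by the smallest label pair and negative branch
lengths clamped to zero with the deficit moved to the sibling edge
(their sum, hence all patristic distances, is preserved). On additive
matrices NJ is exact, which the test suite exploits as an oracle.
Bootstrap supports resample alignment columns with replacement
(seeded), rebuild the tree per replicate from p-distances, and report
the percentage of replicates containing each reference bipartition.

The bundled multiple aligner is progressive: a UPGMA guide tree from
pairwise global-alignment distances, profiles merged by aligning their
consensus sequences and propagating the gap pattern to all members.
This is adequate for near-identical marker genes, which is the scope
here; externally produced alignments are accepted anywhere an alignment
is consumed.

## Whole-genome similarity

**ANI** follows the orthologous-fragment scheme: each genome is cut
into consecutive 1020-bp windows (sub-length remainders discarded);
fragments are matched both ways with a seeded local aligner (exact
15-mer seeds, diagonal anchoring, gapped refinement of the anchored
region); hits below 35% identity or 70% query coverage are discarded;
and ANI is the mean identity of reciprocal best-hit fragment pairs,
each pair contributing the mean of its two directional identities.
Genome order is canonicalized internally, so ANI is exactly symmetric,
and a comparison with no RBH pairs raises an explicit undefined-result
error rather than returning 0.

Two estimator details guard against subtle bias in identity. First,
the anchored region extends beyond the outermost seeds by an X-drop
walk along the diagonal (match +1 / mismatch −1, X = 40; if the walk
reaches the sequence end without dropping, every column to the end is
included). Seeds survive preferentially in match-rich stretches, so
measuring identity only on the seed-delimited span would overestimate
it; through genuinely homologous sequence the walk reaches the ends
almost surely (ruin probability < 10⁻²⁰ at ANI ≥ 85%), so all
overlapping columns are counted, while at a homology boundary — e.g. a
fragment whose register is shifted by an indel elsewhere in the genome
— it stops within ~2X columns and the partial overlap fails the
coverage filter instead of absorbing unrelated tails. Second, because
the gapped refiner minimizes unit-cost edits (a gap as cheap as a
mismatch, letting gap pairs bypass mismatch clusters), the plain
ungapped diagonal alignment is kept whenever it scores at least as well
under the declared match +1 / mismatch −1 / gap −2 scoring. With both
in place the measured (100 − ANI)/100 tracks the Jukes–Cantor
expectation within the binomial sampling error of the aligned columns,
with no detectable estimator bias beyond the simulation draws.

**dDDH** uses the genome-distance route: HSPs are collected
genome-vs-genome as ungapped diagonal segments (seed runs extended with
an X-drop rule, match +1 / mismatch −1, X = 30), then greedily accepted
by descending score with any overlap against previously accepted HSPs
trimmed on both genomes (the longest remaining run is kept and its
matches recounted exactly from the sequences); segments scoring below
60 after trimming are dropped. Ungapped segments are exact under the
substitution-only synthetic model this package validates against, and
genome rearrangements or indels simply split segments across diagonals.
The formula-2 distance is d = 1 − Σidentities / ΣHSP-length, converted
to the DDH scale by a logistic model, logit(dDDH/100) = a + b·ln d.

The bundled coefficient set `ggdc2-logitlog-synthetic-v1`
(a = −3.2576, b = −1.2522) is **synthetic**: it was least-squares
calibrated against publicly reported paired (ANI, dDDH) values for
*Pseudomonas* genome comparisons, approximating d by (100 − ANI)/100.
It reproduces each calibration pair within ~1.3 points and places the
conventional 70% boundary at d = 0.0377 (ANI ≈ 96.2), consistent with
the field's rule of thumb. The coefficients live in a versioned data
file and can be overridden for sensitivity analyses; the species call
itself consumes plain ANI/dDDH percentages, so published values can be
classified directly without the transform.

**Species rule**: same species ⇔ ANI ≥ 95% AND dDDH ≥ 70%, both bounds
inclusive.

## Diagnostic-gene screen

Orthology is reciprocal best hits on proteins (BLOSUM62 local
alignment, gap open −11 / extend −1; candidates prefiltered by a shared
amino-acid 5-mer; an equal-best-score tie yields no hit; pairs must
reach 30% identity and 50% coverage of the shorter protein), and
orthogroups are connected components of the union RBH graph over all
genome pairs. This replaces graph-clustering orthology inference — a
deliberate simplification that is exact for the near-clonal in-groups
this screen targets, and every gene ends up in exactly one group.

The screen keeps groups with a member in **every** in-group genome and
none in **any** out-group genome, where the in-group is defined by the
genome-similarity calls, not by OTU membership (marker OTUs can contain
strains that fail the whole-genome criterion). Candidates are then
re-verified by direct nucleotide search (seeded local alignment,
present ⇔ best hit ≥ 80% identity covering ≥ 80% of the candidate):
a candidate survives only if present in all same-species genomes and
absent from all others. The two-stage design means an orthogroup
fragmented by a missed RBH edge cannot produce a false diagnostic gene
— the sequence search finds the homolog the graph missed.

## Primer design and in-silico PCR

Primer windows are restricted to columns 100% conserved across the
in-group homolog alignment, so designed primers match every target
strain exactly. Constraints (all configurable): length 18–28, GC
0.40–0.60, pair ΔTm ≤ 5 °C, product 150–700 bp, self-complementary run
≤ 6 (longest common substring with the primer's own reverse
complement). Tm is nearest-neighbor thermodynamics (SantaLucia unified
table via Biopython) at 50 mM Na⁺ / 500 nM primer; the Wallace 2(A+T) +
4(G+C) rule is available. One window is kept per start position (the
length with Tm closest to 60 °C) to keep pair enumeration tractable;
pairs are ranked by mate Tm match, then product length closest to the
middle of the allowed range — a deterministic order.

In-silico PCR is pure sequence matching: a site is a primer footprint
with at most `max_mismatch` mismatches (default 1) and zero mismatches
in the 3′-terminal `require_exact_3prime` bases (default 3); every
inward-facing forward/reverse site pair within the product window is
reported, in both orientations, with the product length counting both
footprints. Amplification thermodynamics and single-primer (F–F/R–R)
artifacts are out of scope; multi-product genomes are flagged rather
than collapsed.

## Synthetic panels

The generator builds one ancestor genome — i.i.d. background at the
target GC with non-overlapping codon-structured gene loci (ATG +
non-stop codons + stop), two marker loci and one planted diagnostic
gene — and evolves each strain independently under Jukes–Cantor
substitution: every site mutates with probability
p(t) = ¾(1 − e^(−4t/3)) to a uniformly chosen alternative. This
discrete per-branch scheme composes exactly — two lineages evolved t₁
and t₂ from the ancestor differ like one path of length t₁ + t₂ — so
the closed form is an exact oracle, not an approximation. The planted
gene is deleted cleanly from every out-group genome with downstream
coordinates shifted.

Defaults are chosen to emulate a culture-collection reclassification
panel at desk scale: 4 in-group strains at t = 0.01 (pairwise identity
≈ 98%, safely inside the species boundary), 10 out-group strains at
t = 0.08 (≈ 91.5%, safely outside), 200-kb single-contig genomes
(full-size bacterial genomes would only slow the same computation), GC
0.62 as in pseudomonads, 40 × 900-bp core genes, a 1500-bp 16S-like and
a 760-bp rpoD-like marker, and a 639-bp planted diagnostic gene.
Everything is a pure function of (config, seed).

Indels default to off. When enabled they have geometric lengths
(mean 3 bp) and are restricted to unannotated background — never inside
gene or marker loci — which keeps annotations exact and the planted-gene
truth clean. What the simulator deliberately does **not** model:
rearrangements, horizontal transfer, gene duplication, assembly
fragmentation and base-calling error. Passing tests therefore
demonstrate correctness of the method stack under controlled
divergence, not robustness to every artifact of real draft genomes; the
parameter defaults (fragment thresholds, presence cutoffs, PCR
mismatch budget) are the knobs a user would revisit on real data.

## Numerical and degenerate-input conventions

* Identity/score ties everywhere break lexicographically (smallest
  subject id, smallest label pair, smallest coordinate) — all outputs
  are order-independent and byte-reproducible for a fixed seed.
* Undefined statistics (no RBH pairs, no HSPs) raise typed errors; they
  are never reported as 0.
* dDDH at d = 0 is returned as exactly 100; the logistic applies for
  d > 0.
* Coordinates are 1-based inclusive externally (GFF convention);
  conversion to Python half-open slices happens in one place.
* Sub-fragment-length contigs contribute no ANI fragments; a genome
  with none raises the undefined-ANI error.

## Problem sizes used in validation

The shipped test suite runs the alignment oracle on 1000 random pairs
(length ≤ 12), NJ recovery on 50 random 5–8-leaf additive matrices, ANI
self/symmetry and Jukes–Cantor recovery on 200-kb simulated genomes,
the full end-to-end study on five seeds of the default 14-strain panel,
and the in-silico PCR oracle on 1000 constructed templates. These sizes
keep the whole suite in the tens of minutes on one core while leaving
every statistical check with comfortable margins (3 SE bounds on ≥ 10⁵
aligned columns).
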