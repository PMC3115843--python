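# Methods

This note records the models, conventions and design choices behind each
module, in enough detail to reproduce or audit any number the package
prints.

## Coordinates and alignment conventions

All variant positions are 1-based on a designated reference taxon of the
multiple alignment; insertions relative to the reference anchor to the
preceding reference base (position 0 for insertions before the first base).
Alignment construction itself is out of scope — the alignment is an input.

Substitution and indel variation are counted separately:

* a **substitution record** is an alignment column with no gaps and at
  least two distinct bases among non-`N` rows; columns containing any gap
  are excluded from substitution counting, both globally and pairwise
  (pairwise counts use the pair's mutually ungapped, non-`N` columns);
* an **indel event** is a maximal run of gap-containing columns sharing one
  presence/absence pattern across taxa; adjacent runs with different
  patterns are distinct events;
* every column therefore falls in exactly one of
  {invariant, substitution, gap-involved}, and the three counts sum to the
  alignment length (tested).

A site is **parsimony-informative** iff at least two states are each
carried by at least two taxa.  Multi-allelic columns count once per column
in totals; pairwise counts count each differing pair.  Columns in the
inverted repeat are counted as they appear; no IR deduplication is done.

## Indel classes

Indel events are classified in this order:

1. `ssr_motif` — the event lies inside an annotated SSR tract and its
   length is a multiple of the motif length (a repeat-count step);
2. `long` — length > 12 bp (the diagnostic 225/342-bp deletions fall here);
3. `repeated_motif_7_12` — length 7–12 bp and the indel block equals the
   immediately adjacent upstream or downstream block (a tandem duplication
   of one or two motif copies);
4. `other_short` — everything else ≤ 12 bp.

## SSR detection

Maximal, non-overlapping tracts of a primitive motif (1–6 bp, not itself a
repeat), scanning left to right and preferring the longest tract (ties to
the shorter motif).  Default minimum repeat counts: mono ≥ 8, di ≥ 5,
tri–hexa ≥ 4; these are configurable — no canonical thresholds exist for
plastome SSR surveys, and these defaults keep random 150-kb background
sequence essentially tract-free while catching every marker-grade tract.
Per-taxon repeat counts are read through the alignment over the tract's
column range, widened to adjacent reference-gap columns so expansions in
non-reference taxa are counted.

## Divergence and substitution rate

Percent divergence is `100·k/L` at two decimals.  The substitution rate is
`(k/L)/T` per site per year, reported at two significant figures.  Note the
convention: total pairwise divergence is divided by the divergence time
`T`, not `2T`; this is the convention under which the published olive
bounds (1.2×10⁻¹⁰ at 417/155,896 bp over 22 My; 2.0×10⁻¹⁰ at
432/155,531 bp over 14 My) are reproduced, and it is stated here so the
numbers are interpretable.

Coding effect is classified by translating the containing codon in the
annotated frame and strand for each observed state (standard code);
positions outside any interval are non-coding.

## Marker typing

Fragment sizes are binned to the nearest integer bp, ties rounding half up;
calls more than 1 bp (configurable) outside the locus size range are
flagged off-ladder.  Sizes convert to repeat counts through a per-locus
anchor (`count = anchor_count + (size − anchor_size)/motif_length`); a
non-integer quotient is an inconsistency error, not silently rounded.  The
binning rule is fixed here because sizing software applies its own opaque
binning; reproducibility requires one stated convention.

The two gel-scored long-deletion loci (8 and 61) are binary
presence/absence calls, never sizes.  CAPS loci are cut/uncut.  Primer
sequences and PCR chemistry are opaque metadata with no computational role.

**Multiplex design** is greedy interval-graph coloring: loci sorted by
ascending size-range start are first-fit packed onto dye tracks (one track
per dye, ranges pairwise disjoint within a track), and each track is split
into groups of at most six loci.  The result is always valid and
deterministic; optimality is not claimed.  Because loci are sorted
internally, input order cannot produce an invalid assignment (tested over
all permutations of a six-locus panel).  The packaged default panel
reproduces the published six multiplexes (35 loci over three dyes) plus the
separately amplified locus 10 — the recommended 36-locus rapid set — and
the gel/CAPS loci.  Loci whose size ranges are not published are marked
range-unknown and routed to standalone amplification rather than pooled.

## Haplotype calling and diversity

Individuals with identical complete profiles share a haplotype.  An
individual with missing calls is matched to an existing catalogued profile
only when exactly one profile is consistent with its non-missing calls;
otherwise it is unassigned (the conservative choice — a permissive nearest
match would manufacture haplotype frequency).  Individuals missing more
than half their calls are never matched.

Names are a lineage prefix plus ordinal.  The prefix comes from the first
matching lineage-diagnostic rule (e.g. the 342-bp *ycf1* deletion ⇒ E3, the
225-bp deletion ⇒ the South-Asian C lineages); profiles matching no rule
get prefix `U`.  Ordinals are assigned by descending observed frequency at
catalog build time and are frozen once a catalog is written to JSON, so
re-runs with added samples never rename published haplotypes.

`D = 1 − Σ pᵢ²` uses plug-in frequencies exactly as printed — no
`n/(n−1)` correction.  Pooled `D` is always computed from pooled counts,
never by averaging group values.  Sample-size reconstruction from printed
percentage tables searches for the smallest n under which every percentage
is within printing precision (±0.05) of an integer count; a column whose
rounded counts cannot sum to n (one such typo exists in the bundled wild
population table, which prints to 104.9%) is repaired by adjusting the
single count with the largest rounding deviation, ties toward the last row.
The repaired column changes pooled `D` by less than 0.001 under either tie
choice.

## Character coding and the reduced-median network

Coding follows the single-step mutation convention for plastid SSRs:

* SSR loci → **ordered** characters whose states are repeat counts (one
  mutation = ±1 repeat);
* other indels → **binary** presence/absence;
* loci combining an indel with an SSR emit one character of each kind;
* CAPS loci are excluded by default — they are homoplastic at the lineage
  level — so haplotype pairs distinguished only by CAPS merge into one
  network node; an option includes them as binary.

Ordered characters are expanded into ladders of cumulative threshold
indicators (`state ≥ t` for each unit step between the observed minimum and
maximum), each inheriting the original weight.  This preserves pairwise
distances exactly (Hamming distance on the expansion = summed absolute
state difference), which is the property that justifies running a binary
network construction on ordered data; non-distance-preserving encodings
were rejected.

The network construction:

1. condense binary columns identical up to complementation (same split of
   the haplotypes); weights add, character labels merge;
2. **reduction**: for each incompatible character pair (all four gametes
   present), compare frequency-weighted supports
   `s(c) = w_c · min(freq of 0-class, freq of 1-class)`; if one character's
   support is at least `r` times the other's (default `r = 2`, exposed as
   an option), the weaker character is treated as two independent mutations
   — it is split into two sub-characters partitioned by the stronger
   character — instead of generating reticulation medians; iterate to
   fixpoint;
3. **median closure**: repeatedly add the coordinatewise majority median of
   every node triple until no new vector appears;
4. nodes differing in exactly one condensed character are joined; inferred
   medians carry zero frequency; node and triple processing order is fixed
   by (descending frequency, lexicographic id), making the output
   deterministic.

On homoplasy-free data no pair is incompatible, the closure is exactly the
perfect phylogeny's node set, and the distance-1 edges are its edge set —
verified exhaustively against a planted-tree oracle for up to 8 haplotypes
× 12 characters.  Because the reduction criterion is a ratio, rescaling all
weights by a positive constant cannot change the topology (tested).  The
exact reduction procedure of the original network software is not published;
this construction is this package's own, chosen to be deterministic and to
agree with the published behaviour on the properties that can be checked.

## Parsimony

Fitch small-parsimony with gaps and `N` as fully missing (unconstrained
state sets).  Tree search is exact: all (2n−5)!! unrooted binary topologies
are enumerated by stepwise addition for 3–10 taxa (10,395 trees at n = 8);
more taxa are refused rather than searched heuristically.  The full optimal
set is retained; the strict consensus keeps splits present in every optimal
tree, with splits canonicalized against the lexicographically smallest
taxon so rerooted topologies compare equal.  Bootstrap resamples sites with
replacement and counts each split's presence in the replicate's strict
consensus — ties therefore propagate as unresolved support, never as votes
for one resolution.  Rooting places the root on the outgroup's pendant
edge.  Fitch is validated against an independent unit-cost Sankoff dynamic
program on every topology of random ≤6-taxon matrices.

## Synthetic data generator

The generator emulates the study system at desk scale: plastome-like root
sequences (default 2–20 kb; the full 155 kb runs but is not the test
default) with planted SSR tracts, evolved along a known genealogy under

* per-site substitutions (Poisson per branch, default 1–2×10⁻³ per site
  per branch-length unit — enough divergence to exercise every scanner
  path at a few kb while staying far below saturation, qualitatively
  matching a slowly evolving plastome),
* single-step SSR mutations (±1 repeat; at most one step per locus per
  simulation),
* indels from a mixture of 7–12-bp tandem motif duplications, other short
  (≤6 bp) deletions, and long deletions at designated sites with the
  diagnostic 225/342-bp lengths.

The substitution/indel/SSR rates are testability choices, not biological
calibration — no within-lineage mutation parameters are published for this
system.  Mutation events are globally non-overlapping by rejection
sampling, and indels avoid planted SSR tracts unless the event is the
tract's own step; this keeps every truth event recoverable from the
projected alignment (recall = precision = 1 on noiseless output, tested)
at the price of slightly repelling events at high rates.  Accidental
background tracts meeting the detection thresholds are broken at build
time, and tract flanks are pinned so a planted (T)₁₂ is detected as
exactly 12 repeats.  Alignment projection allocates one column block per
root position, padded to the widest cell, so the column count equals root
length plus total inserted bases (tested).

Population genotype tables are drawn i.i.d. from specified haplotype
frequencies; noise is limited to ±1-bp pre-binning mis-sizing and missing
cells at configurable rates.  What this does **not** emulate: PCR stutter,
allele dropout correlated within runs, null alleles, contamination, or
heteroplasmy — so passing tests demonstrate correctness of the analysis
chain, not robustness to every laboratory artifact.

Randomness: one integer seed fans out through `numpy` SeedSequence
spawning in fixed stream order (0 root sequence, 1 branch events in
pre-order, 2 population sampling, 3 noise), so equal seeds give
byte-identical FASTA/TSV artifacts.

## Problem sizes used in the test suite

Simulated genomes are 1–6 kb with 3–4 SSR loci and seven-leaf genealogies;
population draws are 200–10,000 individuals; bootstrap examples use 5–100
replicates on ≤8-taxon matrices; the exhaustive network oracle covers ≤8
haplotypes × ≤12 characters.  These sizes are the package's chosen
desk-scale defaults; every algorithm runs unchanged at full scale
(155-kb genomes, 10,000 bootstrap replicates) in minutes.

## Known limitations

* The exhaustive tree search is exact but exponential; it refuses > 10
  taxa by design rather than pretending to search heuristically.
* The reduced-median reduction is a documented reimplementation choice;
  on strongly conflicting data its median set may differ from other
  implementations even though observed haplotypes, connectivity and the
  compatible-data behaviour are guaranteed.
* Haplotype frequency reconstruction from printed percentages is exact
  only when each percentage was printed to one decimal from an integer
  count; coarser printing would make n non-identifiable.
* The genome scanner assumes a trustworthy input alignment; misalignment
  artifacts are reported as variation.
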