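# Methods

## Scope and model

`plastotype` analyses the structure of annotated circular plastid genomes
(plastomes). The canonical land-plant plastome is a quadripartite circle: a
large single-copy region (LSC) and a small single-copy region (SSC)
separated by two near-identical inverted-repeat arms (IRa, IRb), with four
junctions named JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa) and JLA
(IRa|LSC). Evolutionary expansion and contraction of the IR boundaries, SSC
insertions, and outright IR loss produce a small set of discrete structural
types. The package detects the IR pair, partitions the genome, profiles the
marker genes that diagnose boundary shifts (rpl2, rpl23, trnI-CAU, ycf2,
plus the SSC anchors trnL-UAG and ccsA), classifies each genome into one of
six types, mines repeats and SSRs under the standard plastome thresholds,
and computes descriptive whole-genome similarity and per-region variability
statistics. Everything is testable offline against a synthetic plastome
generator that emits miniature genomes with exhaustive ground truth.

Coordinates are 0-based half-open internally; GenBank I/O converts to and
from 1-based inclusive at the file boundary. Features that span the
circular origin are stored as a single exon with a `wraps` flag rather than
split, so one gene is always one feature. Ambiguity codes other than N are
normalised to N on read (with a logged count); N never matches anything and
is excluded from GC numerators and denominators.

## IR detection and partitioning

`find_inverted_repeat` seeds exact k-mer matches (default k = 25) between
the doubled sequence and the reverse complement, groups seeds on
anti-diagonals (the quantity `i + p2` is constant along an inverted pair),
splits each anti-diagonal's seeds into the two mirror-image clusters that
an arm pair produces, and extends each cluster's match core outward.
Extension is greedy on exact matches; an interior mismatch run is absorbed
only when it is at most 3 bp long, the following 10 positions contain at
least 8 matches, and the running identity stays above `min_identity`
(default 0.995). This policy tolerates the small arm asymmetries of real
records while guaranteeing that exactly complementary arms are recovered
with exact endpoints whenever the flanking bases do not pair — which the
generator enforces (see below). The defaults `min_len = 1000` and the
doubled-sequence search are chosen so that real IRs (19–26 kb) are always
found, IR-lost genomes cleanly return "absent", ordinary dispersed repeats
(≤ a few hundred bp) are ignored, and origin-spanning arms need no special
casing. Ties on candidate length break toward the smallest start offset.

`partition` labels the longer inter-arm gap LSC and the shorter SSC; the
arm first encountered walking forward from the LSC is IRb. The partition is
asserted to tile the circle exactly on every call. IR-absent genomes get a
degenerate partition (whole genome as LSC, no junctions).

## Structural typing

`profile_markers` assigns each marker copy to the region containing its
feature midpoint, so junction-straddling genes (rps19, ycf1, the complete
ycf2) receive one unambiguous label. ycf2 copies shorter than 80% of the
longest copy are flagged truncated; the published truncated remnants and
complete copies are separated by a wide margin, so the exact cutoff is not
critical. The SSC insertion is the ordered list of genes lying entirely
between the 3' end of trnL-UAG and the 5' start of ccsA; if either anchor
is missing the insertion is flagged undefined rather than treated as empty.

`classify_type` evaluates a fixed decision table in the order VI, I, II,
III, IV, V:

* **VI** — no IR detected (Cassytha-like).
* **I** — rpl2, rpl23 and trnI-CAU each have one copy per arm and at least
  two complete ycf2 copies (the ancestral layout).
* **II** — rpl2 single-copy while rpl23 and trnI-CAU remain duplicated
  (IRb boundary contraction). That rpl23/trnI-CAU stay duplicated is read
  from the published type diagrams rather than stated in prose; the rule
  records this inference.
* **III** — all three markers single-copy, exactly one complete plus one
  truncated ycf2, empty SSC insertion.
* **IV** — as III with a second trnI-CAU inside the SSC insertion.
* **V** — as IV plus a pseudogene-flagged rpl23 in the insertion.

Profiles matching no row return UNKNOWN with the violated rules listed,
never an exception and never a forced nearest type: real genera are known
to show within-genus type reversals, so novel profiles must surface.

`detect_pseudogene` aligns query to reference globally (Bio.Align
PairwiseAligner, match 1 / mismatch −1 / open −2 / extend −0.5), takes
identity as identical columns over all alignment columns, counts internal
stop codons from a frame-0 translation under the plastid/bacterial code
(table 11), and flags a frameshift when any indel run length is not a
multiple of 3. A copy is pseudo iff identity ≥ 0.90 (homology gate, keeping
distant paralogs out) and it has at least one internal stop or a
frameshift. Because the function receives plain strings, it auto-orients:
if the reference does not look like a coding-strand ORF, both sequences are
reverse-complemented first — this makes the call strand-consistent.

## Repeat mining

**SSRs** are maximal perfect tandem arrays with unit length 1–6 and copy
minima 10/6/5/5/5/5. Arrays are found per unit length from maximal
`s[i] == s[i−u]` runs, trimmed to whole copies, reported only at their
smallest period (a unit that is itself periodic is rejected), with motifs
standardised to the lexicographically minimal rotation. Runs break at N.
Compound or interrupted SSRs are not merged — only the length thresholds
are part of the published convention.

**Dispersed repeats** (direct and palindromic pairs, ≥ 30 bp, Hamming
distance ≤ 3, no indels) are defined as inclusion-maximal windows along a
(anti-)diagonal, trimmed so first and last columns match. Every qualifying
window must contain an exact run of at least ⌈(30−3)/4⌉ = 7 bp
(pigeonhole), so exact 7-mer seeding loses nothing. Each seed is extended
to its full exact run; collecting `max_mismatch + 1` mismatch positions
beyond each run end enumerates every maximal window intersecting the run
(left/right bound combinations `i + j = max_mismatch`). The unit tests
check exact set equality against a full all-diagonals enumeration oracle.
By default the IRa/IRb arm self-match, and any hit whose two intervals lie
in opposite arms (≥ 90% containment), are removed from the tables: without
this filter every IR-bearing genome's "longest repeat" would be the ~20 kb
arm itself. Circular sequences are scanned on the doubled string with
coordinates normalised modulo L.

**Tandem repeats** (unit ≥ 7 bp, ≥ 1.9 copies, consensus match fraction
≥ 0.80) use lag-p autocorrelation to propose candidate periods, anchor each
candidate at its autocorrelation maximum so copy rows are phase-aligned,
grow whole copies while they match the majority consensus at ≥ 0.70, and
accept on the final consensus match fraction. This is a deliberate
simplification of the classic tandem-repeat-finder scoring (2 7 7 80 10 50
500); it is validated by planted-array recovery (≥ 95% of corrupted planted
arrays recovered at the correct period), not by output equality with that
program. Two-copy arrays near the acceptance boundary can produce spurious
low-complexity reports in random sequence; consumers should treat 2-copy
hits at match fractions near 0.8 with caution.

## Comparative statistics

`pairwise_identity` is matching columns over total alignment columns from a
global unit-cost alignment (edlib), with gap columns counting in the
denominator — the simplest defensible convention for untrimmed
whole-genome comparisons. Two tie-breaks make it well-behaved: arguments
are put in canonical order (identity is symmetric by construction), and for
equal-length inputs whose Hamming distance equals the edit distance the
ungapped diagonal is preferred, so substitution-only divergence gives
identity = 1 − k/L exactly. That exactness is guaranteed only while the
diagonal is an optimal alignment, which on the generator holds through
roughly 5% divergence; beyond ~8%, chance shift-matches let gapped paths
win and identity is computed from the optimal alignment instead. The
built-in aligner is capped at 50 kb per sequence; longer genome sets must
arrive as a precomputed alignment (whole-plastome alignment construction is
out of scope). `similarity_matrix` accepts either records (all-pairs
built-in alignment) or an aligned FASTA; for alignment rows, both-gap
columns are dropped, N is missing, and remaining gap columns count as
differences.

`variable_percentage` projects ungapped reference intervals through the
reference row's gap structure; a column is variable iff it shows ≥ 2
distinct non-gap, non-N characters and ≥ 2 non-gap rows. Summing variable
columns over a partition of the reference equals the genome-wide count. No
hypothesis tests are computed — the quantities are descriptive fractions.

`nj_tree` is standard neighbor joining (scikit-bio) on 1 − identity, with
taxa sorted lexicographically first so ties break deterministically. It is
a clustering sanity check, not a phylogenetic inference tool.

## The synthetic generator

`build_template` emits a miniature Type-I plastome — defaults LSC 18 kb,
SSC 4 kb, IR 4 kb per arm, 30 kb total, a 1:5 scale model of a real 150 kb
plastome chosen so that quadratic test oracles and alignments run in
seconds. All absolute thresholds (30 bp repeats, SSR copy minima, the 1 kb
IR detection floor) keep their real values at this scale. Whole-genome GC
targets 0.39 (plastome-like); spacers and codon usage are sampled at that
composition. The gene layout carries the canonical junction order: the LSC
ends in rps19; each arm carries rpl2–rpl23–trnI-CAU–ycf2 (mirrored in the
opposite arm); the SSC carries ndhF–rpl32–trnL-UAG–ccsA–ndhD–ycf1;
trnH-GUG sits at the origin. Protein-coding genes are synthetic intact ORFs
(start codon, no internal stops, terminal stop, table 11) — not real gene
sequences, which keeps the generator download-free while leaving
pseudogenisation fully testable. atpF (one intron) and clpP1 (two introns)
provide multi-exon features. The rpl23 template fixes two interior codons
(CAA, TAT) that are a single substitution away from TAA, so
pseudogenisation is a 2-substitution, exactly-2-stop event at ~99%
identity.

Intergenic spacers are random sequence re-sampled until SSR-free, and the
assembled genome is rejected (and rebuilt, bounded retries) if any
accidental SSR survives — so every repeat present is a planted one. Four
bases flanking each arm boundary are forced to non-pairing states, making
the planted arms the *maximal* inverted repeat with exact endpoints; the
forcing only touches positions inside spacers.

Type transforms derive II–VI from a Type-I template. II and III are IR
boundary contractions: the first `cut` bases of IRb fall out of the repeat
(their annotations survive, now labelled LSC) and the mirrored span at the
far end of IRa is deleted, keeping the arms exactly complementary — II cuts
just past rpl2; III cuts through 60% of ycf2, leaving a 40% truncated copy
in IRa while the complete copy straddles the new JLB. IV inserts a copy of
the trnI-CAU sequence (with fresh random flanks) into the spacer between
trnL-UAG and ccsA; V additionally inserts the 2-stop rpl23 pseudogene
downstream of it; VI deletes the whole IRa. Every transform re-verifies the
ground truth against the emitted sequence.

`plant_repeats` overwrites spacer sequence with requested SSR arrays and
direct/palindromic pairs, surrounding each with guard bases that force the
array or pair to be maximal at exactly the planted coordinates (one
breaking base per SSR end; four consecutive non-matching positions per
repeat flank). `plant_trni_duplication` extends the natural trnI-CAU
duplication of a Type IV/V genome to a chosen length (default 153 bp) by
copying the window centred on the single-copy gene over the flanks of the
SSC-inserted copy — emulating the long direct repeat associated with the
SSC expansion — again with guards so the planted length is the maximal hit.

`mutate` applies per-site substitutions (uniform over the three other
bases). Positions sampled inside IRa are skipped and driven instead from
IRb: a mutated IRb base is complemented at its mirror position, so the arms
stay exactly complementary (as concerted evolution keeps them in real
plastomes). Indels (length 1–5, geometric, capped) are placed only in
single-copy intergenic spacers so feature annotations and arm
complementarity remain valid; this placement restriction is a generator
design choice — substitution positions and indel events are both recorded
in the ground truth. All generator randomness derives from the spec seed;
identical specs produce byte-identical genomes.

What the generator does *not* emulate: realistic gene complements (~130
genes), codon usage bias, RNA editing, trans-splicing, compound SSRs,
heteroplasmy, or assembly artefacts. Passing tests therefore demonstrate
correctness of the structural logic under clean, fully-known conditions,
not robustness to annotation noise in real records.

## Problem sizes and determinism

The acceptance checks run the generator at its default 30 kb scale: type
recovery over 6 types × 20 seeds (120 genomes), IR endpoint exactness over
100 genomes plus 20 IR-less genomes, SSR miner/oracle equality over 50
random 10 kb sequences, dispersed-repeat miner/oracle equality over 20
random 5 kb sequences with planted pairs, identity exactness at 1–5%
divergence, and one 153 bp duplication scenario. These sizes keep the full
brute-force oracles exact (no sampling) while the whole battery completes
in a few minutes on one CPU. Every stochastic step takes an explicit seed;
reruns are byte-identical.

## Known limitations

* The classifier is annotation-driven: it trusts gene names and /pseudo
  flags in the input record and does not re-annotate.
* Region labels use feature midpoints; genes almost exactly bisected by a
  junction get whichever side holds the midpoint.
* Tandem detection trades specificity for recall near the 2-copy boundary
  (see above) and does not reproduce TRF scores.
* Identity conventions for gap handling differ between published tools;
  values computed here follow the documented gaps-count-in-denominator
  convention and need not match figures computed under other conventions.
* The built-in aligner rejects sequences over 50 kb rather than risk
  unbounded quadratic fills; full-length plastome sets require an external
  alignment, which is accepted as input.
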