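# Methods

## The events being modeled

L1 endonuclease (EN)-dependent retrotransposition inserts a new Alu,
L1 or tail-only copy by target-primed reverse transcription (TPRT). On
the sequence level a completed event is a contiguous replacement in one
allele: at the integration site the mutant carries the original target
site (the first duplication copy), then optionally a short
non-templated 5' addition, then the element body — possibly
5'-truncated, possibly 5'-inverted by twin priming, reverse-
complemented when inserted antisense — then the poly(A) tail (which
surfaces as a leading poly(T) for antisense inserts), then the second
duplication copy. When the second nick falls on the other side of the
first one, target bases are deleted instead and no duplication forms.

Everything in the package is organized around recovering that anatomy
from a reference/mutant allele pair, and around a simulator that can
generate such pairs with exact ground truth.

## Breakpoint canonicalization

The minimal variant interval (maximal common prefix, then the maximal
non-overlapping common suffix) fixes *what* changed but not *where* the
duplication ends: poly(A)/(T) tails adjacent to A/T-rich duplications,
element termini equal to flank bases, and duplications whose own 3'
ends continue into the downstream flank all create families of
equivalent decompositions `ref[:q] + body + dup + ref[q:]`. Reported
TSD lengths in the source material are element-anchored — the full (or
printed-truncated) element is placed first and the duplication is what
remains — so the canonical call enumerates the equivalent
decompositions and ranks them by

1. edit distance of the (tail-trimmed, strand-corrected) body to its
   best-matching template (edlib, infix mode so truncation is free);
2. truncation offset plus unaligned 5' prefix (so a decomposition that
   absorbs an element terminus into the duplication loses);
3. longest duplication; then the rightmost placement.

For twin-priming (5'-inverted) bodies the located alignment start is
noise, so criterion 2 is dropped and distance plus duplication length
decide. Without a template library the longest duplication wins
outright. HGVS-style 3'-shifting is never applied to the element body;
the insertion point is always reported after the first duplicated copy.

One reconstructed case (the exon 22 (17) AluYa5 insertion) is
genuinely ambiguous even under this convention: the published flank
continues `TT` right after the published 13-nt duplication, so a 15-nt
duplication two bases downstream describes the identical mutant allele.
The canonical resolution reports 15; the fixture records both readings.
Similarly, published in-frame labels for two cases (80- and 68-nt
deletions) disagree with mod-3 arithmetic; frame classification here is
purely arithmetic and the discrepancy is carried as a flag.

## Element templates and classification

The bundled library holds one template per family — AluY (281 bp),
AluYa5 (281 bp, five diagnostic substitutions), AluYb8 (288 bp, eight
substitutions plus a 7-bp insertion), L1 (6000 bp) — generated
deterministically from a fixed seed. They are synthetic stand-ins, not
the deposited consensus sequences: they reproduce the structural
features the algorithms depend on (shared Alu backbone with
family-diagnostic sites, A-rich linker, non-A 3' termini so tail
boundaries are crisp, the L1 Ta/pre-Ta trinucleotide near the 3' end)
and the lengths are chosen so the three published Alu truncations
(17/20/39 nt) yield the published truncated sizes exactly. Family
assignment is the distance argmin over both strands; ties are reported
as `unknown` rather than broken arbitrarily, with a diagnostic-site
vote alongside. Homopolymer-dominated bodies (≥90% one base) are
`polyN`. A tail pins the strand before inversion analysis, because a
twin-priming body is part-forward, part-reverse on either strand.

Truncation and non-templated 5' additions are read from an
exact-20-mer anchor: the alignment alone cannot distinguish a short
random addition from a run of mismatches, so the unaligned prefix is
whatever precedes the first exact 20-mer shared with the template
(a prefix that matches its implied template context ≥70% is treated as
aligned). Inversions are detected from k-mer anchor orientation (21-mers
at stride 7): reverse anchors fix the inverted segment's template end
`j`, forward anchors are extended leftwards to the forward segment
start `f`, and the microhomology is the maximal identical junction
overlap `j − f`, assignable to either segment. The simulator records
the same maximal-overlap normalization, so detection and truth agree by
construction.

## Integration-site analysis

EN scores are strict 0–6 match counts against 3'-AA/TTTT-5' on the
nicked strand; no numeric cutoff is baked in because the source applies
none (the simulator's default site floor is 4, "the consensus and
derivates thereof"). Nick inference: sense inserts place the
bottom-strand first nick at the left TSD boundary, antisense inserts
the top-strand nick at the right TSD boundary (the insertion point);
deletion-associated events get a tentative assignment. This makes the
two acceptor-site insertions of intron 14 (10c) coincide at one
genomic position on opposite strands, which is why the default 12-bp
recurrence window groups them. Clusters are greedy left-to-right
maximal windows (default ≤1500 bp, ≥3 calls). The polypyrimidine-tract
window is intron positions −3..−20 of an acceptor, a documented,
adjustable convention that covers the published tract insertions;
canonical-AG means the event interrupts the intron-terminal AG.

## Splice-effect typing

Types 1–6 are assigned per observed transcript product from the site
annotation and the gene model only (partial-exon losses must match the
printed boundaries exactly; "adjacent" in type 6 means the exon
immediately up- or downstream of the intronic insertion, accepted
symmetrically on the donor side and flagged as an extension). Full
element inclusion would be reported as unclassified/none; none occurs
in the bundled cases. Frame status is the net exonic change mod 3,
counting element-derived cryptic inclusions.

## Fixture reconstruction

The 18 cases are rebuilt on a synthetic mini-gene genome: 49 exons
whose transcript coordinates come from the published r.-level intervals
(boundaries not printed are evenly interpolated; legacy labels follow
the historical numbering), one intron per junction (2000 bp by default;
introns 21 and 22 are 150 bp so the published 1.5-kb cluster geometry
holds), and seeded random filler overwritten with every published
12+24-nt integration-site window at its mapped position. Windows are
printed 3'→5' on the nicked strand: sense rows are embedded as the
complement (bottom strand), antisense rows reversed (top strand), and
the inverted-L1 row as printed; overlapping windows are checked for
agreement, and every TSD/dup string is verified against the embedded
genome before the mutant allele is applied. Tails printed only as
ranges or estimates are fixed at 100 nt and excluded from tail
assertions. Each case's reference allele is a 2.4-kb slice around its
site; recurrence and clustering map per-case calls back to the shared
genome through the case's coordinate map.

The deletion-associated intron 10 (8) case needs one placement choice:
under the antisense window convention the first deleted base would be a
T colliding with the poly(T)-leading insert, making the published 71-bp
deletion textually unrepresentable, so its window is embedded
bottom-strand-style to the right of the published tentative nick and
the unprinted deleted bases are filled with non-colliding sequence.

## Simulator

Defaults are the observed study conditions: TSD length uniform on
7–20 bp, tails uniform on 60–178 nt, L1 categories
full-length/5'-truncated/5'-inverted at 25.5/43.8/30.7%, Alu truncation
probability 0.08, small probabilities (0.05) for target-site deletions
(length uniform on 10–100 bp, covering the 71-bp case) and
non-templated additions (1–10 random nt); truncation extents are
uniform over the element because no distribution is reported; tails are
pure A by default with an optional impurity rate. Sites are drawn
uniformly among EN scores ≥4 on either strand. The generator's contract
is that the TruthRecord is the *canonical* description of the edit, so
draws whose textual decomposition is ambiguous are rejected and
redrawn: a sense event whose duplication is preceded by an A (the
duplication would absorb a tail base), an insertion point whose right
flank begins with the insert's first base, a non-templated addition
whose terminus equals the adjacent flank base, and a TSD terminus that
would extend the truncated element by one. This trims a thin slice of
site space but keeps truth and canonical resolution identical, which is
what makes 100% blind recovery a meaningful gate.

What the simulator does not emulate: sequencing noise, heterozygous
trace mixtures, nested or SVA elements, source-element choice and
chromatin context. Passing the recovery gates therefore demonstrates
correctness of the resolution logic on clean alleles, not robustness to
noisy read-level data.

## Problem sizes and numerics

The bundled analyses are desk-scale: an ~104-kb synthetic genome, 18
cases, 200-event recovery benchmarks, 10,000-draw category-frequency
checks (within 3 binomial standard errors). Alignment is exact edit
distance (edlib); no heuristics with tunable score matrices are
involved. All internal coordinates are 0-based half-open; every
HGVS-facing string is 1-based inclusive. Determinism: every random
draw flows from one integer seed (fixture genome filler and simulator
alike), and identical seeds give byte-identical outputs.
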