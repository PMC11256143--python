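# Methods

## Coordinates and cut-site geometry

All genomic intervals are 0-based, half-open (BED/SAM arithmetic). Cas9 cut
sites are inter-base integers: `cut == c` places the blunt cut between
reference bases `c-1` and `c`. Guides are located by exact protospacer match
on either strand with a configurable PAM rule (default NGG), and the cut is
placed 3 bp 5′ of the PAM — between protospacer positions 17 and 18, the
canonical SpCas9 geometry. The expected blunt dual-cut deletion length is the
difference of the two cut coordinates.

`inframe_removable_exons` applies the length-divisibility criterion
(`len(exon) % 3 == 0`) over coding exons, optionally excluding the first and
last exon; no splice-phase information beyond length is used, and the flag is
exposed rather than a convention imposed.

## The synthetic study

The default locus is a deterministic synthetic 12 kb sequence carrying a
five-exon gene (exon lengths 180/121/63/111/180 bp). The 63 bp target exon
(21 codons) is flanked by two planted guide sites whose blunt cuts sit 126 bp
apart; a ~0.9 kb short amplicon and a ~10 kb long amplicon are centred over
it. This mirrors the geometry of excising a small in-frame exon from a large
collagen gene; only the structure is emulated, the sequence content is
random.

The default outcome mixtures are set to the study conditions the package
models: short-range genotyping with 89.03% target-exon deletion
(predominantly the blunt deletion plus an AG junction insertion), ~10%
single-cut indels and ~1% unedited; long-range genotyping with 78%
target-exon-only deletion and 10.89% large deletions split 6.36 / 4.28 / 0.25%
across the 200–1000 bp, 1–5 kb and >5 kb ranges; and a cDNA mixture with
88.65% target-exon skip, 4.07% other-exon skips and 0.64% intron
read-through. Large deletions are modelled as resections extending outward
from one cut (they delete flanking sequence without removing the target exon)
except in the >5 kb range, where deletions span both cuts and typically
remove a neighbouring exon as well; sizes are log-uniform within each range.
A small class (1.33%) of target-spanning deletions is sized 715–850 bp so
that both short primers stay intact but the predicted product falls below the
recoverable length — the mechanism behind short products being lost in
processing.

## Error model

Sequencing errors are applied per read with per-base *affected* probabilities
(defaults: substitution 0.02, insertion 0.02, deletion 0.04 — the expected
fractions of substituted/inserted/deleted bases). Indel run lengths are
geometric (stop probability 0.5) capped at `max_error_indel` (default 3 bp).
Deletion runs are placed by a renewal process (geometric gaps between runs)
whose mean gap is chosen so the marginal per-base deletion probability equals
`del_rate` exactly up to O(1/L) edge effects; this makes the expected
edit-operation count per template of length L

    sub_rate * (1 - del_rate) * L  +  ins_rate * (L + 1)  +  del_rate * L

(≈ 0.079·L at the defaults), which the test suite verifies against a direct
per-read edit-distance oracle. Errors are injected on a column representation
that maps every read base to its reference coordinate, so the emitted truth
CIGAR is exact by construction; with zero error rates, CIGAR + reference
reproduces each read byte for byte. Reads are emitted with truth SAM, FASTQ
and a truth TSV; identical seeds give byte-identical outputs.

What the generator does **not** emulate: homopolymer-biased or quality-
correlated errors, microhomology-mediated end joining at junctions, PCR
chimeras, UMI structure, or length-dependent PCR efficiency (capture is
all-or-none: primers intact and product above the recoverable length).
Passing tests therefore demonstrate correctness of the classification logic
under a realistic error *load*, not robustness to every artefact of real
libraries; with real alignments the cut-anchoring tolerance and junction
tolerance may need widening (see below).

## Genotyping

Per read, deletion and insertion events are extracted from the op walk.
Indels shorter than `min_noise_indel` outside the cut-site windows are
discarded as sequencing noise. The default is **4 bp = max_error_indel + 1**:
a noise filter must exceed the error model's maximal indel length, otherwise
every multi-kilobase read retains dozens of capped 3 bp error indels, which
would corrupt the deletion-size histogram and the primer-ablation calls.
Deletions separated by at most `merge_gap` (default 10) reference bases merge
into one event whose junction insert records the retained query bases;
insertions sitting exactly at a deletion junction are folded into that
event's insert (exact adjacency — folding across a gap would let nearby noise
deletions capture a true cut-site insertion).

Classification precedence: MULTI_EXON_DELETION > TARGET_EXON_DELETION >
LARGE_SV > BOTH_SITES_INDEL > SITE1/SITE2_INDEL > UNCLASSIFIED; UNEDITED
means no editing-relevant event. TARGET_EXON_DELETION tolerates junction
inserts up to 25 bp; larger inserts are UNCLASSIFIED. LARGE_SV requires a
deletion of at least `sv_min` (default 200 bp, the smallest structural range
reported in this kind of experiment) not containing the target exon.

**Cut anchoring.** A small indel is attributed to a cut site only when its
interval touches the cut inter-base position (deletions of ≥2 bp must span
it, 1 bp deletions must abut it, insertions must sit at it, all within
`anchor_tol`, default 0); `site_window` (default ±10 bp) bounds the candidate
region. A pure window rule is untenable at long-read error rates: the
expected number of noise indels inside a ±10 bp window is ~0.5–1 per read, so
most unedited reads would be called site-edited. Anchoring exploits the fact
that NHEJ indels are anchored at the blunt cut while noise indels are uniform
over the window; it reduces the per-site false-positive rate to ~5% at the
default error model while keeping full sensitivity to 1 bp cut-site indels.
For reads aligned by a real spliced/affine aligner, indels may be left-shifted
away from the cut; `anchor_tol` widens the rule accordingly.

At the defaults, ≥99% of simulated reads (n = 5,000, default error model)
recover their truth category, and error-free truth alignments are classified
100% correctly. Residual confusion is concentrated where it must be: a true
single-cut read with a noise indel that happens to anchor at the other cut
becomes BOTH_SITES_INDEL (~0.3–0.6% of reads), and ~2% of 1 bp site
insertions are destroyed by overlapping deletion errors.

## Capture evasion

Detectability of each long-range read under the short design: a deletion
event of ≥200 bp overlapping either primer interval (even by 1 bp) is
PRIMER_ABLATED — the size gate keeps small in-window noise indels from being
mistaken for primer loss; otherwise the predicted product is the wild-type
product minus deleted bases within the design span plus insert bases, and
products below `min_recoverable_length` (default 200 bp, well under any
intact short amplicon of 0.7–1.2 kb) are SHORT_PRODUCT_DROPOUT. The revised
exon-deletion efficiency uses all primary long-range reads as denominator;
the naive estimate is computed over CAPTURED reads only, which is what
short-amplicon genotyping would report. The deletion-size histogram bins each
read by its largest deletion event into <200, 200–1000, 1000–5000 and
>5000 bp.

## Splice outcomes

Splice chains trust the op kinds: N separates exonic blocks, D stays within a
block. An exon is skipped when no block overlaps it while covered exons flank
it; reads covering fewer than two exons are OTHER (they cannot witness a
junction). Intron read-through means ≥`readthrough_min` (default 15 bp)
contiguous intronic coverage — above alignment slop, below any depicted
retention; block edges within `junction_tol` (default 5 bp) of annotated
boundaries are canonical. The truth simulator emits splice gaps only at
reference gaps ≥30 bp, so capped error deletions never masquerade as introns.
In-silico RT-PCR takes primers in transcript coordinates and subtracts the
skipped exons' overlap with the primer span; product lengths are additive
over disjoint skip sets.

## Off-target comparison

Per site, a read is indel-bearing if it carries an insertion or deletion of
≥`min_indel` (default 1) bases overlapping the ±10 bp window. Edited and
control arms are compared by a two-sided Fisher exact test (scipy, cross-
checked in the tests against exhaustive hypergeometric enumeration) and
Bonferroni-corrected across sites, capped at 1. Because both arms share the
noise process, noise cancels under the null; the family-wise error simulation
(12 sites × 5,000 reads, shared 5% noise rate, 500 replicates) runs at the
count level — binomial draws feed the identical compare-and-correct procedure
a read-level simulation would.

## Numerical and design choices

- Problem sizes: validation runs use 5,000–10,000 reads per arm, matching the
  read depths such experiments report per amplicon; summaries are exact
  percentages with no smoothing.
- Tie-breaks: top-allele rows rank by frequency, then (span, start); signature
  collapse (`collapse_tol`) merges endpoint jitter onto the most frequent
  representative, greedily from the top.
- Degenerate inputs: empty call lists are errors; an allele pool with no
  amplifiable member yields a warning and zero reads (not an error); a site
  with zero reads is unanalyzable and raises.
- Only primary alignments are counted (one vote per molecule); secondary and
  supplementary records are skipped on input.
- Frequencies of unamplifiable alleles are renormalised within each design —
  PCR samples the amplifiable pool, which is precisely how capture bias
  arises.

## Known limitations

- Inversions and translocations are not modelled or called; the taxonomy
  covers deletions and insertions only.
- The capture model is binary; real PCR shows graded, length-dependent
  efficiency, so true evasion fractions are fuzzier than the simulated ones.
- Cut anchoring assumes indels are reported at or across the cut; heavily
  left-aligned real alignments in repetitive flanks may need `anchor_tol` > 0,
  which raises the noise floor of the site-indel categories.
- The gene model is single-transcript; multi-isoform annotation is out of
  scope.
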