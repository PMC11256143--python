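"""Splice-outcome classification of spliced cDNA alignments.

Reads are reduced to a chain of exonic blocks separated by splice gaps, then
classified against the gene model: canonical splicing, skipping of the target
exon (the intended outcome of dual-guide excision), skipping of other exons
(natural alternative splicing or aberrant events), and intron read-through
(retention of intronic sequence in the mature transcript).  The module also
provides an in-silico RT-PCR product-size calculator in transcript
coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .gene_model import GeneModel, GeneModelError, GenomicInterval
from .genotype import ReadAlignment

__all__ = [
    "SpliceChain",
    "IsoformCall",
    "IsoformTable",
    "extract_splice_chain",
    "classify_isoform",
    "isoform_table",
    "insilico_rtpcr",
    "ISOFORM_CATEGORIES",
]

ISOFORM_CATEGORIES = (
    "CANONICAL",
    "TARGET_SKIP",
    "OTHER_EXON_SKIP",
    "INTRON_READTHROUGH",
    "OTHER",
)


@dataclass(frozen=True)
class SpliceChain:
    """Exonic-aligned blocks and the intron gaps between them."""

    read_id: str
    blocks: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev = None
        for s, e in self.blocks:
            if e <= s or (prev is not None and s < prev):
                raise ValueError("blocks must be ascending and non-overlapping")
            prev = e


@dataclass(frozen=True)
class IsoformCall:
    read_id: str
    category: str
    skipped_exons: tuple[int, ...] = ()
    readthrough_bases: int = 0


@dataclass(frozen=True)
class IsoformTable:
    n_reads: int
    category_pct: dict[str, float]
    rows: list[dict]  # per (category, skipped-exon signature) rows


def extract_splice_chain(aln: ReadAlignment) -> SpliceChain:
    """Reconstruct exonic blocks from the op walk.

    Splice gaps (N) separate blocks; deletions stay within a block (they
    extend its reference span), insertions and clips consume only query.
    """
    blocks = []
    gaps = []
    ref = aln.ref_start
    block_start = None
    for kind, length in aln.ops:
        if kind in ("match", "deletion"):
            if block_start is None:
                block_start = ref
            ref += length
        elif kind == "splice_gap":
            if block_start is not None:
                blocks.append((block_start, ref))
                block_start = None
            gaps.append((ref, ref + length))
            ref += length
        # insertion / clip: query only
    if block_start is not None:
        blocks.append((block_start, ref))
    if not blocks:
        raise ValueError(f"read {aln.read_id} has no aligned blocks")
    return SpliceChain(read_id=aln.read_id, blocks=tuple(blocks), gaps=tuple(gaps))


def classify_isoform(
    chain: SpliceChain,
    model: GeneModel,
    target_exon: int,
    junction_tol: int = 5,
    readthrough_min: int = 15,
) -> IsoformCall:
    """Classify one splice chain.

    An exon is *skipped* when no block overlaps it while covered exons flank
    it on both sides.  A block covering at least ``readthrough_min`` intronic
    bases (between covered exons, or extending past an internal junction)
    makes the read INTRON_READTHROUGH.  Reads covering fewer than two exons
    cannot witness a junction and are labelled OTHER.
    """
    exons = [(model.exon_number(ex), ex) for ex in model.exons]

    def overlap(block, iv_start, iv_end) -> int:
        return max(0, min(block[1], iv_end) - max(block[0], iv_start))

    covered = {
        num
        for num, ex in exons
        if any(overlap(b, ex.start, ex.end) > 0 for b in chain.blocks)
    }
    if len(covered) < 2:
        return IsoformCall(chain.read_id, "OTHER")

    # intron read-through: contiguous intronic coverage beyond the tolerance
    readthrough = 0
    for intr in model.introns():
        for b in chain.blocks:
            ov = overlap(b, intr.start, intr.end)
            readthrough = max(readthrough, ov)
    if readthrough >= readthrough_min:
        skipped = _skipped(covered, exons)
        return IsoformCall(
            chain.read_id,
            "INTRON_READTHROUGH",
            skipped_exons=skipped,
            readthrough_bases=readthrough,
        )

    skipped = _skipped(covered, exons)

    # canonical junction check: internal block edges must land near annotated
    # exon boundaries
    boundaries = sorted({ex.start for _, ex in exons} | {ex.end for _, ex in exons})
    internal_edges = []
    for i, b in enumerate(chain.blocks):
        if i > 0:
            internal_edges.append(b[0])
        if i < len(chain.blocks) - 1:
            internal_edges.append(b[1])
    junctions_ok = all(
        any(abs(edge - bd) <= junction_tol for bd in boundaries)
        for edge in internal_edges
    )
    if not junctions_ok:
        return IsoformCall(chain.read_id, "OTHER", skipped_exons=skipped)
    if not skipped:
        return IsoformCall(chain.read_id, "CANONICAL")
    if skipped == (target_exon,):
        return IsoformCall(chain.read_id, "TARGET_SKIP", skipped_exons=skipped)
    return IsoformCall(chain.read_id, "OTHER_EXON_SKIP", skipped_exons=skipped)


def _skipped(covered: set[int], exons) -> tuple[int, ...]:
    nums = sorted(num for num, _ in exons)
    lo = min(covered)
    hi = max(covered)
    return tuple(n for n in nums if lo < n < hi and n not in covered)


def isoform_table(calls: list[IsoformCall]) -> IsoformTable:
    """Per-category and per-signature percentage table."""
    if not calls:
        raise ValueError("isoform_table requires at least one call")
    n = len(calls)
    cat_counts = Counter(c.category for c in calls)
    category_pct = {c: 100.0 * cat_counts.get(c, 0) / n for c in ISOFORM_CATEGORIES}
    sig_counts = Counter((c.category, c.skipped_exons) for c in calls)
    rows = [
        {
            "category": cat,
            "skipped_exons": ",".join(map(str, sk)),
            "reads": cnt,
            "pct": 100.0 * cnt / n,
        }
        for (cat, sk), cnt in sig_counts.most_common()
    ]
    return IsoformTable(n_reads=n, category_pct=category_pct, rows=rows)


def insilico_rtpcr(
    model: GeneModel,
    fwd_primer: GenomicInterval,
    rev_primer: GenomicInterval,
    skipped_exons: tuple[int, ...] = (),
) -> int:
    """RT-PCR product length over the spliced transcript.

    Primers are given in transcript coordinates of the *full* (canonical)
    transcript; the product is the primer-to-primer span minus the skipped
    exons' lengths.  A primer landing inside a skipped exon is an error.
    """
    if fwd_primer.end > rev_primer.start:
        raise GeneModelError("forward primer must precede reverse primer")
    tlen = model.transcript_length()
    if rev_primer.end > tlen:
        raise GeneModelError("primer outside transcript")

    # transcript-coordinate extents of each exon, in transcription order
    extents = {}
    pos = 0
    for num in range(1, model.n_exons + 1):
        ex = model.exon(num)
        extents[num] = (pos, pos + len(ex))
        pos += len(ex)

    removed = 0
    for num in skipped_exons:
        if num not in extents:
            raise GeneModelError(f"unknown exon {num}")
        s, e = extents[num]
        for p in (fwd_primer, rev_primer):
            if p.start < e and p.end > s:
                raise GeneModelError(f"primer lies inside skipped exon {num}")
        removed += max(0, min(e, rev_primer.end) - max(s, fwd_primer.start))
    return rev_primer.end - fwd_primer.start - removed
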