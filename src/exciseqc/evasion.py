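"""Capture evasion: which alleles a short-range amplicon design misses.

Long-range genotyping sees deletions that short-amplicon genotyping cannot:
a deletion that removes a primer site yields no product (PRIMER_ABLATED), and
a deletion that leaves both primers intact but shrinks the product below the
recoverable length is lost during processing (SHORT_PRODUCT_DROPOUT).  This
module classifies each long-range read's detectability under the short
design, partitions deletion sizes, and reports the naive (short-design) vs
revised (long-design) exon-deletion efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gene_model import AmpliconDesign, GeneModel, GeneModelError
from .genotype import AlleleCall, DeletionEvent, InsertionEvent

__all__ = [
    "DetectabilityCall",
    "EvasionSummary",
    "assess_detectability",
    "evasion_summary",
    "deletion_size_histogram",
    "DEFAULT_BINS",
]

CAPTURED = "CAPTURED"
PRIMER_ABLATED = "PRIMER_ABLATED"
SHORT_PRODUCT_DROPOUT = "SHORT_PRODUCT_DROPOUT"

# size ranges reported for large on-target deletions
DEFAULT_BINS = (200, 1000, 5000)


@dataclass(frozen=True)
class DetectabilityCall:
    read_id: str
    status: str
    predicted_product_length: int | None

    def __post_init__(self):
        if self.status == PRIMER_ABLATED and self.predicted_product_length is not None:
            raise ValueError("ablated alleles have no predicted product")


@dataclass(frozen=True)
class EvasionSummary:
    n_reads: int
    primer_ablated_pct: float
    dropout_pct: float
    evaded_pct: float
    size_bin_pcts: dict[str, float]
    naive_exon_deletion_pct: float
    revised_exon_deletion_pct: float


def assess_detectability(
    read_id: str,
    events: list[DeletionEvent],
    design: AmpliconDesign,
    insertions: list[InsertionEvent] | None = None,
    model: GeneModel | None = None,
    ablation_min: int = 200,
) -> DetectabilityCall:
    """Decide whether the short design would capture this read's allele.

    A deletion event of at least ``ablation_min`` bases overlapping either
    primer interval ablates the design (partial primer loss prevents
    priming); the size gate keeps small sequencing-noise indels retained
    inside cut-site windows from being mistaken for primer loss.  Otherwise
    the predicted product is the wild-type product minus deleted bases within
    the design span plus junction-insert bases; products shorter than the
    design's minimum recoverable length are dropped during processing.
    """
    if model is not None and not (
        model.locus.contains(design.fwd_primer)
        and model.locus.contains(design.rev_primer)
    ):
        raise GeneModelError("design primers fall outside the locus")

    for ev in events:
        if ev.span >= ablation_min and (
            _olap(ev, design.fwd_primer) or _olap(ev, design.rev_primer)
        ):
            return DetectabilityCall(read_id, PRIMER_ABLATED, None)

    span_s, span_e = design.fwd_primer.start, design.rev_primer.end
    removed = 0
    added = 0
    for ev in events:
        removed += max(0, min(ev.interval.end, span_e) - max(ev.interval.start, span_s))
        if span_s <= ev.interval.start <= span_e:
            added += ev.junction_insert_len
    for ins in insertions or ():
        if span_s <= ins.ref_pos <= span_e:
            added += ins.length
    product = design.wt_product_length - removed + added
    if product < design.min_recoverable_length:
        return DetectabilityCall(read_id, SHORT_PRODUCT_DROPOUT, product)
    return DetectabilityCall(read_id, CAPTURED, product)


def _olap(ev: DeletionEvent, primer) -> bool:
    return ev.interval.start < primer.end and ev.interval.end > primer.start


def deletion_size_histogram(
    per_read_events: list[list[DeletionEvent]],
    bins: tuple[int, ...] = DEFAULT_BINS,
) -> dict[str, float]:
    """Percentage of reads per deletion-size range, by each read's largest
    deletion.  Default ranges: <200, 200-1000, 1000-5000, >5000 bp (the first
    bin is half-open below the first edge, interior bins are closed on the
    left edge, the last is open-ended).  Reads without a deletion are not
    binned, so percentages need not sum to 100.
    """
    if list(bins) != sorted(set(bins)):
        raise ValueError("bin edges must be strictly increasing")
    edges = list(bins)
    labels = [f"<{edges[0]}"]
    for a, b in zip(edges, edges[1:]):
        labels.append(f"{a}-{b}")
    labels.append(f">{edges[-1]}")
    counts = {lab: 0 for lab in labels}
    n = len(per_read_events)
    for events in per_read_events:
        if not events:
            continue
        size = max(ev.span for ev in events)
        if size < edges[0]:
            lab = labels[0]
        elif size > edges[-1]:
            lab = labels[-1]
        else:
            for a, b, lab_ in zip(edges, edges[1:], labels[1:]):
                if a <= size <= b:
                    lab = lab_
                    break
        counts[lab] += 1
    return {lab: 100.0 * c / n for lab, c in counts.items()}


def evasion_summary(
    long_calls: list[AlleleCall],
    detect: list[DetectabilityCall],
    per_read_events: list[list[DeletionEvent]] | None = None,
    bins: tuple[int, ...] = DEFAULT_BINS,
) -> EvasionSummary:
    """Population summary of short-design capture over long-range reads.

    ``revised_exon_deletion_pct`` is the TARGET_EXON_DELETION share of *all*
    long-range reads; ``naive_exon_deletion_pct`` is the same share computed
    only over reads the short design would capture — what short-amplicon
    genotyping would have reported.
    """
    if len(long_calls) != len(detect):
        raise ValueError("one detectability call per long-range read required")
    n = len(long_calls)
    if n == 0:
        raise ValueError("empty input")
    n_abl = sum(1 for d in detect if d.status == PRIMER_ABLATED)
    n_drop = sum(1 for d in detect if d.status == SHORT_PRODUCT_DROPOUT)
    captured = [c for c, d in zip(long_calls, detect) if d.status == CAPTURED]
    n_cap_target = sum(1 for c in captured if c.category == "TARGET_EXON_DELETION")
    n_target = sum(1 for c in long_calls if c.category == "TARGET_EXON_DELETION")

    size_bins = (
        deletion_size_histogram(per_read_events, bins)
        if per_read_events is not None
        else {}
    )
    return EvasionSummary(
        n_reads=n,
        primer_ablated_pct=100.0 * n_abl / n,
        dropout_pct=100.0 * n_drop / n,
        evaded_pct=100.0 * (n_abl + n_drop) / n,
        size_bin_pcts=size_bins,
        naive_exon_deletion_pct=100.0 * n_cap_target / len(captured)
        if captured
        else 0.0,
        revised_exon_deletion_pct=100.0 * n_target / n,
    )
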