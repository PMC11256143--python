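"""Allele-level classification of NHEJ repair outcomes from long-read
amplicon alignments.

The genotyper consumes per-read alignments (CIGAR walks), extracts deletion
and insertion events with noise filtering and junction merging, classifies
each read into a repair-outcome taxonomy anchored on the two predicted Cas9
cut sites, and summarises the population (total editing, exon-deletion
efficiency, top-allele table).

Category taxonomy
-----------------
TARGET_EXON_DELETION   a deletion fully containing the target exon and no
                       other exon (junction insert up to ``max_target_insert``)
MULTI_EXON_DELETION    a deletion containing the target exon plus >=1 other
LARGE_SV               a deletion >= ``sv_min`` not containing the target exon
SITE1_INDEL /          a small indel anchored at the upstream / downstream cut
SITE2_INDEL / BOTH_SITES_INDEL
UNEDITED               no editing-relevant event
UNCLASSIFIED           events that fit none of the above (e.g. oversized
                       junction inserts)

Small-indel attribution is *cut-anchored*: an indel within the cut-site
window counts as a site edit only if it touches the cut inter-base position
(deletions of >=2 bp must span it, 1 bp deletions must abut it, insertions
must sit at it, all within ``anchor_tol``).  Blunt SpCas9 cuts anchor NHEJ
indels at the cut, whereas sequencing-noise indels are uniform over the
window; anchoring keeps the false site-call rate low at long-read error
rates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .gene_model import GeneModel, GenomicInterval, GuidePair

__all__ = [
    "ReadAlignment",
    "DeletionEvent",
    "InsertionEvent",
    "AlleleCall",
    "InsertionEvent",
    "EditingSummary",
    "call_read",
    "extract_deletions",
    "classify_allele",
    "summarize_editing",
    "top_alleles",
    "read_alignments_from_sam",
    "alignment_from_simulated",
    "CATEGORIES",
]

CATEGORIES = (
    "TARGET_EXON_DELETION",
    "MULTI_EXON_DELETION",
    "SITE1_INDEL",
    "SITE2_INDEL",
    "BOTH_SITES_INDEL",
    "LARGE_SV",
    "UNEDITED",
    "UNCLASSIFIED",
)

_QUERY_OPS = {"match", "insertion", "clip"}
_REF_OPS = {"match", "deletion", "splice_gap"}


@dataclass(frozen=True)
class ReadAlignment:
    """One primary alignment: ordered ops over the reference."""

    read_id: str
    ref_start: int
    ops: tuple[tuple[str, int], ...]
    sequence: str

    def __post_init__(self):
        qlen = 0
        for kind, length in self.ops:
            if kind not in _QUERY_OPS and kind not in _REF_OPS:
                raise ValueError(f"unknown op kind {kind!r}")
            if length < 1:
                raise ValueError("op lengths must be >= 1")
            if kind in _QUERY_OPS:
                qlen += length
        if self.sequence and qlen != len(self.sequence):
            raise ValueError(
                f"query-consuming ops sum to {qlen}, sequence length "
                f"{len(self.sequence)}"
            )


@dataclass(frozen=True)
class DeletionEvent:
    """A (possibly merged) deletion with its junction insert."""

    interval: GenomicInterval
    junction_insert_seq: str = ""

    @property
    def span(self) -> int:
        return len(self.interval)

    @property
    def junction_insert_len(self) -> int:
        return len(self.junction_insert_seq)


@dataclass(frozen=True)
class InsertionEvent:
    ref_pos: int  # inter-base position
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlleleCall:
    read_id: str
    category: str
    signature: tuple[int, int, int] | None = None  # (del start, del end, ins len)


@dataclass(frozen=True)
class EditingSummary:
    """Population summary in the style of an editing-efficiency figure."""

    n_reads: int
    category_pct: dict[str, float]
    total_editing_pct: float
    exon_deletion_pct: float


def _window_overlap(start: int, end: int, windows) -> bool:
    return any(start <= w_end and end >= w_start for w_start, w_end in windows)


def extract_deletions(
    aln: ReadAlignment,
    merge_gap: int = 10,
    min_noise_indel: int = 4,
    windows: tuple[tuple[int, int], ...] = (),
) -> tuple[list[DeletionEvent], list[InsertionEvent]]:
    """Walk the op list and extract deletion/insertion events.

    Indels shorter than ``min_noise_indel`` that do not overlap any cut-site
    window are discarded as sequencing noise.  Deletions separated by at most
    ``merge_gap`` reference bases are merged into one event whose interval is
    the union span and whose junction insert records the retained query bases
    (including any interleaved insertions).  Standalone insertions within
    ``merge_gap`` of a deletion are folded into that event's junction insert.

    ``windows`` are (start, end) inter-base ranges; the default noise filter
    of 4 bp sits one above the error model's default indel-length cap.
    """
    ref = aln.ref_start
    qry = 0
    # raw events: (ref_start, ref_end, query_start, query_end)
    raw_dels: list[tuple[int, int, int]] = []  # (ref_s, ref_e, query_pos_after)
    raw_ins: list[InsertionEvent] = []
    for kind, length in aln.ops:
        if kind == "match":
            ref += length
            qry += length
        elif kind == "deletion":
            if length >= min_noise_indel or _window_overlap(
                ref, ref + length, windows
            ):
                raw_dels.append((ref, ref + length, qry))
            ref += length
        elif kind == "insertion":
            if length >= min_noise_indel or _window_overlap(ref, ref, windows):
                seq = aln.sequence[qry : qry + length] if aln.sequence else "N" * length
                raw_ins.append(InsertionEvent(ref_pos=ref, sequence=seq))
            qry += length
        elif kind == "splice_gap":
            ref += length
        elif kind == "clip":
            qry += length

    # map from reference position to query position for retained-base lookup
    def query_slice(q_start: int, q_end: int) -> str:
        if not aln.sequence:
            return "N" * max(0, q_end - q_start)
        return aln.sequence[q_start:q_end]

    # merge deletions separated by <= merge_gap reference bases; the query
    # bases between merged deletions (matches plus interleaved insertion ops)
    # become the junction insert
    events: list[DeletionEvent] = []
    i = 0
    while i < len(raw_dels):
        s, e, q_after = raw_dels[i]
        insert_parts: list[str] = []
        j = i + 1
        while j < len(raw_dels) and raw_dels[j][0] - e <= merge_gap:
            ns, ne, nq_after = raw_dels[j]
            insert_parts.append(query_slice(q_after, nq_after))
            e, q_after = ne, nq_after
            j += 1
        events.append(
            DeletionEvent(
                interval=_mk_iv(s, e),
                junction_insert_seq="".join(insert_parts),
            )
        )
        i = j

    # fold insertions sitting exactly at a deletion junction into that event;
    # insertions strictly inside a merged event were already captured above
    standalone: list[InsertionEvent] = []
    folded: dict[int, list[str]] = {}
    for ins in raw_ins:
        target = None
        for k, ev in enumerate(events):
            if ev.interval.start < ins.ref_pos < ev.interval.end:
                target = -1  # interior: already part of the junction insert
                break
            if ins.ref_pos in (ev.interval.start, ev.interval.end):
                target = k
                break
        if target is None:
            standalone.append(ins)
        elif target >= 0:
            folded.setdefault(target, []).append(ins.sequence)
    for k, parts in folded.items():
        ev = events[k]
        events[k] = DeletionEvent(
            interval=ev.interval,
            junction_insert_seq=ev.junction_insert_seq + "".join(parts),
        )
    return events, standalone


def _mk_iv(s: int, e: int) -> GenomicInterval:
    return GenomicInterval("ref", s, e)


def _anchored(ev_start: int, ev_end: int, cut: int, tol: int, is_insertion: bool) -> bool:
    """Cut-anchoring rule for small-indel site attribution."""
    if is_insertion:
        return abs(ev_start - cut) <= tol
    length = ev_end - ev_start
    if length == 1:
        # 1 bp deletions must abut the cut inter-base
        return ev_start - tol <= cut <= ev_end + tol
    # longer deletions must span the cut strictly (interior)
    return ev_start - tol < cut < ev_end + tol


def classify_allele(
    events: list[DeletionEvent],
    insertions: list[InsertionEvent],
    pair: GuidePair,
    model: GeneModel,
    site_window: int = 10,
    sv_min: int = 200,
    max_target_insert: int = 25,
    anchor_tol: int = 0,
) -> str:
    """Classify one read's events into the repair-outcome taxonomy.

    Precedence on conflict: MULTI_EXON_DELETION > TARGET_EXON_DELETION >
    LARGE_SV > BOTH_SITES_INDEL > SITEk_INDEL > UNCLASSIFIED.  Small events
    that are neither exon-covering, nor structural, nor cut-anchored are
    treated as residual noise and ignored.
    """
    target = model.exon(pair.target_exon)
    cut1, cut2 = pair.cuts

    def contains(ev: DeletionEvent, exon: GenomicInterval) -> bool:
        return ev.interval.start <= exon.start and exon.end <= ev.interval.end

    oversized_insert = False
    for ev in events:
        if contains(ev, target):
            others = [ex for ex in model.exons if ex != target and contains(ev, ex)]
            if others:
                return "MULTI_EXON_DELETION"
            if ev.junction_insert_len <= max_target_insert:
                return "TARGET_EXON_DELETION"
            oversized_insert = True

    for ev in events:
        if ev.span >= sv_min and not contains(ev, target):
            return "LARGE_SV"

    def site_hit(cut: int) -> bool:
        lo, hi = cut - site_window, cut + site_window
        for ev in events:
            if ev.interval.start <= hi and ev.interval.end >= lo:
                if _anchored(ev.interval.start, ev.interval.end, cut, anchor_tol, False):
                    return True
        for ins in insertions:
            if lo <= ins.ref_pos <= hi and _anchored(
                ins.ref_pos, ins.ref_pos, cut, anchor_tol, True
            ):
                return True
        return False

    hit1, hit2 = site_hit(cut1), site_hit(cut2)
    if hit1 and hit2:
        return "BOTH_SITES_INDEL"
    if hit1:
        return "SITE1_INDEL"
    if hit2:
        return "SITE2_INDEL"
    if oversized_insert:
        return "UNCLASSIFIED"

    # any remaining event that swallows a non-target exon is real but odd
    for ev in events:
        if any(contains(ev, ex) for ex in model.exons):
            return "UNCLASSIFIED"
    return "UNEDITED"


def call_read(
    aln: ReadAlignment,
    pair: GuidePair,
    model: GeneModel,
    merge_gap: int = 10,
    min_noise_indel: int = 4,
    site_window: int = 10,
    sv_min: int = 200,
    max_target_insert: int = 25,
    anchor_tol: int = 0,
) -> AlleleCall:
    """Extract events and classify one read; attaches the allele signature
    (largest deletion's endpoints plus junction-insert length)."""
    cut1, cut2 = pair.cuts
    windows = ((cut1 - site_window, cut1 + site_window),
               (cut2 - site_window, cut2 + site_window))
    events, insertions = extract_deletions(
        aln, merge_gap=merge_gap, min_noise_indel=min_noise_indel, windows=windows
    )
    category = classify_allele(
        events,
        insertions,
        pair,
        model,
        site_window=site_window,
        sv_min=sv_min,
        max_target_insert=max_target_insert,
        anchor_tol=anchor_tol,
    )
    signature = None
    if events:
        ev = max(events, key=lambda e: e.span)
        signature = (ev.interval.start, ev.interval.end, ev.junction_insert_len)
    elif insertions:
        ins = max(insertions, key=lambda i: i.length)
        signature = (ins.ref_pos, ins.ref_pos, ins.length)
    return AlleleCall(read_id=aln.read_id, category=category, signature=signature)


def summarize_editing(calls: list[AlleleCall]) -> EditingSummary:
    """Frequency partition over the taxonomy, plus headline efficiencies.

    ``total_editing_pct`` counts every category except UNEDITED and
    UNCLASSIFIED; ``exon_deletion_pct`` is the TARGET_EXON_DELETION share.
    """
    if not calls:
        raise ValueError("summarize_editing requires at least one call")
    n = len(calls)
    counts = Counter(c.category for c in calls)
    pct = {cat: 100.0 * counts.get(cat, 0) / n for cat in CATEGORIES}
    total_editing = 100.0 - pct["UNEDITED"] - pct["UNCLASSIFIED"]
    return EditingSummary(
        n_reads=n,
        category_pct=pct,
        total_editing_pct=total_editing,
        exon_deletion_pct=pct["TARGET_EXON_DELETION"],
    )


def top_alleles(
    calls: list[AlleleCall], n: int = 10, collapse_tol: int = 0
) -> list[dict]:
    """Rank distinct allele signatures by frequency.

    Signatures whose deletion endpoints differ by at most ``collapse_tol``
    and whose insert lengths match are collapsed onto the most frequent
    representative.  Rows carry the signature, deletion span, read count and
    percentage; ties are broken by (span, start).
    """
    if not calls:
        raise ValueError("top_alleles requires at least one call")
    total = len(calls)
    counts = Counter(c.signature for c in calls if c.signature is not None)
    # collapse: greedy assignment of rarer signatures onto more frequent ones
    reps: list[tuple[tuple[int, int, int], int]] = []
    for sig, cnt in counts.most_common():
        merged = False
        if collapse_tol > 0:
            for i, (rep, rep_cnt) in enumerate(reps):
                if (
                    sig[2] == rep[2]
                    and abs(sig[0] - rep[0]) <= collapse_tol
                    and abs(sig[1] - rep[1]) <= collapse_tol
                ):
                    reps[i] = (rep, rep_cnt + cnt)
                    merged = True
                    break
        if not merged:
            reps.append((sig, cnt))
    reps.sort(key=lambda t: (-t[1], t[0][1] - t[0][0], t[0][0]))
    rows = []
    for sig, cnt in reps[:n]:
        rows.append(
            {
                "del_start": sig[0],
                "del_end": sig[1],
                "span": sig[1] - sig[0],
                "insert_len": sig[2],
                "reads": cnt,
                "pct": 100.0 * cnt / total,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# input adapters
# ---------------------------------------------------------------------------

_CIGAR_KIND = {
    0: "match",  # M
    1: "insertion",  # I
    2: "deletion",  # D
    3: "splice_gap",  # N
    4: "clip",  # S
    5: None,  # H consumes neither
    7: "match",  # =
    8: "match",  # X
}


def read_alignments_from_sam(path: str):
    """Yield primary :class:`ReadAlignment` records from a SAM/BAM file.

    Secondary and supplementary alignments are skipped (one vote per
    molecule); unmapped reads are ignored.
    """
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            ops = []
            for code, length in rec.cigartuples or ():
                kind = _CIGAR_KIND.get(code)
                if kind is not None:
                    ops.append((kind, length))
            yield ReadAlignment(
                read_id=rec.query_name,
                ref_start=rec.reference_start,
                ops=tuple(ops),
                sequence=rec.query_sequence or "",
            )


def alignment_from_simulated(read) -> ReadAlignment:
    """Adapter from :class:`exciseqc.simulate.SimulatedRead`."""
    kind_map = {"M": "match", "I": "insertion", "D": "deletion", "N": "splice_gap", "S": "clip"}
    ops = tuple((kind_map[op], length) for op, length in read.cigar)
    return ReadAlignment(
        read_id=read.read_id,
        ref_start=read.ref_start,
        ops=ops,
        sequence=read.sequence,
    )
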