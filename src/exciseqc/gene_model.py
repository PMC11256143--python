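"""Genomic context for a dual-guide exon-excision experiment.

Everything downstream of this module (simulation, genotyping, splice
classification) works against a single validated :class:`GeneModel` plus the
guide pair and amplicon designs defined here.

Coordinate convention: 0-based, half-open intervals throughout, matching
BED/SAM arithmetic.  Cas9 cut sites are *inter-base* integers: ``cut == c``
means the blunt cut falls between reference bases ``c-1`` and ``c``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GuideSite",
    "GuidePair",
    "AmpliconDesign",
    "GeneModelError",
    "GuideNotFoundError",
    "AmbiguousGuideError",
    "load_gene_model",
    "locate_guide",
    "expected_blunt_deletion",
    "inframe_removable_exons",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GeneModelError(ValueError):
    """Raised when a gene model, guide or amplicon fails validation."""


class GuideNotFoundError(LookupError):
    """Protospacer (with PAM) not found in the locus on either strand."""


class AmbiguousGuideError(LookupError):
    """Protospacer (with PAM) matches more than one position in the locus."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on ``contig``."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GeneModelError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies entirely within this interval."""
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model on one locus.

    ``exons`` are sorted by genomic start and numbered 1..n in transcription
    order (descending coordinates for a minus-strand gene).  ``coding`` flags
    run parallel to ``exons``.
    """

    gene_id: str
    locus: GenomicInterval
    sequence: str
    exons: tuple[GenomicInterval, ...]
    coding: tuple[bool, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.locus):
            raise GeneModelError(
                f"sequence length {len(self.sequence)} != locus length {len(self.locus)}"
            )
        if not self.exons:
            raise GeneModelError("gene model needs at least one exon")
        if len(self.coding) != len(self.exons):
            raise GeneModelError("coding flags must match exon count")
        prev_end = None
        for ex in self.exons:
            if not self.locus.contains(ex):
                raise GeneModelError(f"exon {ex} outside locus {self.locus}")
            if prev_end is not None and ex.start < prev_end:
                raise GeneModelError("exons overlap or are unsorted")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, number: int) -> GenomicInterval:
        """Exon by 1-based number in transcription order."""
        if not 1 <= number <= self.n_exons:
            raise GeneModelError(f"exon number {number} out of range 1..{self.n_exons}")
        if self.strand == "+":
            return self.exons[number - 1]
        return self.exons[self.n_exons - number]

    def exon_number(self, exon: GenomicInterval) -> int:
        idx = self.exons.index(exon)
        return idx + 1 if self.strand == "+" else self.n_exons - idx

    def slice(self, interval: GenomicInterval) -> str:
        """Locus sequence within ``interval`` (locus coordinates)."""
        off = self.locus.start
        return self.sequence[interval.start - off : interval.end - off]

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.locus.contig, a.end, b.start, self.strand)
                )
        return tuple(out)

    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class GuideSite:
    """One sgRNA target: 20-nt protospacer, PAM, and the blunt cut position."""

    protospacer: str
    pam: str
    strand: str
    protospacer_interval: GenomicInterval
    cut: int

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise GeneModelError("protospacer must be 20 nt")
        if len(self.pam) != 3:
            raise GeneModelError("PAM must be 3 nt")
        if not (
            self.protospacer_interval.start < self.cut < self.protospacer_interval.end
        ):
            raise GeneModelError("cut must lie inside the protospacer interval")


@dataclass(frozen=True)
class GuidePair:
    """Two guides whose cuts flank the target exon (both cuts intronic)."""

    upstream: GuideSite
    downstream: GuideSite
    target_exon: int

    def validate(self, model: GeneModel) -> "GuidePair":
        exon = model.exon(self.target_exon)
        if not (self.upstream.cut < exon.start <= exon.end <= self.downstream.cut):
            raise GeneModelError(
                f"cuts {self.upstream.cut}/{self.downstream.cut} do not flank "
                f"target exon {self.target_exon} [{exon.start}, {exon.end})"
            )
        return self

    @property
    def cuts(self) -> tuple[int, int]:
        return (self.upstream.cut, self.downstream.cut)


@dataclass(frozen=True)
class AmpliconDesign:
    """A PCR amplicon: primer intervals and capture limits.

    ``min_recoverable_length`` models loss of very short products during
    library preparation; products shorter than it are treated as dropped.
    """

    name: str
    fwd_primer: GenomicInterval
    rev_primer: GenomicInterval
    min_recoverable_length: int = 200

    def __post_init__(self):
        if self.fwd_primer.end > self.rev_primer.start:
            raise GeneModelError("forward primer must end before reverse primer starts")

    @property
    def wt_product_length(self) -> int:
        return self.rev_primer.end - self.fwd_primer.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.fwd_primer.contig, self.fwd_primer.start, self.rev_primer.end
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_gene_model(gff3_text: str, fasta_text: str) -> GeneModel:
    """Build a validated :class:`GeneModel` from GFF3 + FASTA documents.

    The GFF3 must describe exactly one gene with at least one exon.  Exons are
    numbered in transcription order.  An exon is flagged coding when it
    overlaps a CDS feature; if the annotation carries no CDS features at all,
    every exon is taken as coding.
    """
    db = gffutils.create_db(
        gff3_text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = list(db.features_of_type("gene"))
    if len(genes) != 1:
        raise GeneModelError(f"expected exactly one gene, found {len(genes)}")
    gene = genes[0]

    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(fasta_text), "fasta")
    }
    if gene.seqid not in seqs:
        raise IOError(f"contig {gene.seqid!r} missing from FASTA")
    sequence = seqs[gene.seqid]

    exon_feats = sorted(
        (f for f in db.features_of_type("exon") if f.seqid == gene.seqid),
        key=lambda f: f.start,
    )
    if not exon_feats:
        raise GeneModelError("gene has no exon features")
    strand = gene.strand if gene.strand in ("+", "-") else "+"
    exons = tuple(
        GenomicInterval(gene.seqid, f.start - 1, f.end, strand) for f in exon_feats
    )
    for ex in exons:
        if ex.end > len(sequence):
            raise GeneModelError(f"exon {ex} outside FASTA sequence bounds")

    cds_feats = list(db.features_of_type("CDS"))
    if cds_feats:
        cds = [GenomicInterval(f.seqid, f.start - 1, f.end) for f in cds_feats]
        coding = tuple(any(ex.overlaps(c) for c in cds) for ex in exons)
    else:
        coding = tuple(True for _ in exons)

    locus = GenomicInterval(gene.seqid, 0, len(sequence), strand)
    return GeneModel(
        gene_id=gene.id, locus=locus, sequence=sequence, exons=exons, coding=coding
    )


def to_gff3(model: GeneModel) -> str:
    """Serialise a gene model as GFF3 (inverse of :func:`load_gene_model`)."""
    lines = ["##gff-version 3"]
    c = model.locus.contig
    gene_start = min(e.start for e in model.exons)
    gene_end = max(e.end for e in model.exons)
    lines.append(
        f"{c}\texciseqc\tgene\t{gene_start + 1}\t{gene_end}\t.\t{model.strand}\t.\t"
        f"ID={model.gene_id}"
    )
    for i, (ex, cod) in enumerate(zip(model.exons, model.coding)):
        num = model.exon_number(ex)
        lines.append(
            f"{c}\texciseqc\texon\t{ex.start + 1}\t{ex.end}\t.\t{model.strand}\t.\t"
            f"ID={model.gene_id}.exon{num};Parent={model.gene_id}"
        )
        if cod:
            lines.append(
                f"{c}\texciseqc\tCDS\t{ex.start + 1}\t{ex.end}\t.\t{model.strand}\t0\t"
                f"ID={model.gene_id}.cds{num};Parent={model.gene_id}"
            )
    return "\n".join(lines) + "\n"


def to_fasta(model: GeneModel, width: int = 80) -> str:
    chunks = [
        model.sequence[i : i + width] for i in range(0, len(model.sequence), width)
    ]
    return f">{model.locus.contig}\n" + "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# Guide arithmetic
# ---------------------------------------------------------------------------


def _pam_regex(pam_rule: str) -> re.Pattern:
    return re.compile(pam_rule.upper().replace("N", "[ACGT]"))


def locate_guide(model: GeneModel, protospacer: str, pam_rule: str = "NGG") -> GuideSite:
    """Locate a protospacer in the locus and place the blunt SpCas9 cut.

    The cut is the inter-base position 3 bp 5' of the PAM, i.e. between
    protospacer positions 17 and 18.  Both strands are searched; the match
    must be unique.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != 20 or set(protospacer) - set("ACGT"):
        raise GeneModelError("protospacer must be 20 nt over A/C/G/T")
    pam_re = _pam_regex(pam_rule)
    seq = model.sequence
    off = model.locus.start
    hits: list[GuideSite] = []

    for m in re.finditer(re.escape(protospacer), seq):
        s = m.start() + off
        pam = seq[m.end() : m.end() + 3]
        if len(pam) == 3 and pam_re.fullmatch(pam):
            hits.append(
                GuideSite(
                    protospacer=protospacer,
                    pam=pam,
                    strand="+",
                    protospacer_interval=GenomicInterval(
                        model.locus.contig, s, s + 20, "+"
                    ),
                    cut=s + 17,
                )
            )
    rc = revcomp(protospacer)
    for m in re.finditer(re.escape(rc), seq):
        s = m.start() + off
        if m.start() < 3:
            continue
        pam = revcomp(seq[m.start() - 3 : m.start()])
        if pam_re.fullmatch(pam):
            hits.append(
                GuideSite(
                    protospacer=protospacer,
                    pam=pam,
                    strand="-",
                    protospacer_interval=GenomicInterval(
                        model.locus.contig, s, s + 20, "-"
                    ),
                    cut=s + 3,
                )
            )

    if not hits:
        raise GuideNotFoundError(f"protospacer {protospacer} not found in locus")
    if len(hits) > 1:
        raise AmbiguousGuideError(
            f"protospacer {protospacer} matches {len(hits)} positions"
        )
    return hits[0]


def expected_blunt_deletion(pair: GuidePair) -> int:
    """Length of the blunt dual-cut deletion, ``downstream.cut - upstream.cut``."""
    length = pair.downstream.cut - pair.upstream.cut
    if length <= 0:
        raise GeneModelError("downstream cut must lie beyond upstream cut")
    return length


def inframe_removable_exons(
    model: GeneModel, exclude_terminal: bool = False
) -> list[int]:
    """Exon numbers removable without a frameshift (length divisible by 3).

    Only coding exons are considered.  ``exclude_terminal`` drops the first
    and last exon of the transcript, which cannot form a chimeric intron.
    """
    out = []
    for num in range(1, model.n_exons + 1):
        if exclude_terminal and num in (1, model.n_exons):
            continue
        ex = model.exon(num)
        idx = model.exons.index(ex)
        if not model.coding[idx]:
            continue
        if len(ex) % 3 == 0:
            out.append(num)
    return out
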