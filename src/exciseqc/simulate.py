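"""Ground-truth-labelled simulation of a dual-guide exon-excision experiment.

The simulator emulates the full measurement chain: NHEJ repair alleles on the
locus, PCR amplicons whose capture depends on intact primer sites and on a
minimum recoverable product length, long-read sequencing errors, and spliced
cDNA reads.  Every read is emitted together with a truth alignment (CIGAR
against the unedited locus) and a truth record, so the downstream classifiers
can be validated without an external aligner.

Error model
-----------
Substitution, insertion and deletion rates are *per-base affected*
probabilities: with defaults (0.02, 0.02, 0.04) the expected fractions of
substituted, inserted and deleted bases are 2%, 2% and 4% of the template.
Indel run lengths are geometric, capped at ``max_error_indel``.  Deletion runs
are placed by a renewal process so that the marginal per-base deletion
probability equals ``del_rate`` exactly (up to O(1/L) edge effects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gene_model import (
    AmpliconDesign,
    GeneModel,
    GeneModelError,
    GenomicInterval,
    GuidePair,
)

__all__ = [
    "OutcomeSpec",
    "ErrorModel",
    "ERROR_FREE",
    "SimTruth",
    "Allele",
    "SimulatedRead",
    "simulate_allele",
    "simulate_amplicon_reads",
    "simulate_cdna_reads",
    "IsoformSpec",
    "derive_allele_category",
    "write_fastq",
    "write_sam",
    "write_truth_tsv",
    "reconstruct_from_cigar",
]

# Repair-outcome categories used by OutcomeSpec
BLUNT_DELETION = "BLUNT_DELETION"
DELETION_PLUS_INSERT = "DELETION_PLUS_INSERT"
SITE1_INDEL = "SITE1_INDEL"
SITE2_INDEL = "SITE2_INDEL"
LARGE_DELETION = "LARGE_DELETION"
UNEDITED = "UNEDITED"

_OUTCOME_CATEGORIES = {
    BLUNT_DELETION,
    DELETION_PLUS_INSERT,
    SITE1_INDEL,
    SITE2_INDEL,
    LARGE_DELETION,
    UNEDITED,
}

_CODE2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE2CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE2CODE[_b] = _i
    _BASE2CODE[_b + 32] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _BASE2CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _CODE2BASE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class OutcomeSpec:
    """One repair outcome in a simulation scenario.

    ``site_indel`` is a signed length for the single-cut categories: negative
    for a deletion spanning the cut, positive for an insertion at the cut.
    ``junction_extend`` widens the dual-cut deletion beyond the blunt
    endpoints (left, right), modelling 1-5 bp junction resection.
    """

    category: str
    frequency: float
    junction_insert: str = ""
    site_indel: int = 0
    sv_interval: GenomicInterval | None = None
    junction_extend: tuple[int, int] = (0, 0)
    name: str = ""

    def __post_init__(self):
        if self.category not in _OUTCOME_CATEGORIES:
            raise ValueError(f"unknown outcome category {self.category!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")
        if self.sv_interval is not None and self.category != LARGE_DELETION:
            raise ValueError("sv_interval is only valid for LARGE_DELETION")
        if self.category == LARGE_DELETION and self.sv_interval is None:
            raise ValueError("LARGE_DELETION requires sv_interval")
        if self.category in (SITE1_INDEL, SITE2_INDEL) and self.site_indel == 0:
            raise ValueError("site indel categories require a nonzero site_indel")


def validate_spec_frequencies(specs: list[OutcomeSpec], tol: float = 1e-9) -> None:
    total = sum(s.frequency for s in specs)
    if abs(total - 1.0) > tol:
        raise ValueError(f"outcome frequencies sum to {total}, expected 1")


@dataclass(frozen=True)
class ErrorModel:
    sub_rate: float = 0.02
    ins_rate: float = 0.02
    del_rate: float = 0.04
    max_error_indel: int = 3
    indel_length_p: float = 0.5  # geometric stop probability for run lengths

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")
        if self.max_error_indel < 1:
            raise ValueError("max_error_indel must be >= 1")
        if not 0.0 < self.indel_length_p <= 1.0:
            raise ValueError("indel_length_p must be in (0, 1]")

    @property
    def mean_indel_length(self) -> float:
        # E[min(Geom(p), cap)] = sum_{k=0}^{cap-1} (1-p)^k
        p, cap = self.indel_length_p, self.max_error_indel
        return sum((1.0 - p) ** k for k in range(cap))

    @property
    def is_error_free(self) -> bool:
        return self.sub_rate == 0 and self.ins_rate == 0 and self.del_rate == 0

    def expected_edit_distance(self, length: int) -> float:
        """Expected edit operations per template of ``length`` bases.

        Substitutions are only visible on retained bases, hence the
        ``(1 - del_rate)`` factor.
        """
        return (
            self.sub_rate * (1.0 - self.del_rate) * length
            + self.ins_rate * (length + 1)
            + self.del_rate * length
        )


ERROR_FREE = ErrorModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimTruth:
    """Truth record for one simulated read."""

    read_id: str
    allele_id: str
    allele_category: str  # AlleleCall taxonomy (genotype module)
    deletion_interval: GenomicInterval | None = None
    junction_insert: str = ""
    isoform_category: str | None = None
    skipped_exons: tuple[int, ...] = ()


@dataclass(frozen=True)
class Allele:
    """An edited locus: reference edits plus derived sequence and truth."""

    allele_id: str
    edits: tuple[tuple[int, int, str], ...]  # (ref_start, ref_end, alt) sorted
    sequence: str
    category: str  # AlleleCall taxonomy
    deletion_interval: GenomicInterval | None
    junction_insert: str
    frequency: float


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    truth: SimTruth


# ---------------------------------------------------------------------------
# allele construction
# ---------------------------------------------------------------------------


def _apply_edits(sequence: str, edits, offset: int = 0) -> str:
    parts = []
    pos = 0
    for s, e, alt in edits:
        s -= offset
        e -= offset
        if s < pos:
            raise ValueError("edits overlap")
        parts.append(sequence[pos:s])
        parts.append(alt)
        pos = e
    parts.append(sequence[pos:])
    return "".join(parts)


def derive_allele_category(
    edits,
    model: GeneModel,
    pair: GuidePair,
    sv_min: int = 200,
    max_target_insert: int = 25,
) -> str:
    """Ground-truth repair category implied by a set of reference edits.

    This mirrors the genotyping taxonomy by plain geometry on the *edits*
    (not on alignments), so it serves as an independent oracle for the
    genotyper's classifier.
    """
    target = model.exon(pair.target_exon)
    dels = [(s, e, alt) for s, e, alt in edits if e > s]
    ins_only = [(s, e, alt) for s, e, alt in edits if e == s and alt]

    def contains_exon(s, e, exon):
        return s <= exon.start and exon.end <= e

    for s, e, alt in dels:
        others = [
            ex for ex in model.exons if ex != target and contains_exon(s, e, ex)
        ]
        if contains_exon(s, e, target):
            if others:
                return "MULTI_EXON_DELETION"
            if len(alt) <= max_target_insert:
                return "TARGET_EXON_DELETION"
            return "UNCLASSIFIED"
    for s, e, alt in dels:
        if e - s >= sv_min and not contains_exon(s, e, target):
            return "LARGE_SV"
    cut1, cut2 = pair.cuts
    hit1 = any(s <= cut1 <= e for s, e, _ in dels + ins_only)
    hit2 = any(s <= cut2 <= e for s, e, _ in dels + ins_only)
    if hit1 and hit2:
        return "BOTH_SITES_INDEL"
    if hit1:
        return "SITE1_INDEL"
    if hit2:
        return "SITE2_INDEL"
    if not edits:
        return "UNEDITED"
    return "UNCLASSIFIED"


def simulate_allele(
    model: GeneModel,
    pair: GuidePair,
    spec: OutcomeSpec,
    rng_seed: int | np.random.Generator = 0,
) -> Allele:
    """Apply one repair outcome to the locus and return the edited allele."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pair.validate(model)
    cut1, cut2 = pair.cuts
    cat = spec.category

    if cat in (BLUNT_DELETION, DELETION_PLUS_INSERT):
        left, right = spec.junction_extend
        if left < 0 or right < 0:
            raise GeneModelError("junction_extend must be non-negative")
        edits = [(cut1 - left, cut2 + right, spec.junction_insert)]
    elif cat in (SITE1_INDEL, SITE2_INDEL):
        cut = cut1 if cat == SITE1_INDEL else cut2
        n = spec.site_indel
        if n < 0:
            k = -n
            s = cut - (k + 1) // 2
            edits = [(s, s + k, "")]
        else:
            ins = spec.junction_insert or _decode(rng.integers(0, 4, n, dtype=np.uint8).astype(np.uint8))
            if len(ins) != n:
                raise GeneModelError("junction_insert length must match site_indel")
            edits = [(cut, cut, ins)]
    elif cat == LARGE_DELETION:
        iv = spec.sv_interval
        if not (iv.start <= cut1 <= iv.end or iv.start <= cut2 <= iv.end):
            raise GeneModelError("LARGE_DELETION interval must overlap a cut site")
        edits = [(iv.start, iv.end, spec.junction_insert)]
    elif cat == UNEDITED:
        edits = []
    else:  # pragma: no cover
        raise GeneModelError(f"unhandled category {cat}")

    for s, e, _ in edits:
        if not (model.locus.start <= s <= e <= model.locus.end):
            raise GeneModelError("edit outside locus")

    sequence = _apply_edits(model.sequence, edits, offset=model.locus.start)
    dels = [(s, e) for s, e, _ in edits if e > s]
    deletion_interval = None
    if dels:
        s, e = max(dels, key=lambda d: d[1] - d[0])
        deletion_interval = GenomicInterval(model.locus.contig, s, e)
    junction_insert = "".join(alt for _, _, alt in edits)
    allele_id = spec.name or cat.lower()
    return Allele(
        allele_id=allele_id,
        edits=tuple(edits),
        sequence=sequence,
        category=derive_allele_category(edits, model, pair),
        deletion_interval=deletion_interval,
        junction_insert=junction_insert,
        frequency=spec.frequency,
    )


# ---------------------------------------------------------------------------
# template construction (error-free read + reference mapping)
# ---------------------------------------------------------------------------


def _edit_disrupts(edit, interval: GenomicInterval) -> bool:
    s, e, alt = edit
    if s < interval.end and e > interval.start:
        return True
    # a pure insertion strictly inside the primer breaks priming too
    return s == e and bool(alt) and interval.start < s < interval.end


def build_amplicon_template(model: GeneModel, allele: Allele, design: AmpliconDesign):
    """Error-free amplicon read for an allele under a PCR design.

    Returns ``(codes, qref)`` or ``None`` when the allele yields no product:
    a primer site is disrupted, or the product is shorter than the design's
    minimum recoverable length.  ``qref[i]`` is the reference coordinate of
    read base ``i`` (-1 for bases inserted relative to the reference).
    """
    for primer in (design.fwd_primer, design.rev_primer):
        if any(_edit_disrupts(ed, primer) for ed in allele.edits):
            return None
    a, b = design.fwd_primer.start, design.rev_primer.end
    off = model.locus.start
    ref = model.sequence

    parts_codes: list[np.ndarray] = []
    parts_qref: list[np.ndarray] = []
    pos = a
    for s, e, alt in allele.edits:
        if e <= a or s >= b:
            continue
        if s < pos:  # pragma: no cover - excluded by primer checks
            raise GeneModelError("edit crosses amplicon boundary")
        if s > pos:
            parts_codes.append(_encode(ref[pos - off : s - off]))
            parts_qref.append(np.arange(pos, s, dtype=np.int64))
        if alt:
            parts_codes.append(_encode(alt))
            parts_qref.append(np.full(len(alt), -1, dtype=np.int64))
        pos = e
    if pos < b:
        parts_codes.append(_encode(ref[pos - off : b - off]))
        parts_qref.append(np.arange(pos, b, dtype=np.int64))

    codes = np.concatenate(parts_codes) if parts_codes else np.empty(0, np.uint8)
    qref = np.concatenate(parts_qref) if parts_qref else np.empty(0, np.int64)
    if len(codes) < design.min_recoverable_length:
        return None
    return codes, qref


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------


def _sample_lengths(rng, n, p, cap):
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.minimum(rng.geometric(p, n), cap).astype(np.int64)


def _deletion_mask(rng, L, em: ErrorModel) -> np.ndarray:
    """Renewal-process deletion mask with exact marginal ``del_rate``."""
    mask = np.zeros(L, dtype=bool)
    d = em.del_rate
    if d == 0 or L == 0:
        return mask
    e_len = em.mean_indel_length
    mean_gap = e_len * (1.0 - d) / d
    q_gap = min(1.0, 1.0 / mean_gap)
    n_ev = int(L * d / e_len + 10.0 * math.sqrt(L * d / e_len + 1.0) + 10.0)
    while True:
        gaps = rng.geometric(q_gap, n_ev)
        lens = _sample_lengths(rng, n_ev, em.indel_length_p, em.max_error_indel)
        starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(lens)[:-1]))
        if starts[-1] >= L:
            break
        n_ev *= 2  # extremely unlikely with the safety margin above
    keep = starts < L
    starts = starts[keep]
    ends = np.minimum(starts + lens[keep], L)
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1]) > 0


def inject_errors(codes: np.ndarray, qref: np.ndarray, em: ErrorModel, rng):
    """Apply the error model to one template read; returns (codes, qref)."""
    L = len(codes)
    if em.is_error_free or L == 0:
        return codes, qref

    del_mask = _deletion_mask(rng, L, em)

    ins_len = np.zeros(L + 1, dtype=np.int64)
    if em.ins_rate > 0:
        q_i = em.ins_rate / em.mean_indel_length
        bmask = rng.random(L + 1) < q_i
        ins_len[bmask] = _sample_lengths(
            rng, int(bmask.sum()), em.indel_length_p, em.max_error_indel
        )

    new_codes = codes
    if em.sub_rate > 0:
        smask = rng.random(L) < em.sub_rate
        n_sub = int(smask.sum())
        if n_sub:
            new_codes = codes.copy()
            new_codes[smask] = (codes[smask] + rng.integers(1, 4, n_sub)) % 4

    kept = ~del_mask
    width = ins_len[:L] + kept
    starts_out = np.zeros(L + 1, dtype=np.int64)
    np.cumsum(width, out=starts_out[1:])
    n_out = int(starts_out[L] + ins_len[L])
    pos_t = starts_out[:L] + ins_len[:L]

    out_qref = np.full(n_out, -1, dtype=np.int64)
    out_codes = np.empty(n_out, dtype=np.uint8)
    kidx = np.flatnonzero(kept)
    p = pos_t[kidx]
    out_qref[p] = qref[kidx]
    out_codes[p] = new_codes[kidx]
    assigned = np.zeros(n_out, dtype=bool)
    assigned[p] = True
    n_ins = n_out - len(kidx)
    if n_ins:
        out_codes[~assigned] = rng.integers(0, 4, n_ins, dtype=np.int64).astype(
            np.uint8
        )
    return out_codes, out_qref


def cigar_from_qref(qref: np.ndarray, splice_min: int | None = None):
    """CIGAR (list of (op, length)) and reference start from a qref mapping.

    Reference gaps of at least ``splice_min`` bases are emitted as N (splice
    gaps); smaller gaps as D.  Read bases with no reference assignment at the
    read ends become soft clips, interior ones insertions.
    """
    is_m = qref >= 0
    mpos = np.flatnonzero(is_m)
    if len(mpos) == 0:
        return None
    mref = qref[mpos]
    L = len(qref)
    ops: list[tuple[str, int]] = []
    lead = int(mpos[0])
    trail = int(L - 1 - mpos[-1])
    if lead:
        ops.append(("S", lead))
    dq = np.diff(mpos)
    dr = np.diff(mref)
    events = np.flatnonzero((dq > 1) | (dr > 1))
    seg_start = 0
    for k in events:
        ops.append(("M", int(k - seg_start + 1)))
        qgap = int(dq[k] - 1)
        rgap = int(dr[k] - 1)
        if qgap > 0:
            ops.append(("I", qgap))
        if rgap > 0:
            op = "N" if splice_min is not None and rgap >= splice_min else "D"
            ops.append((op, rgap))
        seg_start = int(k) + 1
    ops.append(("M", int(len(mpos) - seg_start)))
    if trail:
        ops.append(("S", trail))
    return int(mref[0]), tuple(ops)


def reconstruct_from_cigar(read: SimulatedRead, reference: str, offset: int = 0) -> str:
    """Rebuild the read sequence from its CIGAR, taking M/D from the
    reference and I/S from the read itself.  With zero error rates the result
    must equal the emitted read byte for byte."""
    out = []
    rpos = read.ref_start - offset
    qpos = 0
    for op, length in read.cigar:
        if op == "M":
            out.append(reference[rpos : rpos + length])
            rpos += length
            qpos += length
        elif op in ("I", "S"):
            out.append(read.sequence[qpos : qpos + length])
            qpos += length
        elif op in ("D", "N"):
            rpos += length
        else:  # pragma: no cover
            raise ValueError(f"unexpected op {op}")
    return "".join(out)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_amplicon_reads(
    model: GeneModel,
    alleles: list[Allele],
    design: AmpliconDesign,
    error: ErrorModel = ErrorModel(),
    n_reads: int = 1000,
    rng_seed: int = 0,
    read_prefix: str = "read",
) -> list[SimulatedRead]:
    """Draw amplicon reads from an allele mixture under a PCR design.

    Alleles whose product cannot be amplified or recovered under ``design``
    contribute no reads; the remaining allele frequencies are renormalised
    (PCR samples the amplifiable pool).  Identical seeds and inputs produce
    byte-identical output.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))

    templates = []
    weights = []
    kept_alleles = []
    for al in alleles:
        t = build_amplicon_template(model, al, design)
        if t is None:
            continue
        templates.append(t)
        weights.append(al.frequency)
        kept_alleles.append(al)
    if not templates:
        import warnings

        warnings.warn(
            f"no allele is amplifiable under design {design.name!r}; "
            "emitting zero reads"
        )
        return []
    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(n_reads, probs)

    reads: list[SimulatedRead] = []
    idx = 0
    for al, (codes, qref), n in zip(kept_alleles, templates, counts):
        for _ in range(int(n)):
            c, q = inject_errors(codes, qref, error, rng)
            ref_start, cigar = cigar_from_qref(q)
            rid = f"{read_prefix}{idx:06d}"
            truth = SimTruth(
                read_id=rid,
                allele_id=al.allele_id,
                allele_category=al.category,
                deletion_interval=al.deletion_interval,
                junction_insert=al.junction_insert,
            )
            reads.append(
                SimulatedRead(
                    read_id=rid,
                    sequence=_decode(c),
                    ref_start=ref_start,
                    cigar=cigar,
                    truth=truth,
                )
            )
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# spliced cDNA simulation
# ---------------------------------------------------------------------------

CANONICAL = "CANONICAL"
TARGET_SKIP = "TARGET_SKIP"
OTHER_EXON_SKIP = "OTHER_EXON_SKIP"
INTRON_READTHROUGH = "INTRON_READTHROUGH"

_ISOFORM_CATEGORIES = {CANONICAL, TARGET_SKIP, OTHER_EXON_SKIP, INTRON_READTHROUGH}


@dataclass(frozen=True)
class IsoformSpec:
    """A transcript structure for the cDNA simulator.

    ``skipped_exons`` are exon numbers absent from the mature transcript.
    ``readthrough_after`` names the exon whose 3' end (transcription sense)
    reads through into the adjacent intron by ``readthrough_len`` bases.
    """

    category: str
    skipped_exons: tuple[int, ...] = ()
    readthrough_after: int | None = None

    def __post_init__(self):
        if self.category not in _ISOFORM_CATEGORIES:
            raise ValueError(f"unknown isoform category {self.category!r}")


def _resolve_isoform(label, target_exon: int) -> IsoformSpec:
    if isinstance(label, IsoformSpec):
        return label
    if label == CANONICAL:
        return IsoformSpec(CANONICAL)
    if label == TARGET_SKIP:
        return IsoformSpec(TARGET_SKIP, (target_exon,))
    if label == OTHER_EXON_SKIP:
        return IsoformSpec(OTHER_EXON_SKIP, (target_exon, target_exon + 1))
    if label == INTRON_READTHROUGH:
        return IsoformSpec(
            INTRON_READTHROUGH, (target_exon,), readthrough_after=target_exon - 1
        )
    raise ValueError(f"unknown isoform label {label!r}")


def build_transcript_template(
    model: GeneModel,
    spec: IsoformSpec,
    readthrough_len: int = 0,
):
    """Template (codes, qref) for a spliced transcript read on the plus
    strand of the locus."""
    skipped = set(spec.skipped_exons)
    blocks: list[list[int]] = []
    numbers = []
    for num in range(1, model.n_exons + 1):
        if num in skipped:
            continue
        ex = model.exon(num)
        blocks.append([ex.start, ex.end])
        numbers.append(num)
    if not blocks:
        raise ValueError("isoform retains no exons")
    blocks_sorted = sorted(zip(numbers, blocks), key=lambda t: t[1][0])
    if spec.readthrough_after is not None:
        if readthrough_len <= 0:
            raise ValueError("readthrough isoform needs readthrough_len > 0")
        for num, blk in blocks_sorted:
            if num == spec.readthrough_after:
                if model.strand == "+":
                    blk[1] += readthrough_len
                else:
                    blk[0] -= readthrough_len
                break
        else:
            raise ValueError(
                f"readthrough exon {spec.readthrough_after} is not retained"
            )
    off = model.locus.start
    parts_codes = []
    parts_qref = []
    prev_end = None
    for _, (s, e) in blocks_sorted:
        if prev_end is not None and s < prev_end:
            raise ValueError("readthrough extends into the next retained exon")
        parts_codes.append(_encode(model.sequence[s - off : e - off]))
        parts_qref.append(np.arange(s, e, dtype=np.int64))
        prev_end = e
    return np.concatenate(parts_codes), np.concatenate(parts_qref)


def simulate_cdna_reads(
    model: GeneModel,
    isoform_mix: dict,
    target_exon: int,
    readthrough_len: int = 40,
    error: ErrorModel = ErrorModel(),
    n_reads: int = 1000,
    rng_seed: int = 0,
    splice_min: int = 30,
    read_prefix: str = "cdna",
) -> list[SimulatedRead]:
    """Draw spliced cDNA reads from an isoform mixture.

    Keys of ``isoform_mix`` are :class:`IsoformSpec` objects or taxonomy
    labels (CANONICAL, TARGET_SKIP, OTHER_EXON_SKIP, INTRON_READTHROUGH);
    values are proportions summing to 1.  Truth alignments carry N operations
    at the spliced-out introns.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    props = np.asarray(list(isoform_mix.values()), dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"isoform proportions sum to {props.sum()}, expected 1")
    specs = [_resolve_isoform(k, target_exon) for k in isoform_mix.keys()]
    templates = [
        build_transcript_template(model, sp, readthrough_len) for sp in specs
    ]
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    counts = rng.multinomial(n_reads, props)

    reads: list[SimulatedRead] = []
    idx = 0
    for sp, (codes, qref), n in zip(specs, templates, counts):
        for _ in range(int(n)):
            c, q = inject_errors(codes, qref, error, rng)
            ref_start, cigar = cigar_from_qref(q, splice_min=splice_min)
            rid = f"{read_prefix}{idx:06d}"
            truth = SimTruth(
                read_id=rid,
                allele_id=sp.category.lower(),
                allele_category="",
                isoform_category=sp.category,
                skipped_exons=sp.skipped_exons,
            )
            reads.append(
                SimulatedRead(
                    read_id=rid,
                    sequence=_decode(c),
                    ref_start=ref_start,
                    cigar=cigar,
                    truth=truth,
                )
            )
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_fastq(reads: list[SimulatedRead], path: str, qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual_char * len(r.sequence)}\n")


def write_sam(reads: list[SimulatedRead], model: GeneModel, path: str) -> None:
    """Truth alignments as SAM with an @SQ header for the locus."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": model.locus.contig, "LN": len(model.locus)}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 0
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            out.write(a)


def write_truth_tsv(reads: list[SimulatedRead], path: str) -> None:
    import pandas as pd

    rows = []
    for r in reads:
        t = r.truth
        rows.append(
            {
                "read_id": t.read_id,
                "allele_id": t.allele_id,
                "category": t.allele_category or (t.isoform_category or ""),
                "deletion_start": t.deletion_interval.start
                if t.deletion_interval
                else "",
                "deletion_end": t.deletion_interval.end if t.deletion_interval else "",
                "junction_insert": t.junction_insert,
                "isoform_category": t.isoform_category or "",
                "skipped_exons": ",".join(map(str, t.skipped_exons)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
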