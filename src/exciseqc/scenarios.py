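"""Default synthetic study: locus, guide pair, amplicon designs, mixtures.

The locus is a synthetic 12 kb sequence with a five-exon gene whose target
exon mirrors the geometry of a dual-guide excision experiment on a 63 bp
in-frame exon: the two intronic cuts are 126 bp apart and flank the exon, a
short (~0.9 kb) PCR design spans the exon for routine genotyping, and a
~10 kb long-range design centred on the exon captures large structural
variants that the short design misses.

The default outcome mixtures reproduce the *reported* study conditions:

* short-range genotyping: 89.03% of alleles carry a deletion spanning the
  target exon (predominantly the blunt dual-cut deletion with an AG
  insertion), ~10% small indels at the individual cut sites, ~1% unedited;
* long-range genotyping: 78% target-exon deletion after accounting for large
  deletions (6.36% of alleles at 200-1000 bp, 4.28% at 1-5 kb, 0.25% >5 kb)
  that ablate a short-design primer or shrink the short product below the
  recoverable length (~9.95% of alleles evading short-amplicon capture);
* cDNA: 88.65% of transcripts with the target exon skipped, 4.07% skipping
  additional exons, 0.64% intron read-through, the remainder canonical.

All sequence content is synthetic; only the *structure* of the experiment is
emulated.
"""

from __future__ import annotations

import numpy as np

from .gene_model import (
    AmpliconDesign,
    GeneModel,
    GenomicInterval,
    GuidePair,
    locate_guide,
)
from .simulate import (
    Allele,
    IsoformSpec,
    OutcomeSpec,
    simulate_allele,
    validate_spec_frequencies,
)

__all__ = [
    "default_gene_model",
    "default_guide_pair",
    "short_design",
    "long_design",
    "short_scenario",
    "long_scenario",
    "cdna_mix",
    "build_alleles",
    "rtpcr_primers",
    "TARGET_EXON",
]

CONTIG = "locusA"
LOCUS_LEN = 12_000
TARGET_EXON = 3

# exon intervals (0-based, half-open); target exon 3 is 63 bp = 21 codons
_EXONS = ((1000, 1180), (2300, 2421), (5470, 5533), (7200, 7311), (9500, 9680))

# planted guide geometry: blunt cuts at 5440 and 5566, 126 bp apart
GUIDE_UP = "GATTCAGCTTCGTAACCTGA"  # plus strand, PAM TGG at 5443, cut 5440
GUIDE_DOWN = "CCATACGTTGAGCTTGGACT"  # minus strand, PAM at 5560-5563, cut 5566
_UP_START = 5423
_DOWN_START = 5563

_MODEL_SEED = 713_402_881  # fixed: the locus is a constant of the package


def _build_sequence() -> str:
    rng = np.random.default_rng(_MODEL_SEED)
    seq = rng.integers(0, 4, LOCUS_LEN)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = bases[seq].copy()

    def put(pos: int, s: str):
        arr[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)

    # canonical splice dinucleotides at intron boundaries (cosmetic but keeps
    # the annotation biologically plausible)
    for (s1, e1), (s2, _) in zip(_EXONS, _EXONS[1:]):
        put(e1, "GT")
        put(s2 - 2, "AG")

    put(_UP_START, GUIDE_UP + "TGG")
    from .gene_model import revcomp

    put(_DOWN_START - 3, revcomp("CGG") + revcomp(GUIDE_DOWN))
    return arr.tobytes().decode("ascii")


def default_gene_model() -> GeneModel:
    """The package's synthetic test locus (deterministic)."""
    seq = _build_sequence()
    exons = tuple(GenomicInterval(CONTIG, s, e, "+") for s, e in _EXONS)
    model = GeneModel(
        gene_id="synthgene1",
        locus=GenomicInterval(CONTIG, 0, LOCUS_LEN, "+"),
        sequence=seq,
        exons=exons,
        coding=tuple(True for _ in exons),
    )
    return model


def default_guide_pair(model: GeneModel | None = None) -> GuidePair:
    model = model or default_gene_model()
    up = locate_guide(model, GUIDE_UP)
    down = locate_guide(model, GUIDE_DOWN)
    assert up.cut == 5440 and down.cut == 5566, "planted guide geometry changed"
    return GuidePair(upstream=up, downstream=down, target_exon=TARGET_EXON).validate(
        model
    )


def short_design() -> AmpliconDesign:
    """Routine short-range genotyping amplicon spanning the target exon."""
    return AmpliconDesign(
        name="short",
        fwd_primer=GenomicInterval(CONTIG, 5100, 5125),
        rev_primer=GenomicInterval(CONTIG, 5980, 6005),
        min_recoverable_length=200,
    )


def long_design() -> AmpliconDesign:
    """~10 kb long-range amplicon centred over the target exon."""
    return AmpliconDesign(
        name="long",
        fwd_primer=GenomicInterval(CONTIG, 950, 975),
        rev_primer=GenomicInterval(CONTIG, 10950, 10975),
        min_recoverable_length=200,
    )


def rtpcr_primers() -> tuple[GenomicInterval, GenomicInterval]:
    """In-silico RT-PCR primers in transcript coordinates (exons 1 and 5)."""
    return (
        GenomicInterval("transcript", 10, 32),
        GenomicInterval("transcript", 618, 640),
    )


# ---------------------------------------------------------------------------
# outcome mixtures
# ---------------------------------------------------------------------------


def short_scenario() -> list[OutcomeSpec]:
    """Short-amplicon repair-outcome mixture (bulk-edited keratinocyte-like).

    Target-exon deletions total 89.03%; small single-cut indels ~10%;
    unedited 1.03%.
    """
    return [
        OutcomeSpec("DELETION_PLUS_INSERT", 0.5486, junction_insert="AG", name="del+AG"),
        OutcomeSpec("BLUNT_DELETION", 0.1617, name="blunt"),
        OutcomeSpec("DELETION_PLUS_INSERT", 0.06, junction_insert="A", name="del+A"),
        OutcomeSpec("BLUNT_DELETION", 0.04, junction_extend=(1, 0), name="del-1L"),
        OutcomeSpec("BLUNT_DELETION", 0.04, junction_extend=(0, 2), name="del-2R"),
        OutcomeSpec("BLUNT_DELETION", 0.04, junction_extend=(2, 3), name="del-2L3R"),
        OutcomeSpec("SITE1_INDEL", 0.02, site_indel=-2, name="site1-del2"),
        OutcomeSpec("SITE1_INDEL", 0.0297, site_indel=1, junction_insert="T", name="site1-ins1"),
        OutcomeSpec("SITE2_INDEL", 0.025, site_indel=-3, name="site2-del3"),
        OutcomeSpec("SITE2_INDEL", 0.0247, site_indel=1, junction_insert="C", name="site2-ins1"),
        OutcomeSpec("UNEDITED", 0.0103, name="wt"),
    ]


def _sv_intervals(rng, n, lo, hi, pair, model, spanning=False):
    """Sample large-deletion intervals, log-uniform in [lo, hi].

    One-sided deletions resect outward from one cut (never removing the
    target exon); spanning deletions remove the exon plus flanking introns
    and model the largest events.
    """
    cut1, cut2 = pair.cuts
    out = []
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), n)).astype(int)
    for s in sizes:
        s = int(max(lo, min(s, hi)))
        if spanning:
            extra = s - (cut2 - cut1)
            a = int(extra // 2 + rng.integers(-min(200, extra // 4), min(200, extra // 4) + 1))
            a = max(1, min(a, extra - 1))
            iv = GenomicInterval(model.locus.contig, cut1 - a, cut2 + (extra - a))
        elif rng.random() < 0.5:
            iv = GenomicInterval(model.locus.contig, cut1 - s, cut1)
        else:
            iv = GenomicInterval(model.locus.contig, cut2, cut2 + s)
        out.append(iv)
    return out


def long_scenario(rng_seed: int = 0) -> list[OutcomeSpec]:
    """Long-amplicon mixture with large structural variants.

    Target-exon-only deletions total 78% (76.67% recoverable by the short
    design plus 1.33% whose product is too short to survive processing);
    one-sided/spanning large deletions total 10.89% in the three reported
    size ranges; the rest are single-cut indels and unedited alleles.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 9021]))
    model = default_gene_model()
    pair = default_guide_pair(model)
    cut1, cut2 = pair.cuts

    specs = [
        OutcomeSpec("DELETION_PLUS_INSERT", 0.48, junction_insert="AG", name="del+AG"),
        OutcomeSpec("BLUNT_DELETION", 0.1467, name="blunt"),
        OutcomeSpec("DELETION_PLUS_INSERT", 0.06, junction_insert="A", name="del+A"),
        OutcomeSpec("BLUNT_DELETION", 0.04, junction_extend=(1, 0), name="del-1L"),
        OutcomeSpec("BLUNT_DELETION", 0.04, junction_extend=(0, 2), name="del-2R"),
        OutcomeSpec("SITE1_INDEL", 0.04, site_indel=-2, name="site1-del2"),
        OutcomeSpec("SITE2_INDEL", 0.04, site_indel=1, junction_insert="T", name="site2-ins1"),
        OutcomeSpec("UNEDITED", 0.0311, name="wt"),
    ]

    # 1.33%: deletions spanning only the target exon but so large that the
    # short product (905 - size bp) drops below the recoverable length
    n_drop = 8
    for i in range(n_drop):
        size = int(rng.integers(715, 850))
        extra = size - (cut2 - cut1)
        # keep both short primers intact: start > 5125, end < 5980
        a = int(rng.integers(max(10, size - 540), min(extra - 10, cut1 - 5126)))
        iv = GenomicInterval(model.locus.contig, cut1 - a, cut1 - a + size)
        specs.append(
            OutcomeSpec(
                "LARGE_DELETION", 0.0133 / n_drop, sv_interval=iv, name=f"dropout{i}"
            )
        )

    for label, freq, lo, hi, spanning, n in (
        ("sv_small", 0.0636, 200, 1000, False, 40),
        ("sv_mid", 0.0428, 1001, 4990, False, 30),
        ("sv_large", 0.0025, 5001, 6400, True, 6),
    ):
        for i, iv in enumerate(
            _sv_intervals(rng, n, lo, hi, pair, model, spanning=spanning)
        ):
            specs.append(
                OutcomeSpec(
                    "LARGE_DELETION", freq / n, sv_interval=iv, name=f"{label}{i}"
                )
            )
    validate_spec_frequencies(specs)
    return specs


def cdna_mix() -> dict:
    """Default isoform mixture for the spliced cDNA simulation."""
    t = TARGET_EXON
    return {
        IsoformSpec("TARGET_SKIP", (t,)): 0.8865,
        IsoformSpec("OTHER_EXON_SKIP", (t, t + 1)): 0.0307,
        IsoformSpec("OTHER_EXON_SKIP", (t - 1,)): 0.0100,
        IsoformSpec("INTRON_READTHROUGH", (t,), readthrough_after=t - 1): 0.0064,
        IsoformSpec("CANONICAL"): 0.0664,
    }


def build_alleles(
    model: GeneModel, pair: GuidePair, specs: list[OutcomeSpec], rng_seed: int = 0
) -> list[Allele]:
    """Materialise a scenario's outcome specs into edited alleles."""
    validate_spec_frequencies(specs)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 40_127]))
    return [simulate_allele(model, pair, sp, rng) for sp in specs]
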