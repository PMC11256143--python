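"""Synthetic-data generator: allele edits, read sampling, error model,
determinism and truth consistency."""

import numpy as np
import pytest

from exciseqc.gene_model import GenomicInterval
from exciseqc.simulate import (
    ERROR_FREE,
    ErrorModel,
    OutcomeSpec,
    build_amplicon_template,
    reconstruct_from_cigar,
    simulate_allele,
    simulate_amplicon_reads,
    simulate_cdna_reads,
    write_fastq,
    write_sam,
    write_truth_tsv,
)
from exciseqc.scenarios import (
    TARGET_EXON,
    build_alleles,
    cdna_mix,
    long_scenario,
    short_scenario,
)
from exciseqc.stats import clopper_pearson


class TestSimulateAllele:
    def test_blunt_deletion_length(self, model, pair):
        spec = OutcomeSpec("BLUNT_DELETION", 1.0)
        allele = simulate_allele(model, pair, spec)
        assert len(allele.sequence) == len(model.sequence) - 126
        assert allele.category == "TARGET_EXON_DELETION"
        assert allele.deletion_interval == GenomicInterval("locusA", 5440, 5566)

    def test_deletion_plus_ag_insert_length(self, model, pair):
        spec = OutcomeSpec("DELETION_PLUS_INSERT", 1.0, junction_insert="AG")
        allele = simulate_allele(model, pair, spec)
        assert len(allele.sequence) == len(model.sequence) - 126 + 2
        assert allele.junction_insert == "AG"

    def test_large_deletion_interval_passthrough(self, model, pair):
        iv = GenomicInterval("locusA", 400, 5600)  # overlaps both cuts
        spec = OutcomeSpec("LARGE_DELETION", 1.0, sv_interval=iv)
        allele = simulate_allele(model, pair, spec)
        assert allele.deletion_interval == iv
        assert len(allele.sequence) == len(model.sequence) - 5200

    def test_sv_must_overlap_a_cut(self, model, pair):
        from exciseqc.gene_model import GeneModelError

        iv = GenomicInterval("locusA", 100, 400)
        with pytest.raises(GeneModelError, match="overlap a cut"):
            simulate_allele(model, pair, OutcomeSpec("LARGE_DELETION", 1.0, sv_interval=iv))

    def test_site_indels_touch_their_cut(self, model, pair):
        cut1, cut2 = pair.cuts
        d = simulate_allele(model, pair, OutcomeSpec("SITE1_INDEL", 1.0, site_indel=-3))
        (s, e, alt), = d.edits
        assert s <= cut1 <= e and e - s == 3 and alt == ""
        i = simulate_allele(model, pair, OutcomeSpec("SITE2_INDEL", 1.0, site_indel=2))
        (s, e, alt), = i.edits
        assert s == e == cut2 and len(alt) == 2
        assert d.category == "SITE1_INDEL" and i.category == "SITE2_INDEL"


class TestAmpliconReads:
    def test_error_free_reads_equal_wt_product(self, model, pair, short_design):
        wt = simulate_allele(model, pair, OutcomeSpec("UNEDITED", 1.0))
        reads = simulate_amplicon_reads(
            model, [wt], short_design, ERROR_FREE, n_reads=10, rng_seed=1
        )
        assert len(reads) == 10
        product = model.sequence[
            short_design.fwd_primer.start : short_design.rev_primer.end
        ]
        for r in reads:
            assert r.sequence == product
            assert r.cigar == (("M", len(product)),)
            assert r.ref_start == short_design.fwd_primer.start

    def test_primer_ablating_allele_yields_no_reads(self, model, pair, short_design):
        iv = GenomicInterval("locusA", 5110, 5450)  # covers fwd primer + cut1
        sv = simulate_allele(model, pair, OutcomeSpec("LARGE_DELETION", 1.0, sv_interval=iv))
        with pytest.warns(UserWarning, match="no allele is amplifiable"):
            reads = simulate_amplicon_reads(
                model, [sv], short_design, ERROR_FREE, n_reads=10, rng_seed=1
            )
        assert reads == []

    def test_unamplifiable_allele_excluded_from_mixture(self, model, pair, short_design):
        iv = GenomicInterval("locusA", 5110, 5450)
        sv = simulate_allele(
            model, pair, OutcomeSpec("LARGE_DELETION", 0.5, sv_interval=iv, name="sv")
        )
        wt = simulate_allele(model, pair, OutcomeSpec("UNEDITED", 0.5, name="wt"))
        reads = simulate_amplicon_reads(
            model, [sv, wt], short_design, ERROR_FREE, n_reads=50, rng_seed=1
        )
        assert len(reads) == 50
        assert {r.truth.allele_id for r in reads} == {"wt"}

    def test_determinism_byte_identical(self, model, pair, short_design, tmp_path):
        alleles = build_alleles(model, pair, short_scenario(), rng_seed=7)
        outs = []
        for rep in range(2):
            reads = simulate_amplicon_reads(
                model, alleles, short_design, ErrorModel(), n_reads=300, rng_seed=11
            )
            fq = tmp_path / f"r{rep}.fastq"
            sam = tmp_path / f"r{rep}.sam"
            tsv = tmp_path / f"r{rep}.tsv"
            write_fastq(reads, str(fq))
            write_sam(reads, model, str(sam))
            write_truth_tsv(reads, str(tsv))
            outs.append((fq.read_bytes(), sam.read_bytes(), tsv.read_bytes()))
        assert outs[0] == outs[1]

    def test_truth_consistency_zero_error(self, model, pair, long_design):
        """CIGAR + reference reproduces each error-free read exactly."""
        alleles = build_alleles(model, pair, long_scenario(3), rng_seed=3)
        reads = simulate_amplicon_reads(
            model, alleles, long_design, ERROR_FREE, n_reads=400, rng_seed=5
        )
        for r in reads:
            assert reconstruct_from_cigar(r, model.sequence) == r.sequence

    def test_cigar_query_length_consistency_with_errors(self, model, pair, short_design):
        alleles = build_alleles(model, pair, short_scenario(), rng_seed=2)
        reads = simulate_amplicon_reads(
            model, alleles, short_design, ErrorModel(), n_reads=200, rng_seed=6
        )
        for r in reads:
            qlen = sum(n for op, n in r.cigar if op in ("M", "I", "S"))
            assert qlen == len(r.sequence)

    def test_frequency_fidelity(self, model, pair, short_design):
        """Realized allele fractions lie in the exact binomial 99.9% CI of the
        specified frequencies at n = 10,000."""
        alleles = build_alleles(model, pair, short_scenario(), rng_seed=1)
        reads = simulate_amplicon_reads(
            model, alleles, short_design, ERROR_FREE, n_reads=10_000, rng_seed=9
        )
        from collections import Counter

        counts = Counter(r.truth.allele_id for r in reads)
        for al in alleles:
            k = counts.get(al.allele_id, 0)
            lo, hi = clopper_pearson(k, len(reads), conf=0.999)
            assert lo <= al.frequency <= hi, (al.allele_id, k, al.frequency)

    def test_mean_edit_distance_matches_error_model(self, model, pair, short_design):
        """Injected error mass ~ 8% of template length, cross-checked with a
        direct edit-distance oracle (edlib).

        Expected ops per template: sub_rate*(1-del_rate)*L visible
        substitutions + ins_rate*(L+1) inserted + del_rate*L deleted bases
        (~0.079*L at the default 0.02/0.02/0.04 rates).  The injected count is
        re-derived per read by walking the emitted alignment against the
        reference and must match the expectation to 3 standard errors.  The
        *minimal* edit distance computed by edlib is bounded above by the
        injected count and runs only slightly below it (independent errors
        occasionally collide and re-align more cheaply).
        """
        import edlib

        em = ErrorModel(0.02, 0.02, 0.04)
        wt = simulate_allele(model, pair, OutcomeSpec("UNEDITED", 1.0))
        tseq = model.sequence[
            short_design.fwd_primer.start : short_design.rev_primer.end
        ]
        L = len(tseq)
        reads = simulate_amplicon_reads(
            model, [wt], short_design, em, n_reads=2000, rng_seed=13
        )

        def injected_ops(read):
            """Subs + inserted + deleted bases, from the truth alignment."""
            n = 0
            rpos, qpos = read.ref_start, 0
            for op, length in read.cigar:
                if op == "M":
                    ref_seg = model.sequence[rpos : rpos + length]
                    qry_seg = read.sequence[qpos : qpos + length]
                    n += sum(a != b for a, b in zip(ref_seg, qry_seg))
                    rpos += length
                    qpos += length
                elif op in ("I", "S"):
                    n += length
                    qpos += length
                elif op in ("D", "N"):
                    n += length
                    rpos += length
            return n

        injected = np.array([injected_ops(r) for r in reads], float)

        def aligned_ref(read):
            span = sum(n for op, n in read.cigar if op in ("M", "D", "N"))
            return model.sequence[read.ref_start : read.ref_start + span]

        minimal = np.array(
            [
                edlib.align(r.sequence, aligned_ref(r))["editDistance"]
                for r in reads
            ],
            float,
        )
        expected = em.expected_edit_distance(L)
        se = injected.std(ddof=1) / np.sqrt(len(injected))
        assert abs(injected.mean() - expected) <= 3 * se, (injected.mean(), expected)
        assert (minimal <= injected).all()
        assert minimal.mean() >= 0.85 * injected.mean()


class TestCdnaReads:
    def test_pure_target_skip_reads(self, model):
        reads = simulate_cdna_reads(
            model, {"TARGET_SKIP": 1.0}, target_exon=TARGET_EXON,
            error=ERROR_FREE, n_reads=5, rng_seed=1,
        )
        expected = "".join(
            model.slice(model.exon(n)) for n in (1, 2, 4, 5)
        )
        for r in reads:
            assert r.sequence == expected
            assert sum(1 for op, _ in r.cigar if op == "N") == 3

    def test_mix_proportions_must_sum_to_one(self, model):
        with pytest.raises(ValueError, match="sum"):
            simulate_cdna_reads(
                model, {"TARGET_SKIP": 0.6, "CANONICAL": 0.3},
                target_exon=TARGET_EXON, n_reads=10,
            )

    def test_unknown_label_rejected(self, model):
        with pytest.raises(ValueError, match="unknown"):
            simulate_cdna_reads(
                model, {"NOT_A_LABEL": 1.0}, target_exon=TARGET_EXON, n_reads=10
            )

    def test_fifty_fifty_split(self, model):
        reads = simulate_cdna_reads(
            model,
            {"CANONICAL": 0.5, "OTHER_EXON_SKIP": 0.5},
            target_exon=TARGET_EXON,
            error=ERROR_FREE,
            n_reads=2000,
            rng_seed=2,
        )
        n_canon = sum(r.truth.isoform_category == "CANONICAL" for r in reads)
        lo, hi = clopper_pearson(n_canon, len(reads), conf=0.999)
        assert lo <= 0.5 <= hi

    def test_truth_consistency_zero_error(self, model):
        reads = simulate_cdna_reads(
            model, cdna_mix(), target_exon=TARGET_EXON, error=ERROR_FREE,
            n_reads=100, rng_seed=3,
        )
        for r in reads:
            assert reconstruct_from_cigar(r, model.sequence) == r.sequence
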