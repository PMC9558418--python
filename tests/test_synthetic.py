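"""Generator contracts: determinism, truth consistency, format validity."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from neoenhancer import synthetic as syn
from neoenhancer.annotate import PromoterWindow, classify_context, flag_bound
from neoenhancer.msat import RepeatUnit, scan_genome
from neoenhancer import io as nio


class TestMakeGenome:
    def test_planted_run_verbatim(self):
        spec = syn.GenomeSpec(
            lengths={"chr1": 5000}, planted=(syn.PlantedRun("chr1", 1000, 25),)
        )
        seqs, truth = syn.make_genome(spec, seed=1)
        assert seqs["chr1"][1000:1100] == "GGAA" * 25
        assert truth.planted_runs[0].repeat_count == 25

    def test_minus_strand_planted_as_revcomp(self):
        spec = syn.GenomeSpec(
            lengths={"chr1": 2000}, planted=(syn.PlantedRun("chr1", 500, 6, "-"),)
        )
        seqs, _ = syn.make_genome(spec, seed=1)
        assert seqs["chr1"][500:524] == "TTCC" * 6

    def test_seed_determinism_byte_identical(self, tmp_path):
        spec = syn.GenomeSpec(
            lengths={"chr1": 20_000}, planted=(syn.PlantedRun("chr1", 100, 8),)
        )
        digests = []
        for _ in range(2):
            seqs, _ = syn.make_genome(spec, seed=7)
            p = tmp_path / "g.fa"
            nio.write_fasta(seqs, p)
            digests.append(hashlib.sha256(p.read_bytes()).hexdigest())
        assert digests[0] == digests[1]

    def test_different_seeds_differ(self):
        spec = syn.GenomeSpec(lengths={"chr1": 5000})
        assert syn.make_genome(spec, seed=1)[0] != syn.make_genome(spec, seed=2)[0]

    def test_oracle_union_equals_truth(self, small_genome):
        seqs, truth = small_genome
        expected = {
            (h.chrom, h.start, h.end, h.strand, h.repeat_count)
            for h in truth.all_runs
        }
        scanned = set()
        for chrom, seq in seqs.items():
            for h in syn.oracle_scan(seq, min_repeats=1, chrom=chrom):
                scanned.add((h.chrom, h.start, h.end, h.strand, h.repeat_count))
        assert scanned == expected

    def test_planted_and_accidental_disjoint(self, small_genome):
        _, truth = small_genome
        by_chrom = {}
        for h in truth.all_runs:
            for s, e in by_chrom.get((h.chrom, h.strand), []):
                assert h.end <= s or e <= h.start or (s, e) == (h.start, h.end)
            by_chrom.setdefault((h.chrom, h.strand), []).append((h.start, h.end))

    def test_scanner_matches_generator_truth(self, small_genome):
        seqs, truth = small_genome
        hits = scan_genome(seqs, RepeatUnit("GGAA", 1))
        got = {(h.chrom, h.start, h.end, h.strand, h.repeat_count) for h in hits}
        want = {(h.chrom, h.start, h.end, h.strand, h.repeat_count) for h in truth.all_runs}
        assert got == want

    def test_overlapping_planted_rejected_naming_pair(self):
        spec = syn.GenomeSpec(
            lengths={"chr1": 5000},
            planted=(syn.PlantedRun("chr1", 100, 10), syn.PlantedRun("chr1", 120, 10)),
        )
        with pytest.raises(ValueError, match="overlapping planted runs"):
            syn.make_genome(spec, seed=1)

    def test_out_of_bounds_planted_rejected(self):
        spec = syn.GenomeSpec(
            lengths={"chr1": 50}, planted=(syn.PlantedRun("chr1", 30, 10),)
        )
        with pytest.raises(ValueError, match="bounds"):
            syn.make_genome(spec, seed=1)

    def test_gc_content_approximate(self):
        spec = syn.GenomeSpec(lengths={"chr1": 200_000}, gc=0.6)
        seqs, _ = syn.make_genome(spec, seed=3)
        gc = sum(c in "GC" for c in seqs["chr1"]) / len(seqs["chr1"])
        assert gc == pytest.approx(0.6, abs=0.01)


class TestMakeAnnotation:
    def test_promoter_pin_49bp(self, small_genome):
        _, truth = small_genome
        run = truth.planted_runs[0]
        pin = syn.LayoutPin(run=run, context="promoter_proximal", gap=49)
        genes = syn.make_annotation(5, truth.genome_length, seed=2, layout=[pin])
        a = classify_context(run, genes)
        assert a.context == "promoter_proximal"
        assert a.interval_bp == 49

    @pytest.mark.parametrize("context", ["exonic", "intronic", "intergenic"])
    def test_context_pins_honored(self, context, small_genome):
        _, truth = small_genome
        run = truth.planted_runs[0]
        pin = syn.LayoutPin(run=run, context=context)
        genes = syn.make_annotation(0, truth.genome_length, seed=2, layout=[pin])
        assert classify_context(run, genes).context == context

    def test_minus_strand_promoter_pin(self, small_genome):
        _, truth = small_genome
        run = truth.planted_runs[1]  # enough upstream room for a minus-strand gene
        pin = syn.LayoutPin(run=run, context="promoter_proximal", gene_strand="-", gap=49)
        genes = syn.make_annotation(0, truth.genome_length, seed=2, layout=[pin])
        a = classify_context(run, genes)
        assert a.context == "promoter_proximal"
        assert a.interval_bp == 49

    def test_unsatisfiable_promoter_gap_errors(self, small_genome):
        _, truth = small_genome
        pin = syn.LayoutPin(
            run=truth.planted_runs[0], context="promoter_proximal", gap=1500
        )
        with pytest.raises(ValueError, match="unsatisfiable layout"):
            syn.make_annotation(0, truth.genome_length, seed=2, layout=[pin])

    def test_minus_strand_tss_convention(self):
        genes = syn.make_annotation(30, {"chr1": 500_000}, seed=9)
        for g in genes:
            if g.strand == "-":
                assert g.tss == g.end - 1
            else:
                assert g.tss == g.start

    def test_gff3_round_trip(self, tmp_path):
        genes = syn.make_annotation(50, {"chr1": 800_000, "chr2": 400_000}, seed=4)
        path = tmp_path / "genes.gff3"
        nio.write_gff3(genes, path)
        back = nio.read_gff3(path)
        key = lambda g: g.gene_id
        assert sorted(back, key=key) == sorted(genes, key=key)


class TestMakePeaks:
    def test_full_coverage(self, small_genome):
        _, truth = small_genome
        peaks, bound = syn.make_peaks(truth, bound_fraction=1.0, seed=1)
        flags = flag_bound(truth.all_runs, peaks)
        assert all(flags)
        assert len(bound) == len(truth.all_runs)

    def test_zero_coverage(self, small_genome):
        _, truth = small_genome
        peaks, bound = syn.make_peaks(truth, bound_fraction=0.0, seed=1)
        assert peaks == [] and bound == []
        assert not any(flag_bound(truth.all_runs, peaks))

    def test_exact_half_count(self):
        spec = syn.GenomeSpec(
            lengths={"chr1": 400_000},
            planted=tuple(
                syn.PlantedRun("chr1", 2000 + 5000 * i, 5) for i in range(40)
            ),
            gc=0.5,
        )
        _, truth = syn.make_genome(spec, seed=5)
        # 40 planted runs at fraction 0.5 -> exactly 20 bound
        peaks, bound = syn.make_peaks(truth, 0.5, seed=6, planted_only=True)
        assert len(bound) == 20
        peaks_all, bound_all = syn.make_peaks(truth, bound_fraction=0.5, seed=6)
        assert len(bound_all) == round(0.5 * len(truth.all_runs))

    def test_flags_equal_truth_with_jitter(self, small_genome):
        _, truth = small_genome
        runs = truth.all_runs
        for jitter in (0, 5, 20):
            peaks, bound = syn.make_peaks(truth, 0.5, jitter=jitter, seed=8)
            flags = flag_bound(runs, peaks)
            got = {(h.chrom, h.start, h.strand) for h, f in zip(runs, flags) if f}
            assert got == {(h.chrom, h.start, h.strand) for h in bound}

    def test_excessive_jitter_rejected(self, small_genome):
        _, truth = small_genome
        with pytest.raises(ValueError, match="jitter"):
            syn.make_peaks(truth, 0.5, jitter=50, seed=1, extension=50)

    def test_bad_fraction_rejected(self, small_genome):
        _, truth = small_genome
        with pytest.raises(ValueError, match="bound_fraction"):
            syn.make_peaks(truth, 1.5, seed=1)


class TestMakeExpression:
    def test_paper_scale_dimensions(self):
        truth = syn.ExpressionTruth(n_background_genes=5)
        mat, labels = syn.make_expression(truth, seed=1)
        assert mat.shape[1] == 978  # 50 tumor + 928 normal
        assert (labels == "EwS").sum() == 50
        assert labels.nunique() == 71  # 70 tissues + tumor

    def test_tissue_sizes_sum(self):
        sizes = syn.default_tissue_sizes()
        assert sum(sizes.values()) == 928
        assert len(sizes) == 70

    def test_planted_shift_construction(self):
        truth = syn.ExpressionTruth(
            planted_genes={"T": 4.0},
            n_tumor=200,
            tissue_sizes=syn.default_tissue_sizes(5, 500),
            noise_sd=0.5,
            n_background_genes=3,
        )
        mat, labels = syn.make_expression(truth, seed=2)
        tumor_mean = mat.loc["T", labels == "EwS"].mean()
        normal_mean = mat.loc["T", labels != "EwS"].mean()
        assert tumor_mean - normal_mean == pytest.approx(4.0, abs=0.2)

    def test_duplicate_gene_ids_error(self):
        truth = syn.ExpressionTruth(
            planted_genes={"gene_00001": 2.0}, n_background_genes=5,
            tissue_sizes=syn.default_tissue_sizes(3, 12),
        )
        with pytest.raises(ValueError, match="duplicate"):
            syn.make_expression(truth, seed=1)

    def test_effect_must_be_positive(self):
        with pytest.raises(ValueError, match="> 0"):
            syn.ExpressionTruth(planted_genes={"T": -1.0})

    def test_determinism(self):
        truth = syn.ExpressionTruth(
            n_background_genes=10, tissue_sizes=syn.default_tissue_sizes(3, 12)
        )
        m1, _ = syn.make_expression(truth, seed=5)
        m2, _ = syn.make_expression(truth, seed=5)
        pd.testing.assert_frame_equal(m1, m2)


class TestMakeDoseResponse:
    def test_noiseless_midpoint(self):
        truth = syn.DoseResponseTruth(e=0.4, noise_sd=0.0, doses=(0.1, 0.4, 1.0, 10.0))
        df = syn.make_dose_response(truth, seed=1)
        at_e = df.loc[df["dose"] == 0.4, "response"]
        assert np.allclose(at_e, 0.5)

    def test_noiseless_asymptotes(self):
        truth = syn.DoseResponseTruth(
            e=0.4, noise_sd=0.0, doses=(1e-8, 0.4, 1e8)
        )
        df = syn.make_dose_response(truth, seed=1)
        assert df.loc[df["dose"] == 1e-8, "response"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert df.loc[df["dose"] == 1e8, "response"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_vehicle_rows_present(self):
        df = syn.make_dose_response(syn.DoseResponseTruth(), seed=1)
        assert (df["dose"] == 0).sum() == 4  # one per replicate

    def test_row_count(self):
        truth = syn.DoseResponseTruth(replicates=3)
        df = syn.make_dose_response(truth, seed=1, vehicle=False)
        assert len(df) == 3 * len(truth.doses)

    def test_invalid_truths(self):
        with pytest.raises(ValueError, match="ed50"):
            syn.DoseResponseTruth(e=-1)
        with pytest.raises(ValueError, match="positive"):
            syn.DoseResponseTruth(doses=(0.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="sorted"):
            syn.DoseResponseTruth(doses=(2.0, 1.0, 3.0))

    def test_fitter_recovers_planted(self):
        from neoenhancer.doseresponse import DoseResponseData, fit_ll3

        df = syn.make_dose_response(syn.DoseResponseTruth(e=0.4), seed=3)
        fit = fit_ll3(DoseResponseData(df["dose"].to_numpy(), df["response"].to_numpy()))
        assert fit.e == pytest.approx(0.4, rel=0.10)
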