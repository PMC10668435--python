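"""SAM parsing, per-feature pileup coverage, and splicing-efficiency estimators."""

import numpy as np
import pytest

from conftest import binomial_3se, write_sam
from splicemyco.annotation import Intron
from splicemyco.retention import (
    AlignedRead,
    FeatureError,
    NoCoverageError,
    NoInformativeReadsError,
    efficiency_from_coverage,
    efficiency_from_junctions,
    feature_coverage,
    read_sam,
)


def make_intron(start, end, strand="+", seq_id="chr1"):
    return Intron(
        transcript_id="t", gene_id="g", index=1, seq_id=seq_id,
        strand=strand, start=start, end=end,
    )


class TestReadSam:
    def test_unmapped_and_secondary_excluded(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [
                ("r1", 0, 10, "20M"),
                ("r2", 4, 0, "*"),      # unmapped
                ("r3", 256, 10, "20M"),  # secondary
                ("r4", 2048, 10, "20M"),  # supplementary
            ],
        )
        (reads,) = read_sam(sam).values()
        assert [r.read_id for r in reads] == ["r1"]

    def test_junction_read_reference_span(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 1, "50M100N50M")])
        (reads,) = read_sam(sam).values()
        assert reads[0].reference_span == 200

    def test_unsupported_cigar_op_rejected_with_warning(self, tmp_path, caplog):
        sam = write_sam(
            tmp_path / "a.sam",
            [("r1", 0, 10, "10M5H"), ("r2", 0, 10, "10M")],
        )
        with caplog.at_level("WARNING"):
            (reads,) = read_sam(sam).values()
        assert [r.read_id for r in reads] == ["r2"]
        assert any("unsupported CIGAR" in r.message for r in caplog.records)

    def test_read_group_tags_define_replicates(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [("r1", 0, 10, "10M", "rep1"), ("r2", 0, 10, "10M", "rep2"),
             ("r3", 0, 30, "10M", "rep1")],
            read_groups=("rep1", "rep2"),
        )
        reads = read_sam(sam)
        assert {k: len(v) for k, v in reads.items()} == {"rep1": 2, "rep2": 1}

    def test_generator_read_count_matches_manifest(self, tmp_path):
        from splicemyco import annotation, simulate

        rng = np.random.default_rng(3)
        genome = annotation.GenomeSequence(
            "c", "".join(rng.choice(list("ACGT"), size=1500))
        )
        model = annotation.TranscriptModel(
            "t", "g", "c", "+", [(101, 400), (501, 900)]
        )
        spec = simulate.ReadSimSpec(depth=5, retention=0.3, seed=9, n_replicates=2)
        result = simulate.simulate_reads(
            genome, model, spec,
            out_sam=tmp_path / "sim.sam",
            out_manifest=tmp_path / "sim.manifest.tsv",
        )
        reads = read_sam(result.sam_path)
        assert sum(len(v) for v in reads.values()) == result.n_reads
        n_manifest = sum(
            1 for _ in open(result.manifest_path)
        ) - 1  # header
        assert n_manifest == result.n_reads


class TestFeatureCoverage:
    def test_exact_single_read_depth_one(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 11, "10M")])
        rows = feature_coverage(read_sam(sam), [("exon", "chr1", 11, 20)])
        assert rows[0].coverage == 1.0
        assert rows[0].sd == 0.0  # single replicate

    def test_skipped_intron_contributes_no_depth(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 6, "5M10N5M")])
        rows = feature_coverage(read_sam(sam), [("intron", "chr1", 11, 20)])
        assert rows[0].coverage == 0.0

    def test_deletion_counts_softclip_does_not(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 11, "3S5M2D5M4S")])
        rows = feature_coverage(read_sam(sam), [("f", "chr1", 11, 22)])
        # M(11-15) D(16-17) M(18-22): all 12 bases covered once
        assert rows[0].coverage == 1.0

    def test_matches_brute_force_pileup_oracle(self, retention_pipeline, tmp_path):
        from splicemyco import annotation, simulate
        from splicemyco.retention import read_sam as _read_sam

        rng = np.random.default_rng(11)
        genome = annotation.GenomeSequence(
            "c", "".join(rng.choice(list("ACGT"), size=1200))
        )
        model = annotation.TranscriptModel(
            "t", "g", "c", "+", [(51, 250), (401, 600), (801, 1000)]
        )
        spec = simulate.ReadSimSpec(depth=8, retention=0.3, seed=13, n_replicates=3)
        sam = tmp_path / "sim.sam"
        simulate.simulate_reads(genome, model, spec, out_sam=sam)
        reads = _read_sam(sam)
        features = [
            (fid, "c", s, e) for fid, s, e in annotation.feature_intervals(model)
        ]
        rows = feature_coverage(reads, features)

        # independent per-base tally: expand every read's M/D ops base by base
        def oracle_depth(replicate_reads, start, end):
            depth = {pos: 0 for pos in range(start, end + 1)}
            for read in replicate_reads:
                pos = read.pos
                for op, n in read.cigar:
                    if op in ("M", "D"):
                        for p in range(pos, pos + n):
                            if start <= p <= end:
                                depth[p] += 1
                        pos += n
                    elif op == "N":
                        pos += n
            return sum(depth.values()) / len(depth)

        for row in rows:
            means = []
            for rep in sorted(reads):
                expected = oracle_depth(reads[rep], row.start, row.end)
                assert row.per_replicate[rep] == pytest.approx(expected)
                means.append(expected)
            assert row.coverage == pytest.approx(np.mean(means))
            assert row.sd == pytest.approx(np.std(means, ddof=1))

    def test_pileup_conservation(self, tmp_path):
        """Total depth over the reference equals total aligned M bases."""
        from splicemyco import annotation, simulate

        rng = np.random.default_rng(21)
        genome = annotation.GenomeSequence(
            "c", "".join(rng.choice(list("ACGT"), size=1200))
        )
        model = annotation.TranscriptModel(
            "t", "g", "c", "+", [(101, 400), (551, 900)]
        )
        spec = simulate.ReadSimSpec(depth=6, retention=0.4, seed=4, n_replicates=1)
        sam = tmp_path / "sim.sam"
        simulate.simulate_reads(genome, model, spec, out_sam=sam)
        reads = read_sam(sam)
        rows = feature_coverage(reads, [("all", "c", 1, 1200)])
        total_depth = rows[0].coverage * rows[0].length
        total_m = sum(
            n for rep in reads.values() for r in rep for op, n in r.cigar
            if op == "M"
        )
        assert total_depth == pytest.approx(total_m)

    def test_zero_length_feature_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 11, "10M")])
        with pytest.raises(FeatureError):
            feature_coverage(read_sam(sam), [("bad", "chr1", 20, 10)])


class TestEfficiencyFromCoverage:
    def test_moderate_retention(self):
        est = efficiency_from_coverage(4.6, [91.8, 109.4])
        assert est.efficiency == pytest.approx(0.9543, abs=5e-5)

    def test_near_complete_splicing(self):
        est = efficiency_from_coverage(0.2, [158.9, 159.3])
        assert est.efficiency == pytest.approx(0.9987, abs=5e-5)

    def test_zero_retention_gives_one(self):
        assert efficiency_from_coverage(0.0, [100.0, 100.0]).efficiency == 1.0

    def test_clamped_to_unit_interval(self):
        assert efficiency_from_coverage(150.0, [100.0, 100.0]).efficiency == 0.0

    def test_zero_flanking_coverage_rejected(self):
        with pytest.raises(NoCoverageError):
            efficiency_from_coverage(1.0, [0.0, 0.0])


class TestEfficiencyFromJunctions:
    def test_hand_classified_reads(self, tmp_path):
        """4 exact-junction reads, 1 boundary-spanning read, and 1 junction
        read with a 2-bp anchor (below min_anchor=3) give 4/5 = 0.8."""
        intron = make_intron(201, 300)
        reads = [
            ("j1", 0, 191, "10M100N10M"),
            ("j2", 0, 195, "6M100N14M"),
            ("j3", 0, 185, "16M100N4M"),
            ("j4", 0, 198, "3M100N17M"),
            ("u1", 0, 195, "20M"),        # spans the donor boundary 200|201
            ("short", 0, 199, "2M100N18M"),  # anchor 2 < 3: uninformative
        ]
        sam = write_sam(tmp_path / "a.sam", reads)
        pooled = [r for v in read_sam(sam).values() for r in v]
        est = efficiency_from_junctions(pooled, intron, min_anchor=3)
        assert est.details == {"spliced": 4, "unspliced": 1, "min_anchor": 3}
        assert est.efficiency == pytest.approx(0.8)

    def test_gap_must_match_intron_exactly(self, tmp_path):
        intron = make_intron(201, 300)
        sam = write_sam(
            tmp_path / "a.sam",
            [("off", 0, 191, "10M99N10M"), ("ok", 0, 191, "10M100N10M")],
        )
        pooled = [r for v in read_sam(sam).values() for r in v]
        est = efficiency_from_junctions(pooled, intron)
        assert est.details["spliced"] == 1

    def test_minus_strand_donor_boundary_is_at_intron_end(self, tmp_path):
        intron = make_intron(201, 300, strand="-")
        # covers genomic 295-314, i.e. the minus-strand donor boundary 300|301
        sam = write_sam(tmp_path / "a.sam", [("u1", 0, 295, "20M")])
        pooled = [r for v in read_sam(sam).values() for r in v]
        est = efficiency_from_junctions(pooled, intron)
        assert est.details["unspliced"] == 1

    def test_all_spliced(self, tmp_path):
        intron = make_intron(201, 300)
        sam = write_sam(
            tmp_path / "a.sam",
            [(f"j{i}", 0, 191, "10M100N10M") for i in range(5)],
        )
        pooled = [r for v in read_sam(sam).values() for r in v]
        assert efficiency_from_junctions(pooled, intron).efficiency == 1.0

    def test_no_informative_reads_rejected(self, tmp_path):
        intron = make_intron(201, 300)
        sam = write_sam(tmp_path / "a.sam", [("far", 0, 500, "20M")])
        pooled = [r for v in read_sam(sam).values() for r in v]
        with pytest.raises(NoInformativeReadsError):
            efficiency_from_junctions(pooled, intron)


class TestEstimatorsOnSimulation:
    def test_both_estimators_recover_truth(self, retention_pipeline):
        r = 0.2
        out = retention_pipeline(r, depth=500, seed=42)
        tol = binomial_3se(r, out["n_informative"])
        assert abs(out["junction"] - (1 - r)) <= tol
        assert abs(out["coverage"] - (1 - r)) <= tol

    def test_fully_spliced_simulation(self, retention_pipeline):
        out = retention_pipeline(0.0, depth=200, seed=7)
        assert out["junction"] == 1.0
        assert out["coverage"] >= 0.99  # edge effects < 0.01

    def test_efficiency_decreases_with_retention(self, retention_pipeline):
        """Mean efficiency over seeds never increases with retention."""
        rates = [0.0, 0.2, 0.5]
        seeds = [101, 202, 303]
        means = {"junction": [], "coverage": []}
        for r in rates:
            outs = [retention_pipeline(r, depth=250, seed=s) for s in seeds]
            for key in means:
                means[key].append(np.mean([o[key] for o in outs]))
        for key, series in means.items():
            assert series[0] >= series[1] >= series[2], (key, series)
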