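import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_fasta(tmp_path):
    """Two-sequence FASTA with a plus- and a minus-strand intron planted.

    chr1: exon (1-10), intron GT..AG (11-30), exon (31-40), plus strand.
    chr2: same layout but the genomic intron reads CT..AC, i.e. a GT-AG
    intron on the minus strand.
    """
    chr1 = "A" * 10 + "GT" + "C" * 16 + "AG" + "A" * 10
    chr2 = "A" * 10 + "CT" + "C" * 16 + "AC" + "A" * 10
    path = tmp_path / "toy.fasta"
    path.write_text(f">chr1\n{chr1}\n>chr2\n{chr2}\n")
    return path


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t1\t40\t.\t+\t.\tID=geneA\n"
        "chr1\ttest\tmRNA\t1\t40\t.\t+\t.\tID=mrnaA;Parent=geneA\n"
        "chr1\ttest\texon\t1\t10\t.\t+\t.\tID=mrnaA.e1;Parent=mrnaA\n"
        "chr1\ttest\texon\t31\t40\t.\t+\t.\tID=mrnaA.e2;Parent=mrnaA\n"
        "chr2\ttest\tgene\t1\t40\t.\t-\t.\tID=geneB\n"
        "chr2\ttest\tmRNA\t1\t40\t.\t-\t.\tID=mrnaB;Parent=geneB\n"
        "chr2\ttest\texon\t1\t10\t.\t-\t.\tID=mrnaB.e1;Parent=mrnaB\n"
        "chr2\ttest\texon\t31\t40\t.\t-\t.\tID=mrnaB.e2;Parent=mrnaB\n"
    )
    return path


def write_sam(path, reads, seq_id="chr1", length=1000, read_groups=()):
    """Write a minimal SAM file. ``reads`` rows: (name, flag, pos, cigar)
    or (name, flag, pos, cigar, rg)."""
    lines = ["@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:{seq_id}\tLN:{length}"]
    for rg in read_groups:
        lines.append(f"@RG\tID:{rg}\tSM:test")
    for row in reads:
        name, flag, pos, cigar = row[:4]
        n_bases = sum(
            int(x) for x, op in _split_cigar(cigar) if op in "MIS"
        ) if cigar != "*" else 0
        seq = "A" * n_bases if n_bases else "*"
        fields = [name, str(flag), seq_id if flag != 4 else "*",
                  str(pos) if flag != 4 else "0", "60" if flag != 4 else "0",
                  cigar, "*", "0", "0", seq, "*"]
        if len(row) == 5:
            fields.append(f"RG:Z:{row[4]}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def _split_cigar(cigar):
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((num, ch))
            num = ""
    return out


def binomial_3se(p, n):
    return 3.0 * np.sqrt(max(p * (1 - p), 1e-12) / n)


@pytest.fixture(scope="session")
def retention_pipeline(tmp_path_factory):
    """Run the full simulate -> SAM -> parse -> estimate pipeline.

    Uses a four-exon transcript and targets its middle intron so both
    flanking exons are interior to the transcript (no coverage ramp-down at
    molecule ends to bias the coverage-ratio estimator).
    """
    from splicemyco import annotation, retention, simulate

    rng = np.random.default_rng(20240901)
    exon_len, intron_len = 300, 150
    exons, cursor = [], 101
    for _ in range(4):
        exons.append((cursor, cursor + exon_len - 1))
        cursor += exon_len + intron_len
    span_end = exons[-1][1]
    residues = "".join(rng.choice(list("ACGT"), size=span_end + 100))
    genome = annotation.GenomeSequence("chrS", residues)
    model = annotation.TranscriptModel("tS", "gS", "chrS", "+", exons)
    target = annotation.derive_introns(model)[1]  # middle intron (index 2)
    base = tmp_path_factory.mktemp("retention_sim")

    def run(retention_rate, depth, seed, n_replicates=1):
        spec = simulate.ReadSimSpec(
            read_length=100, depth=depth, n_replicates=n_replicates,
            retention=retention_rate, seed=seed,
        )
        sam = base / f"r{retention_rate}_{depth}_{seed}.sam"
        simulate.simulate_reads(genome, model, spec, out_sam=sam)
        reads = retention.read_sam(sam)
        pooled = [r for v in reads.values() for r in v]
        features = [
            (fid, model.seq_id, s, e)
            for fid, s, e in annotation.feature_intervals(model)
        ]
        rows = {r.feature_id: r for r in retention.feature_coverage(reads, features)}
        cov_est = retention.efficiency_from_coverage(
            rows["intron2"].coverage,
            [rows["exon2"].coverage, rows["exon3"].coverage],
        )
        jn_est = retention.efficiency_from_junctions(pooled, target, min_anchor=3)
        n_informative = jn_est.details["spliced"] + jn_est.details["unspliced"]
        return {
            "coverage": cov_est.efficiency,
            "junction": jn_est.efficiency,
            "n_informative": n_informative,
        }

    return run
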