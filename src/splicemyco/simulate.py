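"""Synthetic genomes, gene models, spliced/retained reads, and fragment scores.

Every generator emits a ground-truth manifest next to its data so pipeline
estimates can be checked against what was planted. All sampling goes through
``numpy.random.default_rng(seed)``; identical spec + seed gives byte-identical
output files.

The read simulator models uniform fragment sampling: a read is an (isoform,
start) pair drawn uniformly over all start positions of all molecules,
weighted by isoform abundance (per-intron Bernoulli retention). Sampling the
isoform first and the start second would overweight short (fully spliced)
molecules at junctions; the length-weighted draw keeps per-base depth uniform
across isoforms, which is what both splicing-efficiency estimators assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amf import ARBUSCULE_WEIGHTS, INTENSITY_WEIGHTS
from .annotation import (
    GenomeSequence,
    TranscriptModel,
    revcomp,
    write_gff3,
)
from .survey import MOTIF_CLASSES

_KNOWN_PAIRS = {
    "GT-AG": ("GT", "AG"),
    "GC-AG": ("GC", "AG"),
    "AT-AC": ("AT", "AC"),
    "GA-AG": ("GA", "AG"),
}
_BASES = np.array(list("ACGT"))
_TWO_MERS = [a + b for a in "ACGT" for b in "ACGT"]
# all (donor, acceptor) pairs that do not match a named motif class
_OTHER_PAIRS = [
    (d, a)
    for d in _TWO_MERS
    for a in _TWO_MERS
    if (d, a) not in set(_KNOWN_PAIRS.values())
]


class SimulationError(ValueError):
    pass


class ReadLengthError(SimulationError):
    pass


# Default motif frequencies mirror a typical dicot annotation set: GT-AG vastly
# dominant, GC-AG the most common alternative, AT-AC and GA-AG vanishingly rare.
DEFAULT_MOTIF_DISTRIBUTION = {
    "GT-AG": 0.9809,
    "GC-AG": 0.0052,
    "AT-AC": 0.0001,
    "GA-AG": 0.0001,
    "Others": 0.0137,
}


@dataclass
class GenomeSpec:
    """Parameters of a synthetic genome with planted splice motifs."""

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 400)
    motif_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_DISTRIBUTION)
    )
    minus_fraction: float = 0.5
    intergenic: int = 300
    seq_id: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        for name, (lo, hi) in (
            ("exons_per_gene", self.exons_per_gene),
            ("exon_length", self.exon_length),
            ("intron_length", self.intron_length),
        ):
            if lo < 1 or hi < lo:
                raise SimulationError(f"infeasible range for {name}: ({lo}, {hi})")
        if self.exons_per_gene[0] < 1:
            raise SimulationError("genes need at least one exon")
        if self.intron_length[0] < 20:
            raise SimulationError("intron lengths must be >= 20")
        unknown = set(self.motif_distribution) - set(MOTIF_CLASSES)
        if unknown:
            raise SimulationError(f"unknown motif classes {sorted(unknown)}")
        total = sum(self.motif_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"motif probabilities sum to {total}, not 1")
        if not 0.0 <= self.minus_fraction <= 1.0:
            raise SimulationError("minus_fraction outside [0, 1]")


@dataclass
class GenomeBundle:
    genomes: dict[str, GenomeSequence]
    models: list[TranscriptModel]
    manifest: pd.DataFrame
    fasta_path: Path | None = None
    gff3_path: Path | None = None
    manifest_path: Path | None = None


def _sample_pair(label: str, rng: np.random.Generator) -> tuple[str, str]:
    if label in _KNOWN_PAIRS:
        return _KNOWN_PAIRS[label]
    return _OTHER_PAIRS[int(rng.integers(len(_OTHER_PAIRS)))]


def make_genome(
    spec: GenomeSpec, out_dir: str | Path | None = None, prefix: str = "genome"
) -> GenomeBundle:
    """Generate a genome FASTA + GFF3 + ground-truth motif manifest.

    Background sequence is uniform over ACGT; each intron's boundary 2-mers
    are overwritten according to its sampled motif class (reverse-complemented
    and swapped for minus-strand genes, so transcript-orientation extraction
    recovers the planted pair).
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(MOTIF_CLASSES)
    probs = np.array([spec.motif_distribution.get(l, 0.0) for l in labels])

    chrom_parts: list[str] = []
    offset = spec.intergenic  # leading margin
    models: list[TranscriptModel] = []
    manifest_rows: list[dict] = []
    chrom_parts.append("".join(rng.choice(_BASES, size=spec.intergenic)))

    for g in range(spec.n_genes):
        gene_id = f"gene{g + 1}"
        transcript_id = f"mRNA{g + 1}"
        n_exons = int(
            rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1)
        )
        exon_lens = rng.integers(
            spec.exon_length[0], spec.exon_length[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            spec.intron_length[0], spec.intron_length[1] + 1, size=max(n_exons - 1, 0)
        )
        strand = "-" if rng.random() < spec.minus_fraction else "+"
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        gene_seq = rng.choice(_BASES, size=gene_len)

        # local exon/intron layout
        exons_local: list[tuple[int, int]] = []
        introns_local: list[tuple[int, int]] = []
        cursor = 0
        for k, el in enumerate(exon_lens):
            exons_local.append((cursor, cursor + int(el) - 1))
            cursor += int(el)
            if k < n_exons - 1:
                il = int(intron_lens[k])
                introns_local.append((cursor, cursor + il - 1))
                cursor += il

        n_introns = len(introns_local)
        for j, (istart, iend) in enumerate(introns_local):
            label = labels[int(rng.choice(len(labels), p=probs))]
            donor, acceptor = _sample_pair(label, rng)
            if strand == "+":
                gene_seq[istart : istart + 2] = list(donor)
                gene_seq[iend - 1 : iend + 1] = list(acceptor)
            else:
                gene_seq[istart : istart + 2] = list(revcomp(acceptor))
                gene_seq[iend - 1 : iend + 1] = list(revcomp(donor))
            index = j + 1 if strand == "+" else n_introns - j
            manifest_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": transcript_id,
                    "intron_index": index,
                    "seq_id": spec.seq_id,
                    "start": offset + istart + 1,
                    "end": offset + iend + 1,
                    "strand": strand,
                    "motif_class": label,
                    "donor": donor,
                    "acceptor": acceptor,
                }
            )

        models.append(
            TranscriptModel(
                transcript_id=transcript_id,
                gene_id=gene_id,
                seq_id=spec.seq_id,
                strand=strand,
                exons=[(offset + s + 1, offset + e + 1) for s, e in exons_local],
            )
        )
        chrom_parts.append("".join(gene_seq))
        chrom_parts.append("".join(rng.choice(_BASES, size=spec.intergenic)))
        offset += gene_len + spec.intergenic

    residues = "".join(chrom_parts)
    genome = GenomeSequence(spec.seq_id, residues)
    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "gene_id", "transcript_id", "intron_index", "seq_id", "start",
            "end", "strand", "motif_class", "donor", "acceptor",
        ],
    )
    bundle = GenomeBundle({spec.seq_id: genome}, models, manifest)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle.fasta_path = out_dir / f"{prefix}.fasta"
        bundle.gff3_path = out_dir / f"{prefix}.gff3"
        bundle.manifest_path = out_dir / f"{prefix}.manifest.tsv"
        write_fasta({spec.seq_id: genome}, bundle.fasta_path)
        write_gff3(models, bundle.gff3_path)
        manifest.to_csv(bundle.manifest_path, sep="\t", index=False)
    return bundle


def write_fasta(
    genomes: Mapping[str, GenomeSequence], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for seq_id, genome in genomes.items():
            fh.write(f">{seq_id}\n")
            residues = genome.residues
            for i in range(0, len(residues), width):
                fh.write(residues[i : i + width] + "\n")


@dataclass
class ReadSimSpec:
    """Parameters of the spliced/intron-retaining read simulator.

    ``depth`` is the target mean reads/base per replicate over the expressed
    region; replicate totals are jittered by a multiplicative factor drawn
    uniformly from [1 - jitter, 1 + jitter] so cross-replicate s.d. columns
    are nonzero. ``retention`` is the per-intron probability that a molecule
    retains that intron (scalar, or one value per intron in genomic order).
    """

    read_length: int = 100
    depth: float = 50.0
    n_replicates: int = 3
    retention: float | Sequence[float] = 0.05
    replicate_depth_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if self.read_length < 8:
            raise SimulationError("read_length must be >= 8")
        if self.n_replicates < 1:
            raise SimulationError("need at least one replicate")
        if not 0.0 <= self.replicate_depth_jitter < 1.0:
            raise SimulationError("jitter must be in [0, 1)")
        rates = np.atleast_1d(np.asarray(self.retention, dtype=float))
        if np.any((rates < 0) | (rates > 1)):
            raise SimulationError("retention outside [0, 1]")


@dataclass
class ReadSimResult:
    sam_path: Path
    manifest_path: Path | None
    n_reads: int
    n_reads_per_replicate: dict[str, int]
    pattern_counts: dict[tuple[int, ...], int]  # retained intron bitmask -> reads


def _pattern_blocks(
    exons: list[tuple[int, int]],
    introns: list[tuple[int, int]],
    bits: tuple[int, ...],
) -> list[tuple[int, int]]:
    """Genomic blocks of a molecule retaining the flagged introns, merged."""
    blocks = [exons[0]]
    for k, (istart, iend) in enumerate(introns):
        nxt = exons[k + 1]
        if bits[k]:
            blocks[-1] = (blocks[-1][0], nxt[1])  # exon-intron-exon contiguous
        else:
            blocks.append(nxt)
    return blocks


def simulate_reads(
    genome: GenomeSequence,
    model: TranscriptModel,
    spec: ReadSimSpec,
    out_sam: str | Path,
    out_manifest: str | Path | None = None,
) -> ReadSimResult:
    """Simulate spliced / intron-retaining reads for one transcript into SAM.

    Spliced reads carry N operations exactly matching the skipped introns;
    reads through a retained intron align contiguously (pure M). Reads are
    written with an RG tag per replicate; the optional manifest records each
    read's retained introns (transcript-orientation indices).
    """
    exons = model.exons
    introns = [
        (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])
    ]
    k = len(introns)
    rates = np.asarray(spec.retention, dtype=float)
    if rates.ndim == 0:
        rates = np.full(k, float(rates))
    if len(rates) != k:
        raise SimulationError(
            f"{len(rates)} retention values for {k} introns"
        )
    spliced_len = sum(e - s + 1 for s, e in exons)
    if spec.read_length > spliced_len:
        raise ReadLengthError(
            f"read length {spec.read_length} exceeds spliced transcript "
            f"length {spliced_len}"
        )
    intron_lens = np.array([e - s + 1 for s, e in introns], dtype=float)
    rl = spec.read_length
    max_len = spliced_len + int(intron_lens.sum())
    max_starts = max_len - rl + 1
    expected_len = spliced_len + float((rates * intron_lens).sum())

    rng = np.random.default_rng(spec.seed)
    rep_names = [f"rep{i + 1}" for i in range(spec.n_replicates)]
    jit = spec.replicate_depth_jitter
    factors = 1.0 + rng.uniform(-jit, jit, size=spec.n_replicates)
    n_per_rep = {
        rep: max(1, int(round(spec.depth * f * expected_len / rl)))
        for rep, f in zip(rep_names, factors)
    }

    # cache per retention pattern: genomic blocks, molecule sequence, length
    cache: dict[tuple[int, ...], tuple[list[tuple[int, int]], str, int]] = {}

    def molecule(bits: tuple[int, ...]):
        hit = cache.get(bits)
        if hit is None:
            blocks = _pattern_blocks(exons, introns, bits)
            seq = "".join(genome.fetch(s, e) for s, e in blocks)
            hit = (blocks, seq, len(seq))
            cache[bits] = hit
        return hit

    def draw_pattern() -> tuple[int, ...]:
        # length-weighted isoform draw via rejection against the longest molecule
        while True:
            bits = tuple((rng.random(k) < rates).astype(int)) if k else ()
            _, _, length = molecule(bits)
            if rng.random() < (length - rl + 1) / max_starts:
                return bits

    pattern_counts: dict[tuple[int, ...], int] = {}
    manifest_fh = open(out_manifest, "w") if out_manifest is not None else None
    if manifest_fh is not None:
        manifest_fh.write("read_id\treplicate\tretained_introns\tn_retained\n")

    n_introns = k
    with open(out_sam, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unknown\n")
        sam.write(f"@SQ\tSN:{genome.seq_id}\tLN:{len(genome)}\n")
        for rep in rep_names:
            sam.write(f"@RG\tID:{rep}\tSM:simulated\n")
        for rep in rep_names:
            for i in range(n_per_rep[rep]):
                bits = draw_pattern()
                pattern_counts[bits] = pattern_counts.get(bits, 0) + 1
                blocks, mol_seq, mol_len = molecule(bits)
                start = int(rng.integers(mol_len - rl + 1))
                seq = mol_seq[start : start + rl]

                # map molecule offset -> genomic CIGAR
                cigar_parts: list[str] = []
                remaining = rl
                mol_cursor = 0
                pos = None
                prev_block_end = None
                for b_start, b_end in blocks:
                    b_len = b_end - b_start + 1
                    if start >= mol_cursor + b_len:
                        mol_cursor += b_len
                        prev_block_end = b_end
                        continue
                    in_block_offset = max(0, start - mol_cursor)
                    g_start = b_start + in_block_offset
                    if pos is None:
                        pos = g_start
                    elif prev_block_end is not None:
                        gap = b_start - prev_block_end - 1
                        if gap > 0:
                            cigar_parts.append(f"{gap}N")
                    take = min(remaining, b_len - in_block_offset)
                    cigar_parts.append(f"{take}M")
                    remaining -= take
                    mol_cursor += b_len
                    prev_block_end = b_end
                    if remaining == 0:
                        break
                cigar = "".join(cigar_parts)
                read_id = f"{rep}.{i}"
                sam.write(
                    f"{read_id}\t0\t{genome.seq_id}\t{pos}\t60\t{cigar}\t*\t0"
                    f"\t0\t{seq}\t*\tRG:Z:{rep}\n"
                )
                if manifest_fh is not None:
                    retained = [
                        str(j + 1 if model.strand == "+" else n_introns - j)
                        for j, b in enumerate(bits)
                        if b
                    ]
                    manifest_fh.write(
                        f"{read_id}\t{rep}\t{','.join(retained) or '-'}"
                        f"\t{len(retained)}\n"
                    )
    if manifest_fh is not None:
        manifest_fh.close()

    return ReadSimResult(
        sam_path=Path(out_sam),
        manifest_path=Path(out_manifest) if out_manifest is not None else None,
        n_reads=sum(n_per_rep.values()),
        n_reads_per_replicate=n_per_rep,
        pattern_counts=pattern_counts,
    )


def expected_indices(
    class_probs: Mapping[int, float], arb_probs: Mapping[str, float]
) -> dict[str, float]:
    """Large-sample (plug-in) Trouvelot indices implied by sampling
    probabilities: the values the per-plant indices converge to as the number
    of scored fragments grows."""
    p0 = float(class_probs.get(0, 0.0))
    M = sum(INTENSITY_WEIGHTS[c] * class_probs.get(c, 0.0) for c in range(6))
    F = 100.0 * (1.0 - p0)
    m = M / (1.0 - p0) if p0 < 1.0 else 0.0
    a = sum(
        ARBUSCULE_WEIGHTS[label] * arb_probs.get(label, 0.0)
        for label in ("A1", "A2", "A3")
    )
    if p0 >= 1.0:
        a = 0.0
    A = a * M / 100.0
    return {"F": F, "M": M, "m": m, "a": a, "A": A}


def make_fragment_scores(
    n_plants: int,
    n_fragments: int,
    class_probs: Mapping[int, float],
    arb_probs: Mapping[str, float],
    seed: int = 0,
    out_scores: str | Path | None = None,
    out_manifest: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Sample per-fragment colonization/arbuscule classes for many plants.

    ``class_probs`` are probabilities over colonization classes 0-5;
    ``arb_probs`` are probabilities over A0-A3 *conditional on the fragment
    being colonized* (class-0 fragments are always A0). Returns the score
    table plus the analytic index expectations; both can be written to TSV.
    """
    for name, probs in (("class_probs", class_probs), ("arb_probs", arb_probs)):
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise SimulationError(f"{name} is not a probability distribution")
    if set(class_probs) - set(range(6)):
        raise SimulationError("colonization classes must be 0-5")
    if set(arb_probs) - set(ARBUSCULE_WEIGHTS):
        raise SimulationError("arbuscule classes must be A0-A3")
    if n_plants < 1 or n_fragments < 1:
        raise SimulationError("need at least one plant and one fragment")

    rng = np.random.default_rng(seed)
    classes = sorted(class_probs)
    cp = np.array([class_probs[c] for c in classes])
    arb_labels = sorted(arb_probs)
    ap = np.array([arb_probs[a] for a in arb_labels])

    rows = []
    for p in range(n_plants):
        plant_id = f"plant{p + 1}"
        sampled = rng.choice(classes, size=n_fragments, p=cp)
        for f, c in enumerate(sampled):
            if c == 0:
                arb = "A0"
            else:
                arb = str(rng.choice(arb_labels, p=ap))
            rows.append(
                {
                    "plant_id": plant_id,
                    "fragment_id": f"frag{f + 1}",
                    "colonization_class": int(c),
                    "arbuscule_class": arb,
                }
            )
    scores = pd.DataFrame(rows)
    expectations = expected_indices(class_probs, arb_probs)

    if out_scores is not None:
        scores.to_csv(out_scores, sep="\t", index=False)
    if out_manifest is not None:
        with open(out_manifest, "w") as fh:
            fh.write("quantity\tvalue\n")
            for c in classes:
                fh.write(f"p_class{c}\t{class_probs[c]}\n")
            for a in arb_labels:
                fh.write(f"p_{a}\t{arb_probs[a]}\n")
            for key, value in expectations.items():
                fh.write(f"expected_{key}\t{value}\n")
    return scores, expectations
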