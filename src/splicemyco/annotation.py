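"""Genome sequences, gene models, and intron boundary dinucleotides.

Coordinates are GFF3-style 1-based closed intervals everywhere inside the
package; conversions (e.g. to the BED-style intron table) happen only at the
I/O boundary. Donor and acceptor dinucleotides are always reported in
transcript orientation: for a minus-strand intron the genomic boundary 2-mers
are reverse-complemented and swapped, so a canonical intron reads GT..AG
regardless of strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class AnnotationError(ValueError):
    """Base class for annotation and sequence errors."""


class EmptyFastaError(AnnotationError):
    pass


class DuplicateSequenceError(AnnotationError):
    pass


class Gff3ParseError(AnnotationError):
    pass


class CoordinateError(AnnotationError):
    pass


class IntronTooShortError(AnnotationError):
    """Intron shorter than 4 nt cannot carry distinct donor/acceptor 2-mers."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence restricted to the {A,C,G,T,N} alphabet."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AnnotationError(f"sequence {self.seq_id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Return residues on the 1-based closed interval [start, end]."""
        if start < 1 or end > len(self.residues) or start > end:
            raise CoordinateError(
                f"[{start}, {end}] outside [1, {len(self.residues)}] on {self.seq_id}"
            )
        return self.residues[start - 1 : end]


@dataclass
class TranscriptModel:
    """A gene model: ordered exon intervals on a named sequence with strand.

    Exons are normalised to ascending genomic start order on construction;
    overlapping or inverted exon intervals are rejected.
    """

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if s > e or s < 1:
                raise CoordinateError(f"invalid exon interval ({s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        self.exons = exons

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class Intron:
    """An inter-exon interval with transcript-orientation boundary 2-mers.

    ``index`` is the 1-based ordinal in transcript orientation (5'->3'), i.e.
    reversed genomic order on the minus strand. ``donor``/``acceptor`` are
    filled by :func:`splice_dinucleotides` / :func:`annotate_introns`; they are
    ``None`` for introns too short to classify.
    """

    transcript_id: str
    gene_id: str
    index: int
    seq_id: str
    strand: str
    start: int
    end: int
    donor: str | None = None
    acceptor: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-)FASTA into an ordered mapping of GenomeSequence.

    Residues are uppercased; characters outside {A,C,G,T,N} are replaced by N
    with a logged warning. Duplicate identifiers and empty files are rejected.
    """
    genomes: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genomes:
            raise DuplicateSequenceError(f"duplicate sequence id {record.id!r}")
        residues = str(record.seq).upper()
        cleaned, n_sub = _NON_ACGTN.subn("N", residues)
        if n_sub:
            log.warning(
                "%s: %d non-ACGTN residue(s) in %s replaced by N",
                path, n_sub, record.id,
            )
        genomes[record.id] = GenomeSequence(record.id, cleaned)
    if not genomes:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return genomes


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read GFF3 gene models (mRNA + exon/CDS children linked by Parent).

    One TranscriptModel per mRNA feature. mRNAs without exon children fall
    back to their CDS children; mRNAs with neither are dropped with a warning.
    Exons whose Parent cannot be resolved are skipped with a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except (ValueError, TypeError) as exc:
        raise Gff3ParseError(f"cannot parse GFF3 {path}: {exc}") from exc

    known_ids = {f.id for f in db.all_features()}
    for exon in db.features_of_type("exon"):
        for parent_id in exon.attributes.get("Parent", []):
            if parent_id not in known_ids:
                log.warning(
                    "%s: exon at %s:%d-%d has unresolvable Parent=%s; skipped",
                    path, exon.seqid, exon.start, exon.end, parent_id,
                )

    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        children = list(db.children(mrna, featuretype="exon"))
        if not children:
            children = list(db.children(mrna, featuretype="CDS"))
        if not children:
            log.warning(
                "%s: mRNA %s has no exon or CDS children; dropped", path, mrna.id
            )
            continue
        gene_id = mrna.attributes.get("Parent", [None])[0] or mrna.id
        models.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                seq_id=mrna.seqid,
                strand=mrna.strand,
                exons=[(c.start, c.end) for c in children],
            )
        )
    return models


def derive_introns(model: TranscriptModel) -> list[Intron]:
    """Derive the introns of a transcript, ordered 5'->3' in transcript
    orientation (reversed genomic order for minus-strand models).

    A zero-length gap between adjacent exons is an annotation error and
    rejects the model.
    """
    introns_genomic: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        gap = s2 - e1 - 1
        if gap <= 0:
            raise AnnotationError(
                f"transcript {model.transcript_id}: adjacent exons "
                f"({s1},{e1}) and ({s2},{e2}) leave no intron"
            )
        introns_genomic.append((e1 + 1, s2 - 1))

    n = len(introns_genomic)
    introns = []
    for j, (start, end) in enumerate(introns_genomic):
        index = j + 1 if model.strand == "+" else n - j
        introns.append(
            Intron(
                transcript_id=model.transcript_id,
                gene_id=model.gene_id,
                index=index,
                seq_id=model.seq_id,
                strand=model.strand,
                start=start,
                end=end,
            )
        )
    introns.sort(key=lambda i: i.index)
    return introns


def splice_dinucleotides(
    intron: Intron, genome: GenomeSequence
) -> tuple[str, str]:
    """Donor and acceptor 2-mers of an intron, in transcript orientation.

    Plus strand: donor = genomic [start, start+1], acceptor = [end-1, end].
    Minus strand: the two genomic boundary 2-mers are reverse-complemented
    and swapped so the result still reads donor..acceptor along the pre-mRNA.
    """
    if intron.length < 4:
        raise IntronTooShortError(
            f"intron {intron.transcript_id}#{intron.index} has length "
            f"{intron.length} < 4 and is unclassifiable"
        )
    five = genome.fetch(intron.start, intron.start + 1)
    three = genome.fetch(intron.end - 1, intron.end)
    if intron.strand == "+":
        return five, three
    return revcomp(three), revcomp(five)


def annotate_introns(
    model: TranscriptModel, genome: GenomeSequence
) -> list[Intron]:
    """Derive introns and fill donor/acceptor motifs from the genome.

    Introns too short to carry distinct boundary 2-mers keep donor/acceptor
    as None; downstream classification routes them to the Others class.
    """
    introns = derive_introns(model)
    for intron in introns:
        try:
            intron.donor, intron.acceptor = splice_dinucleotides(intron, genome)
        except IntronTooShortError:
            log.warning(
                "intron %s#%d (length %d) unclassifiable; routed to Others",
                intron.transcript_id, intron.index, intron.length,
            )
    return introns


def extract_introns(
    models: Iterable[TranscriptModel],
    genomes: Mapping[str, GenomeSequence],
    dedup: bool = False,
) -> list[Intron]:
    """Annotated introns for a set of transcripts.

    By default every intron of every transcript is counted once per
    transcript; ``dedup=True`` collapses introns sharing
    (seq_id, strand, start, end) across isoforms.
    """
    introns: list[Intron] = []
    seen: set[tuple[str, str, int, int]] = set()
    for model in models:
        if model.seq_id not in genomes:
            raise AnnotationError(
                f"transcript {model.transcript_id} references unknown "
                f"sequence {model.seq_id!r}"
            )
        for intron in annotate_introns(model, genomes[model.seq_id]):
            if dedup:
                key = (intron.seq_id, intron.strand, intron.start, intron.end)
                if key in seen:
                    continue
                seen.add(key)
            introns.append(intron)
    return introns


def feature_intervals(model: TranscriptModel) -> list[tuple[str, int, int]]:
    """Exon/intron intervals labelled in transcript orientation.

    Returns rows (feature_id, start, end) with feature ids exon1..exonN and
    intron1..intronN-1 numbered 5'->3'; rows are in transcript order.
    """
    introns = {i.index: (i.start, i.end) for i in derive_introns(model)}
    n = model.n_exons
    rows: list[tuple[str, int, int]] = []
    exon_order = model.exons if model.strand == "+" else model.exons[::-1]
    for k, (s, e) in enumerate(exon_order, start=1):
        rows.append((f"exon{k}", s, e))
        if k in introns:
            rows.append((f"intron{k}", *introns[k]))
    return rows


def write_gff3(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GFF3 (gene, mRNA, exon features)."""
    genes: dict[str, list[TranscriptModel]] = {}
    for m in models:
        genes.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in genes:
            members = genes[gene_id]
            seq_id = members[0].seq_id
            strand = members[0].strand
            g_start = min(m.span[0] for m in members)
            g_end = max(m.span[1] for m in members)
            fh.write(
                f"{seq_id}\tsplicemyco\tgene\t{g_start}\t{g_end}\t.\t{strand}"
                f"\t.\tID={gene_id}\n"
            )
            for m in members:
                s, e = m.span
                fh.write(
                    f"{m.seq_id}\tsplicemyco\tmRNA\t{s}\t{e}\t.\t{m.strand}\t."
                    f"\tID={m.transcript_id};Parent={gene_id}\n"
                )
                for k, (es, ee) in enumerate(m.exons, start=1):
                    fh.write(
                        f"{m.seq_id}\tsplicemyco\texon\t{es}\t{ee}\t.\t"
                        f"{m.strand}\t.\tID={m.transcript_id}.exon{k};"
                        f"Parent={m.transcript_id}\n"
                    )


def write_introns_tsv(introns: Sequence[Intron], path: str | Path) -> None:
    """Write introns as a BED-style TSV (0-based half-open on disk) with
    donor/acceptor columns appended."""
    with open(path, "w") as fh:
        fh.write(
            "# coordinates are 0-based half-open (BED convention)\n"
            "seq_id\tstart\tend\tname\tscore\tstrand\tdonor\tacceptor\n"
        )
        for i in introns:
            name = f"{i.transcript_id}:intron{i.index}"
            fh.write(
                f"{i.seq_id}\t{i.start - 1}\t{i.end}\t{name}\t.\t{i.strand}"
                f"\t{i.donor or 'NA'}\t{i.acceptor or 'NA'}\n"
            )


def write_feature_table(
    model: TranscriptModel, path: str | Path
) -> None:
    """Write the exon/intron interval table used by the coverage stage."""
    with open(path, "w") as fh:
        fh.write("feature_id\tseq_id\tstart\tend\tstrand\tlength\n")
        for feature_id, s, e in feature_intervals(model):
            fh.write(
                f"{feature_id}\t{model.seq_id}\t{s}\t{e}\t{model.strand}"
                f"\t{e - s + 1}\n"
            )


def read_feature_table(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read a feature interval table written by :func:`write_feature_table`.

    Returns rows (feature_id, seq_id, start, end), 1-based closed.
    """
    rows: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(
                (
                    parts[idx["feature_id"]],
                    parts[idx["seq_id"]],
                    int(parts[idx["start"]]),
                    int(parts[idx["end"]]),
                )
            )
    return rows
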