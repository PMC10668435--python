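"""Splice-motif classification and genome-wide frequency tables.

Introns are classified by their joint (donor, acceptor) dinucleotide pair into
GT-AG (the canonical U2-type motif), the non-canonical GC-AG, AT-AC and GA-AG
pairs, or Others. "Canonical" means GT-AG only; everything else, including
unclassifiable introns (boundary N, or too short to carry two distinct
2-mers), rolls up into the non-canonical total.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import Intron

MOTIF_CLASSES: tuple[str, ...] = ("GT-AG", "GC-AG", "AT-AC", "GA-AG", "Others")
CANONICAL_CLASS = "GT-AG"

_PAIR_TO_CLASS = {
    ("GT", "AG"): "GT-AG",
    ("GC", "AG"): "GC-AG",
    ("AT", "AC"): "AT-AC",
    ("GA", "AG"): "GA-AG",
}
_ALPHABET = set("ACGTN")


class MotifError(ValueError):
    pass


class EmptySurveyError(ValueError):
    pass


def classify(donor: str, acceptor: str) -> str:
    """Classify a (donor, acceptor) 2-mer pair into a splice-motif class.

    Classification is by the joint pair: a GA donor with a non-AG acceptor is
    Others, not GA-AG. Pairs containing N never match a named class.
    """
    for mer in (donor, acceptor):
        if not isinstance(mer, str) or len(mer) != 2 or not set(mer) <= _ALPHABET:
            raise MotifError(f"malformed 2-mer {mer!r}")
    return _PAIR_TO_CLASS.get((donor, acceptor), "Others")


def classify_intron(intron: Intron) -> str:
    """Motif class of an annotated intron; unclassifiable introns -> Others."""
    if intron.donor is None or intron.acceptor is None:
        return "Others"
    return classify(intron.donor, intron.acceptor)


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals (display convention)."""
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class SurveyTable:
    """Per-class splice-motif counts with canonical/non-canonical rollups."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(MOTIF_CLASSES)
        if unknown:
            raise MotifError(f"unknown motif classes {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise MotifError("negative count")
        if self.grand_total == 0:
            raise EmptySurveyError("survey over zero introns")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "SurveyTable":
        return cls({label: int(counts.get(label, 0)) for label in MOTIF_CLASSES})

    def count(self, label: str) -> int:
        return int(self.counts.get(label, 0))

    @property
    def grand_total(self) -> int:
        return sum(self.counts.values())

    @property
    def canonical_count(self) -> int:
        return self.count(CANONICAL_CLASS)

    @property
    def noncanonical_count(self) -> int:
        return self.grand_total - self.canonical_count

    def percent(self, label: str) -> float:
        return _pct(self.count(label), self.grand_total)

    @property
    def canonical_percent(self) -> float:
        return _pct(self.canonical_count, self.grand_total)

    @property
    def noncanonical_percent(self) -> float:
        return _pct(self.noncanonical_count, self.grand_total)

    def rows(self) -> list[tuple[str, int, float]]:
        """Table rows: the five classes plus rollups, as (label, count, %)."""
        out = [(label, self.count(label), self.percent(label)) for label in MOTIF_CLASSES]
        out.append(("Canonical", self.canonical_count, self.canonical_percent))
        out.append(("Non-canonical", self.noncanonical_count, self.noncanonical_percent))
        out.append(("Grand Total", self.grand_total, _pct(self.grand_total, self.grand_total)))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("splice_motif\tcount\tpercent\n")
            for label, count, pct in self.rows():
                fh.write(f"{label}\t{count}\t{pct:.2f}\n")


def build_survey(introns: Iterable[Intron]) -> SurveyTable:
    """Tally classified introns into a motif-frequency table."""
    counts = {label: 0 for label in MOTIF_CLASSES}
    n = 0
    for intron in introns:
        counts[classify_intron(intron)] += 1
        n += 1
    if n == 0:
        raise EmptySurveyError("no introns to survey")
    return SurveyTable(counts)


def read_counts_tsv(path: str | Path) -> SurveyTable:
    """Build a SurveyTable from a two-column TSV of per-class counts.

    Rollup rows (Canonical, Non-canonical, Grand Total), if present, are
    ignored and recomputed.
    """
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, value = line.split("\t")[:2]
            if label in MOTIF_CLASSES:
                counts[label] = int(value.replace(",", ""))
    return SurveyTable.from_counts(counts)


def locate_motif(
    introns: Iterable[Intron], target_class: str
) -> list[Intron]:
    """All introns of a target motif class, sorted by (seq_id, start, end,
    transcript_id, index) for a stable, deterministic report."""
    if target_class not in MOTIF_CLASSES:
        raise MotifError(f"unknown motif class {target_class!r}")
    hits = [i for i in introns if classify_intron(i) == target_class]
    hits.sort(key=lambda i: (i.seq_id, i.start, i.end, i.transcript_id, i.index))
    return hits


def write_locations_tsv(hits: Sequence[Intron], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\ttranscript_id\tintron_index\tseq_id\tstart\tend\tstrand"
            "\tdonor\tacceptor\n"
        )
        for i in hits:
            fh.write(
                f"{i.gene_id}\t{i.transcript_id}\t{i.index}\t{i.seq_id}"
                f"\t{i.start}\t{i.end}\t{i.strand}\t{i.donor or 'NA'}"
                f"\t{i.acceptor or 'NA'}\n"
            )
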