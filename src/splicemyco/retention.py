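"""Per-feature RNA-seq coverage and intron splicing-efficiency estimation.

Depth follows conventional pileup semantics: a base is covered by a read when
an M (aligned) or D (deletion) CIGAR operation consumes it; N (skipped
junction) gaps and soft-clips contribute nothing. Feature coverage is the
per-base mean depth over the feature, reported per replicate and summarised
across replicates as mean +/- sample s.d. (ddof=1).

Two estimators of splicing efficiency are provided:

* coverage ratio — ``1 - intron coverage / mean(flanking exon coverages)``,
  the primary statistic (it reproduces published per-gene coverage tables);
* junction counting — exact junction-spanning reads vs reads aligned
  continuously across the donor boundary, an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .annotation import Intron

log = logging.getLogger(__name__)

_CIGAR_CODE = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S"}
_CONSUMES_REF = {"M": True, "I": False, "D": True, "N": True, "S": False}


class SamError(ValueError):
    pass


class MissingReferenceError(SamError):
    pass


class FeatureError(ValueError):
    pass


class NoCoverageError(ValueError):
    pass


class NoInformativeReadsError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedRead:
    """A primary alignment reduced to what pileup and junction counting need."""

    seq_id: str
    pos: int  # 1-based leftmost aligned reference base
    cigar: tuple[tuple[str, int], ...]
    read_id: str = ""

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if _CONSUMES_REF[op])

    @property
    def reference_end(self) -> int:
        """Last reference base consumed (1-based closed)."""
        return self.pos + self.reference_span - 1


def read_sam(
    path: str | Path, default_replicate: str | None = None
) -> dict[str, list[AlignedRead]]:
    """Read primary alignments from a SAM file, grouped by replicate.

    Unmapped, secondary and supplementary records are excluded. Records whose
    CIGAR contains an operation outside {M,I,D,N,S} are rejected with a
    warning. Replicates come from the RG tag when present, otherwise every
    read falls into one group named after the file stem (or
    ``default_replicate``).
    """
    fallback = default_replicate or Path(path).stem
    grouped: dict[str, list[AlignedRead]] = {}
    try:
        handle = pysam.AlignmentFile(str(path), "r")
    except ValueError as exc:
        raise MissingReferenceError(f"cannot open SAM {path}: {exc}") from exc
    with handle:
        try:
            for rec in handle:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                ops: list[tuple[str, int]] = []
                bad = None
                for code, length in rec.cigartuples or []:
                    op = _CIGAR_CODE.get(code)
                    if op is None:
                        bad = code
                        break
                    ops.append((op, length))
                if bad is not None or not ops:
                    log.warning(
                        "%s: read %s has unsupported CIGAR; rejected",
                        path, rec.query_name,
                    )
                    continue
                rg = rec.get_tag("RG") if rec.has_tag("RG") else fallback
                grouped.setdefault(str(rg), []).append(
                    AlignedRead(
                        seq_id=rec.reference_name,
                        pos=rec.reference_start + 1,
                        cigar=tuple(ops),
                        read_id=rec.query_name or "",
                    )
                )
        except ValueError as exc:
            # pysam raises when a record names a reference absent from @SQ
            raise MissingReferenceError(
                f"{path}: alignment references a sequence missing from the "
                f"header ({exc})"
            ) from exc
    return grouped


def read_sam_replicates(paths: Sequence[str | Path]) -> dict[str, list[AlignedRead]]:
    """Read several SAM files, merging their replicate groups."""
    merged: dict[str, list[AlignedRead]] = {}
    for path in paths:
        for rep, reads in read_sam(path).items():
            merged.setdefault(rep, []).extend(reads)
    return merged


def _covered_blocks(read: AlignedRead) -> list[tuple[int, int]]:
    """Reference intervals (1-based closed) consuming depth (M and D ops)."""
    blocks: list[tuple[int, int]] = []
    cursor = read.pos
    for op, n in read.cigar:
        if op in ("M", "D"):
            if blocks and blocks[-1][1] == cursor - 1 and op in ("M", "D"):
                blocks[-1] = (blocks[-1][0], cursor + n - 1)
            else:
                blocks.append((cursor, cursor + n - 1))
            cursor += n
        elif op == "N":
            cursor += n
        # I and S consume no reference
    return blocks


@dataclass
class FeatureCoverageRow:
    """Per-feature mean per-base depth per replicate, summarised across
    replicates (Table-style row: length, coverage, s.d.)."""

    feature_id: str
    seq_id: str
    start: int
    end: int
    per_replicate: dict[str, float]
    coverage: float
    sd: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def feature_coverage(
    reads_by_replicate: Mapping[str, Sequence[AlignedRead]],
    features: Sequence[tuple[str, str, int, int]],
) -> list[FeatureCoverageRow]:
    """Mean per-base depth of each feature, per replicate and summarised.

    ``features`` rows are (feature_id, seq_id, start, end) in 1-based closed
    coordinates. The cross-replicate summary is the mean of replicate means
    and their sample standard deviation (0 when a single replicate is given).
    """
    if not reads_by_replicate:
        raise SamError("no replicates supplied")
    for fid, _, start, end in features:
        if end < start:
            raise FeatureError(f"feature {fid} has non-positive length")

    # one depth array per (replicate, seq_id) over the span the features need
    bounds: dict[str, tuple[int, int]] = {}
    for _, seq_id, start, end in features:
        lo, hi = bounds.get(seq_id, (start, end))
        bounds[seq_id] = (min(lo, start), max(hi, end))

    depth: dict[tuple[str, str], np.ndarray] = {}
    for rep, reads in reads_by_replicate.items():
        for seq_id, (lo, hi) in bounds.items():
            depth[(rep, seq_id)] = np.zeros(hi - lo + 1, dtype=np.int64)
        for read in reads:
            if read.seq_id not in bounds:
                continue
            lo, hi = bounds[read.seq_id]
            arr = depth[(rep, read.seq_id)]
            for b_start, b_end in _covered_blocks(read):
                s = max(b_start, lo) - lo
                e = min(b_end, hi) - lo
                if s <= e:
                    arr[s : e + 1] += 1

    replicates = list(reads_by_replicate)
    rows: list[FeatureCoverageRow] = []
    for fid, seq_id, start, end in features:
        lo, _ = bounds[seq_id]
        means = {
            rep: float(depth[(rep, seq_id)][start - lo : end - lo + 1].mean())
            for rep in replicates
        }
        values = np.array(list(means.values()), dtype=float)
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        rows.append(
            FeatureCoverageRow(
                feature_id=fid,
                seq_id=seq_id,
                start=start,
                end=end,
                per_replicate=means,
                coverage=float(values.mean()),
                sd=sd,
            )
        )
    return rows


def write_coverage_table(
    rows: Sequence[FeatureCoverageRow], path: str | Path
) -> None:
    reps = sorted({rep for row in rows for rep in row.per_replicate})
    with open(path, "w") as fh:
        header = ["feature_id", "length"] + [f"depth_{r}" for r in reps]
        header += ["coverage", "sd"]
        fh.write("\t".join(header) + "\n")
        for row in rows:
            cells = [row.feature_id, str(row.length)]
            cells += [f"{row.per_replicate.get(r, 0.0):.4f}" for r in reps]
            cells += [f"{row.coverage:.4f}", f"{row.sd:.4f}"]
            fh.write("\t".join(cells) + "\n")


@dataclass(frozen=True)
class SpliceEfficiencyEstimate:
    """A splicing-efficiency estimate in [0, 1] with its supporting numbers."""

    method: str  # "coverage_ratio" or "junction"
    efficiency: float
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(f"efficiency {self.efficiency} outside [0, 1]")


def efficiency_from_coverage(
    intron_cov: float, flanking_exon_covs: Sequence[float]
) -> SpliceEfficiencyEstimate:
    """Splicing efficiency as 1 - intron coverage / mean flanking coverage.

    The intron's per-base mean depth is compared with the mean of its two
    flanking exons' depths; the ratio estimates the retained fraction, so its
    complement estimates efficiency (clamped to [0, 1]).
    """
    flank = float(np.mean(flanking_exon_covs))
    if flank <= 0:
        raise NoCoverageError("flanking exon coverage is zero; efficiency undefined")
    eff = min(1.0, max(0.0, 1.0 - intron_cov / flank))
    return SpliceEfficiencyEstimate(
        "coverage_ratio",
        eff,
        {"intron_coverage": float(intron_cov), "flanking_mean": flank},
    )


def _m_runs(read: AlignedRead) -> list[tuple[int, int]]:
    """Maximal reference intervals continuously covered by M operations.

    Insertions do not break continuity on the reference; D and N gaps do.
    """
    runs: list[tuple[int, int]] = []
    cursor = read.pos
    open_start: int | None = None
    for op, n in read.cigar:
        if op == "M":
            if open_start is None:
                open_start = cursor
            cursor += n
        elif op in ("D", "N"):
            if open_start is not None:
                runs.append((open_start, cursor - 1))
                open_start = None
            cursor += n
        # I, S: neither advance reference nor break an M run
    if open_start is not None:
        runs.append((open_start, cursor - 1))
    return runs


def efficiency_from_junctions(
    reads: Iterable[AlignedRead], intron: Intron, min_anchor: int = 3
) -> SpliceEfficiencyEstimate:
    """Splicing efficiency from junction-spanning vs boundary-spanning reads.

    A read counts as *spliced* when it carries an N gap whose skipped
    reference interval equals the intron exactly and it has at least
    ``min_anchor`` aligned (M) bases on each side of the gap. It counts as
    *unspliced* when M operations continuously cover the donor boundary (the
    last exon base and the first intron base, in transcript orientation) with
    at least ``min_anchor`` bases on each side. Efficiency is
    spliced / (spliced + unspliced).
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if intron.strand == "+":
        boundary_left, boundary_right = intron.start - 1, intron.start
    else:
        boundary_left, boundary_right = intron.end, intron.end + 1
    lo = boundary_left - (min_anchor - 1)
    hi = boundary_right + (min_anchor - 1)

    spliced = 0
    unspliced = 0
    for read in reads:
        if read.seq_id != intron.seq_id:
            continue
        cursor = read.pos
        left_m = 0  # aligned bases before the current point
        is_spliced = False
        for op, n in read.cigar:
            if op == "M":
                left_m += n
                cursor += n
            elif op == "N":
                if cursor == intron.start and cursor + n - 1 == intron.end:
                    right_m = sum(m for o, m in read.cigar if o == "M") - left_m
                    if left_m >= min_anchor and right_m >= min_anchor:
                        is_spliced = True
                cursor += n
            elif op == "D":
                cursor += n
            # I, S consume no reference
        if is_spliced:
            spliced += 1
            continue
        for run_start, run_end in _m_runs(read):
            if run_start <= lo and run_end >= hi:
                unspliced += 1
                break

    total = spliced + unspliced
    if total == 0:
        raise NoInformativeReadsError(
            f"no reads informative for intron {intron.transcript_id}"
            f"#{intron.index}"
        )
    return SpliceEfficiencyEstimate(
        "junction",
        spliced / total,
        {"spliced": spliced, "unspliced": unspliced, "min_anchor": min_anchor},
    )


def write_efficiency_report(
    estimates: Sequence[SpliceEfficiencyEstimate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("method\tefficiency\tdetails\n")
        for est in estimates:
            detail = ";".join(f"{k}={v}" for k, v in sorted(est.details.items()))
            fh.write(f"{est.method}\t{est.efficiency:.6f}\t{detail}\n")
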