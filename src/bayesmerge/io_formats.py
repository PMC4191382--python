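"""Reading and writing reads as FASTQ (plain or gzip) and unaligned BAM.

FASTQ parsing goes through :class:`pysam.FastxFile` (gzip handled
transparently); BAM through :class:`pysam.AlignmentFile` with unmapped
flags. Outputs are routed by merge outcome: merged (or trimmed) sequences
become single records, ambiguous and kept pairs stay as pairs. In BAM mode
every record carries a ``dm`` aux tag recording the decision
(M merged, A ambiguous, K kept-as-pair, T trimmed).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import IO, Iterator

import pysam

from .model import Decision, MergeResult
from .records import ReadRecord

DEFAULT_PHRED_OFFSET = 33
_MAX_QUAL_CHAR = 93  # '~' at offset 33

_DECISION_TAG = {
    Decision.MERGED: "M",
    Decision.AMBIGUOUS: "A",
    Decision.KEPT_AS_PAIR: "K",
    Decision.TRIMMED_SINGLE: "T",
}
_TAG_DECISION = {v: k for k, v in _DECISION_TAG.items()}


class ParseError(ValueError):
    pass


@dataclass
class RecordOutcome:
    """One input record (pair or single read) with its merge outcome."""

    r1: ReadRecord
    r2: ReadRecord | None
    result: MergeResult


def strip_mate_suffix(name: str) -> str:
    name = name.split()[0]
    if len(name) > 1 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


# ---------------------------------------------------------------------------
# reading

def _fastq_records(path: str, offset: int) -> Iterator[ReadRecord]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            if rec.quality is None:
                raise ParseError(f"record {rec.name!r} in {path}: missing qualities")
            quals = [ord(c) - offset for c in rec.quality]
            if quals and min(quals) < 0:
                raise ParseError(
                    f"record {rec.name!r} in {path}: quality below offset {offset}"
                )
            yield ReadRecord(rec.name, rec.sequence.upper(), quals)


def _bam_records(path: str) -> Iterator[ReadRecord]:
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            yield ReadRecord(
                aln.query_name, aln.query_sequence.upper(), list(aln.query_qualities)
            )


def read_singles(
    fastq: str | None = None,
    bam: str | None = None,
    phred_offset: int = DEFAULT_PHRED_OFFSET,
) -> Iterator[ReadRecord]:
    """Stream single-end reads from one FASTQ (or gzip FASTQ) or BAM."""
    if (fastq is None) == (bam is None):
        raise ValueError("provide exactly one of fastq or bam")
    yield from _fastq_records(fastq, phred_offset) if fastq else _bam_records(bam)


def _pair_up(records: Iterator[ReadRecord], source: str) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    it = iter(records)
    for r1 in it:
        r2 = next(it, None)
        if r2 is None:
            raise ParseError(f"{source}: odd record count, read {r1.id!r} has no mate")
        if strip_mate_suffix(r1.id) != strip_mate_suffix(r2.id):
            raise ParseError(f"{source}: mate mismatch {r1.id!r} vs {r2.id!r}")
        yield r1, r2


def read_pairs(
    fq1: str | None = None,
    fq2: str | None = None,
    interleaved: str | None = None,
    bam: str | None = None,
    phred_offset: int = DEFAULT_PHRED_OFFSET,
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Stream read pairs from two FASTQs, an interleaved FASTQ, or a BAM.

    Mate identifiers must agree after stripping a ``/1``-``/2`` suffix; a
    mismatch, an odd interleaved count, or a missing mate raises
    :class:`ParseError` naming the offending record.
    """
    modes = sum(x is not None for x in (fq1, interleaved, bam))
    if modes != 1 or (fq1 is not None) != (fq2 is not None):
        raise ValueError("provide exactly one input mode: (fq1, fq2), interleaved, or bam")
    if fq1 is not None:
        for r1, r2 in zip(
            _fastq_records(fq1, phred_offset), _fastq_records(fq2, phred_offset), strict=True
        ):
            if strip_mate_suffix(r1.id) != strip_mate_suffix(r2.id):
                raise ParseError(f"mate mismatch {r1.id!r} vs {r2.id!r}")
            yield r1, r2
    elif interleaved is not None:
        yield from _pair_up(_fastq_records(interleaved, phred_offset), interleaved)
    else:
        yield from _pair_up(_bam_records(bam), bam)


# ---------------------------------------------------------------------------
# writing

def _open_text(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _write_fastq_record(fh: IO[str], read: ReadRecord, offset: int) -> None:
    quals = "".join(
        chr(min(int(q), _MAX_QUAL_CHAR) + offset) for q in read.quals
    )
    fh.write(f"@{read.id}\n{read.bases}\n+\n{quals}\n")


class FastqResultWriter:
    """Route outcomes to ``<prefix>.merged/.r1/.r2.fastq`` (or ``.trimmed``/
    ``.untrimmed`` for single-end input)."""

    def __init__(
        self,
        prefix: str,
        phred_offset: int = DEFAULT_PHRED_OFFSET,
        gz: bool = False,
        paired: bool | None = True,
    ):
        ext = ".fastq.gz" if gz else ".fastq"
        self.prefix = str(prefix)
        self.offset = phred_offset
        self._ext = ext
        self._files: dict[str, IO[str]] = {}
        # pre-create the routing files so "no records of a kind" still leaves
        # a (valid, empty) file behind
        labels = () if paired is None else (
            ("merged", "r1", "r2") if paired else ("trimmed", "untrimmed")
        )
        for label in labels:
            self._fh(label)

    def _fh(self, label: str) -> IO[str]:
        if label not in self._files:
            self._files[label] = _open_text(f"{self.prefix}.{label}{self._ext}")
        return self._files[label]

    def write(self, out: RecordOutcome) -> None:
        res = out.result
        if out.r2 is None:
            if res.decision is Decision.TRIMMED_SINGLE:
                _write_fastq_record(self._fh("trimmed"), res.sequence, self.offset)
            else:
                _write_fastq_record(self._fh("untrimmed"), out.r1, self.offset)
            return
        if res.decision is Decision.MERGED:
            _write_fastq_record(self._fh("merged"), res.sequence, self.offset)
        else:
            _write_fastq_record(self._fh("r1"), out.r1, self.offset)
            _write_fastq_record(self._fh("r2"), out.r2, self.offset)

    def close(self) -> None:
        for fh in self._files.values():
            fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _uBAM_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"}, "PG": [{"ID": "bayesmerge", "PN": "bayesmerge"}]}
    )


def _to_unaligned(read: ReadRecord, flag: int, tag: str) -> pysam.AlignedSegment:
    aln = pysam.AlignedSegment()
    aln.query_name = read.id
    aln.query_sequence = read.bases
    aln.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(min(int(q), _MAX_QUAL_CHAR) + 33) for q in read.quals)
    )
    aln.flag = flag
    aln.reference_id = -1
    aln.reference_start = -1
    aln.set_tag("dm", tag, value_type="A")
    return aln


class BamResultWriter:
    """Write all outcomes into one unaligned BAM; decisions go into ``dm``."""

    _FLAG_SINGLE = 0x4
    _FLAG_R1 = 0x1 | 0x4 | 0x8 | 0x40
    _FLAG_R2 = 0x1 | 0x4 | 0x8 | 0x80

    def __init__(self, path: str):
        self.path = str(path)
        self._fh = pysam.AlignmentFile(self.path, "wb", header=_uBAM_header())

    def write(self, out: RecordOutcome) -> None:
        tag = _DECISION_TAG[out.result.decision]
        if out.result.decision in (Decision.MERGED, Decision.TRIMMED_SINGLE):
            self._fh.write(_to_unaligned(out.result.sequence, self._FLAG_SINGLE, tag))
        elif out.r2 is None:
            self._fh.write(_to_unaligned(out.r1, self._FLAG_SINGLE, tag))
        else:
            self._fh.write(_to_unaligned(out.r1, self._FLAG_R1, tag))
            self._fh.write(_to_unaligned(out.r2, self._FLAG_R2, tag))

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_pairs_bam(pairs, path: str) -> None:
    """Write raw read pairs as an unaligned BAM (for round-tripping FASTQ)."""
    with pysam.AlignmentFile(str(path), "wb", header=_uBAM_header()) as fh:
        for r1, r2 in pairs:
            aln1 = _to_unaligned(r1, BamResultWriter._FLAG_R1, "K")
            aln2 = _to_unaligned(r2, BamResultWriter._FLAG_R2, "K")
            fh.write(aln1)
            fh.write(aln2)


def write_pairs_fastq(pairs, path1: str, path2: str,
                      phred_offset: int = DEFAULT_PHRED_OFFSET) -> None:
    """Write raw read pairs as two FASTQ files."""
    with _open_text(path1) as f1, _open_text(path2) as f2:
        for r1, r2 in pairs:
            _write_fastq_record(f1, r1, phred_offset)
            _write_fastq_record(f2, r2, phred_offset)


def write_results(
    outcomes,
    prefix: str | None = None,
    bam_out: str | None = None,
    phred_offset: int = DEFAULT_PHRED_OFFSET,
    paired: bool = True,
) -> dict[str, int]:
    """Write a stream of outcomes; returns per-decision counts.

    Exactly one of ``prefix`` (FASTQ mode) or ``bam_out`` must be given.
    """
    if (prefix is None) == (bam_out is None):
        raise ValueError("provide exactly one of prefix (FASTQ) or bam_out")
    counts = {d.value: 0 for d in Decision}
    writer = (
        FastqResultWriter(prefix, phred_offset, paired=paired)
        if prefix
        else BamResultWriter(bam_out)
    )
    with writer:
        for out in outcomes:
            counts[out.result.decision.value] += 1
            writer.write(out)
    return counts
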