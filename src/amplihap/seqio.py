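"""Sequence and alignment records, standard-format I/O, and short-read quality trimming.

Internal coordinates are 0-based half-open everywhere.  Every user-facing
report (SAM POS, VCF POS, change lists, breakpoint tables) converts to
1-based on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: CIGAR operations that consume the query sequence.
QUERY_OPS = frozenset("M=XIS")
#: CIGAR operations that consume the reference.
REF_OPS = frozenset("M=XD")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed input files or invalid records."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base Phred qualities."""

    id: str
    bases: str
    quals: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quals)} != "
                f"sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentRecord:
    """A read-to-reference pairwise alignment.

    ``ref_start`` is 0-based; ``cigar`` is a list of ``(op, length)`` with op
    in ``{M, =, X, I, D, S}``; ``identity`` is matches / aligned columns.
    ``query_seq`` holds the aligned (strand-corrected) query sequence when
    available; it is required for SAM output with sequence.
    """

    query_id: str
    ref_id: str
    ref_start: int
    cigar: list[tuple[str, int]]
    strand: str = "+"
    score: float = 0.0
    identity: float = 1.0
    query_seq: Optional[str] = None

    @property
    def query_len(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_OPS)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_OPS)

    def cigar_string(self, collapse_matches: bool = False) -> str:
        ops = self.cigar
        if collapse_matches:
            merged: list[tuple[str, int]] = []
            for op, n in ops:
                op = "M" if op in "=X" else op
                if merged and merged[-1][0] == op:
                    merged[-1] = (op, merged[-1][1] + n)
                else:
                    merged.append((op, n))
            ops = merged
        return "".join(f"{n}{op}" for op, n in ops)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*" or not text:
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise FormatError(f"malformed CIGAR string {text!r}")
    return ops


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _to_biopython(rec: SequenceRecord, with_quals: bool) -> SeqRecord:
    if not rec.bases:
        raise FormatError(f"record {rec.id!r} has empty sequence")
    out = SeqRecord(Seq(rec.bases), id=rec.id, description="")
    if with_quals:
        if rec.quals is None:
            raise FormatError(f"record {rec.id!r} has no qualities for FASTQ output")
        out.letter_annotations["phred_quality"] = list(rec.quals)
    return out


def read_fastq(path) -> list[SequenceRecord]:
    """Parse a Sanger (Phred+33) FASTQ file into records."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append(
                SequenceRecord(
                    rec.id, str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:  # Biopython reports the offending record
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write((_to_biopython(r, True) for r in records), str(path), "fastq")


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if not rec.bases:
                raise FormatError(f"record {rec.id!r} has empty sequence")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM (minimal dialect, via pysam)
# ---------------------------------------------------------------------------

def write_sam(
    alignments: Sequence[AlignmentRecord],
    references: Sequence[SequenceRecord],
    path,
    emit_eq_x: bool = True,
) -> None:
    """Write alignments as SAM 1.6 with @HD/@SQ headers.

    ``emit_eq_x`` keeps =/X CIGAR ops; when False they are collapsed to M.
    """
    ref_lens = {r.id: len(r.bases) for r in references}
    for aln in alignments:
        if aln.ref_id not in ref_lens:
            raise FormatError(f"alignment {aln.query_id!r}: unknown reference {aln.ref_id!r}")
        if aln.query_seq is not None and len(aln.query_seq) != aln.query_len:
            raise FormatError(
                f"alignment {aln.query_id!r}: CIGAR consumes {aln.query_len} query "
                f"bases but sequence has {len(aln.query_seq)}"
            )
        if aln.ref_end > ref_lens[aln.ref_id]:
            raise FormatError(f"alignment {aln.query_id!r} extends past reference end")
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": r.id, "LN": len(r.bases)} for r in references],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.query_id
            seg.reference_name = aln.ref_id
            seg.reference_start = aln.ref_start
            seg.flag = 16 if aln.strand == "-" else 0
            seg.mapping_quality = 60
            seg.cigarstring = aln.cigar_string(collapse_matches=not emit_eq_x)
            seg.query_sequence = aln.query_seq if aln.query_seq is not None else None
            fh.write(seg)


def read_sam(path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Read a SAM file; returns (alignments, reference-length map)."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        ref_lens = dict(zip(fh.references, fh.lengths))
        for seg in fh:
            if seg.is_unmapped:
                continue
            cigar = parse_cigar(seg.cigarstring or "*")
            out.append(
                AlignmentRecord(
                    query_id=seg.query_name,
                    ref_id=seg.reference_name,
                    ref_start=seg.reference_start,
                    cigar=cigar,
                    strand="-" if seg.is_reverse else "+",
                    query_seq=seg.query_sequence,
                )
            )
    return out, ref_lens


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------

def quality_trim(
    record: SequenceRecord,
    window_size: int = 4,
    avg_q: float = 30,
    lead_trail_q: int = 5,
    min_len: int = 40,
) -> Optional[SequenceRecord]:
    """Sliding-window quality trim of one short read.

    Leading and trailing bases below ``lead_trail_q`` are removed first; the
    remainder is scanned 5'->3' in windows of ``window_size`` advancing one
    base at a time, cutting before the first window whose mean quality drops
    below ``avg_q``.  Returns ``None`` (discarded) if the result is shorter
    than ``min_len``.
    """
    if record.quals is None:
        raise FormatError(f"record {record.id!r} has no qualities; cannot trim")
    q = record.quals
    lo, hi = 0, len(q)
    while lo < hi and q[lo] < lead_trail_q:
        lo += 1
    while hi > lo and q[hi - 1] < lead_trail_q:
        hi -= 1
    cut = hi
    for i in range(lo, hi - window_size + 1):
        if sum(q[i : i + window_size]) / window_size < avg_q:
            cut = i
            break
    if cut - lo < min_len:
        return None
    return SequenceRecord(record.id, record.bases[lo:cut], q[lo:cut])


def trim_pairs(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]], **kwargs
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], int]:
    """Trim read pairs; a pair survives only if both mates survive.

    Returns the surviving pairs and the number of pairs dropped.
    """
    kept, dropped = [], 0
    for r1, r2 in pairs:
        t1 = quality_trim(r1, **kwargs)
        t2 = quality_trim(r2, **kwargs)
        if t1 is None or t2 is None:
            dropped += 1
        else:
            kept.append((t1, t2))
    return kept, dropped
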