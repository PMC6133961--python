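"""Per-read-position error-rate profiling from control-read alignments.

Each alignment's CIGAR is walked in read coordinates (reverse-strand reads
are walked 3'->5' so position 1 is always the sequencing start).  An X
column counts one substitution at its read position, an I op counts its
length in insertions at the read positions of the inserted bases, and a D
op attributes its length in deletions to the read position preceding the
gap.  Rates are events per aligned reference-consuming column, binned along
the read coordinate; the overall averages are the column-weighted means of
the bins, i.e. total events over total aligned columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignParams, LONG_READ_PARAMS, ReferenceIndex, map_read
from .seqio import AlignmentRecord, SequenceRecord


@dataclass
class ErrorProfile:
    """Binned positional error rates plus their aligned-base-weighted averages."""

    bin_edges: np.ndarray          # len n_bins + 1, read coordinates
    sub_rate: np.ndarray
    ins_rate: np.ndarray
    del_rate: np.ndarray
    reads_per_bin: np.ndarray
    avg_sub: float
    avg_ins: float
    avg_del: float
    n_reads: int
    n_aligned_bases: int

    @property
    def avg_total(self) -> float:
        return self.avg_sub + self.avg_ins + self.avg_del

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1],
            "bin_end": self.bin_edges[1:],
            "n_reads": self.reads_per_bin,
            "sub": self.sub_rate,
            "ins": self.ins_rate,
            "del": self.del_rate,
        })

    def summary(self) -> str:
        return (
            f"{self.n_reads} reads, {self.n_aligned_bases} aligned bases: "
            f"sub {self.avg_sub:.2%}, ins {self.avg_ins:.2%}, "
            f"del {self.avg_del:.2%}, total {self.avg_total:.2%}"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        for y, label in ((self.sub_rate, "SNV"), (self.ins_rate, "INS"),
                         (self.del_rate, "DEL")):
            ax.plot(x, y, label=label)
        ax.set_xlabel("read position (bp)")
        ax.set_ylabel("error rate")
        ax.legend()
        return ax


def _add_interval(acc, start, end, bin_size):
    """Add 1 per read position in [start, end) to per-bin accumulator."""
    b0, b1 = start // bin_size, (end - 1) // bin_size
    if b0 == b1:
        acc[b0] += end - start
        return
    acc[b0] += (b0 + 1) * bin_size - start
    for b in range(b0 + 1, b1):
        acc[b] += bin_size
    acc[b1] += end - b1 * bin_size


def profile_errors(
    alignments: Sequence[AlignmentRecord],
    ref: Optional[str] = None,
    bin_size: int = 100,
) -> ErrorProfile:
    """Estimate substitution/insertion/deletion rates along the read coordinate.

    Alignments must carry =/X-style CIGARs (M ops are rejected unless the
    reference is supplied for re-scoring against ``query_seq``).
    """
    max_len = 0
    for aln in alignments:
        if any(op == "M" for op, _ in aln.cigar) and ref is None:
            raise ValueError(
                "M-only CIGARs cannot be profiled without the reference"
            )
        max_len = max(max_len, aln.query_len)
    if not alignments:
        raise ValueError("no alignments to profile")
    n_bins = (max_len + bin_size - 1) // bin_size
    sub = np.zeros(n_bins)
    ins = np.zeros(n_bins)
    dele = np.zeros(n_bins)
    denom = np.zeros(n_bins)
    reads_spanning = np.zeros(n_bins, np.int64)

    for aln in alignments:
        L = aln.query_len
        reads_spanning[: (L + bin_size - 1) // bin_size] += 1
        minus = aln.strand == "-"

        def rd(q):  # query coordinate -> read (sequencing) coordinate
            return L - 1 - q if minus else q

        qpos = 0
        rseq = None
        if ref is not None:
            rseq = ref[aln.ref_start : aln.ref_end]
        rpos_local = 0
        for op, n in aln.cigar:
            if op in "=XM":
                if op == "M":
                    # re-score against the reference slice
                    for t in range(n):
                        match = aln.query_seq[qpos + t] == rseq[rpos_local + t]
                        a, b = sorted((rd(qpos + t), rd(qpos + t)))
                        denom[a // bin_size] += 1
                        if not match:
                            sub[a // bin_size] += 1
                else:
                    a, b = sorted((rd(qpos), rd(qpos + n - 1)))
                    _add_interval(denom, a, b + 1, bin_size)
                    if op == "X":
                        _add_interval(sub, a, b + 1, bin_size)
                qpos += n
                rpos_local += n
            elif op == "I":
                a, b = sorted((rd(qpos), rd(qpos + n - 1)))
                _add_interval(ins, a, b + 1, bin_size)
                qpos += n
            elif op == "D":
                anchor = rd(max(qpos - 1, 0))
                dele[anchor // bin_size] += n
                denom[anchor // bin_size] += n
                rpos_local += n
            elif op == "S":
                qpos += n

    with np.errstate(invalid="ignore", divide="ignore"):
        sub_rate = np.where(denom > 0, sub / denom, 0.0)
        ins_rate = np.where(denom > 0, ins / denom, 0.0)
        del_rate = np.where(denom > 0, dele / denom, 0.0)
    total = denom.sum()
    return ErrorProfile(
        bin_edges=np.arange(n_bins + 1) * bin_size,
        sub_rate=sub_rate,
        ins_rate=ins_rate,
        del_rate=del_rate,
        reads_per_bin=reads_spanning,
        avg_sub=float(sub.sum() / total),
        avg_ins=float(ins.sum() / total),
        avg_del=float(dele.sum() / total),
        n_reads=len(alignments),
        n_aligned_bases=int(total),
    )


#: three built-in aligner parameterizations standing in for independent
#: mapping strategies (different gap penalties); the default keeps a lone
#: substitution cheaper than a gap pair while a true ins+del pair stays
#: gaps, which minimizes leakage between the three error components
MAPPER_PRESETS: dict[str, AlignParams] = {
    "affine-default": AlignParams(match=2, mismatch=-4, gap_open=-2,
                                  gap_extend=-1, band_width=250),
    "affine-balanced": AlignParams(match=3, mismatch=-5, gap_open=-3,
                                   gap_extend=-1, band_width=250),
    "gap-strict": AlignParams(match=2, mismatch=-4, gap_open=-4,
                              gap_extend=-2, band_width=250),
}


def profile_reads(
    reads: Sequence[SequenceRecord],
    ref: SequenceRecord,
    params: AlignParams = MAPPER_PRESETS["affine-default"],
    bin_size: int = 100,
) -> ErrorProfile:
    """Map control reads to the control reference and profile their errors."""
    index = ReferenceIndex(ref.bases)
    alns = [a for a in (map_read(r, ref, params, index=index) for r in reads)
            if a is not None]
    return profile_errors(alns, bin_size=bin_size)


def compare_mappers(profiles: dict[str, ErrorProfile]) -> pd.DataFrame:
    """Tabulate per-component averages across aligner settings.

    The combined row is the per-component median across settings; ``spread``
    is (max - min) / median per component.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    rows = {
        label: [p.avg_sub, p.avg_ins, p.avg_del, p.avg_total]
        for label, p in profiles.items()
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["avg_sub", "avg_ins", "avg_del", "avg_total"]
    )
    med = df.median()
    spread = (df.max() - df.min()) / med.where(med > 0, np.nan)
    df.loc["combined (median)"] = med
    df.loc["relative spread"] = spread
    return df
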