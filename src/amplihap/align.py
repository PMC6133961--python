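"""Banded affine-gap semi-global alignment and read mapping.

This is the pairwise engine behind consensus building, polishing, error
profiling and genotyping.  Alignments are semi-global with free end gaps on
the reference: the query is consumed in full and may land anywhere on the
reference.  Long references are handled by a k-mer diagonal vote that places
a band around the likely location before running the DP.

Acceptance filters follow the long-read mapping convention used throughout
the pipeline: a read is rejected when its mismatch fraction exceeds 40%, its
total gap fraction exceeds 20%, or any single indel exceeds 50 bp.  Both
fractions are computed over aligned read bases.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _kernels
from .seqio import AlignmentRecord, revcomp

_ENCODE = np.full(256, 4, np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0..T=3, anything else 4)."""
    return _ENCODE[np.frombuffer(seq.encode(), np.uint8)]


class BandOverflowError(RuntimeError):
    """The band was too narrow for any alignment path; widen band_width."""


@dataclass(frozen=True)
class AlignParams:
    """Scoring and acceptance parameters for the banded aligner.

    The default scores follow the usual noisy-long-read convention: one
    mismatch (-4) is cheaper than a 1 bp gap (-6), but a 1 bp gap is
    cheaper than two mismatches, so the indel-dominated errors of nanopore
    reads stay gaps instead of being smeared into mismatch pairs.
    """

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -4.0
    gap_extend: float = -2.0
    band_width: int = 400
    max_mismatch_frac: float = 0.40
    max_gap_frac: float = 0.20
    max_gap_len: int = 50


#: default parameter sets for long and short reads
LONG_READ_PARAMS = AlignParams(band_width=400)
SHORT_READ_PARAMS = AlignParams(band_width=50)


def _record_from_kernel(query, ref_id, score, ref_start, ops, lens, n_ops,
                        strand: str) -> AlignmentRecord:
    cigar = [(_kernels.OP_CHARS[ops[t]], int(lens[t])) for t in range(n_ops)]
    matches = sum(n for op, n in cigar if op == "=")
    cols = sum(n for op, n in cigar)
    return AlignmentRecord(
        query_id="", ref_id=ref_id, ref_start=int(ref_start), cigar=cigar,
        strand=strand, score=float(score),
        identity=matches / cols if cols else 0.0, query_seq=query,
    )


def semiglobal_align(
    query: str,
    ref: str,
    params: AlignParams = AlignParams(),
    offset: Optional[int] = None,
    ref_id: str = "ref",
) -> AlignmentRecord:
    """Align ``query`` within ``ref`` (free reference end gaps).

    ``offset`` centres the band: row ``i`` visits reference columns near
    ``i + offset``.  The default centres the band mid-reference, which is
    only adequate when ``band_width`` covers the start uncertainty; raise
    ``band_width`` (up to ``len(ref)``) for unseeded use.
    """
    if not query or not ref:
        raise ValueError("query and reference must be non-empty")
    if offset is None:
        offset = (len(ref) - len(query)) // 2
    ok, score, start, ops, lens, n_ops = _kernels.banded_semiglobal(
        encode(query), encode(ref), params.match, params.mismatch,
        params.gap_open, params.gap_extend, int(params.band_width), int(offset),
    )
    if not ok:
        raise BandOverflowError(
            f"band_width={params.band_width} cannot connect query "
            f"(len {len(query)}) to reference (len {len(ref)}); widen the band"
        )
    return _record_from_kernel(query, ref_id, score, start, ops, lens, n_ops, "+")


class ReferenceIndex:
    """k-mer index of a reference for diagonal voting.

    Used to place the DP band before aligning a read against a reference too
    long for an unseeded band.
    """

    def __init__(self, ref: str, k: int = 13, max_hits: int = 8):
        self.ref = ref
        self.k = k
        self.max_hits = max_hits
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(ref) - k + 1):
            index[ref[i : i + k]].append(i)
        self.index = {
            kmer: pos for kmer, pos in index.items() if len(pos) <= max_hits
        }

    def locate(self, query: str, stride: int = 3, bin_size: int = 64) -> Optional[int]:
        """Estimated reference start of ``query`` by diagonal vote, or None.

        Side effect: ``self.vote_strength`` holds the winning bin's vote
        count for the most recent call (used to rank candidate strands).
        """
        k = self.k
        votes: dict[int, int] = defaultdict(int)
        for qpos in range(0, len(query) - k + 1, stride):
            for rpos in self.index.get(query[qpos : qpos + k], ()):
                votes[(rpos - qpos) // bin_size] += 1
        self.vote_strength = 0
        if not votes:
            return None
        best_bin, best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
        if best < 2 and len(query) - k + 1 > 3 * stride:
            return None
        self.vote_strength = best
        return best_bin * bin_size + bin_size // 2


def _aligned_or_none(query, ref, params, offset, ref_id):
    ok, score, start, ops, lens, n_ops = _kernels.banded_semiglobal(
        encode(query), encode(ref), params.match, params.mismatch,
        params.gap_open, params.gap_extend, int(params.band_width), int(offset),
    )
    if not ok:
        return None
    return _record_from_kernel(query, ref_id, score, start, ops, lens, n_ops, "+")


def _align_windowed(query, ref, params, est_start, ref_id):
    """Run the banded DP on a reference window around an estimated start."""
    pad = params.band_width + 64
    lo = max(0, est_start - pad)
    hi = min(len(ref), est_start + len(query) + pad)
    aln = _aligned_or_none(query, ref[lo:hi], params, est_start - lo, ref_id)
    if aln is None:
        return None
    return replace(aln, ref_start=aln.ref_start + lo)


def left_align_indels(aln: AlignmentRecord, ref_seq: str) -> AlignmentRecord:
    """Shift every gap to its leftmost score-equivalent placement.

    Canonicalizes indel placement inside repeats so that reads aligned from
    either strand contribute gap evidence to the same pileup column.
    """
    if not any(op in "ID" for op, _ in aln.cigar):
        return aln
    query = aln.query_seq
    cols: list[tuple[str, int, int]] = []  # (kind M/I/D/S, q index, r index)
    qpos, rpos = 0, aln.ref_start
    for op, n in aln.cigar:
        for _ in range(n):
            if op in "M=X":
                cols.append(("M", qpos, rpos))
                qpos += 1
                rpos += 1
            elif op == "I":
                cols.append(("I", qpos, -1))
                qpos += 1
            elif op == "D":
                cols.append(("D", -1, rpos))
                rpos += 1
            else:  # S
                cols.append(("S", qpos, -1))
                qpos += 1
    i = 0
    while i < len(cols):
        kind = cols[i][0]
        if kind not in "ID":
            i += 1
            continue
        j = i
        while j < len(cols) and cols[j][0] == kind:
            j += 1
        n = j - i
        while i > 0 and cols[i - 1][0] == "M":
            qm, rm = cols[i - 1][1], cols[i - 1][2]
            if kind == "I":
                q_last = cols[j - 1][1]
                if not (query[qm] == ref_seq[rm] == query[q_last]):
                    break
                repl = [("I", qm + t, -1) for t in range(n)] + [("M", qm + n, rm)]
            else:
                r_last = cols[j - 1][2]
                if not (ref_seq[rm] == query[qm] == ref_seq[r_last]):
                    break
                repl = [("D", -1, rm + t) for t in range(n)] + [("M", qm, rm + n)]
            cols[i - 1 : j] = repl
            i -= 1
            j -= 1
        i = j if j > i else i + 1
    # rebuild the run-length CIGAR, restoring =/X from base identity
    new: list[tuple[str, int]] = []
    for kind, q, r in cols:
        if kind == "M":
            op = "=" if query[q] == ref_seq[r] else "X"
        else:
            op = kind
        if new and new[-1][0] == op:
            new[-1] = (op, new[-1][1] + 1)
        else:
            new.append((op, 1))
    return replace(aln, cigar=new)


def passes_filters(aln: AlignmentRecord, params: AlignParams) -> bool:
    """Apply the mismatch/gap acceptance caps to a candidate alignment."""
    qlen = aln.query_len
    if qlen == 0:
        return False
    mismatches = sum(n for op, n in aln.cigar if op == "X")
    gap = sum(n for op, n in aln.cigar if op in "ID")
    max_indel = max((n for op, n in aln.cigar if op in "ID"), default=0)
    return (
        mismatches / qlen <= params.max_mismatch_frac
        and gap / qlen <= params.max_gap_frac
        and max_indel <= params.max_gap_len
    )


def map_read(
    read,
    ref,
    params: AlignParams = LONG_READ_PARAMS,
    index: Optional[ReferenceIndex] = None,
    apply_filters: bool = True,
) -> Optional[AlignmentRecord]:
    """Map a read (both strands) to a reference; None when unmapped.

    ``read`` is a SequenceRecord or string; ``ref`` likewise.  A prebuilt
    ``ReferenceIndex`` avoids re-indexing when mapping many reads.
    """
    query = read if isinstance(read, str) else read.bases
    query_id = "" if isinstance(read, str) else read.id
    ref_seq = ref if isinstance(ref, str) else ref.bases
    ref_id = "ref" if isinstance(ref, str) else ref.id
    if not query:
        return None

    use_seed = len(ref_seq) > 2000 and len(query) >= 3 * 13
    if use_seed and index is None:
        index = ReferenceIndex(ref_seq)

    best = None
    if use_seed:
        # vote both strands, align the better-supported one first and skip
        # the other when the vote ratio makes it hopeless
        cands = []
        for strand, seq in (("+", query), ("-", revcomp(query))):
            est = index.locate(seq)
            if est is not None:
                cands.append((index.vote_strength, strand, seq, est))
        cands.sort(key=lambda c: -c[0])
        for rank, (votes, strand, seq, est) in enumerate(cands):
            if best is not None and votes * 4 < cands[0][0]:
                break
            aln = _align_windowed(seq, ref_seq, params, est, ref_id)
            if aln is None:
                continue
            aln = replace(aln, strand=strand, query_id=query_id)
            if best is None or aln.score > best.score:
                best = aln
    else:
        for strand, seq in (("+", query), ("-", revcomp(query))):
            # widen the band enough to reach any start position
            w = max(params.band_width, abs(len(ref_seq) - len(query)) // 2 + 8)
            aln = _aligned_or_none(
                seq, ref_seq, replace(params, band_width=w),
                (len(ref_seq) - len(query)) // 2, ref_id,
            )
            if aln is None:
                continue
            aln = replace(aln, strand=strand, query_id=query_id)
            if best is None or aln.score > best.score:
                best = aln
    if best is None:
        return None
    if apply_filters and not passes_filters(best, params):
        return None
    return left_align_indels(best, ref_seq)
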