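"""Draft consensus from noisy long reads.

The procedure mirrors a reference-free amplicon workflow: discard reads
outside a plausible length window, screen positional chimeras by split
alignment, pick ~20 seed reads near the expected amplicon length, and build
an iterative star-pileup consensus (medoid seed as the first template, then
plurality calls column by column; five iterations by default, the later
ones using every kept read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .align import AlignParams, LONG_READ_PARAMS, ReferenceIndex, map_read
from .polish import build_pileup
from .seqio import SequenceRecord


def length_filter(
    reads: Sequence[SequenceRecord],
    min_len: int = 1000,
    max_len: int = 10000,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[SequenceRecord]]:
    """Partition reads into (kept, too_short, too_long); bounds inclusive."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept, short, long_ = [], [], []
    for r in reads:
        (short if len(r) < min_len else long_ if len(r) > max_len else kept).append(r)
    return kept, short, long_


@dataclass
class ChimeraFlag:
    read: SequenceRecord
    breakpoint: int           # read coordinate of the segment boundary
    segments: list[tuple[int, int]]  # read-coordinate spans of aligned segments


def _segment_scan(read: SequenceRecord, ref: str, index: ReferenceIndex,
                  params: AlignParams, chunk: int = 250,
                  min_identity: float = 0.75):
    """Chunk-map a read and merge chunks into diagonal-consistent segments."""
    hits = []  # (read_pos, strand, diagonal, identity)
    for qpos in range(0, max(len(read) - chunk + 1, 1), chunk):
        piece = read.bases[qpos : qpos + chunk]
        if len(piece) < 50:
            continue
        aln = map_read(piece, ref, params, index=index, apply_filters=False)
        if aln is None or aln.identity < min_identity:
            hits.append(None)
            continue
        diag = aln.ref_start - qpos if aln.strand == "+" else aln.ref_start + qpos
        hits.append((qpos, min(qpos + chunk, len(read)), aln.strand, diag))
    segments = []
    cur = None
    for h in hits:
        if h is None:
            # an unmapped chunk is most likely local noise, not a junction;
            # only a strand or diagonal change closes a segment
            continue
        s, e, strand, diag = h
        if cur and cur[2] == strand and abs(diag - cur[3]) <= 150:
            cur = (cur[0], e, strand, diag)
        else:
            if cur:
                segments.append(cur)
            cur = (s, e, strand, diag)
    if cur:
        segments.append(cur)
    return [(s, e) for s, e, *_ in segments]


def screen_chimeras(
    long_reads: Sequence[SequenceRecord],
    template,
    params: AlignParams = LONG_READ_PARAMS,
    min_segment: int = 500,
    max_single_cover: float = 0.80,
    min_identity: float = 0.75,
) -> tuple[list[SequenceRecord], list[ChimeraFlag]]:
    """Split-alignment chimera screen against a draft or trusted template.

    A read is flagged when no single diagonal-consistent alignment covers
    >= ``max_single_cover`` of it while two disjoint segments of
    >= ``min_segment`` bp each align independently at >= ``min_identity``.
    """
    ref = template if isinstance(template, str) else template.bases
    index = ReferenceIndex(ref)
    clean, flagged = [], []
    for read in long_reads:
        segments = _segment_scan(read, ref, index, params,
                                 min_identity=min_identity)
        best_cover = max((e - s for s, e in segments), default=0) / max(len(read), 1)
        big = [seg for seg in segments if seg[1] - seg[0] >= min_segment]
        if best_cover < max_single_cover and len(big) >= 2:
            big.sort(key=lambda seg: seg[0] - seg[1])  # by size, descending
            first, second = sorted(big[:2])
            flagged.append(ChimeraFlag(read, (first[1] + second[0]) // 2,
                                       sorted(segments)))
        else:
            clean.append(read)
    return clean, flagged


def select_seed_reads(
    reads: Sequence[SequenceRecord],
    target_len: int,
    k: int = 20,
    tolerance: float = 0.10,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Uniform random sample of k reads within +-tolerance of target_len.

    The eligibility interval is closed.  Returns all eligible reads when
    fewer than k are available.
    """
    lo, hi = target_len * (1 - tolerance), target_len * (1 + tolerance)
    eligible = [r for r in reads if lo <= len(r) <= hi]
    if not eligible:
        raise ValueError(
            f"no reads within {tolerance:.0%} of {target_len} bp; widen the tolerance"
        )
    if len(eligible) <= k:
        return list(eligible)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in sorted(idx)]


@dataclass
class ConsensusDraft:
    """A called consensus with a per-column support track."""

    bases: str
    per_column_support: list[tuple[int, float]]  # (depth, agreement)
    iterations_run: int

    def support_table(self) -> str:
        lines = ["pos\tdepth\tagreement"]
        for i, (d, a) in enumerate(self.per_column_support):
            lines.append(f"{i + 1}\t{d}\t{a:.3f}")
        return "\n".join(lines) + "\n"


def _medoid(seeds: Sequence[SequenceRecord]) -> SequenceRecord:
    """Seed with the smallest summed edit distance to the other seeds."""
    if len(seeds) == 1:
        return seeds[0]
    total = np.zeros(len(seeds))
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            d = edlib.align(seeds[i].bases, seeds[j].bases, task="distance")
            dd = d["editDistance"]
            # strand-unaware reads: also try the reverse complement
            from .seqio import revcomp
            d2 = edlib.align(revcomp(seeds[i].bases), seeds[j].bases,
                             task="distance")["editDistance"]
            dd = min(dd, d2)
            total[i] += dd
            total[j] += dd
    # ties (e.g. two seeds) go to the longer read: a fuller template can be
    # refined by the pileup iterations, a truncated one cannot be extended
    order = sorted(range(len(seeds)), key=lambda i: (total[i], -len(seeds[i])))
    return seeds[order[0]]


def _call_columns(pileup, template: str):
    """Plurality call per column; strict >50% for deletions and insertions."""
    out = []
    support = []
    for col in pileup:
        depth = sum(col.base_counts.values()) + col.del_count
        if depth == 0:
            out.append(template[col.ref_pos])
            support.append((0, 0.0))
        elif col.del_count * 2 > depth:
            pass  # deleted column: emit nothing
        else:
            base, count = max(col.base_counts.items(),
                              key=lambda kv: (kv[1], -ord(kv[0][0])))
            # alphabetical tie-break
            ties = sorted(b for b, c in col.base_counts.items() if c == count)
            base = ties[0]
            out.append(base)
            support.append((depth, count / depth))
        ins_reads = sum(col.ins_counts.values())
        if depth > 0 and ins_reads * 2 > depth:
            seqs = sorted(col.ins_counts.items(), key=lambda kv: (-kv[1], kv[0]))
            ins_seq = seqs[0][0]
            out.append(ins_seq)
            support.extend([(depth, ins_reads / depth)] * len(ins_seq))
    return "".join(out), support


def build_consensus(
    seed_reads: Sequence[SequenceRecord],
    all_reads: Sequence[SequenceRecord],
    params: AlignParams = LONG_READ_PARAMS,
    n_iterations: int = 5,
) -> ConsensusDraft:
    """Iterative star-pileup consensus.

    Iteration 1 maps the seed reads to the medoid seed; later iterations map
    every kept read to the current template.  Stops early when the template
    no longer changes.
    """
    if not seed_reads:
        raise ValueError("seed_reads must be non-empty")
    template = _medoid(seed_reads).bases
    support: list[tuple[int, float]] = [(1, 1.0)] * len(template)
    iterations = 0
    for it in range(n_iterations):
        reads = seed_reads if it == 0 else all_reads
        index = ReferenceIndex(template)
        alns = []
        for r in reads:
            aln = map_read(r, template, params, index=index)
            if aln is not None:
                alns.append(aln)
        if not alns:
            raise RuntimeError("no reads mapped to the consensus template")
        pileup = build_pileup(alns, template)
        called, support = _call_columns(pileup, template)
        iterations = it + 1
        if called == template:
            break
        template = called
    return ConsensusDraft(template, support, iterations)
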