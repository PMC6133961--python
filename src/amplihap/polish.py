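"""Short-read polishing of a long-read draft, diploid-aware.

Pileup evidence from accurate short reads corrects draft base calls:
a column is corrected when a plurality allele reaches ``hom_frac`` of the
spanning reads and disagrees with the draft; columns whose top two allele
fractions both fall in the heterozygous band are left untouched and
reported as het candidates, so true heterozygous variation survives
(the "diploid mode" of consensus polishers).  The full map->pileup->correct
cycle repeats (with re-mapping) until no change or three rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import AlignParams, SHORT_READ_PARAMS, ReferenceIndex, map_read
from .seqio import AlignmentRecord, SequenceRecord

DEL = "<del>"


@dataclass
class PileupColumn:
    """Per-reference-position tallies of bases, deletions and insertions.

    ``ins_counts`` records insertions occurring *after* this position.
    ``depth`` counts reads spanning the column (base calls + deletions).
    """

    ref_pos: int
    base_counts: dict = field(default_factory=dict)
    del_count: int = 0
    ins_counts: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.del_count


def build_pileup(alignments: Sequence[AlignmentRecord], ref: str) -> list[PileupColumn]:
    """One column per reference position; soft-clipped bases are ignored."""
    cols = [PileupColumn(i) for i in range(len(ref))]
    for aln in alignments:
        if aln.query_seq is None:
            raise ValueError(f"alignment {aln.query_id!r} carries no sequence")
        if aln.ref_start < 0 or aln.ref_end > len(ref):
            raise ValueError(f"alignment {aln.query_id!r} outside reference bounds")
        rpos, qpos = aln.ref_start, 0
        seq = aln.query_seq
        for op, n in aln.cigar:
            if op in "M=X":
                for t in range(n):
                    b = seq[qpos + t]
                    col = cols[rpos + t]
                    col.base_counts[b] = col.base_counts.get(b, 0) + 1
                rpos += n
                qpos += n
            elif op == "I":
                if rpos > 0:
                    ins = seq[qpos : qpos + n]
                    col = cols[rpos - 1]
                    col.ins_counts[ins] = col.ins_counts.get(ins, 0) + 1
                qpos += n
            elif op == "D":
                for t in range(n):
                    cols[rpos + t].del_count += 1
                rpos += n
            elif op == "S":
                qpos += n
    return cols


@dataclass
class PolishReport:
    """Accounting of every change the polisher made."""

    n_substitutions: int = 0
    n_deletions_restored: int = 0   # bases the draft was missing, re-inserted
    n_insertions_removed: int = 0   # spurious draft bases removed
    changes: list = field(default_factory=list)  # (1-based pos, before, after)
    het_candidates: list = field(default_factory=list)  # 1-based positions
    rounds: int = 0

    @property
    def n_total(self) -> int:
        return self.n_substitutions + self.n_deletions_restored + self.n_insertions_removed

    def change_table(self) -> str:
        lines = ["pos\tbefore\tafter"]
        for pos, before, after in self.changes:
            lines.append(f"{pos}\t{before}\t{after}")
        return "\n".join(lines) + "\n"


def _column_decisions(pileup, draft, min_depth, hom_frac, het_band):
    """Yield per-column edits as (pos, kind, payload) on the current draft."""
    lo, hi = het_band
    edits = []
    hets = []
    for col in pileup:
        depth = col.depth
        if depth < min_depth:
            continue
        alleles = dict(col.base_counts)
        if col.del_count:
            alleles[DEL] = col.del_count
        ranked = sorted(alleles.items(), key=lambda kv: (-kv[1], kv[0]))
        top, top_n = ranked[0]
        fracs = [n / depth for _, n in ranked[:2]]
        draft_base = draft[col.ref_pos]
        if fracs[0] >= hom_frac:
            if top == DEL:
                edits.append((col.ref_pos, "remove", None))
            elif top != draft_base:
                edits.append((col.ref_pos, "sub", top))
        elif len(fracs) == 2 and lo <= fracs[0] <= hi and lo <= fracs[1] <= hi:
            hets.append(col.ref_pos)
        # insertions restored only when a single inserted sequence dominates
        ins_total = sum(col.ins_counts.values())
        if ins_total / depth >= hom_frac:
            seqs = sorted(col.ins_counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if seqs[0][1] / ins_total >= hom_frac:
                edits.append((col.ref_pos, "insert_after", seqs[0][0]))
    return edits, hets


def polish_consensus(
    draft: str,
    short_reads: Sequence[SequenceRecord],
    min_depth: int = 20,
    hom_frac: float = 0.80,
    het_band: tuple[float, float] = (0.25, 0.75),
    params: AlignParams = SHORT_READ_PARAMS,
    max_rounds: int = 3,
) -> tuple[str, PolishReport]:
    """Polish ``draft`` with short reads; returns (sequence, report).

    Reads are re-mapped to the updated sequence after every round, so no
    coordinate bookkeeping between rounds is needed.
    """
    if not short_reads:
        raise ValueError("no short reads supplied")
    report = PolishReport()
    current = draft
    for round_no in range(1, max_rounds + 1):
        index = ReferenceIndex(current)
        alns = [a for a in (map_read(r, current, params, index=index)
                            for r in short_reads) if a is not None]
        if not alns:
            raise ValueError("no short reads aligned to the draft")
        pileup = build_pileup(alns, current)
        edits, hets = _column_decisions(pileup, current, min_depth,
                                        hom_frac, het_band)
        report.rounds = round_no
        if round_no == 1:
            report.het_candidates = [p + 1 for p in hets]
        if not edits:
            break
        # apply right-to-left so earlier coordinates stay valid
        seq = current
        for pos, kind, payload in sorted(edits, key=lambda e: -e[0]):
            if kind == "sub":
                report.n_substitutions += 1
                report.changes.append((pos + 1, seq[pos], payload))
                seq = seq[:pos] + payload + seq[pos + 1:]
            elif kind == "remove":
                report.n_insertions_removed += 1
                report.changes.append((pos + 1, seq[pos], "-"))
                seq = seq[:pos] + seq[pos + 1:]
            else:  # insert_after
                report.n_deletions_restored += len(payload)
                report.changes.append((pos + 1, "-", payload))
                seq = seq[: pos + 1] + payload + seq[pos + 1:]
        current = seq
    report.changes.sort()
    return current, report
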