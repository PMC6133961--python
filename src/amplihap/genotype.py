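"""Variant calling, low-complexity masking, STR typing, duplication screen.

The caller is a plain high-coverage pileup genotyper: at amplicon coverage
(hundreds to thousands fold) allele fractions are essentially exact, so a
site is genotyped from fraction bands (>= 80% homozygous, 25-75% both
alleles heterozygous) after discarding noise alleles below a 10%
observation floor.  Homopolymer and short-tandem-repeat tracts are masked:
genotypes there are reported as undefined rather than guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .polish import DEL, PileupColumn
from .seqio import SequenceRecord, revcomp

FILTER_NAMES = ("low_depth", "low_complexity", "tri_allelic", "balance_skew")


# ---------------------------------------------------------------------------
# Low-complexity masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskInterval:
    start: int  # 0-based half-open
    end: int
    kind: str   # homopolymer | STR


class MaskTrack:
    """Sorted, maximal low-complexity intervals on a reference."""

    def __init__(self, intervals: Sequence[MaskInterval]):
        self.intervals = sorted(intervals, key=lambda m: (m.start, m.end))

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)

    def contains(self, pos: int, width: int = 1) -> bool:
        """True when [pos, pos+width) intersects any interval (0-based)."""
        return any(m.start < pos + width and m.end > pos for m in self.intervals)

    def to_bed(self, ref_id: str = "ref") -> str:
        return "".join(f"{ref_id}\t{m.start}\t{m.end}\t{m.kind}\n"
                       for m in self.intervals)


def mask_low_complexity(
    ref: str,
    min_homopolymer: int = 6,
    str_min_units: int = 4,
    str_motif_max: int = 6,
) -> MaskTrack:
    """Mask homopolymer runs and short tandem repeats on a reference.

    Every maximal single-base run of >= ``min_homopolymer`` and every tandem
    repeat of a motif of <= ``str_motif_max`` bp repeated >= ``str_min_units``
    times (partial trailing units included) becomes one interval.
    """
    out = [MaskInterval(m.start(), m.end(), "homopolymer")
           for m in re.finditer(r"(A+|C+|G+|T+)", ref)
           if m.end() - m.start() >= min_homopolymer]
    n = len(ref)
    for k in range(2, str_motif_max + 1):
        i = 0
        while i + k * str_min_units <= n:
            motif = ref[i : i + k]
            if len(set(motif)) == 1:  # homopolymer, handled above
                i += 1
                continue
            j = i + k
            while j + k <= n and ref[j : j + k] == motif:
                j += k
            units = (j - i) // k
            if units >= str_min_units:
                # extend over partial trailing and leading units
                t = 0
                while j + t < n and ref[j + t] == motif[t % k]:
                    t += 1
                u = 0
                while i - u - 1 >= 0 and ref[i - u - 1] == motif[(k - 1 - u) % k]:
                    u += 1
                out.append(MaskInterval(i - u, j + t, "STR"))
                i = j + t
            else:
                i += 1
    # merge overlapping intervals of the same kind
    out.sort(key=lambda m: (m.start, m.end))
    merged: list[MaskInterval] = []
    for m in out:
        if merged and m.start <= merged[-1].end and m.kind == merged[-1].kind:
            merged[-1] = MaskInterval(merged[-1].start,
                                      max(merged[-1].end, m.end), m.kind)
        else:
            merged.append(m)
    return MaskTrack(merged)


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------

@dataclass
class VariantCall:
    """One emitted site: alleles, per-sample genotypes, evidence, filters.

    ``genotypes`` maps sample -> allele-index pair (0 = reference) or None
    for an undefined genotype; ``allele_counts`` maps sample -> {allele: n}.
    """

    pos: int                     # 1-based, anchored VCF-style for indels
    ref_allele: str
    alt_alleles: list[str]
    genotypes: dict[str, Optional[tuple[int, int]]]
    depths: dict[str, int]
    allele_counts: dict[str, dict[str, int]]
    filters: set[str] = field(default_factory=set)

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref_allele) for a in self.alt_alleles)

    def genotype_string(self, sample: str) -> str:
        gt = self.genotypes.get(sample)
        return "./." if gt is None else f"{gt[0]}/{gt[1]}"


def left_normalize(pos0: int, ref: str, alt: str, refseq: str) -> tuple[int, str, str]:
    """Left-normalize an indel (0-based ``pos0``) against ``refseq``."""
    # trim identical trailing bases, shifting left through repeats
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] != alt[1]:
        break
    while (len(ref) > 1 or len(alt) > 1) and ref[-1] == alt[-1] and pos0 > 0:
        ref = refseq[pos0 - 1] + ref[:-1]
        alt = refseq[pos0 - 1] + alt[:-1]
        pos0 -= 1
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0, ref, alt


def _column_alleles(col: PileupColumn, ref_base: str):
    """Allele -> count for one column; insertions are composite alleles."""
    alleles = {b: c for b, c in col.base_counts.items()}
    if col.del_count:
        alleles[DEL] = col.del_count
    for seq, c in col.ins_counts.items():
        alleles[f"INS:{seq}"] = alleles.get(f"INS:{seq}", 0) + c
    return alleles


def _genotype_sample(alleles, depth, ref_base, min_depth, het_band, hom_frac,
                     obs_floor=0.10):
    """Returns (genotype alleles tuple or None, observed alleles, flag)."""
    if depth < min_depth:
        return None, [], "low_depth"
    observed = [(a, c) for a, c in sorted(alleles.items(),
                                          key=lambda kv: (-kv[1], kv[0]))
                if c / depth >= obs_floor and not a.startswith("INS:")]
    ins_obs = [(a, c) for a, c in alleles.items()
               if a.startswith("INS:") and c / depth >= obs_floor]
    observed = observed + sorted(ins_obs, key=lambda kv: -kv[1])
    observed.sort(key=lambda kv: (-kv[1], kv[0]))
    if len(observed) > 2:
        return None, [a for a, _ in observed], "tri_allelic"
    if not observed:
        return None, [], "balance_skew"
    lo, hi = het_band
    top, top_n = observed[0]
    f1 = top_n / depth
    # insertion alleles co-exist with the anchor base call of the same reads:
    # a homozygous insertion shows the anchor base at ~100% plus INS at ~100%
    if len(observed) == 2 and observed[1][0].startswith("INS:"):
        ins_a, ins_n = observed[1]
        fi = ins_n / depth
        if fi >= hom_frac:
            return (ins_a, ins_a), [top, ins_a], None
        if lo <= fi <= hi:
            return (top, ins_a), [top, ins_a], None
        return (top, top), [top], None
    if len(observed) == 1 and top.startswith("INS:"):
        return (top, top), [top], None
    if f1 >= hom_frac:
        return (top, top), [top], None
    if len(observed) == 2:
        f2 = observed[1][1] / depth
        if lo <= f1 <= hi and lo <= f2 <= hi:
            return (top, observed[1][0]), [a for a, _ in observed], None
    return None, [a for a, _ in observed], "balance_skew"


def call_variants(
    sample_pileups: dict[str, list[PileupColumn]],
    ref: str,
    mask: Optional[MaskTrack] = None,
    min_depth: int = 20,
    het_band: tuple[float, float] = (0.25, 0.75),
    hom_frac: float = 0.80,
) -> list[VariantCall]:
    """Joint pileup genotyping of all samples against one reference.

    A site is emitted iff at least one sample carries a non-reference
    genotype or allele evidence triggering a filter; masked columns are
    reported (as undefined genotypes) only where non-reference evidence
    exists, keeping the output to actual variant sites.
    """
    samples = list(sample_pileups)
    lens = {len(p) for p in sample_pileups.values()}
    if len(lens) != 1 or lens.pop() != len(ref):
        raise ValueError("sample pileups must all be against the given reference")
    if mask is None:
        mask = MaskTrack([])

    raw_sites = []
    for i in range(len(ref)):
        ref_base = ref[i]
        per_sample = {}
        any_reason = False
        for s in samples:
            col = sample_pileups[s][i]
            depth = col.depth
            alleles = _column_alleles(col, ref_base)
            gt, obs, flag = _genotype_sample(
                alleles, depth, ref_base, min_depth, het_band, hom_frac
            )
            per_sample[s] = (gt, obs, flag, depth, alleles)
            nonref = [a for a in obs if a != ref_base]
            if nonref or (gt is not None and set(gt) != {ref_base}):
                any_reason = True
        if not any_reason:
            continue
        raw_sites.append((i, per_sample))

    calls: list[VariantCall] = []
    used_del_run: set[int] = set()
    for idx, (i, per_sample) in enumerate(raw_sites):
        if i in used_del_run:
            continue
        # collect site-level alt alleles in deterministic order
        site_alleles: list[str] = []
        for s in samples:
            gt, obs, flag, depth, alleles = per_sample[s]
            for a in obs:
                if a != ref[i] and a not in site_alleles:
                    site_alleles.append(a)
        if not site_alleles and not any(per_sample[s][2] for s in samples):
            continue

        # deletion runs: merge consecutive columns where DEL is called
        del_len = 0
        if DEL in site_alleles:
            j = i
            run = []
            while j < len(ref):
                site = next((ps for (p, ps) in raw_sites if p == j), None)
                if site is None:
                    break
                if not any(site[s][0] is not None and DEL in site[s][0]
                           for s in samples):
                    break
                run.append(j)
                j += 1
            del_len = max(len(run), 1)
            used_del_run.update(run[1:])

        # indels touch the following column too (insertions live between
        # columns; deletions span a run), so widen the mask query for them
        width = max(del_len, 1)
        if any(a.startswith("INS:") for a in site_alleles):
            width = max(width, 2)
        in_mask = mask.contains(i, width)

        pos0, ref_allele, alts, gt_map, counts_map, depths = _format_site(
            i, per_sample, samples, ref, site_alleles, del_len
        )
        filters = set()
        if in_mask:
            filters.add("low_complexity")
        for s in samples:
            gt, obs, flag, depth, alleles = per_sample[s]
            if flag and not in_mask:
                filters.add(flag)
        call = VariantCall(pos0 + 1, ref_allele, alts, gt_map, depths,
                           counts_map, filters)
        if in_mask:
            call.genotypes = {s: None for s in samples}
        calls.append(call)
    return calls


def _format_site(i, per_sample, samples, ref, site_alleles, del_len):
    """Convert a per-column call into anchored, left-normalized VCF alleles."""
    is_indel = DEL in site_alleles or any(a.startswith("INS:") for a in site_alleles)
    if not is_indel:
        pos0 = i
        ref_allele = ref[i]
        alts = [a for a in site_alleles]
        allele_of = {ref_allele: 0}
        allele_of.update({a: k + 1 for k, a in enumerate(alts)})
    else:
        anchor = max(i - 1, 0)
        ref_allele = ref[anchor : i + max(del_len, 1)]
        alts = []
        allele_of = {}
        for a in site_alleles:
            if a == DEL:
                vcf_alt = ref[anchor : i]  # anchor base(s) only
            elif a.startswith("INS:"):
                vcf_alt = ref[anchor : i + 1] + a[4:] + ref[i + 1 : i + max(del_len, 1)]
            else:
                vcf_alt = ref[anchor : i] + a + ref[i + 1 : i + max(del_len, 1)]
            if vcf_alt not in alts:
                alts.append(vcf_alt)
            allele_of[a] = alts.index(vcf_alt) + 1
        pos0 = anchor
        # left-normalize against the single alternate when unambiguous
        if len(alts) == 1:
            p, r, a = left_normalize(pos0, ref_allele, alts[0], ref)
            pos0, ref_allele, alts = p, r, [a]

    gt_map, counts_map, depths = {}, {}, {}
    for s in samples:
        gt, obs, flag, depth, alleles = per_sample[s]
        depths[s] = depth
        counts_map[s] = dict(alleles)
        if gt is None:
            gt_map[s] = None
        else:
            pair = tuple(sorted(allele_of.get(a, 0) if a != ref[i] else 0
                                for a in gt))
            gt_map[s] = pair
    return pos0, ref_allele, alts, gt_map, counts_map, depths


# ---------------------------------------------------------------------------
# STR typing
# ---------------------------------------------------------------------------

@dataclass
class StrGenotype:
    sample: str
    alleles: list[tuple[str, int]]   # (tract sequence, supporting reads)
    n_spanning: int
    called: bool


def _find_anchor(seq: str, anchor: str, max_mismatch: int = 1) -> int:
    """Leftmost occurrence of ``anchor`` in ``seq`` with <= 1 mismatch, or -1."""
    hit = seq.find(anchor)
    if hit >= 0:
        return hit
    la = len(anchor)
    if len(seq) < la:
        return -1
    s = np.frombuffer(seq.encode(), np.uint8)
    a = np.frombuffer(anchor.encode(), np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, la)
    mism = (windows != a).sum(axis=1)
    best = int(np.argmin(mism))
    return best if mism[best] <= max_mismatch else -1


def genotype_str(
    reads: Sequence[SequenceRecord],
    ref: str,
    str_interval: tuple[int, int],
    flank_len: int = 20,
    min_spanning: int = 5,
) -> StrGenotype:
    """Type an STR from reads spanning both flanks.

    For each read containing both flank anchors (exact or one mismatch) the
    enclosed tract is extracted verbatim; tracts are clustered by sequence
    and the top one or two reported with their read counts.  Fewer than
    ``min_spanning`` spanning reads yields a no-call.
    """
    s, e = str_interval
    if not (0 <= s < e <= len(ref)):
        raise ValueError("STR interval outside the reference")
    left = ref[max(s - flank_len, 0) : s]
    right = ref[e : e + flank_len]
    tracts: dict[str, int] = {}
    n_span = 0
    for read in reads:
        for seq in (read.bases, revcomp(read.bases)):
            li = _find_anchor(seq, left)
            if li < 0:
                continue
            tract_start = li + len(left)
            ri = _find_anchor(seq[tract_start:], right)
            if ri < 0:
                continue
            tract = seq[tract_start : tract_start + ri]
            if len(tract) > (e - s) + 5 * (e - s):
                continue
            tracts[tract] = tracts.get(tract, 0) + 1
            n_span += 1
            break
    ranked = sorted(tracts.items(), key=lambda kv: (-kv[1], kv[0]))
    if n_span < min_spanning:
        return StrGenotype("", [], n_span, False)
    # keep the top two alleles, dropping noise clusters below 20% of spanning
    alleles = [(t, c) for t, c in ranked[:2] if c / n_span >= 0.20]
    return StrGenotype("", alleles, n_span, True)


# ---------------------------------------------------------------------------
# Duplication signatures
# ---------------------------------------------------------------------------

@dataclass
class DuplicationReport:
    n_tri_allelic: int
    balance_skew_sites: list[int]        # 1-based positions rejecting 50:50
    het_fraction: dict[str, float]
    n_het_tests: int
    verdict: str

    def summary(self) -> str:
        lines = [
            f"tri-allelic sites: {self.n_tri_allelic}",
            f"balance-skew sites (Bonferroni 0.05): {len(self.balance_skew_sites)}",
        ]
        for s, f in self.het_fraction.items():
            lines.append(f"heterozygous-site fraction [{s}]: {f:.3f}")
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)


def duplication_signatures(
    calls: Sequence[VariantCall],
    alpha: float = 0.05,
) -> DuplicationReport:
    """Screen genotype calls for multi-copy (duplicated locus) signatures.

    A duplicated locus sequenced as one amplicon shows tri-allelic sites,
    heterozygous sites with 25:75-like allele balance, and elevated
    heterozygosity; absence of all three supports a single-copy locus.
    """
    n_tri = sum(1 for c in calls if "tri_allelic" in c.filters)
    tests = []  # (pos, pvalue)
    het_counts: dict[str, int] = {}
    def_counts: dict[str, int] = {}
    for c in calls:
        for s, gt in c.genotypes.items():
            if gt is None:
                continue
            def_counts[s] = def_counts.get(s, 0) + 1
            if gt[0] == gt[1]:
                continue
            het_counts[s] = het_counts.get(s, 0) + 1
            counts = c.allele_counts.get(s, {})
            ins_n = sum(n for a, n in counts.items() if a.startswith("INS:"))
            depth = c.depths.get(s, 0)
            if ins_n and depth and 0 < ins_n < depth:
                # insertion het: every read also shows the anchor base, so
                # the complement of the INS allele is depth - INS
                k, n = ins_n, depth
            else:
                ranked = sorted((kv for kv in counts.items()
                                 if not kv[0].startswith("INS:")),
                                key=lambda kv: -kv[1])[:2]
                if len(ranked) < 2:
                    continue
                k = ranked[0][1]
                n = ranked[0][1] + ranked[1][1]
            p = stats.binomtest(k, n, 0.5).pvalue
            tests.append((c.pos, p, max(k, n - k) / n))
    m = len(tests)
    # a duplicated locus mixed 50:50 shows ~25:75 at het sites: require both
    # a Bonferroni-corrected rejection of 50:50 and an effect size near 3:1
    skew = sorted({pos for pos, p, frac in tests
                   if m and p * m < alpha and 0.70 <= frac <= 0.80})
    het_frac = {s: het_counts.get(s, 0) / def_counts[s]
                for s in def_counts if def_counts[s]}
    verdict = ("no duplication signature"
               if n_tri == 0 and not skew
               else "possible duplication signature")
    return DuplicationReport(n_tri, skew, het_frac, m, verdict)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(
    calls: Sequence[VariantCall],
    samples: Sequence[str],
    path,
    ref_id: str = "consensus",
    ref_len: Optional[int] = None,
) -> None:
    """Write calls as VCF 4.2 (FILTER strings match the internal flag names)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(ref_id, length=ref_len)
    for name in FILTER_NAMES:
        header.filters.add(name, None, None, f"site flagged {name}")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: c.pos):
            rec = out.new_record()
            rec.contig = ref_id
            rec.start = c.pos - 1
            rec.alleles = tuple([c.ref_allele] + (c.alt_alleles or [c.ref_allele]))
            if c.filters:
                for f in sorted(c.filters):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            for s in samples:
                gt = c.genotypes.get(s)
                rec.samples[s]["GT"] = gt if gt is not None else (None, None)
                rec.samples[s]["DP"] = c.depths.get(s, 0)
            out.write(rec)
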