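"""Synthetic data generator for the whole pipeline.

Emulates the structure of a multi-kilobase diploid MHC-like amplicon
experiment: a ~9 kb template carrying SNPs, short indels, one heterozygous
dinucleotide STR and several homopolymer tracts; noisy long reads with
substitution/insertion/deletion errors; accurate 2 x 250 bp paired short
reads; a lambda-sized spike-in control; and positional chimeras.

Every read id carries its ground truth after the reserved token
``|truth|`` (source haplotype, coordinates, realized error counts).  Only
tests may parse it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .seqio import SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", np.uint8)
TRUTH_TOKEN = "|truth|"


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant: 1-based position on hap A, VCF-style alleles."""

    pos: int
    ref: str
    alt: str
    kind: str  # SNP | indel | STR


@dataclass(frozen=True)
class Feature:
    """Labelled half-open interval [start, end) on hap A (0-based)."""

    start: int
    end: int
    kind: str  # exon | homopolymer | STR


@dataclass
class DiploidTemplate:
    """Two haplotypes of one amplicon plus the variant/feature ground truth."""

    hap_a: str
    hap_b: str
    truth_variants: list[TruthVariant]
    features: list[Feature]

    def masked_intervals(self) -> list[tuple[int, int]]:
        return [(f.start, f.end) for f in self.features
                if f.kind in ("homopolymer", "STR")]

    def variant_in_mask(self, v: TruthVariant, pad: int = 0) -> bool:
        s, e = v.pos - 1, v.pos - 1 + len(v.ref)
        return any(s < me + pad and e > ms - pad
                   for ms, me in self.masked_intervals())


@dataclass(frozen=True)
class NoiseModel:
    """Per-base i.i.d. error rates and the read-length distribution.

    ``length_dist`` is (family, mean bp, sd bp, min bp, max bp); the only
    family implemented is a truncated log-normal, parameterized by its mean
    and standard deviation.  ``homopolymer_indel_multiplier`` > 1 inflates
    insertion and deletion rates inside annotated homopolymer/STR tracts.
    """

    sub_rate: float = 0.048
    ins_rate: float = 0.041
    del_rate: float = 0.030
    length_dist: tuple = ("lognormal", 4186.0, 2550.0, 200, 12000)
    homopolymer_indel_multiplier: float = 1.0

    def __post_init__(self):
        if not 0 <= self.sub_rate + self.ins_rate + self.del_rate < 1:
            raise ValueError("component error rates must sum to < 1")


NOISELESS = NoiseModel(0.0, 0.0, 0.0)


def _draw_lengths(rng, dist, n, cap):
    """Read lengths: log-normal, rejected below ``min``, clamped above.

    Draws above ``min(max, cap)`` are clamped rather than redrawn: a read
    cannot be longer than its molecule, so the over-length mass piles up at
    full molecule length — the spike of full-length amplicon reads that
    seed selection relies on.
    """
    family, mean, sd, lo, hi = dist
    if family != "lognormal":
        raise ValueError(f"unsupported length family {family!r}")
    hi = min(hi, cap)
    lo = min(lo, cap)
    if sd <= 0:
        return np.full(n, int(min(mean, cap)))
    s2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2
    out = np.empty(n, np.int64)
    todo = np.arange(n)
    while todo.size:
        draw = rng.lognormal(mu, math.sqrt(s2), todo.size).astype(np.int64)
        draw = np.minimum(draw, hi)
        ok = draw >= lo
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrSpec:
    """Heterozygous STR: reference tract vs alternative tract at ``pos`` (1-based)."""

    pos: int = 369
    ref_tract: str = "GTGTGT" + "T" + "GTGTGTGT"  # (GT)3 T (GT)4
    alt_tract: str = "GT" * 9                     # (GT)9


def _random_seq(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _scan_homopolymers(seq: str, min_len: int) -> list[tuple[int, int]]:
    return [(m.start(), m.end())
            for m in re.finditer(r"(A+|C+|G+|T+)", seq)
            if m.end() - m.start() >= min_len]


def make_amplicon_template(
    length: int = 9001,
    n_snps: int = 102,
    n_indels: int = 7,
    str_spec: Optional[StrSpec] = StrSpec(),
    homopolymer_spec: Sequence[tuple[str, int]] = (
        ("T", 13), ("A", 10), ("A", 9), ("T", 8), ("G", 8), ("C", 8),
    ),
    gc_fraction: float = 0.41,
    seed: int = 0,
    edge_margin: int = 100,
    max_indel_len: int = 3,
) -> DiploidTemplate:
    """Build a diploid template with planted SNPs, indels, STR and homopolymers.

    Variants avoid the first/last ``edge_margin`` bp (primer-like anchors)
    and all low-complexity tracts; hap B is hap A with every alternative
    allele applied.  Deterministic for a fixed seed.
    """
    if length < 1000:
        raise ValueError("template length must be >= 1000")
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length, gc_fraction))

    blocked: list[tuple[int, int]] = []  # tracts where variants may not land

    # plant homopolymer tracts, evenly spread through the middle
    n_hp = len(homopolymer_spec)
    hp_anchors = np.linspace(edge_margin + 200, length - edge_margin - 200,
                             n_hp + 2)[1:-1].astype(int)
    for (base, run), pos in zip(homopolymer_spec, hp_anchors):
        seq[pos : pos + run] = base * run
        # break accidental extensions at the tract boundaries
        for edge, off in ((pos - 1, -1), (pos + run, +1)):
            if 0 <= edge < length and seq[edge] == base:
                seq[edge] = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        blocked.append((pos - 2, pos + run + 2))

    # plant the STR tract on hap A
    str_variant = None
    if str_spec is not None:
        s0 = str_spec.pos - 1
        tract = str_spec.ref_tract
        seq[s0 : s0 + len(tract)] = tract
        for edge in (s0 - 1, s0 + len(tract)):
            if 0 <= edge < length and seq[edge] in "GT":
                seq[edge] = "A"
        blocked.append((s0 - 2, s0 + len(tract) + 2))
        str_variant = TruthVariant(str_spec.pos, tract, str_spec.alt_tract, "STR")

    hap_a = "".join(seq)
    # block every homopolymer run >= 6 that arose by chance as well
    for s, e in _scan_homopolymers(hap_a, 6):
        blocked.append((s - 2, e + 2))

    # candidate variant positions: spaced, outside blocked tracts and margins
    spacing = 2 * max_indel_len + 6
    candidates = []
    pos = edge_margin
    blocked.sort()
    while pos < length - edge_margin - max_indel_len - 1:
        if not any(bs <= pos < be for bs, be in blocked):
            candidates.append(pos)
            pos += spacing
        else:
            pos += 1
    n_var = n_snps + n_indels
    if n_var > len(candidates):
        raise ValueError(
            f"cannot place {n_var} variants: only {len(candidates)} "
            f"non-overlapping positions available"
        )
    chosen = rng.choice(len(candidates), size=n_var, replace=False)
    chosen_pos = sorted(candidates[i] for i in chosen)
    snp_idx = set(rng.choice(n_var, size=n_snps, replace=False).tolist())

    variants: list[TruthVariant] = []
    for i, p0 in enumerate(chosen_pos):
        if i in snp_idx:
            ref = hap_a[p0]
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            variants.append(TruthVariant(p0 + 1, ref, alt, "SNP"))
        else:
            ilen = int(rng.integers(1, max_indel_len + 1))
            if rng.random() < 0.5:  # deletion of ilen bases after the anchor
                ref = hap_a[p0 : p0 + 1 + ilen]
                variants.append(TruthVariant(p0 + 1, ref, ref[0], "indel"))
            else:  # insertion after the anchor
                ins = "".join("ACGT"[b] for b in rng.integers(0, 4, ilen))
                ref = hap_a[p0]
                variants.append(TruthVariant(p0 + 1, ref, ref + ins, "indel"))
    if str_variant is not None:
        variants.append(str_variant)
    variants.sort(key=lambda v: v.pos)

    hap_b = apply_variants(hap_a, variants)

    features = [Feature(s, e, "homopolymer") for s, e in _scan_homopolymers(hap_a, 6)]
    if str_spec is not None:
        s0 = str_spec.pos - 1
        features.append(Feature(s0, s0 + len(str_spec.ref_tract), "STR"))
    if length >= 7000:
        features.append(Feature(6568, 6838, "exon"))  # exon-2-like interval
    features.sort(key=lambda f: f.start)
    return DiploidTemplate(hap_a, hap_b, variants, features)


def apply_variants(seq: str, variants: Sequence[TruthVariant]) -> str:
    """Apply alternative alleles (1-based, on ``seq``) right to left."""
    out = seq
    for v in sorted(variants, key=lambda v: -v.pos):
        s = v.pos - 1
        if out[s : s + len(v.ref)] != v.ref:
            raise ValueError(f"variant at {v.pos} does not match the sequence")
        out = out[:s] + v.alt + out[s + len(v.ref):]
    return out


# ---------------------------------------------------------------------------
# Noise application
# ---------------------------------------------------------------------------

def _apply_noise(frag_enc: np.ndarray, noise: NoiseModel, rng,
                 tract_mask: Optional[np.ndarray] = None):
    """Apply i.i.d. per-base errors; returns (sequence, nsub, nins, ndel)."""
    n = frag_enc.size
    sub = np.full(n, noise.sub_rate)
    dele = np.full(n, noise.del_rate)
    ins = np.full(n, noise.ins_rate)
    if tract_mask is not None and noise.homopolymer_indel_multiplier != 1.0:
        m = noise.homopolymer_indel_multiplier
        dele[tract_mask] *= m
        ins[tract_mask] *= m
    u = rng.random(n)
    sub_mask = u < sub
    del_mask = (u >= sub) & (u < sub + dele)
    ins_mask = rng.random(n) < ins
    out_base = frag_enc.copy()
    n_sub = int(sub_mask.sum())
    if n_sub:
        out_base[sub_mask] = (
            frag_enc[sub_mask] + 1 + rng.integers(0, 3, n_sub)
        ) % 4
    keep = ~del_mask
    counts = keep.astype(np.int64) + ins_mask
    total = int(counts.sum())
    off = np.cumsum(counts) - counts
    out = np.empty(total, np.uint8)
    out[off[keep]] = out_base[keep]
    if ins_mask.any():
        ins_bases = rng.integers(0, 4, int(ins_mask.sum())).astype(np.uint8)
        out[(off + keep)[ins_mask]] = ins_bases
    return (
        _BASES[out].tobytes().decode(),
        n_sub, int(ins_mask.sum()), int(del_mask.sum()),
    )


def _truth_id(prefix, i, **kv):
    return f"{prefix}{i:05d}{TRUTH_TOKEN}" + ";".join(f"{k}={v}" for k, v in kv.items())


def parse_truth(read_id: str) -> dict:
    """Parse the ``|truth|`` token of a simulated read id (tests only)."""
    _, _, tail = read_id.partition(TRUTH_TOKEN)
    out = {}
    for item in tail.split(";"):
        k, _, v = item.partition("=")
        if v.endswith("/1") or v.endswith("/2"):  # paired-read mate suffix
            v = v[:-2]
        out[k] = int(v) if v.lstrip("-").isdigit() else v
    return out


def _tract_mask_for(template, hap, start, length):
    if not isinstance(template, DiploidTemplate):
        return None
    mask = np.zeros(length, bool)
    # tract coordinates are on hap A; for hap B reads this is approximate,
    # which is acceptable for an error-inflation heuristic
    for s, e in template.masked_intervals():
        lo, hi = max(s - start, 0), min(e - start, length)
        if lo < hi:
            mask[lo:hi] = True
    return mask


# ---------------------------------------------------------------------------
# Read simulators
# ---------------------------------------------------------------------------

def simulate_long_reads(
    template: Union[DiploidTemplate, str],
    n_reads: int,
    noise: NoiseModel = NoiseModel(),
    hap_ratio: float = 1.0,
    seed: int = 0,
    id_prefix: str = "lr",
    start_model: str = "ends",
) -> list[SequenceRecord]:
    """Noisy single-molecule long reads from a diploid (or haploid) template.

    ``hap_ratio`` is the probability a read derives from hap A; 1.0 emulates
    sequencing a homozygous individual.

    ``start_model='ends'`` (the amplicon model) starts every read at one end
    of the molecule on either strand and truncates it at the drawn length,
    as adapter-ligated amplicon molecules behave in a nanopore run; coverage
    is then roughly even across the amplicon.  ``'uniform'`` places fragments
    uniformly (appropriate for sheared genomic DNA such as a spike-in
    control).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if start_model not in ("ends", "uniform"):
        raise ValueError("start_model must be 'ends' or 'uniform'")
    rng = np.random.default_rng(seed)
    haps = ((template, template) if isinstance(template, str)
            else (template.hap_a, template.hap_b))
    enc = [np.frombuffer(h.encode(), np.uint8) for h in haps]
    enc = [np.searchsorted(_BASES, e) for e in enc]
    reads = []
    for i in range(n_reads):
        h = 0 if rng.random() < hap_ratio else 1
        hap = haps[h]
        L = int(_draw_lengths(rng, noise.length_dist, 1, len(hap))[0])
        if start_model == "ends":
            # left end read forward, or right end read on the minus strand
            if rng.random() < 0.5:
                start, strand = 0, "+"
            else:
                start, strand = len(hap) - L, "-"
        else:
            start = int(rng.integers(0, len(hap) - L + 1))
            strand = "-" if rng.random() < 0.5 else "+"
        tracts = (_tract_mask_for(template, h, start, L)
                  if noise.homopolymer_indel_multiplier != 1.0 else None)
        seq, nsub, nins, ndel = _apply_noise(
            enc[h][start : start + L], noise, rng, tracts
        )
        if strand == "-":
            seq = revcomp(seq)
        rid = _truth_id(id_prefix, i, hap="AB"[h], start=start, len=L,
                        strand=strand, sub=nsub, ins=nins, del_=ndel)
        rid = rid.replace("del_=", "del=")
        reads.append(SequenceRecord(rid, seq, [9] * len(seq)))
    return reads


def simulate_short_reads(
    template: Union[DiploidTemplate, tuple[str, str], str],
    n_pairs: int,
    read_len: int = 250,
    frag_mean: float = 300.0,
    frag_sd: float = 60.0,
    error_rate: float = 0.001,
    seed: int = 0,
    id_prefix: str = "sr",
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Accurate paired-end short reads (R1 forward, R2 reverse-complement)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(template, DiploidTemplate):
        haps = (template.hap_a, template.hap_b)
    elif isinstance(template, str):
        haps = (template, template)
    else:
        haps = template
    q = 40 if error_rate <= 0 else min(40, round(-10 * math.log10(error_rate)))
    r1s, r2s = [], []
    for i in range(n_pairs):
        h = int(rng.random() < 0.5)
        hap = haps[h]
        frag_len = int(np.clip(round(rng.normal(frag_mean, frag_sd)),
                               30, len(hap)))
        start = int(rng.integers(0, len(hap) - frag_len + 1))
        frag = hap[start : start + frag_len]
        r1 = frag[:read_len]
        r2 = revcomp(frag)[:read_len]
        out = []
        for seq in (r1, r2):
            if error_rate > 0:
                enc = np.searchsorted(_BASES, np.frombuffer(seq.encode(), np.uint8))
                m = rng.random(enc.size) < error_rate
                if m.any():
                    enc = enc.copy()
                    enc[m] = (enc[m] + 1 + rng.integers(0, 3, int(m.sum()))) % 4
                seq = _BASES[enc].tobytes().decode()
            out.append(seq)
        rid = _truth_id(id_prefix, i, hap="AB"[h], start=start, frag=frag_len)
        r1s.append(SequenceRecord(rid + "/1", out[0], [q] * len(out[0])))
        r2s.append(SequenceRecord(rid + "/2", out[1], [q] * len(out[1])))
    return r1s, r2s


def simulate_control(
    ref_length: int = 48502,
    n_reads: int = 2000,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """A lambda-sized random control reference plus noisy long reads from it."""
    rng = np.random.default_rng(seed)
    ref = _random_seq(rng, ref_length, 0.5)
    reads = simulate_long_reads(
        ref, n_reads, noise, hap_ratio=1.0,
        seed=int(rng.integers(0, 2**31)), id_prefix="ctrl",
        start_model="uniform",
    )
    return SequenceRecord("control", ref), reads


def simulate_chimeras(
    source_a: Union[DiploidTemplate, str],
    source_b: Union[DiploidTemplate, str],
    breakpoint_fraction: float,
    n_reads: int,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> list[SequenceRecord]:
    """Positional chimeras: prefix from source A, suffix from source B.

    The prefix/suffix split point (pre-noise read coordinate) is recorded in
    the read id as ``bp=``; ``breakpoint_fraction=0`` yields pure source-B
    reads.
    """
    rng = np.random.default_rng(seed)
    seq_a = source_a.hap_a if isinstance(source_a, DiploidTemplate) else source_a
    seq_b = source_b.hap_a if isinstance(source_b, DiploidTemplate) else source_b
    reads = []
    for i in range(n_reads):
        L = int(_draw_lengths(rng, noise.length_dist, 1,
                              min(len(seq_a), len(seq_b)))[0])
        pre = int(round(breakpoint_fraction * L))
        suf = L - pre
        sa = int(rng.integers(0, len(seq_a) - pre + 1)) if pre else 0
        sb = int(rng.integers(0, len(seq_b) - suf + 1)) if suf else 0
        frag = seq_a[sa : sa + pre] + seq_b[sb : sb + suf]
        enc = np.searchsorted(_BASES, np.frombuffer(frag.encode(), np.uint8))
        seq, nsub, nins, ndel = _apply_noise(enc, noise, rng)
        rid = _truth_id("chim", i, bp=pre, len=L, a_start=sa, b_start=sb,
                        sub=nsub, ins=nins, del_=ndel).replace("del_=", "del=")
        reads.append(SequenceRecord(rid, seq, [9] * len(seq)))
    return reads


# ---------------------------------------------------------------------------
# Population helpers (multi-individual scenarios)
# ---------------------------------------------------------------------------

def make_haplotype_pool(
    template: DiploidTemplate,
    n_haplotypes: int,
    seed: int = 0,
    include_parental: bool = True,
) -> tuple[list[str], np.ndarray]:
    """Distinct haplotype sequences built from the template's variant set.

    Returns (sequences, allele matrix) where row h of the 0/1 matrix says
    which non-STR variants haplotype h carries.  Haplotype 0 is hap A
    (all reference) and haplotype 1 is hap B (all alternative) when
    ``include_parental``.
    """
    rng = np.random.default_rng(seed)
    variants = [v for v in template.truth_variants if v.kind != "STR"]
    nv = len(variants)
    rows: list[tuple] = []
    if include_parental:
        rows = [tuple([0] * nv), tuple([1] * nv)]
    guard = 0
    while len(rows) < n_haplotypes:
        cand = tuple(rng.integers(0, 2, nv).tolist())
        if cand not in rows:
            rows.append(cand)
        guard += 1
        if guard > 1000 * n_haplotypes:
            raise ValueError("cannot build that many distinct haplotypes")
    mat = np.array(rows[:n_haplotypes], dtype=np.int8)
    seqs = []
    str_vars = [v for v in template.truth_variants if v.kind == "STR"]
    for row in mat:
        chosen = [v for v, a in zip(variants, row) if a == 1]
        # parental hap B also carries the alternative STR tract
        if include_parental and tuple(row.tolist()) == tuple([1] * nv):
            chosen = chosen + str_vars
        seqs.append(apply_variants(template.hap_a, chosen))
    return seqs, mat


def sample_individuals(
    n_haplotypes: int,
    frequencies: Sequence[float],
    n_individuals: int,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Draw diploid individuals as ordered haplotype-index pairs (HWE)."""
    rng = np.random.default_rng(seed)
    f = np.asarray(frequencies, float)
    if f.size != n_haplotypes or abs(f.sum() - 1) > 1e-9:
        raise ValueError("frequencies must match n_haplotypes and sum to 1")
    return [tuple(rng.choice(n_haplotypes, 2, p=f).tolist())
            for _ in range(n_individuals)]
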