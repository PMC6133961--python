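"""Statistical haplotype phasing by expectation-maximization.

Unphased diploid genotypes over biallelic sites (SNPs and indels coded
0/1 alike) are resolved into haplotype pairs with the classical
haplotype-frequency EM: the E-step distributes each individual's genotype
over compatible ordered haplotype pairs in proportion to current frequency
products, the M-step re-estimates frequencies from the expected counts.
Sites with many simultaneously ambiguous (heterozygous or missing)
genotypes are handled by partitioning into blocks of bounded ambiguity,
phasing each block, then ligating blocks left to right with a restricted
EM over the two possible joins per individual.

Multiple restarts from perturbed initial frequencies guard against local
optima; given the seed, the result is deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Sites (1-based positions, ref/alt labels) by individuals (0/1/2/missing).

    ``genotypes[i][j]`` counts alternative alleles of individual i at site j;
    ``MISSING`` (-1) marks an undefined genotype.  STR and masked sites are
    expected to be excluded upstream.
    """

    positions: list[int]
    ref_alleles: list[str]
    alt_alleles: list[str]
    individuals: list[str]
    genotypes: np.ndarray  # shape (n_individuals, n_sites), int8

    @classmethod
    def from_variant_calls(cls, calls, samples) -> "GenotypeMatrix":
        """Build from genotype.VariantCall objects (biallelic sites only)."""
        positions, refs, alts, rows = [], [], [], []
        usable = [c for c in calls
                  if len(c.alt_alleles) == 1 and "low_complexity" not in c.filters]
        for c in sorted(usable, key=lambda c: c.pos):
            positions.append(c.pos)
            refs.append(c.ref_allele)
            alts.append(c.alt_alleles[0])
            row = []
            for s in samples:
                gt = c.genotypes.get(s)
                row.append(MISSING if gt is None else int(gt[0] > 0) + int(gt[1] > 0))
            rows.append(row)
        g = (np.array(rows, np.int8).T if rows
             else np.zeros((len(samples), 0), np.int8))
        return cls(positions, refs, alts, list(samples), g)


@dataclass
class PhaseResult:
    """Inferred haplotypes, their frequencies, and per-individual best pairs."""

    haplotypes: list[str]               # binary strings over the sites
    frequencies: np.ndarray
    best_pairs: list[tuple[int, int]]   # haplotype indices per individual
    posteriors: list[float]
    log_likelihood: float
    positions: list[int] = field(default_factory=list)

    def haplotype_of(self, idx: int) -> str:
        return self.haplotypes[idx]


def _compatible_pairs(genotype_row) -> list[tuple[tuple, tuple]]:
    """All unordered compatible haplotype pairs for one individual.

    Heterozygous sites contribute a phase choice; missing sites contribute
    free alleles on both haplotypes (marginalized by enumeration).
    """
    amb = [j for j, g in enumerate(genotype_row) if g == 1 or g == MISSING]
    base = [0 if g == 0 else 1 if g == 2 else None for g in genotype_row]
    pairs = set()
    n_choice = []
    for j in amb:
        n_choice.append(4 if genotype_row[j] == MISSING else 2)
    for combo in itertools.product(*(range(c) for c in n_choice)):
        h1 = list(base)
        h2 = list(base)
        for j, choice in zip(amb, combo):
            if genotype_row[j] == 1:
                h1[j], h2[j] = (0, 1) if choice == 0 else (1, 0)
            else:  # missing: both alleles free
                h1[j], h2[j] = choice // 2, choice % 2
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        pairs.add(pair)
    return sorted(pairs)


def _em_on_pairs(pair_lists, n_restarts, max_iter, tol, rng):
    """Frequency EM over explicit per-individual compatible pair lists.

    Returns (haplotypes, frequencies, per-individual pair posteriors as
    lists of ((h1, h2), posterior) sorted best-first, log-likelihood).
    """
    haps = sorted({h for pairs in pair_lists for pair in pairs for h in pair})
    hidx = {h: i for i, h in enumerate(haps)}
    H = len(haps)
    n_ind = len(pair_lists)
    ind_pairs = [[(hidx[a], hidx[b]) for a, b in pairs] for pairs in pair_lists]

    best = None
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            f = np.full(H, 1.0 / H)
        else:
            f = rng.dirichlet(np.ones(H))
            f = np.maximum(f, 1e-12)
            f /= f.sum()
        prev_ll = -math.inf
        for _ in range(max_iter):
            counts = np.zeros(H)
            ll = 0.0
            for pairs in ind_pairs:
                w = np.array([(1 if a == b else 2) * f[a] * f[b]
                              for a, b in pairs])
                tot = w.sum()
                if tot <= 0:
                    w = np.full(len(pairs), 1.0 / len(pairs))
                    ll += -745.0  # log of ~5e-324; degenerate guard
                else:
                    ll += math.log(tot)
                    w = w / tot
                for (a, b), wi in zip(pairs, w):
                    counts[a] += wi
                    counts[b] += wi
            assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
            f_new = counts / (2 * n_ind)
            if ll - prev_ll < tol and np.abs(f_new - f).max() < tol:
                f = f_new
                prev_ll = ll
                break
            f = f_new
            prev_ll = ll
        if best is None or prev_ll > best[0]:
            best = (prev_ll, f.copy())
    ll, f = best

    pair_posts = []
    for pairs in ind_pairs:
        w = np.array([(1 if a == b else 2) * f[a] * f[b] for a, b in pairs])
        tot = w.sum()
        w = w / tot if tot > 0 else np.full(len(pairs), 1.0 / len(pairs))
        order = np.argsort(-w)
        pair_posts.append([((haps[pairs[k][0]], haps[pairs[k][1]]), float(w[k]))
                           for k in order])
    return haps, f, pair_posts, ll


def _blocks(genotypes, max_ambiguous):
    """Partition site indices into consecutive blocks with bounded ambiguity."""
    n_sites = genotypes.shape[1]
    blocks = []
    start = 0
    amb = np.zeros(genotypes.shape[0], int)
    for j in range(n_sites):
        add = (genotypes[:, j] == 1) | (genotypes[:, j] == MISSING)
        if (amb + add).max() > max_ambiguous and j > start:
            blocks.append((start, j))
            start = j
            amb = add.astype(int)
        else:
            amb += add
    blocks.append((start, n_sites))
    return blocks


def _pair_compatible(pair, row) -> bool:
    h1, h2 = pair
    for j, gj in enumerate(row):
        if gj != MISSING and h1[j] + h2[j] != gj:
            return False
    return True


def em_phase(
    genotypes: GenotypeMatrix,
    n_restarts: int = 3,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int = 0,
    max_block_ambiguity: int = 12,
    n_carry: int = 4,
) -> PhaseResult:
    """Phase a genotype matrix; returns haplotypes, frequencies and pairs.

    Blocks are ligated left to right carrying the ``n_carry`` best pair
    candidates per individual; a final refinement EM re-explains every
    individual with pairs drawn from the shared haplotype pool, which pulls
    the solution toward few common haplotypes the way a coalescent prior
    would.
    """
    g = genotypes.genotypes
    if g.shape[0] < 1:
        raise ValueError("need at least one individual")
    for i, name in enumerate(genotypes.individuals):
        if g.shape[1] and (g[i] == MISSING).all():
            raise ValueError(f"individual {name!r} has no defined genotypes")
    rng = np.random.default_rng(seed)
    n_ind = g.shape[0]
    if g.shape[1] == 0:
        return PhaseResult([""], np.array([1.0]), [(0, 0)] * n_ind,
                           [1.0] * n_ind, 0.0, list(genotypes.positions))

    blocks = _blocks(g, max_block_ambiguity)

    def phase_block(s, e):
        pls = [_compatible_pairs(g[i, s:e]) for i in range(n_ind)]
        _, _, posts, ll = _em_on_pairs(pls, n_restarts, max_iter, tol, rng)
        return [p[:n_carry] for p in posts], ll

    cur, ll = phase_block(*blocks[0])
    for (s, e) in blocks[1:]:
        nxt, _ = phase_block(s, e)
        join_lists = []
        for i in range(n_ind):
            cands = set()
            for (a1, a2), _pa in cur[i]:
                for (b1, b2), _pb in nxt[i]:
                    cands.add(tuple(sorted((a1 + b1, a2 + b2))))
                    cands.add(tuple(sorted((a1 + b2, a2 + b1))))
            join_lists.append(sorted(cands))
        _, _, posts, ll = _em_on_pairs(join_lists, n_restarts, max_iter,
                                       tol, rng)
        cur = [p[:n_carry] for p in posts]

    # refinement: re-explain individuals with the shared haplotype pool
    for _ in range(2):
        pool = sorted({h for cands in cur for pair, _ in cands for h in pair})
        cand_lists = []
        for i in range(n_ind):
            row = g[i]
            cands = {pair for pair, _ in cur[i]}
            for a in range(len(pool)):
                for b in range(a, len(pool)):
                    pair = (pool[a], pool[b])
                    if _pair_compatible(pair, row):
                        cands.add(pair)
            cand_lists.append(sorted(cands))
        haps, f, posts, ll = _em_on_pairs(cand_lists, n_restarts, max_iter,
                                          tol, rng)
        cur = [p[:n_carry] for p in posts]

    hidx = {h: i for i, h in enumerate(haps)}
    best_pairs = [tuple(sorted((hidx[p[0][0][0]], hidx[p[0][0][1]])))
                  for p in cur]
    posteriors = [p[0][1] for p in cur]
    hap_strings = ["".join(map(str, h)) for h in haps]
    return PhaseResult(
        hap_strings, np.asarray(f), best_pairs, posteriors,
        float(ll), list(genotypes.positions),
    )


def count_haplotypes(result: PhaseResult, posterior_threshold: float = 0.9) -> int:
    """Distinct haplotypes in confidently phased individuals' best pairs."""
    seen = set()
    for (a, b), post in zip(result.best_pairs, result.posteriors):
        if post >= posterior_threshold:
            seen.add(a)
            seen.add(b)
    if not seen:
        import warnings

        warnings.warn("no individual phased above the posterior threshold")
    return len(seen)
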