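"""Recombination detection among haplotypes: MaxChi and Chimaera scans.

Both tests scan candidate breakpoints between consecutive informative
sites.  MaxChi compares the match/mismatch composition of a sequence pair
in windows of ``window_w`` informative sites either side of the candidate
with a 2x2 chi-square (no continuity correction); Chimaera first encodes a
putative recombinant child by which of two parents it matches at sites
where the parents differ, then applies the same scan to that binary
string.  Significance comes from permuting the order of the informative
sites; breakpoint uncertainty from bootstrapping sites with replacement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class RecombScan:
    """Result of one breakpoint scan."""

    method: str
    statistic: float
    breakpoint: Optional[int]            # 1-based alignment coordinate
    p_value: float
    window_w: int
    n_informative: int
    pair: tuple = ()
    site_positions: np.ndarray = field(default_factory=lambda: np.array([], int))
    labels: np.ndarray = field(default_factory=lambda: np.array([], bool))
    ci: Optional[tuple[int, int]] = None


def _chi2_scan(labels: np.ndarray, w: int):
    """Max 2x2 chi-square over boundaries with w sites either side.

    Returns (max statistic, boundary index k: left window is sites
    [k-w, k), right window is [k, k+w)).
    """
    V = labels.size
    cum = np.concatenate(([0], np.cumsum(labels)))
    ks = np.arange(w, V - w + 1)
    b = cum[ks] - cum[ks - w]          # mismatches left
    d = cum[ks + w] - cum[ks]          # mismatches right
    a = w - b
    c = w - d
    n = 2 * w
    row1 = a + b
    denom = (a + c) * (b + d) * row1 * row1  # row sums both equal w
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    k = int(np.argmax(chi))
    return float(chi[k]), int(ks[k])


def _scan_labels(labels, positions, w, n_permutations, rng):
    stat, k = _chi2_scan(labels, w)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        s, _ = _chi2_scan(perm, w)
        if s >= stat:
            exceed += 1
    p = exceed / n_permutations if n_permutations else 1.0
    bp = int((positions[k - 1] + positions[k]) // 2) + 1  # 1-based midpoint
    return stat, bp, p


def maxchi(
    s1: str,
    s2: str,
    window_w: int = 35,
    n_permutations: int = 1000,
    seed: int = 0,
    variable_sites: Optional[Sequence[int]] = None,
) -> RecombScan:
    """MaxChi scan of one aligned sequence pair.

    ``variable_sites`` (0-based alignment columns) defaults to the columns
    where the two sequences differ; pass the polymorphic columns of the
    full alignment when scanning within a larger haplotype set.
    """
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned to equal length")
    if variable_sites is None:
        variable_sites = [i for i, (a, b) in enumerate(zip(s1, s2)) if a != b]
    positions = np.asarray(variable_sites, int)
    if positions.size < 2 * window_w:
        raise ValueError(
            f"{positions.size} variable sites < 2*window ({2 * window_w}); "
            "use a smaller window"
        )
    labels = np.array([s1[i] != s2[i] for i in positions], bool)
    rng = np.random.default_rng(seed)
    stat, bp, p = _scan_labels(labels, positions, window_w, n_permutations, rng)
    return RecombScan("maxchi", stat, bp, p, window_w, int(positions.size),
                      site_positions=positions, labels=labels)


def chimaera(
    child: str,
    parent_a: str,
    parent_b: str,
    window_w: int = 35,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RecombScan:
    """Chimaera scan of a (child, parent, parent) triplet."""
    if not (len(child) == len(parent_a) == len(parent_b)):
        raise ValueError("sequences must be aligned to equal length")
    informative = [i for i, (a, b) in enumerate(zip(parent_a, parent_b)) if a != b]
    if not informative:
        raise ValueError("parents are identical at every site")
    sites, labels = [], []
    for i in informative:
        if child[i] == parent_a[i]:
            sites.append(i)
            labels.append(False)
        elif child[i] == parent_b[i]:
            sites.append(i)
            labels.append(True)
        # child matches neither parent: site dropped
    positions = np.asarray(sites, int)
    if positions.size < 2 * window_w:
        raise ValueError(
            f"{positions.size} informative sites < 2*window ({2 * window_w}); "
            "use a smaller window"
        )
    labels = np.asarray(labels, bool)
    rng = np.random.default_rng(seed)
    stat, bp, p = _scan_labels(labels, positions, window_w, n_permutations, rng)
    return RecombScan("chimaera", stat, bp, p, window_w, int(positions.size),
                      site_positions=positions, labels=labels)


def breakpoint_ci(
    scan: RecombScan,
    level: float = 0.99,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> Optional[tuple[int, int]]:
    """Bootstrap CI for the breakpoint; None when the scan is not significant.

    Informative sites are resampled with replacement (order preserved) and
    the scan repeated; the CI is the empirical central ``level`` interval,
    widened if needed to contain the point estimate.
    """
    if scan.p_value > 0.05 or scan.breakpoint is None:
        return None
    rng = np.random.default_rng(seed)
    V = scan.site_positions.size
    w = scan.window_w
    estimates = []
    for _ in range(n_bootstrap):
        idx = np.sort(rng.integers(0, V, V))
        labels = scan.labels[idx]
        positions = scan.site_positions[idx]
        _, k = _chi2_scan(labels, w)
        estimates.append(int((positions[k - 1] + positions[k]) // 2) + 1)
    lo, hi = np.quantile(estimates, [(1 - level) / 2, (1 + level) / 2])
    lo, hi = int(lo), int(np.ceil(hi))
    return min(lo, scan.breakpoint), max(hi, scan.breakpoint)


@dataclass
class ScanReport:
    scans: list[RecombScan]
    table: pd.DataFrame
    n_scans: int

    def significant(self, alpha: float = 0.05):
        return self.table[self.table["p_adjusted"] <= alpha]

    def summary(self) -> str:
        sig = self.significant()
        if sig.empty:
            return f"{self.n_scans} scans: no significant recombination signal"
        bps = sig["breakpoint"].to_numpy()
        return (
            f"{self.n_scans} scans: {len(sig)} significant "
            f"(breakpoints {bps.min()}-{bps.max()})"
        )


def scan_all(
    haplotypes: Sequence[str],
    methods: Sequence[str] = ("maxchi", "chimaera"),
    window_w: int = 35,
    n_permutations: int = 1000,
    seed: int = 0,
    labels: Optional[Sequence[str]] = None,
) -> ScanReport:
    """Run the requested scans on all pairs/triplets with Bonferroni control.

    Pairwise MaxChi scans use the polymorphic columns of the full haplotype
    alignment as the variable-site set; Chimaera runs every (child, parents)
    triplet.  Per-scan permutation p-values are Bonferroni-adjusted across
    all scans.
    """
    n = len(haplotypes)
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if labels is None:
        labels = [f"h{i}" for i in range(n)]
    L = len(haplotypes[0])
    if any(len(h) != L for h in haplotypes):
        raise ValueError("haplotypes must be aligned to equal length")
    poly = [i for i in range(L) if len({h[i] for h in haplotypes}) > 1]

    rng = np.random.default_rng(seed)
    scans: list[RecombScan] = []
    if "maxchi" in methods:
        for i, j in itertools.combinations(range(n), 2):
            try:
                sc = maxchi(haplotypes[i], haplotypes[j], window_w,
                            n_permutations, int(rng.integers(2**31)),
                            variable_sites=poly)
            except ValueError:
                continue
            sc.pair = (labels[i], labels[j])
            scans.append(sc)
    if "chimaera" in methods:
        for c in range(n):
            for i, j in itertools.combinations(
                    [k for k in range(n) if k != c], 2):
                try:
                    sc = chimaera(haplotypes[c], haplotypes[i], haplotypes[j],
                                  window_w, n_permutations,
                                  int(rng.integers(2**31)))
                except ValueError:
                    continue
                sc.pair = (labels[c], labels[i], labels[j])
                scans.append(sc)
    if not scans:
        raise ValueError("no scan had enough informative sites; reduce window_w")
    m = len(scans)
    rows = [{
        "method": sc.method,
        "sequences": "/".join(sc.pair),
        "statistic": sc.statistic,
        "breakpoint": sc.breakpoint,
        "p_value": sc.p_value,
        "p_adjusted": min(1.0, sc.p_value * m),
        "n_informative": sc.n_informative,
    } for sc in scans]
    return ScanReport(scans, pd.DataFrame(rows), m)
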