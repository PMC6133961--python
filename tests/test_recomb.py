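import numpy as np
import pytest
from scipy import stats

from amplihap.recomb import (RecombScan, _chi2_scan, breakpoint_ci, chimaera,
                             maxchi, scan_all)


def random_pair(rng, n_sites=120, spacing=50, divergence=0.5):
    """Two sequences differing at a random subset of evenly spaced sites."""
    L = n_sites * spacing + spacing
    a = rng.choice(list("ACGT"), L)
    b = a.copy()
    sites = np.arange(spacing, L, spacing)[:n_sites]
    diff = rng.random(n_sites) < divergence
    for p in sites[diff]:
        b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
    return "".join(a), "".join(b), sites.tolist()


def recombinant_triplet(rng, n_sites=120, switch_at=60, divergence=0.15):
    L = 3000
    pa = rng.choice(list("ACGT"), L)
    pb = pa.copy()
    div = rng.random(L) < divergence
    for i in np.where(div)[0]:
        pb[i] = "ACGT"[("ACGT".index(pb[i]) + 1) % 4]
    var = np.where(div)[0]
    child = pa.copy()
    child[var[switch_at]:] = pb[var[switch_at]:]
    return "".join(child), "".join(pa), "".join(pb), int(var[switch_at])


class TestChiSquare:
    def test_hand_computed_two_by_two(self):
        # left 10 sites all match, right 10 all mismatch, window 10:
        # table [[10,0],[0,10]] -> chi2 = 20*(100)^2/10^4 = 20
        labels = np.array([False] * 10 + [True] * 10)
        stat, k = _chi2_scan(labels, 10)
        assert stat == pytest.approx(20.0)
        assert k == 10

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_formula_on_every_boundary(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.random(40) < 0.4
        w = 12
        V = labels.size
        best = 0.0
        for k in range(w, V - w + 1):
            b = labels[k - w : k].sum()
            d = labels[k : k + w].sum()
            a, c = w - b, w - d
            denom = (a + b) * (c + d) * (a + c) * (b + d)
            if denom:
                best = max(best, 2 * w * (a * d - b * c) ** 2 / denom)
        stat, _ = _chi2_scan(labels, w)
        assert stat == pytest.approx(best)


class TestMaxChi:
    def test_identical_sequences_error(self):
        with pytest.raises(ValueError):
            maxchi("ACGT" * 100, "ACGT" * 100, window_w=5)

    def test_constructed_recombinant_detected(self):
        child, pa, pb, truth = recombinant_triplet(np.random.default_rng(5))
        poly = [i for i, (x, y) in enumerate(zip(pa, pb)) if x != y]
        sc = maxchi(child, pb, window_w=35, n_permutations=1000, seed=1,
                    variable_sites=poly)
        assert sc.p_value <= 0.001
        # within two windows of informative sites of the true breakpoint
        sites = sc.site_positions
        k = int(np.searchsorted(sites, truth))
        est_k = int(np.searchsorted(sites, sc.breakpoint))
        assert abs(est_k - k) <= 2 * 35

    def test_breakpoint_is_midpoint_between_flanking_sites(self):
        labels_sites = list(range(0, 2000, 100))
        s1 = "A" * 2000
        s2 = list(s1)
        for i, p in enumerate(labels_sites):
            if i >= 10:
                s2[p] = "T"
        sc = maxchi(s1, "".join(s2), window_w=10, n_permutations=100,
                    seed=0, variable_sites=labels_sites)
        assert sc.breakpoint == (900 + 1000) // 2 + 1


class TestChimaera:
    def test_child_identical_to_parent_not_significant(self):
        rng = np.random.default_rng(6)
        _, pa, pb, _ = recombinant_triplet(rng)
        sc = chimaera(pa, pa, pb, window_w=35, n_permutations=300, seed=2)
        assert sc.statistic == pytest.approx(0.0)
        assert sc.p_value > 0.9

    def test_recombinant_triplet_detected(self):
        child, pa, pb, truth = recombinant_triplet(np.random.default_rng(7))
        sc = chimaera(child, pa, pb, window_w=35, n_permutations=1000, seed=3)
        assert sc.p_value <= 0.001
        assert abs(sc.breakpoint - truth) <= 300

    def test_identical_parents_rejected(self):
        with pytest.raises(ValueError):
            chimaera("ACGT", "AAAA", "AAAA")


class TestCalibration:
    def test_permutation_p_uniform_under_null(self):
        # type-I calibration: p-values of non-recombinant children are
        # uniform (KS test at alpha=0.01 over 200 replicates)
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            s1, s2, sites = random_pair(rng, n_sites=90)
            sc = maxchi(s1, s2, window_w=20, n_permutations=200,
                        seed=int(rng.integers(2**31)), variable_sites=sites)
            pvals.append(sc.p_value + rng.random() / 200)  # de-discretize
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestBreakpointCi:
    def test_ci_contains_estimate_and_is_tight_when_clean(self):
        child, pa, pb, truth = recombinant_triplet(np.random.default_rng(9))
        sc = chimaera(child, pa, pb, window_w=35, n_permutations=500, seed=4)
        ci = breakpoint_ci(sc, level=0.99, n_bootstrap=300, seed=5)
        assert ci is not None
        lo, hi = ci
        assert lo <= sc.breakpoint <= hi
        assert lo <= truth <= hi

    def test_no_ci_for_insignificant_scan(self):
        sc = RecombScan("maxchi", 1.0, 500, 0.8, 35, 100)
        assert breakpoint_ci(sc) is None


class TestScanAll:
    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            scan_all(["ACGT"])

    def test_nonrecombinant_set_not_significant(self):
        rng = np.random.default_rng(10)
        L = 3000
        base = rng.choice(list("ACGT"), L)
        haps = []
        for _ in range(4):
            h = base.copy()
            m = rng.random(L) < 0.05
            for i in np.where(m)[0]:
                h[i] = "ACGT"[("ACGT".index(h[i]) + 1) % 4]
            haps.append("".join(h))
        rep = scan_all(haps, window_w=20, n_permutations=300, seed=6)
        assert rep.significant(0.05).empty

    def test_recombinant_found_by_both_methods_concordantly(self):
        child, pa, pb, truth = recombinant_triplet(np.random.default_rng(11))
        rep = scan_all([child, pa, pb], window_w=35, n_permutations=500,
                       seed=7)
        sig = rep.significant(0.05)
        assert set(sig["method"]) == {"maxchi", "chimaera"}
        bps = sig["breakpoint"].to_numpy()
        assert bps.max() - bps.min() <= 600  # within ~2 windows of sites
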