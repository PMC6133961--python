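import numpy as np
import pytest

from amplihap.align import ReferenceIndex, SHORT_READ_PARAMS, map_read
from amplihap.genotype import (call_variants, duplication_signatures,
                               genotype_str, left_normalize,
                               mask_low_complexity, write_vcf)
from amplihap.polish import build_pileup
from amplihap.simulate import make_amplicon_template, simulate_short_reads


def pileups_for(samples, ref, n_pairs=700, err=0.001, seed0=50):
    """samples: dict name -> (hap1, hap2)."""
    index = ReferenceIndex(ref)
    out = {}
    for k, (name, pair) in enumerate(samples.items()):
        r1, r2 = simulate_short_reads(pair, n_pairs, error_rate=err,
                                      seed=seed0 + k)
        alns = [a for a in (map_read(r, ref, SHORT_READ_PARAMS, index=index)
                            for r in r1 + r2) if a is not None]
        out[name] = build_pileup(alns, ref)
    return out


class TestMask:
    def test_embedded_homopolymer(self):
        rng = np.random.default_rng(0)
        seq = "CGTACGTACG" + "A" * 6 + "CGTCGATCGT"
        track = mask_low_complexity(seq)
        assert [(m.start, m.end, m.kind) for m in track] == \
            [(10, 16, "homopolymer")]

    def test_gt_repeat_masked(self):
        seq = "CCATTACCAT" + "GT" * 9 + "ACCATTACCA"
        track = mask_low_complexity(seq)
        strs = [m for m in track if m.kind == "STR"]
        assert len(strs) == 1
        # the full (GT)9 tract is covered (partial-unit extension may pull
        # in a coincidentally alternating flanking base)
        assert strs[0].start <= 10 and strs[0].end >= 28

    def test_compound_str_masks_repeat_portion(self):
        # (GT)3 T (GT)4 : the >=4-unit half of the compound tract is masked
        seq = "CCATTACCAT" + "GTGTGT" + "T" + "GTGTGTGT" + "ACCATTACCA"
        track = mask_low_complexity(seq)
        strs = [m for m in track if m.kind == "STR"]
        assert any(m.start <= 17 and m.end >= 25 for m in strs)

    def test_no_tracts_empty_track(self):
        rng = np.random.default_rng(3)
        # build a sequence with no >=4-unit repeat and no >=6 homopolymer
        seq = "".join(rng.choice(list("ACGT"), 300))
        track = mask_low_complexity(seq, min_homopolymer=50, str_min_units=50)
        assert len(track) == 0


class TestLeftNormalize:
    def test_deletion_shifts_through_repeat(self):
        #     0123456789
        ref = "ACGTGTGTAC"
        # deleting GT at 6..8 is the same event as deleting at 2..4
        pos, r, a = left_normalize(5, "TGT", "T", ref)
        assert (pos, r, a) == (1, "CGT", "C")

    def test_snp_unchanged(self):
        assert left_normalize(4, "G", "T", "ACGTGACGT") == (4, "G", "T")


@pytest.fixture(scope="module")
def calls_setup():
    t = make_amplicon_template(length=3000, n_snps=25, n_indels=4,
                               seed=5, max_indel_len=2)
    ref = t.hap_a
    mask = mask_low_complexity(ref)
    samples = {
        "homA": (t.hap_a, t.hap_a),
        "het": (t.hap_a, t.hap_b),
        "homB": (t.hap_b, t.hap_b),
    }
    pileups = pileups_for(samples, ref)
    calls = call_variants(pileups, ref, mask)
    return t, ref, mask, calls


class TestCallVariants:
    def test_all_truth_sites_recovered_outside_mask(self, calls_setup):
        t, ref, mask, calls = calls_setup
        truth = [v for v in t.truth_variants if v.kind != "STR"]
        norm_truth = set()
        for v in truth:
            p, r, a = left_normalize(v.pos - 1, v.ref, v.alt, ref)
            norm_truth.add((p + 1, r, a))
        found = {(c.pos, c.ref_allele, c.alt_alleles[0])
                 for c in calls if c.alt_alleles}
        missing = norm_truth - found
        assert not missing

    def test_genotypes_match_construction(self, calls_setup):
        t, ref, mask, calls = calls_setup
        truth = {}
        for v in t.truth_variants:
            if v.kind == "STR":
                continue
            p, r, a = left_normalize(v.pos - 1, v.ref, v.alt, ref)
            truth[(p + 1, r, a)] = v
        bad = 0
        total = 0
        for c in calls:
            key = (c.pos, c.ref_allele, c.alt_alleles[0] if c.alt_alleles else "")
            if key not in truth:
                continue
            for sample, expected in (("homA", (0, 0)), ("het", (0, 1)),
                                     ("homB", (1, 1))):
                total += 1
                if c.genotypes[sample] != expected:
                    bad += 1
        assert total >= 3 * 25
        assert bad / total <= 0.01

    def test_undefined_genotypes_only_in_mask(self, calls_setup):
        t, ref, mask, calls = calls_setup
        for c in calls:
            for s, gt in c.genotypes.items():
                if gt is None and "low_depth" not in c.filters:
                    assert "low_complexity" in c.filters

    def test_masked_sites_not_genotyped(self, calls_setup):
        t, ref, mask, calls = calls_setup
        for c in calls:
            if "low_complexity" in c.filters:
                assert all(g is None for g in c.genotypes.values())

    def test_mismatched_references_rejected(self, calls_setup):
        t, ref, mask, calls = calls_setup
        pile = pileups_for({"x": (t.hap_a, t.hap_a)}, ref, n_pairs=30)
        with pytest.raises(ValueError):
            call_variants(pile, ref + "ACGT", mask)


@pytest.fixture(scope="module")
def str_setup(template):
    ref = template.hap_a
    mask = mask_low_complexity(ref)
    iv = next((m.start, m.end) for m in mask if m.kind == "STR")
    return template, ref, iv


class TestGenotypeStr:

    def test_homozygous_alternative_allele(self, str_setup):
        t, ref, iv = str_setup
        r1, r2 = simulate_short_reads((t.hap_b, t.hap_b), 900,
                                      error_rate=0.0, seed=60)
        sg = genotype_str(r1 + r2, ref, iv)
        assert sg.called and len(sg.alleles) == 1
        assert sg.alleles[0][0] != ref[iv[0]:iv[1]]

    def test_heterozygote_recovers_both_tracts(self, str_setup):
        t, ref, iv = str_setup
        r1, r2 = simulate_short_reads((t.hap_a, t.hap_b), 900,
                                      error_rate=0.001, seed=61)
        sg = genotype_str(r1 + r2, ref, iv)
        assert sg.called and len(sg.alleles) == 2
        counts = [c for _, c in sg.alleles]
        frac = counts[0] / sum(counts)
        assert 0.3 <= frac <= 0.7
        tracts = {a for a, _ in sg.alleles}
        assert ref[iv[0]:iv[1]] in tracts

    def test_too_few_spanning_reads_no_call(self, str_setup):
        t, ref, iv = str_setup
        r1, r2 = simulate_short_reads((t.hap_a, t.hap_a), 3,
                                      error_rate=0.0, seed=62,
                                      frag_mean=2000, frag_sd=0)
        sg = genotype_str(r1 + r2, ref, iv)
        assert not sg.called

    def test_interval_outside_reference_rejected(self, str_setup):
        t, ref, iv = str_setup
        with pytest.raises(ValueError):
            genotype_str([], ref, (len(ref), len(ref) + 10))


class TestDuplicationSignatures:
    def test_clean_diploid_no_signature(self):
        t = make_amplicon_template(length=3000, n_snps=25, n_indels=0,
                                   str_spec=None, seed=6)
        pileups = pileups_for({"a": (t.hap_a, t.hap_b)}, t.hap_a)
        calls = call_variants(pileups, t.hap_a,
                              mask_low_complexity(t.hap_a))
        rep = duplication_signatures(calls)
        assert rep.verdict == "no duplication signature"
        assert rep.n_tri_allelic == 0

    def test_mixed_templates_raise_signature(self):
        # two distinct diploid loci sequenced as one amplicon: reads mixed
        # 50:50 produce tri-allelic sites and/or 25:75 balance
        t1 = make_amplicon_template(length=3000, n_snps=25, n_indels=0,
                                    str_spec=None, seed=7)
        t2 = make_amplicon_template(length=3000, n_snps=25, n_indels=0,
                                    str_spec=None, seed=7, edge_margin=150)
        # same backbone, different variant positions: t2 acts as a paralog
        ref = t1.hap_a
        index = ReferenceIndex(ref)
        reads = []
        for k, tpl in enumerate((t1, t2)):
            r1, r2 = simulate_short_reads((tpl.hap_a, tpl.hap_b), 400,
                                          error_rate=0.001, seed=70 + k)
            reads += r1 + r2
        alns = [a for a in (map_read(r, ref, SHORT_READ_PARAMS, index=index)
                            for r in reads) if a is not None]
        pile = {"dup": build_pileup(alns, ref)}
        calls = call_variants(pile, ref, mask_low_complexity(ref))
        rep = duplication_signatures(calls)
        assert rep.n_tri_allelic > 0 or rep.balance_skew_sites

    def test_no_het_sites_no_tests(self):
        t = make_amplicon_template(length=3000, n_snps=10, n_indels=0,
                                   str_spec=None, seed=8)
        pileups = pileups_for({"a": (t.hap_a, t.hap_a)}, t.hap_a,
                              n_pairs=400)
        calls = call_variants(pileups, t.hap_a, mask_low_complexity(t.hap_a))
        rep = duplication_signatures(calls)
        assert rep.n_het_tests == 0
        assert rep.het_fraction.get("a", 0.0) == 0.0


class TestVcf:
    def make_calls(self):
        t = make_amplicon_template(length=3000, n_snps=10, n_indels=3,
                                   seed=9, max_indel_len=2)
        ref = t.hap_a
        pileups = pileups_for({"s1": (t.hap_a, t.hap_b),
                               "s2": (t.hap_b, t.hap_b)}, ref, n_pairs=500)
        calls = call_variants(pileups, ref, mask_low_complexity(ref))
        return t, ref, calls

    def test_vcf_structure_and_round_trip(self, tmp_path):
        import pysam

        t, ref, calls = self.make_calls()
        path = tmp_path / "out.vcf"
        write_vcf(calls, ["s1", "s2"], path, ref_len=len(ref))
        text = path.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        with pysam.VariantFile(str(path)) as vf:
            recs = list(vf)
            assert len(recs) == len(calls)
            by_pos = {c.pos: c for c in calls}
            for rec in recs:
                c = by_pos[rec.pos]  # VCF pos is 1-based
                assert rec.ref == c.ref_allele
                # indel records carry an anchor base (left-normalized form)
                if c.is_indel:
                    assert len(rec.ref) > 1 or any(len(a) > 1
                                                   for a in rec.alts)
                for s in ("s1", "s2"):
                    gt = rec.samples[s]["GT"]
                    want = c.genotypes[s]
                    assert (tuple(sorted(x for x in gt if x is not None))
                            or None) == (want if want else None) or \
                        (want is None and set(gt) == {None})
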