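import math

import numpy as np
import pytest

from amplihap.seqio import revcomp
from amplihap.simulate import (NOISELESS, NoiseModel, StrSpec, apply_variants,
                               make_amplicon_template, make_haplotype_pool,
                               parse_truth, sample_individuals,
                               simulate_chimeras, simulate_control,
                               simulate_long_reads, simulate_short_reads)


class TestTemplate:
    def test_default_shape(self, template):
        assert len(template.hap_a) == 9001
        kinds = [v.kind for v in template.truth_variants]
        assert kinds.count("SNP") == 102
        assert kinds.count("indel") == 7
        assert kinds.count("STR") == 1
        gc = sum(template.hap_a.count(b) for b in "GC") / len(template.hap_a)
        assert abs(gc - 0.41) <= 0.02

    def test_hap_b_derivable_from_truth(self, template):
        assert apply_variants(template.hap_a, template.truth_variants) == \
            template.hap_b

    def test_variants_avoid_edges_and_tracts(self, template):
        tracts = template.masked_intervals()
        for v in template.truth_variants:
            assert 100 < v.pos <= len(template.hap_a) - 100
            if v.kind != "STR":
                s, e = v.pos - 1, v.pos - 1 + len(v.ref)
                assert not any(ms < e and me > s for ms, me in tracts)

    def test_no_variants_means_identical_haplotypes(self):
        t = make_amplicon_template(n_snps=0, n_indels=0, str_spec=None, seed=2)
        assert t.hap_a == t.hap_b

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            make_amplicon_template(length=1000, n_snps=400, n_indels=0, seed=0)

    def test_annotations_cover_planted_tracts(self, template):
        hp = [f for f in template.features if f.kind == "homopolymer"]
        assert len(hp) >= 4
        assert any(f.end - f.start >= 13 for f in hp)  # the 13-mer run
        assert any(f.kind == "STR" for f in template.features)

    def test_deterministic(self):
        a = make_amplicon_template(seed=9)
        b = make_amplicon_template(seed=9)
        assert a.hap_a == b.hap_a and a.truth_variants == b.truth_variants


class TestLongReads:
    def test_noiseless_reads_are_exact_fragments(self, small_template):
        reads = simulate_long_reads(small_template, 8, NOISELESS, seed=1)
        for r in reads:
            tr = parse_truth(r.id)
            hap = (small_template.hap_a if tr["hap"] == "A"
                   else small_template.hap_b)
            frag = hap[tr["start"] : tr["start"] + tr["len"]]
            seq = r.bases if tr["strand"] == "+" else revcomp(r.bases)
            assert seq == frag

    def test_realized_error_rates_match_noise_model(self, template):
        noise = NoiseModel()
        reads = simulate_long_reads(template, 400, noise, seed=2)
        tot = {"sub": 0, "ins": 0, "del": 0}
        n_bases = 0
        for r in reads:
            tr = parse_truth(r.id)
            for k in tot:
                tot[k] += tr[k]
            n_bases += tr["len"]
        for k, rate in (("sub", noise.sub_rate), ("ins", noise.ins_rate),
                        ("del", noise.del_rate)):
            se = math.sqrt(rate * (1 - rate) / n_bases)
            assert abs(tot[k] / n_bases - rate) <= 3 * se

    def test_hap_ratio_balances_haplotypes(self, template):
        reads = simulate_long_reads(template, 600, NOISELESS, hap_ratio=0.5,
                                    seed=3)
        n_a = sum(1 for r in reads if parse_truth(r.id)["hap"] == "A")
        se = math.sqrt(0.25 / 600)
        assert abs(n_a / 600 - 0.5) <= 3 * se

    def test_fixed_seed_reproducible(self, small_template):
        a = simulate_long_reads(small_template, 5, seed=4)
        b = simulate_long_reads(small_template, 5, seed=4)
        assert [(r.id, r.bases) for r in a] == [(r.id, r.bases) for r in b]

    def test_invalid_noise_model(self):
        with pytest.raises(ValueError):
            NoiseModel(0.5, 0.4, 0.3)


class TestShortReads:
    def test_mate_is_reverse_complement_without_errors(self, small_template):
        r1, r2 = simulate_short_reads(small_template.hap_a, 5, read_len=100,
                                      frag_mean=100, frag_sd=0,
                                      error_rate=0.0, seed=5)
        for a, b in zip(r1, r2):
            assert b.bases == revcomp(a.bases)

    def test_mean_coverage_matches_closed_form(self, template):
        n_pairs = 5000
        r1, r2 = simulate_short_reads(template, n_pairs, seed=6)
        total = sum(len(r) for r in r1 + r2)
        expected = n_pairs * 2 * 250
        # fragments shorter than 2x250 truncate the mates slightly
        assert total / len(template.hap_a) == pytest.approx(
            expected / len(template.hap_a), rel=0.05
        )

    def test_realized_substitution_rate(self, template):
        err = 0.001
        r1, r2 = simulate_short_reads(template.hap_a, 2000, error_rate=err,
                                      seed=7)
        mism = 0
        n = 0
        hap = template.hap_a
        for r in r1:
            tr = parse_truth(r.id)
            frag = hap[tr["start"] : tr["start"] + tr["frag"]][: len(r.bases)]
            mism += sum(a != b for a, b in zip(r.bases, frag))
            n += len(r.bases)
        se = math.sqrt(err * (1 - err) / n)
        assert abs(mism / n - err) <= 3 * se

    def test_nonpositive_pairs_rejected(self, template):
        with pytest.raises(ValueError):
            simulate_short_reads(template, 0)


class TestControl:
    def test_reference_is_lambda_sized(self):
        ref, reads = simulate_control(n_reads=3, seed=8)
        assert len(ref.bases) == 48502 and len(reads) == 3

    def test_zero_noise_reads_match_reference(self):
        ref, reads = simulate_control(n_reads=5, noise=NOISELESS, seed=9)
        for r in reads:
            tr = parse_truth(r.id)
            frag = ref.bases[tr["start"] : tr["start"] + tr["len"]]
            seq = r.bases if tr["strand"] == "+" else revcomp(r.bases)
            assert seq == frag

    def test_realized_deletion_rate(self):
        ref, reads = simulate_control(n_reads=300, seed=10)
        dels = sum(parse_truth(r.id)["del"] for r in reads)
        n = sum(parse_truth(r.id)["len"] for r in reads)
        se = math.sqrt(0.03 * 0.97 / n)
        assert abs(dels / n - 0.03) <= 3 * se


class TestChimeras:
    def test_zero_fraction_is_pure_source_b(self, small_template):
        reads = simulate_chimeras(small_template.hap_a, small_template.hap_b,
                                  0.0, 3, NOISELESS, seed=11)
        for r in reads:
            tr = parse_truth(r.id)
            assert tr["bp"] == 0
            frag = small_template.hap_b[tr["b_start"] : tr["b_start"] + tr["len"]]
            assert r.bases == frag

    def test_half_fraction_splits_exactly(self, small_template):
        reads = simulate_chimeras(small_template.hap_a, small_template.hap_b,
                                  0.5, 3, NOISELESS, seed=12)
        for r in reads:
            tr = parse_truth(r.id)
            assert tr["bp"] == round(0.5 * tr["len"])
            pre = small_template.hap_a[tr["a_start"] : tr["a_start"] + tr["bp"]]
            assert r.bases.startswith(pre)


class TestPopulation:
    def test_pool_rows_give_sequences(self, small_template):
        seqs, mat = make_haplotype_pool(small_template, 4, seed=13)
        assert len(seqs) == 4 and mat.shape[0] == 4
        assert seqs[0] == small_template.hap_a
        assert len({tuple(r) for r in mat}) == 4

    def test_individual_sampling_frequencies(self):
        inds = sample_individuals(4, [0.4, 0.3, 0.2, 0.1], 2000, seed=14)
        counts = np.bincount([h for pair in inds for h in pair], minlength=4)
        freqs = counts / counts.sum()
        assert np.allclose(freqs, [0.4, 0.3, 0.2, 0.1], atol=0.03)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            sample_individuals(3, [0.5, 0.5], 5)
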