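import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirtronkit.locus_features import (
    LogoConfig,
    dinucleotide_shuffle,
    host_intron_count_stats,
    intron_length_hist,
    logo_matrix,
    mfe_comparison,
    premirna_length_stats,
    sample_length_matched,
    seed_conservation,
    seed_mimics,
    trimmed_mean,
)


class TestIntronLengthHist:
    def test_binning(self):
        df = intron_length_hist({"a": [150, 199], "b": []}, ("a", "b"))
        assert df.loc["a", "[100,200)"] == 2
        assert df.loc["b"].sum() == 0

    def test_pooling_above_cap(self):
        df = intron_length_hist({"a": [20000]}, ("a",), pool_above=15000)
        assert df.loc["a", ">=15000"] == 1

    def test_bin_sums_equal_class_sizes(self):
        rng = np.random.default_rng(0)
        lengths = {"a": rng.integers(50, 20000, 100).tolist(),
                   "b": rng.integers(50, 500, 17).tolist()}
        df = intron_length_hist(lengths, ("a", "b"))
        assert df.loc["a"].sum() == 100
        assert df.loc["b"].sum() == 17

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            intron_length_hist({"mystery": [100]}, ("a",))


class TestLogoMatrix:
    def test_identical_sequences_give_indicator_columns(self):
        m = logo_matrix([("GATTACA", 0)] * 5, LogoConfig(window=10)).set_index("position")
        assert m.loc[0, "G"] == 1.0
        assert m.loc[1, "A"] == 1.0
        assert m.loc[2, "U"] == 1.0  # T reported in RNA space

    def test_counting_two_sequences(self):
        m = logo_matrix(
            [("GTAAAAAAAAA", 0), ("GAAAAAAAAAA", 0)], LogoConfig(window=10)
        ).set_index("position")
        assert m.loc[0, "G"] == 1.0
        assert m.loc[1, "U"] == 0.5
        assert m.loc[1, "A"] == 0.5

    def test_columns_sum_to_one_over_covered(self):
        rng = np.random.default_rng(1)
        seqs = [
            ("".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60)))), 10)
            for _ in range(20)
        ]
        m = logo_matrix(seqs, LogoConfig(window=15))
        covered = m[m["coverage"] > 0]
        sums = covered[["A", "C", "G", "U"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_zero_coverage_flagged_not_nan_propagated(self):
        m = logo_matrix([("ACGT", 0)], LogoConfig(window=10)).set_index("position")
        assert m.loc[-5, "coverage"] == 0
        assert np.isnan(m.loc[-5, "A"])

    def test_window_floor(self):
        with pytest.raises(ValueError):
            LogoConfig(window=5)


class TestMfe:
    def test_identical_case_and_control_gives_null_result(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(10)]
        res = mfe_comparison(seqs, seqs, seed=0)
        assert res.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert res.test_p > 0.9

    def test_matched_sampler_bin_counts_equal(self):
        rng = np.random.default_rng(3)
        case = rng.integers(40, 400, size=30).tolist()
        pool = rng.integers(30, 500, size=500).tolist()
        idx = sample_length_matched(case, pool, rng)
        got = {}
        for i in idx:
            got[pool[i] // 100] = got.get(pool[i] // 100, 0) + 1
        want = {}
        for l in case:
            want[l // 100] = want.get(l // 100, 0) + 1
        assert got == want
        assert len(set(idx)) == len(idx)  # without replacement

    def test_small_pool_falls_back_unmatched(self):
        rng = np.random.default_rng(4)
        case = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(10)]
        pool = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(3)]
        res = mfe_comparison(case, pool, seed=0)
        assert not res.matched

    def test_dinucleotide_shuffle_preserves_composition(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            sh = dinucleotide_shuffle(seq, rng)
            assert len(sh) == len(seq)
            assert sh[0] == seq[0] and sh[-1] == seq[-1]

            def dinucs(s):
                d = {}
                for a, b in zip(s, s[1:]):
                    d[a + b] = d.get(a + b, 0) + 1
                return d

            assert dinucs(sh) == dinucs(seq)


class TestIntronCounts:
    def test_trimmed_mean_arithmetic(self):
        assert trimmed_mean(list(range(1, 101)), 0.02) == pytest.approx(
            np.mean(range(1, 99))
        )

    def test_trimmed_leq_untrimmed(self):
        rng = np.random.default_rng(6)
        v = rng.poisson(8, 200)
        assert trimmed_mean(v) <= v.mean()

    def test_identical_distributions_nonsignificant(self):
        v = list(range(1, 50))
        res = host_intron_count_stats({"bulk": v, "x": v})
        x = next(s for s in res if s.label == "x")
        assert x.ranksum_p_vs_bulk > 0.9

    def test_threefold_enrichment_detected(self):
        rng = np.random.default_rng(7)
        bulk = (1 + rng.poisson(4, 300)).tolist()
        hosts = (1 + rng.poisson(14, 60)).tolist()
        res = host_intron_count_stats({"bulk": bulk, "host": hosts})
        h = next(s for s in res if s.label == "host")
        ratio = h.trimmed_mean / next(s for s in res if s.label == "bulk").trimmed_mean
        assert 2.2 < ratio < 3.8
        assert h.ranksum_p_vs_bulk < 1e-6

    def test_low_n_flag(self):
        res = host_intron_count_stats({"bulk": [1, 2, 3, 4], "tiny": [9, 9]})
        assert next(s for s in res if s.label == "tiny").low_n


class TestPremirnaLengths:
    def test_degenerate_class(self):
        df = premirna_length_stats({"x": [60, 60, 60], "canonical": [60, 61, 59]})
        row = df.set_index("class").loc["x"]
        assert row["mean"] == 60 and row["sd"] == 0

    def test_identical_classes_nonsignificant(self):
        v = list(range(55, 75))
        df = premirna_length_stats({"x": v, "canonical": v})
        assert df.set_index("class").loc["x", "p_vs_canonical"] > 0.9

    def test_single_member_class_flagged(self):
        df = premirna_length_stats({"x": [83], "canonical": [60, 61]})
        row = df.set_index("class").loc["x"]
        assert row["low_n"] and np.isnan(row["sd"])


class _FakeCall:
    def __init__(self, locus_id, mature):
        self.locus_id = locus_id
        self.mature_arm = "5p"
        self.fivep_seq = mature
        self.threep_seq = ""


class TestSeeds:
    def test_identical_matures_in_homologous_introns_conserved(self):
        a = [_FakeCall("A1", "TGAGGTAGTAGGTTGTATAGTT")]
        b = [_FakeCall("B1", "TGAGGTAGTAGGTTGTATAGTT")]
        conserved, positional = seed_conservation(a, b, {"A1": "B1"})
        assert conserved == [("A1", "B1")]
        assert positional == []

    def test_seed_mismatch_is_positional_only(self):
        a = [_FakeCall("A1", "TGAGGTAGTAGGTTGTATAGTT")]
        b = [_FakeCall("B1", "TGAGCTAGTAGGTTGTATAGTT")]  # differs at seed pos 4
        conserved, positional = seed_conservation(a, b, {"A1": "B1"})
        assert conserved == []
        assert positional == [("A1", "B1")]

    def test_permuted_homology_gives_chance_level(self):
        rng = np.random.default_rng(8)
        n = 60
        seqs = ["".join(rng.choice(list("ACGT"), size=22)) for _ in range(n)]
        a = [_FakeCall(f"A{i}", s) for i, s in enumerate(seqs)]
        b = [_FakeCall(f"B{i}", s) for i, s in enumerate(seqs)]
        perm = rng.permutation(n)
        homology = {f"A{i}": f"B{perm[i]}" for i in range(n)}
        conserved, _ = seed_conservation(a, b, homology)
        # chance of a random 7-mer seed match is ~n/4^7; with fixed
        # points of the permutation excluded this stays tiny
        n_nonfixed = sum(1 for i in range(n) if perm[i] != i)
        assert len(conserved) <= (n - n_nonfixed) + 3

    def test_mimic_match(self):
        calls = [_FakeCall("A1", "TGAGGTAGTAGGTTGTATAGTT")]
        df = seed_mimics(calls, {"let7": "GAGGUA"})
        assert list(df["reference_id"]) == ["let7"]

    def test_no_references_empty(self):
        assert seed_mimics([_FakeCall("A1", "TGAGGTAGTAGGTTGTATAGTT")], {}).empty

    def test_random_match_rate_near_expectation(self):
        rng = np.random.default_rng(9)
        n_refs = 64
        refs = {
            f"r{i}": "".join(rng.choice(list("ACGT"), size=6))
            for i in range(n_refs)
        }
        n_loci = 400
        calls = [
            _FakeCall(f"A{i}", "".join(rng.choice(list("ACGT"), size=22)))
            for i in range(n_loci)
        ]
        df = seed_mimics(calls, refs)
        n_unique_refs = len(set(refs.values()))
        p_match = 1 - (1 - 1 / 4**6) ** n_unique_refs
        hits = df["locus_id"].nunique() if len(df) else 0
        assert stats.binomtest(hits, n_loci, p_match).pvalue > 0.001

    def test_short_mature_skipped_with_flag(self):
        df = seed_mimics([_FakeCall("A1", "TGAGG")], {"x": "GAGGTA"})
        assert df["skipped_short"].all()
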