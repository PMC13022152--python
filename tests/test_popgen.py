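"""Diversity statistics against a brute-force oracle, plus cohort stats."""

import itertools

import numpy as np
import pytest

import sd1hap as s
from sd1hap.popgen import harmonic


def brute_force_stats(seqs):
    """Independent per-pair / per-column counting oracle (complete deletion)."""
    n = len(seqs)
    keep = [
        j for j in range(len(seqs[0]))
        if all(seq[j] in "ACGT" for seq in seqs)
    ]
    L = len(keep)
    S = eta = 0
    for j in keep:
        alleles = {seq[j] for seq in seqs}
        if len(alleles) > 1:
            S += 1
        eta += len(alleles) - 1
    diffs = [
        sum(a[j] != b[j] for j in keep)
        for a, b in itertools.combinations(seqs, 2)
    ]
    k = sum(diffs) / len(diffs)
    a1 = harmonic(n - 1)
    return dict(
        L_used=L, S=S, eta=eta, k=k,
        pi=k / L if L else float("nan"),
        theta_per_seq=eta / a1,
        theta_w_site=eta / a1 / L if L else float("nan"),
    )


def _random_matrix(rng, n=None, L=None, missing=0.05):
    n = n or int(rng.integers(2, 13))
    L = L or int(rng.integers(5, 101))
    data = rng.choice(list("ACGT"), size=(n, L))
    mask = rng.random((n, L)) < missing
    data[mask] = rng.choice(["-", "N"], size=int(mask.sum()))
    seqs = ["".join(row) for row in data]
    return s.SequenceMatrix.from_strings([f"s{i}" for i in range(n)], seqs), seqs


class TestDiversityStats:
    def test_identical_sequences(self):
        m = s.SequenceMatrix.from_strings(["a", "b", "c"], ["ACGT"] * 3)
        st = s.diversity_stats(m)
        assert (st.S, st.eta, st.k, st.pi) == (0, 0, 0.0, 0.0)

    def test_two_sequence_analytic(self):
        st = s.diversity_stats(s.SequenceMatrix.from_strings(["a", "b"], ["AAAA", "AAAT"]))
        assert st.S == 1 and st.eta == 1
        assert st.k == 1.0 and st.pi == 0.25 and st.theta_w_site == 0.25

    def test_multiallelic_column_eta_exceeds_S(self):
        m = s.SequenceMatrix.from_strings(["a", "b", "c"], ["A", "C", "G"])
        st = s.diversity_stats(m)
        assert st.S == 1 and st.eta == 2

    def test_complete_deletion_removes_gapped_columns(self):
        m = s.SequenceMatrix.from_strings(["a", "b"], ["A-CT", "AACT"])
        st = s.diversity_stats(m)
        assert st.L_used == 3 and st.S == 0

    def test_all_columns_gapped_flags_undefined(self):
        m = s.SequenceMatrix.from_strings(["a", "b"], ["--", "AA"])
        assert not s.diversity_stats(m).defined

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            m, seqs = _random_matrix(rng)
            st = s.diversity_stats(m)
            oracle = brute_force_stats(seqs)
            assert st.L_used == oracle["L_used"]
            assert st.S == oracle["S"] and st.eta == oracle["eta"]
            assert st.k == pytest.approx(oracle["k"])
            assert st.pi == pytest.approx(oracle["pi"])
            assert st.theta_per_seq == pytest.approx(oracle["theta_per_seq"])
            assert st.theta_w_site == pytest.approx(oracle["theta_w_site"])
            assert st.eta >= st.S
            assert st.k == pytest.approx(st.pi * st.L_used)


class TestTajimaD:
    def test_undefined_without_segregating_sites(self):
        m = s.SequenceMatrix.from_strings(["a", "b", "c", "d"], ["ACGT"] * 4)
        td = s.tajima_d(s.diversity_stats(m))
        assert not td.defined

    def test_undefined_below_four_samples(self):
        m = s.SequenceMatrix.from_strings(["a", "b"], ["AAAA", "AAAT"])
        assert not s.tajima_d(s.diversity_stats(m)).defined

    def test_singleton_excess_gives_negative_D(self):
        """One singleton per column (star-like) forces D < 0."""
        n, L = 10, 20
        seqs = [["A"] * L for _ in range(n)]
        for j in range(L):
            seqs[j % n][j] = "G"
        m = s.SequenceMatrix.from_strings([f"s{i}" for i in range(n)],
                                          ["".join(x) for x in seqs])
        td = s.tajima_d(s.diversity_stats(m))
        assert td.defined and td.D < 0

    def test_balanced_polymorphism_gives_positive_D(self):
        seqs = ["AAAA"] * 5 + ["GGGG"] * 5
        m = s.SequenceMatrix.from_strings([f"s{i}" for i in range(10)], seqs)
        td = s.tajima_d(s.diversity_stats(m))
        assert td.D > 0

    def test_neutral_mean_near_zero(self):
        reps = 300
        ds = []
        for i in range(reps):
            st = s.diversity_stats(s.simulate_neutral_sample(20, 5.0, 1000, seed=7_000 + i))
            td = s.tajima_d(st)
            if td.defined:
                ds.append(td.D)
        ds = np.array(ds)
        se = ds.std(ddof=1) / np.sqrt(len(ds))
        assert abs(ds.mean()) < max(3 * se, 0.15)

    def test_p_value_in_unit_interval(self):
        m = s.SequenceMatrix.from_strings(
            [f"s{i}" for i in range(6)],
            ["AAAA", "AAAT", "AATT", "AAAA", "AAAA", "AAAA"],
        )
        td = s.tajima_d(s.diversity_stats(m))
        assert 0.0 <= td.p_value <= 1.0


class TestWindowScan:
    def test_published_ten_kb_region(self):
        spec = s.WindowSpec(38_382_466, 38_385_208, flank=10_000)
        assert spec.region == (38_372_466, 38_395_208)

    def test_zero_flank_equals_gene_span(self):
        spec = s.WindowSpec(100, 200, flank=0)
        assert spec.region == (100, 200)

    def test_nested_windows_monotonic_S(self, rng):
        m, _ = _random_matrix(rng, n=8, L=100, missing=0.0)
        s_small = s.window_scan(m, s.WindowSpec(40, 60, flank=10)).S
        s_large = s.window_scan(m, s.WindowSpec(40, 60, flank=40)).S
        assert s_small <= s_large

    def test_empty_window_undefined(self, rng):
        m, _ = _random_matrix(rng, n=4, L=50, missing=0.0)
        st = s.window_scan(m, s.WindowSpec(900, 950, flank=0))
        assert not st.defined


class TestAnovaLetters:
    def test_identical_groups_share_letter(self):
        res = s.anova_letters({"g1": [5.0, 5.1, 4.9], "g2": [5.0, 5.1, 4.9]})
        assert res.letters["g1"] == res.letters["g2"]

    def test_separated_groups_differ(self, rng):
        res = s.anova_letters(
            {"a": rng.normal(60, 5, 30), "b": rng.normal(150, 5, 30)}
        )
        assert set(res.letters["a"]).isdisjoint(res.letters["b"])
        assert res.p < 1e-6

    def test_f_statistic_matches_hand_computation(self):
        # groups: [1,2,3], [2,3,4], [6,7,8]; grand mean 4
        # SSB = 3*((2-4)^2+(3-4)^2+(7-4)^2) = 42 ; SSW = 6 ; F = (42/2)/(6/6) = 21
        res = s.anova_letters({"a": [1, 2, 3], "b": [2, 3, 4], "c": [6, 7, 8]})
        assert res.F == pytest.approx(21.0)

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = s.anova_letters({"a": [1, 2, 3], "b": [2, 3, 4], "tiny": [9]})
        assert res.excluded == ["tiny"]

    def test_intermediate_group_shares_letters_both_ways(self, rng):
        res = s.anova_letters(
            {
                "low": rng.normal(0, 1, 20),
                "mid": rng.normal(1.0, 1, 20),
                "high": rng.normal(2.0, 1, 20),
            }
        )
        # low vs high separated; mid may share with either, letters stay consistent
        assert set(res.letters["low"]).isdisjoint(res.letters["high"])


class TestSnpSharing:
    def test_two_set_example(self):
        out = s.snp_sharing({"A": {1, 2}, "B": {2, 3}})
        assert out[frozenset({"A"})] == 1
        assert out[frozenset({"B"})] == 1
        assert out[frozenset({"A", "B"})] == 1

    def test_identical_sets_only_full_region(self):
        out = s.snp_sharing({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        assert out[frozenset({"A", "B", "C"})] == 2
        assert sum(v for k, v in out.items() if len(k) < 3) == 0

    def test_counts_sum_to_union(self, rng):
        sets = {
            name: set(rng.integers(0, 50, size=rng.integers(5, 30)).tolist())
            for name in "ABCDE"
        }
        out = s.snp_sharing(sets)
        assert sum(out.values()) == len(set().union(*sets.values()))
        assert len(out) == 2**5 - 1

    def test_brute_force_membership_tally(self, rng):
        sets = {name: set(rng.integers(0, 30, size=15).tolist()) for name in "ABC"}
        out = s.snp_sharing(sets)
        for subset, count in out.items():
            expected = sum(
                1
                for x in set().union(*sets.values())
                if all((x in sets[n]) == (n in subset) for n in sets)
            )
            assert count == expected

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            s.snp_sharing({"A": {1}})
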