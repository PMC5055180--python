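import math

import numpy as np
import pandas as pd
import pytest

from umirep.stats import (AbundanceSpectrum, abundance_class, ace,
                          default_rarefaction_grid, frequency_classes,
                          rarefaction, sharing, spectrum, subsample,
                          subsample_clonotypes, vj_usage)


from oracles import ace_oracle, rarefaction_oracle  # noqa: E402


class TestSpectrum:
    def test_counting(self):
        spec = spectrum([1, 1, 2, 3, 15])
        assert spec.f == {1: 2, 2: 1, 3: 1, 15: 1}
        assert spec.n_molecules == 22
        assert spec.s_obs == 5

    def test_singletons_only(self):
        spec = spectrum([1] * 7)
        assert spec.f == {1: 7} and spec.n_molecules == 7

    def test_tied_abundances(self):
        assert spectrum([20, 20]).f == {20: 2}

    def test_invariants(self):
        counts = np.random.default_rng(1).integers(1, 30, 100)
        spec = spectrum(counts)
        assert sum(i * fi for i, fi in spec.f.items()) == counts.sum()
        assert sum(spec.f.values()) == 100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spectrum([])


class TestACE:
    def test_all_abundant(self):
        est = ace(spectrum([20] * 5))
        assert est.s_ace == 5.0 and est.method == "abundant_only"

    def test_no_singletons_gives_coverage_one(self):
        est = ace(spectrum([2, 2, 3]))
        assert est.c_ace == 1.0 and est.gamma2 == 0.0
        assert est.s_ace == pytest.approx(3.0)

    def test_hand_checked_case(self):
        # counts [1,1,1,2,2,5,20]: C_ACE=0.75, gamma2=5/11, S_ACE=10.81818...
        est = ace(spectrum([1, 1, 1, 2, 2, 5, 20]))
        assert est.c_ace == pytest.approx(0.75)
        assert est.gamma2 == pytest.approx(5 / 11)
        assert est.s_ace == pytest.approx(10.8181818181818, abs=1e-9)

    def test_all_singletons_falls_back_to_chao1(self):
        with pytest.warns(UserWarning, match="Chao1"):
            est = ace(spectrum([1, 1, 1, 1]))
        assert est.method == "chao1"
        assert est.s_ace == 4 + 4 * 3 / 2

    def test_single_rare_molecule_undefined(self):
        with pytest.raises(ValueError, match="ACE undefined"):
            ace(spectrum([1]))

    def test_matches_independent_oracle_on_random_spectra(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            s = int(rng.integers(2, 40))
            counts = rng.integers(1, 40, s)
            if (counts <= 10).sum() and counts[counts <= 10].sum() <= 1:
                continue
            spec = spectrum(counts)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = ace(spec)
            assert est.s_ace == pytest.approx(ace_oracle(counts), abs=1e-9)

    def test_ace_at_least_observed_when_rare_group_nondegenerate(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            counts = rng.integers(1, 15, 30)
            if counts[counts <= 10].sum() <= 1 or (counts == 1).sum() == (counts <= 10).sum():
                continue
            est = ace(spectrum(counts))
            assert est.s_ace >= est.s_obs - 1e-12


class TestRarefaction:
    def test_full_sample_gives_observed_richness(self):
        spec = spectrum([3, 1, 7, 2])
        assert rarefaction(spec, [13])[0] == pytest.approx(4.0)

    def test_single_molecule_gives_one(self):
        spec = spectrum([3, 1, 7, 2])
        assert rarefaction(spec, [1])[0] == pytest.approx(1.0)

    def test_two_from_counts_3_1(self):
        assert rarefaction(spectrum([3, 1]), [2])[0] == pytest.approx(1.5)

    @pytest.mark.parametrize("counts", [[3, 1], [2, 2, 1], [4, 3, 2, 1], [1, 1, 1]])
    def test_matches_enumeration_on_small_spectra(self, counts):
        n = sum(counts)
        ms = range(1, n + 1)
        got = rarefaction(spectrum(counts), list(ms))
        for m, g in zip(ms, got):
            assert g == pytest.approx(rarefaction_oracle(counts, m), abs=1e-9)

    def test_monotone_in_m(self):
        counts = np.random.default_rng(3).integers(1, 50, 80)
        grid = default_rarefaction_grid(int(counts.sum()))
        vals = rarefaction(spectrum(counts), grid)
        assert np.all(np.diff(vals) >= -1e-9)

    def test_matches_monte_carlo_within_3_se(self, rng):
        counts = np.array([10, 5, 3, 2, 1, 1, 1])
        m = 8
        exact = rarefaction(spectrum(counts), [m])[0]
        draws = np.array([(subsample(counts, m, rng) > 0).sum() for _ in range(1000)])
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - exact) <= 3 * se

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            rarefaction(spectrum([2, 2]), [5])


class TestSubsample:
    def test_exhaustive_draw_is_identity(self, rng):
        counts = np.array([5, 3, 2])
        assert (subsample(counts, 10, rng) == counts).all()

    def test_deterministic_given_seed(self):
        counts = np.arange(1, 30)
        a = subsample(counts, 100, 42)
        b = subsample(counts, 100, 42)
        assert (a == b).all()

    def test_hypergeometric_mean(self):
        counts = np.array([40, 30, 20, 10])
        rng = np.random.default_rng(9)
        draws = np.array([subsample(counts, 25, rng)[0] for _ in range(1000)])
        mean = 25 * 40 / 100
        var = 25 * 0.4 * 0.6 * (100 - 25) / (100 - 1)
        assert abs(draws.mean() - mean) <= 3 * math.sqrt(var / 1000)

    def test_clonotype_table_subsample_drops_zeros(self, rng):
        df = pd.DataFrame({"sample_id": "s", "cdr3_aa": list("ABCDE"),
                           "n_molecules": [100, 1, 1, 1, 1]})
        out = subsample_clonotypes(df, 50, rng)
        assert out.n_molecules.sum() == 50
        assert (out.n_molecules > 0).all()


class TestFrequencyClasses:
    @pytest.mark.parametrize("n,expected", [(9, "low"), (10, "middle"),
                                            (99, "middle"), (100, "high")])
    def test_boundaries_at_1e5_molecules(self, n, expected):
        assert abundance_class(n, 100_000) == expected

    def test_table_counts_and_fractions(self):
        df = pd.DataFrame({"n_molecules": [9, 10, 100, 99881]})
        out = frequency_classes(df)
        assert list(out.n_clonotypes) == [1, 1, 2]
        assert out.fraction.sum() == pytest.approx(1.0)


class TestVJUsage:
    def test_single_segment_is_one(self):
        df = pd.DataFrame({"v_name": ["V01"] * 3, "j_name": ["J01", "J02", "J02"],
                           "n_molecules": [5, 1, 1]})
        assert vj_usage(df, "V").to_dict() == {"V01": 1.0}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"v_name": rng.choice(["V01", "V02", "V03"], 50),
                           "j_name": rng.choice(["J01", "J02"], 50),
                           "n_molecules": rng.integers(1, 20, 50)})
        for kind in ("V", "J"):
            for w in ("by_molecule", "by_clonotype"):
                assert vj_usage(df, kind, w).sum() == pytest.approx(1.0, abs=1e-12)

    def test_weightings_differ_under_skew(self):
        df = pd.DataFrame({"v_name": ["V01", "V02"], "j_name": ["J01", "J01"],
                           "n_molecules": [99, 1]})
        assert vj_usage(df, "V", "by_molecule")["V01"] == pytest.approx(0.99)
        assert vj_usage(df, "V", "by_clonotype")["V01"] == pytest.approx(0.5)


def aa_table(sample_id, rows):
    return pd.DataFrame([{"sample_id": sample_id, "v_name": v, "j_name": j,
                          "cdr3_nt": nt, "cdr3_aa": aa, "n_molecules": n}
                         for v, j, nt, aa, n in rows])


class TestSharing:
    def test_exact_m_counts(self):
        a = aa_table("a", [("V01", "J01", "aaa", "A", 1), ("V01", "J01", "bbb", "B", 1)])
        b = aa_table("b", [("V01", "J01", "bbb", "B", 1), ("V01", "J01", "ccc", "C", 1)])
        c = aa_table("c", [("V01", "J01", "bbb", "B", 1)])
        out = sharing({"a": a, "b": b, "c": c}, level="aa")
        assert out.loc[("all",), "shared_by_2"].sum() == 0
        assert out.loc[("all",), "shared_by_3"].sum() == 1

    def test_category_rules_min_and_max_class(self):
        # clonotype low in sample 1, high in sample 2
        s1 = aa_table("s1", [("V01", "J01", "aaa", "A", 1),
                             ("V01", "J01", "xxx", "X", 99_999)])
        s2 = aa_table("s2", [("V02", "J02", "aab", "A", 200),
                             ("V01", "J01", "yyy", "Y", 99_800)])
        out = sharing({"s1": s1, "s2": s2}, level="aa")
        assert out.loc[("all", "low"), "shared_by_2"] == 1
        assert out.loc[("any", "high"), "shared_by_2"] == 1
        assert out.loc[("all", "high"), "shared_by_2"] == 0

    def test_aa_sharing_without_nt_sharing(self):
        # disjoint nt rearrangements translating to the same amino acids
        s1 = aa_table("s1", [("V01", "J01", "TGTGCCAGCTTT", "CASF", 5)])
        s2 = aa_table("s2", [("V02", "J02", "TGCGCCAGCTTC", "CASF", 5)])
        aa = sharing({"s1": s1, "s2": s2}, level="aa")
        nt = sharing({"s1": s1, "s2": s2}, level="nt")
        assert aa.to_numpy().sum() == 2          # one clonotype, both category rules
        assert nt.to_numpy().sum() == 0

    def test_row_sums_match_total_shared(self):
        rng = np.random.default_rng(11)
        samples = {}
        keys = [f"K{i}" for i in range(30)]
        for sid in ("p1", "p2", "p3", "p4"):
            chosen = rng.choice(30, 15, replace=False)
            samples[sid] = aa_table(sid, [("V01", "J01", keys[i], keys[i],
                                           int(rng.integers(1, 50))) for i in chosen])
        out = sharing(samples, level="aa")
        for m in (2, 3, 4):
            assert out.loc[("all",), f"shared_by_{m}"].sum() == \
                   out.loc[("any",), f"shared_by_{m}"].sum()

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            sharing({"only": aa_table("only", [("V01", "J01", "a", "A", 1)])})
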