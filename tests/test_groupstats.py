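"""Nonparametric group tests against exhaustive permutation oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiocoh import (
    GenotypeTable,
    collect_band_stats,
    condition_comparison,
    genotype_comparison,
    kruskal_wallis,
    rank_sum,
)
from cardiocoh.coherence import CoherenceSpectrum


# --- independent oracles ----------------------------------------------------


def oracle_kw_h(groups):
    """Kruskal-Wallis H from first principles (no ties assumed)."""
    flat = np.concatenate(groups)
    n = flat.size
    ranks = np.empty(n)
    ranks[np.argsort(flat)] = np.arange(1, n + 1)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def oracle_perm_h_values(values, sizes):
    """H over every distinct assignment of `values` into groups of `sizes`."""
    n = len(values)
    idx = set(range(n))
    out = []

    def rec(remaining, sizes_left, chosen):
        if not sizes_left:
            groups = [np.asarray([values[i] for i in grp]) for grp in chosen]
            out.append(oracle_kw_h(groups))
            return
        k = sizes_left[0]
        pool = sorted(remaining)
        for comb in itertools.combinations(pool, k):
            rec(remaining - set(comb), sizes_left[1:], chosen + [comb])

    rec(idx, list(sizes), [])
    return np.array(out)


def oracle_ranksum_exact_p(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    values = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.empty(values.size)
    ranks[np.argsort(values)] = np.arange(1, values.size + 1)
    obs = ranks[:n1].sum()
    mean = n1 * (values.size + 1) / 2.0
    stats = [
        ranks[list(comb)].sum()
        for comb in itertools.combinations(range(values.size), n1)
    ]
    stats = np.asarray(stats)
    p = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)
    return min(1.0, p)


# --- tests ------------------------------------------------------------------


class TestKruskalWallis:
    @pytest.mark.parametrize(
        "groups",
        [
            ([1.0, 2.0, 3.0], [10.0, 11.0, 12.0]),
            ([5.0, 1.0, 7.0], [2.0, 9.0, 4.0], [3.0, 8.0]),
        ],
    )
    def test_h_matches_first_principles_oracle(self, groups):
        H, _ = kruskal_wallis([np.asarray(g) for g in groups])
        assert H == pytest.approx(oracle_kw_h([np.asarray(g) for g in groups]), abs=1e-10)

    def test_permutation_distribution_mean_is_k_minus_one(self):
        # for all-distinct values the permutation mean of H is exactly k-1
        values = [3.1, 0.2, 5.7, 1.4, 9.9, 2.2]
        hs = oracle_perm_h_values(values, (3, 3))
        assert hs.mean() == pytest.approx(1.0, abs=1e-10)
        hs3 = oracle_perm_h_values(values + [7.3, 4.8], (3, 3, 2))
        assert hs3.mean() == pytest.approx(2.0, abs=1e-10)

    def test_identical_distributions(self):
        assert kruskal_wallis([[1, 2, 3], [1, 2, 3]]) == (0.0, 1.0) or \
            kruskal_wallis([[1, 2, 3], [1, 2, 3]])[1] == pytest.approx(1.0)
        assert kruskal_wallis([[2, 2], [2, 2, 2]]) == (0.0, 1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            g = [rng.normal(size=8) for _ in range(3)]
            _, p = kruskal_wallis(g)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_relabelling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        g = [rng.normal(size=6), rng.normal(size=5), rng.normal(size=7)]
        h1, p1 = kruskal_wallis(g)
        h2, p2 = kruskal_wallis([np.exp(x) for x in g])
        assert h1 == pytest.approx(h2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestRankSum:
    def test_extreme_small_case(self):
        W, p = rank_sum([1.0, 2.0], [3.0, 4.0])
        assert W == 3.0
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1.0, 2.0], [3.0, 4.0]),
            ([0.3, 2.5, 1.1], [1.9, 0.7, 3.3]),
            ([5.0, 1.0, 4.0, 2.0], [3.5, 0.5, 6.0]),
        ],
    )
    def test_exact_p_matches_enumeration_oracle(self, x, y):
        _, p = rank_sum(x, y)
        assert p == pytest.approx(oracle_ranksum_exact_p(x, y), abs=1e-10)

    def test_identical_groups(self):
        _, p = rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_swap_antisymmetry(self):
        x, y = [0.3, 2.5, 1.1, 4.0], [1.9, 0.7, 3.3]
        _, p1 = rank_sum(x, y)
        _, p2 = rank_sum(y, x)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


def _fake_coh(value: float) -> CoherenceSpectrum:
    f = 0.03 * 2 ** (np.arange(8) / 32)
    return CoherenceSpectrum(freqs=f, raw_coh=np.full(8, value),
                             phase_diff=np.zeros(8), n_valid=np.ones(8, int))


class TestCollectAndCompare:
    def test_collect_band_stats_rows(self):
        results = {
            (f"S{i:02d}", cond): _fake_coh(0.1 * i)
            for i in range(3) for cond in ("NN", "NH")
        }
        df = collect_band_stats(results, (0.03, 0.15))
        assert len(df) == 6
        assert set(df["condition"]) == {"NN", "NH"}

    def test_collect_respects_missing_recordings(self):
        sizes = {"NN": 5, "NHa": 5, "NH": 4, "HHa": 3, "HH": 2}
        results = {
            (f"S{i:02d}", cond): _fake_coh(0.2)
            for cond, n in sizes.items() for i in range(n)
        }
        df = collect_band_stats(results, (0.03, 0.15))
        assert df.groupby("condition").size().to_dict() == sizes

    def test_condition_comparison_requires_two_groups(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "condition": ["NN", "NN"],
                           "value": [0.1, 0.2]})
        with pytest.raises(ValueError):
            condition_comparison(df)

    def test_pairwise_only_when_significant(self):
        rng = np.random.default_rng(7)
        null = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(30)],
            "condition": ["NN", "NH", "HH"] * 10,
            "value": rng.normal(size=30),
        })
        shifted = null.copy()
        shifted.loc[shifted["condition"] == "HH", "value"] += 10.0
        res_null = condition_comparison(null)
        res_shift = condition_comparison(shifted)
        if not res_null.significant:
            assert res_null.pairwise == []
        assert res_shift.significant and len(res_shift.pairwise) == 3

    def test_genotype_comparison_paths(self):
        table = GenotypeTable({
            "S00": {"NOTCH4": "GG"}, "S01": {"NOTCH4": "GG"},
            "S02": {"NOTCH4": "GA"}, "S03": {"NOTCH4": "GA"},
            "S04": {"NOTCH4": "GG"}, "S05": {"NOTCH4": "GA"},
        })
        df = pd.DataFrame({
            "subject_id": [f"S{i:02d}" for i in range(6)],
            "condition": ["NH"] * 6,
            "value": [0.1, 0.2, 0.8, 0.9, 0.15, 0.85],
        })
        with pytest.warns(UserWarning, match="empty"):
            res = genotype_comparison(df, table, "NOTCH4")
        assert set(res.groups) == {"GG", "GA"}
        # two conditions at once is a usage error
        df2 = df.copy()
        df2.loc[0, "condition"] = "NN"
        with pytest.raises(ValueError):
            genotype_comparison(df2, table, "NOTCH4")
        # single-genotype cohort cannot be compared
        mono = GenotypeTable({f"S{i:02d}": {"CAT": "CC"} for i in range(6)})
        with pytest.raises(ValueError):
            genotype_comparison(df, mono, "CAT")

    def test_genotype_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            GenotypeTable({"S00": {"NOTCH4": "XX"}})

    def test_genotype_table_round_trip(self, tmp_path):
        table = GenotypeTable({"S01": {"NOTCH4": "GA", "CAT": "CC"},
                               "S02": {"NOTCH4": "GG", "CAT": "TT"}})
        table.write_tsv(tmp_path / "geno.tsv")
        back = GenotypeTable.read_tsv(tmp_path / "geno.tsv")
        assert back.table == table.table
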