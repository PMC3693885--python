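import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirmeth import (
    correlation_pvalue,
    coupling_correlation,
    mean_rank_profile,
    simulate_coupled_pvalue_tables,
    spearman,
)
from mirmeth.targeting import DirectionalPValueTable


def average_ranks(v):
    """Independent average-rank oracle (sort-and-sweep, no scipy)."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    sv = v[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return np.corrcoef(average_ranks(x), average_ranks(y))[0, 1]


def table_from(p_greater: pd.DataFrame, layer="mrna", pair=("A", "B")):
    return DirectionalPValueTable(
        layer=layer,
        region_pair=pair,
        p_less=(1 - p_greater).clip(lower=1e-12),
        p_greater=p_greater.clip(lower=1e-12, upper=1.0),
        method="test",
    )


class TestMeanRankProfile:
    def test_single_subject_rescaled_ranks(self):
        t = table_from(pd.DataFrame({"s1": [0.1, 0.5, 0.9]}, index=list("abc")))
        prof = mean_rank_profile(t, "greater")
        assert np.allclose(prof.to_numpy(), [1 / 3, 2 / 3, 1.0])

    def test_identical_subjects_average_to_either(self):
        col = [0.3, 0.8, 0.1, 0.6]
        t = table_from(pd.DataFrame({"s1": col, "s2": col}, index=list("abcd")))
        prof = mean_rank_profile(t, "greater")
        single = mean_rank_profile(
            table_from(pd.DataFrame({"s1": col}, index=list("abcd"))), "greater"
        )
        assert np.allclose(prof.to_numpy(), single.to_numpy())

    def test_ties_get_average_ranks(self):
        t = table_from(pd.DataFrame({"s1": [0.2, 0.2, 0.8]}, index=list("abc")))
        prof = mean_rank_profile(t, "greater")
        assert np.allclose(prof.to_numpy() * 3, [1.5, 1.5, 3.0])

    def test_missing_mirnas_rescale_within_subject(self):
        frame = pd.DataFrame(
            {"s1": [0.1, np.nan, 0.9], "s2": [0.3, 0.2, 0.1]}, index=list("abc")
        )
        prof = mean_rank_profile(table_from(frame), "greater")
        # s1 ranks over 2 entries: a=1/2, c=1; s2 over 3: a=1, b=2/3, c=1/3
        assert prof["a"] == pytest.approx((0.5 + 1.0) / 2)
        assert prof["b"] == pytest.approx(2 / 3)
        assert prof["c"] == pytest.approx((1.0 + 1 / 3) / 2)


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = rng.normal(size=20)
        assert spearman(x, np.sort(x)[np.argsort(np.argsort(x))]) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_hand_example_point_eight(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_hand_example_with_ties(self):
        assert spearman([1, 1, 2], [1, 2, 3]) == pytest.approx(
            1.5 / np.sqrt(3), abs=1e-12
        )

    def test_constant_vector_gives_nan(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_matches_rank_pearson_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            x = rng.integers(0, 8, size=n).astype(float)
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10**6))
    def test_invariant_under_strictly_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y), abs=1e-12)
        assert spearman(x, 3 * y + 1) == pytest.approx(spearman(x, y), abs=1e-12)


class TestCorrelationPValue:
    def test_central_statistic(self):
        assert correlation_pvalue(0.0, 50) == pytest.approx(1.0)

    def test_hand_example(self):
        # rho=0.5, M=12 -> t = 0.5*sqrt(10/0.75) ~= 1.826, df=10
        t = 0.5 * np.sqrt(10 / 0.75)
        expected = 2 * stats.t.sf(t, df=10)
        assert correlation_pvalue(0.5, 12) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0977, abs=5e-4)

    def test_monotone_in_abs_rho(self):
        rhos = np.linspace(0.0, 0.95, 20)
        ps = [correlation_pvalue(r, 30) for r in rhos]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_degenerate_rho_returns_zero(self):
        assert correlation_pvalue(1.0, 10) == 0.0

    def test_small_m_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 3)


class TestCouplingCorrelation:
    def test_self_correlation_is_one(self):
        tx, _ = simulate_coupled_pvalue_tables(40, 6, 0.3, seed=2)
        ty = DirectionalPValueTable(
            layer="methylation", region_pair=tx.region_pair,
            p_less=tx.p_less.copy(), p_greater=tx.p_greater.copy(), method="test",
        )
        cs = coupling_correlation(tx, ty)
        assert cs.rho_mean_rank == pytest.approx(1.0)
        assert np.allclose(cs.rho_per_subject.to_numpy(), 1.0)
        assert cs.delta_rho == pytest.approx(1.0)
        assert cs.rho_degenerate
        assert cs.p_value == 0.0

    def test_mismatched_mirna_sets_rejected(self):
        tx, ty = simulate_coupled_pvalue_tables(10, 5, 0.3, seed=3)
        ty_bad = DirectionalPValueTable(
            layer="methylation", region_pair=ty.region_pair,
            p_less=ty.p_less.iloc[:-1], p_greater=ty.p_greater.iloc[:-1], method="t",
        )
        with pytest.raises(ValueError, match="miRNA set"):
            coupling_correlation(tx, ty_bad)

    def test_delta_rho_dominates_mean_rho(self):
        # RMS >= |mean| (Jensen); holds for every simulated table pair
        for seed in range(10):
            tx, ty = simulate_coupled_pvalue_tables(80, 8, 0.2, seed=seed)
            cs = coupling_correlation(tx, ty)
            assert cs.delta_rho >= abs(np.nanmean(cs.rho_per_subject)) - 1e-12

    def test_row_permutation_breaks_coupling(self):
        tx, ty = simulate_coupled_pvalue_tables(100, 10, 0.6, seed=5)
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(100):
            perm = rng.permutation(len(ty.p_greater))
            ty_perm = DirectionalPValueTable(
                layer=ty.layer, region_pair=ty.region_pair,
                p_less=pd.DataFrame(
                    ty.p_less.to_numpy()[perm], index=ty.p_less.index,
                    columns=ty.p_less.columns,
                ),
                p_greater=pd.DataFrame(
                    ty.p_greater.to_numpy()[perm], index=ty.p_greater.index,
                    columns=ty.p_greater.columns,
                ),
                method=ty.method,
            )
            rhos.append(coupling_correlation(tx, ty_perm).rho_mean_rank)
        assert np.mean(np.abs(rhos)) < 2 / np.sqrt(100)
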