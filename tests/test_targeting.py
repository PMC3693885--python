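import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirmeth import (
    compute_pvalue_table,
    default_null_config,
    generate_study,
    net_direction,
    per_gene_delta,
    planted_regulation_config,
    summarize_direction_counts,
    target_set_test,
)
from mirmeth.targeting import DirectionalPValueTable


def exact_ranksum_oracle(x, y, direction):
    """Exhaustive enumeration of all C(n1+n2, n1) rank splits (tie-free data)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = round(ranks[:n1].sum() * 2)  # doubled to keep ties-at-.5 integral
    sums = [
        round(sum(ranks[list(c)]) * 2)
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    if direction == "greater":
        hits = sum(s >= obs for s in sums)
    else:
        hits = sum(s <= obs for s in sums)
    return hits / len(sums)


class TestPerGeneDelta:
    def test_log_ratio_and_identity(self, tiny_study):
        # subject s1: region A = e * region B -> delta 1; s2 identical -> 0
        d1 = per_gene_delta(tiny_study, "mrna", ("A", "B"), "s1")
        d2 = per_gene_delta(tiny_study, "mrna", ("A", "B"), "s2")
        assert np.allclose(d1.to_numpy(), 1.0)
        assert np.allclose(d2.to_numpy(), 0.0)

    def test_methylation_is_plain_difference(self, tiny_study):
        d = per_gene_delta(tiny_study, "methylation", ("A", "B"), "s1")
        assert np.allclose(d.to_numpy(), 0.5)

    def test_unpaired_subject_rejected(self, tiny_study):
        with pytest.raises(ValueError, match="not paired"):
            per_gene_delta(tiny_study, "mrna", ("A", "B"), "ghost")


class TestTargetSetTest:
    def test_exact_example_one_twentieth(self):
        delta = np.array([2.0, 3.0, 4.0, -1.0, 0.0, 1.0])
        mask = np.array([True, True, True, False, False, False])
        p = target_set_test(delta, mask, "greater", "ranksum_exact")
        assert p == pytest.approx(1 / 20, abs=1e-12)
        assert target_set_test(delta, mask, "less", "ranksum_exact") == pytest.approx(
            1.0, abs=1e-12
        )

    def test_series_and_target_set_interface(self, tiny_study):
        delta = per_gene_delta(tiny_study, "methylation", ("A", "B"), "s1") + \
            np.arange(6) * 0.01
        p = target_set_test(delta, tiny_study.target_map.targets["m1"], "greater", "ttest")
        assert 0 < p <= 1

    def test_ttest_tails_sum_to_one(self, rng):
        for _ in range(50):
            d = rng.normal(size=40)
            mask = np.zeros(40, bool)
            mask[rng.choice(40, 15, replace=False)] = True
            pl = target_set_test(d, mask, "less", "ttest")
            pg = target_set_test(d, mask, "greater", "ttest")
            assert pl + pg == pytest.approx(1.0, abs=1e-12)

    def test_normal_matches_scipy_with_ties(self, rng):
        for _ in range(50):
            d = rng.integers(0, 6, size=60).astype(float)  # heavy ties
            mask = np.zeros(60, bool)
            mask[rng.choice(60, 25, replace=False)] = True
            for direction in ("less", "greater"):
                mine = target_set_test(d, mask, direction, "ranksum_normal")
                ref = stats.mannwhitneyu(
                    d[mask], d[~mask], alternative=direction, method="asymptotic"
                ).pvalue
                assert mine == pytest.approx(ref, abs=1e-12)

    def test_empty_group_yields_missing(self):
        d = np.arange(5.0)
        assert np.isnan(target_set_test(d, np.ones(5, bool), "greater", "auto"))
        assert np.isnan(target_set_test(d, np.zeros(5, bool), "greater", "auto"))

    def test_normal_converges_to_exact(self, rng):
        worst = 0.0
        for _ in range(300):
            n1, n2 = rng.integers(30, 45, size=2)
            d = rng.normal(size=n1 + n2)
            mask = np.zeros(n1 + n2, bool)
            mask[:n1] = True
            pn = target_set_test(d, mask, "greater", "ranksum_normal")
            pe = target_set_test(d, mask, "greater", "ranksum_exact")
            worst = max(worst, abs(pn - pe))
        assert worst < 0.01

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=8, max_size=30, unique=True
        ),
        st.integers(0, 10**6),
        st.floats(0.1, 5.0),
    )
    def test_monotone_in_target_shift(self, values, pick_seed, c):
        """Adding c > 0 to all target deltas never increases P_greater."""
        values = np.asarray(values)
        rng = np.random.default_rng(pick_seed)
        mask = np.zeros(len(values), bool)
        mask[rng.choice(len(values), len(values) // 2, replace=False)] = True
        shifted = values.copy()
        shifted[mask] += c
        if len(np.unique(shifted)) < len(shifted):  # shift created ties
            return
        p0 = target_set_test(values, mask, "greater", "ranksum_normal")
        p1 = target_set_test(shifted, mask, "greater", "ranksum_normal")
        assert p1 <= p0 + 1e-15


class TestPValueTable:
    def small_study(self, seed=21, **kw):
        cfg = dataclasses.replace(
            default_null_config(15, 8, seed),
            n_genes=200,
            region_labels=("A", "B"),
            **kw,
        )
        return generate_study(cfg)[0]

    def test_shape_contract(self):
        study = self.small_study()
        t = compute_pvalue_table(study, "mrna", ("A", "B"))
        assert t.p_less.shape == (15, 8)
        assert t.p_greater.shape == (15, 8)

    def test_region_swap_swaps_tails_exactly(self):
        study = self.small_study()
        ab = compute_pvalue_table(study, "mrna", ("A", "B"), method="ranksum_normal")
        ba = compute_pvalue_table(study, "mrna", ("B", "A"), method="ranksum_normal")
        assert np.array_equal(ab.p_less.to_numpy(), ba.p_greater.to_numpy())
        assert np.array_equal(ab.p_greater.to_numpy(), ba.p_less.to_numpy())

    def test_auto_uses_exact_for_small_target_sets(self):
        study = self.small_study(targets_per_mirna=(4, 8))
        auto = compute_pvalue_table(study, "mrna", ("A", "B"), method="auto")
        exact = compute_pvalue_table(study, "mrna", ("A", "B"), method="ranksum_exact")
        assert np.allclose(auto.p_greater.to_numpy(), exact.p_greater.to_numpy())

    def test_mirna_with_all_targets_missing_gets_nan_row(self):
        study = self.small_study()
        mirna0 = study.target_map.mirna_ids[0]
        victim_genes = sorted(study.target_map.targets[mirna0])
        sample = study.sample_id(study.paired_subjects(("A", "B"))[0], "A")
        study.mrna.values.loc[victim_genes, sample] = np.nan
        t = compute_pvalue_table(study, "mrna", ("A", "B"))
        assert t.p_greater.loc[mirna0].isna().all()
        others = t.p_greater.drop(index=mirna0)
        assert others.notna().all().all()

    def test_long_frame_round_trip(self):
        study = self.small_study()
        t = compute_pvalue_table(study, "mrna", ("A", "B"))
        back = DirectionalPValueTable.from_long_frame(t.to_long_frame())
        pd.testing.assert_frame_equal(
            back.p_greater.sort_index(), t.p_greater.sort_index()
        )


class TestDirectionCounts:
    def test_arrow_logic(self):
        assert net_direction(889, 173) == "up"
        assert net_direction(183, 280) == "down"
        assert net_direction(5, 5) == "none"

    def test_all_ones_yield_no_significance(self):
        frame = pd.DataFrame(np.ones((4, 3)), index=list("abcd"), columns=list("xyz"))
        t = DirectionalPValueTable(
            layer="mrna", region_pair=("A", "B"), p_less=frame,
            p_greater=frame.copy(), method="auto",
        )
        s = summarize_direction_counts(t)
        assert (s.n_up, s.n_down, s.net_direction) == (0, 0, "none")

    def test_planted_directions_recovered(self):
        recovered_up, n_up_gt_down = 0, 0
        for seed in range(20):
            cfg = planted_regulation_config(
                20, 5, delta=2.0, seed=400 + seed, n_mirnas=60, n_subjects=15,
                n_genes=500, region_labels=("A", "B"), targets_per_mirna=(15, 25),
            )
            study, truth = generate_study(cfg)
            t = compute_pvalue_table(study, "mrna", ("A", "B"))
            s = summarize_direction_counts(t)
            planted_up = {
                m for m, sign in truth.regulation_mirnas(("A", "B")).items() if sign > 0
            }
            found_up = set(s.per_mirna.index[s.per_mirna["significant_up"]])
            recovered_up += len(found_up & planted_up)
            n_up_gt_down += s.n_up > s.n_down
        assert n_up_gt_down == 20
        assert recovered_up / 20 >= 18
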