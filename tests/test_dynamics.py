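import math

import numpy as np
import pytest

from tcrdyn.dynamics import (
    ExpansionConfig,
    classify_dynamics,
    classify_expanded,
    expanded_mass_sweep,
    label_fates,
    mean_frequency_ratio,
    rate_test_pvalue,
)

from conftest import make_repertoire


def binom_rate_test_oracle(x, y, total_x, total_y):
    """Independent exact conditional binomial p-value by direct CDF summation."""
    n = x + y
    p0 = total_x / (total_x + total_y)
    pmf = [math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(n + 1)]
    lower = sum(pmf[: x + 1])
    upper = sum(pmf[x:])
    return min(1.0, 2.0 * min(lower, upper))


class TestClassifyExpanded:
    def test_clone_above_two_per_thousand_is_expanded(self):
        counts = {"big": 3}
        counts.update({f"s{i}": 1 for i in range(997)})  # big at 3/1000 = 0.003
        rep = make_repertoire(counts)
        assert "big" in classify_expanded(rep)

    def test_exactly_at_threshold_is_not_expanded(self):
        counts = {"edge": 2}
        counts.update({f"s{i}": 1 for i in range(998)})  # edge at exactly 2/1000
        rep = make_repertoire(counts)
        assert "edge" not in classify_expanded(rep)
        # inclusive mode flips the boundary decision
        assert "edge" in classify_expanded(rep, ExpansionConfig(inclusive=True))

    def test_uniform_thousand_clone_repertoire_has_no_expansion(self):
        rep = make_repertoire({f"c{i}": 4 for i in range(1000)})
        assert classify_expanded(rep) == set()


class TestMassSweep:
    def test_dominant_clone_mass(self):
        counts = {"big": 300}
        counts.update({f"s{i}": 1 for i in range(700)})
        sweep = expanded_mass_sweep(make_repertoire(counts), [0.002])
        assert sweep.loc[0, "n_expanded"] == 1
        assert sweep.loc[0, "mass_fraction"] == pytest.approx(0.3)

    def test_threshold_above_max_frequency(self):
        sweep = expanded_mass_sweep(make_repertoire({"a": 5, "b": 5}), [0.9])
        assert sweep.loc[0, "n_expanded"] == 0
        assert sweep.loc[0, "mass_fraction"] == 0.0

    def test_vanishing_threshold_captures_all_mass(self):
        sweep = expanded_mass_sweep(make_repertoire({"a": 5, "b": 5}), [1e-12])
        assert sweep.loc[0, "mass_fraction"] == pytest.approx(1.0)


class TestRateTest:
    def test_identical_rates_give_p_one(self):
        assert rate_test_pvalue(2, 2, 1000, 1000)[0] == pytest.approx(1.0)

    def test_appearance_from_zero_is_expanded(self):
        # 0 of 10,000 -> 60 of 10,000: two-sided p = 2 * 0.5^60
        p = rate_test_pvalue(0, 60, 10_000, 10_000)[0]
        assert p == pytest.approx(2 * 0.5**60, rel=1e-9)

    def test_halved_rate_is_significant(self):
        p = rate_test_pvalue(50, 50, 1000, 2000)[0]
        assert p < 0.01
        assert p == pytest.approx(binom_rate_test_oracle(50, 50, 1000, 2000), rel=1e-9)

    def test_matches_enumeration_oracle_on_grid(self):
        totals = [(500, 500), (1000, 2000), (750, 1250)]
        for tx, ty in totals:
            for x in range(0, 30, 7):
                for y in range(0, 30, 5):
                    if x + y == 0:
                        continue
                    got = rate_test_pvalue(x, y, tx, ty)[0]
                    want = binom_rate_test_oracle(x, y, tx, ty)
                    assert got == pytest.approx(want, rel=1e-9), (x, y, tx, ty)


class TestClassifyDynamics:
    def _reps(self, pre_counts, post_counts):
        return (
            make_repertoire(pre_counts, timepoint="pre"),
            make_repertoire(post_counts, timepoint="post"),
        )

    def test_labels_on_hand_cases(self):
        pre = {"stable": 2, "gone": 50, "filler": 948}
        post = {"stable": 2, "new": 60, "filler": 9938}
        rpre, rpost = self._reps(pre, post)
        calls = classify_dynamics(rpre, rpost).set_index("clone_key")
        assert calls.loc["new", "dynamic"] == "expanded"
        assert calls.loc["gone", "dynamic"] == "contracted"

    def test_swapping_timepoints_swaps_expansion_and_contraction(self, rng):
        pre_counts = {f"c{i}": int(c) + 1 for i, c in enumerate(rng.integers(0, 200, 50))}
        post_counts = {f"c{i}": int(c) + 1 for i, c in enumerate(rng.integers(0, 200, 50))}
        rpre, rpost = self._reps(pre_counts, post_counts)
        fwd = classify_dynamics(rpre, rpost).set_index("clone_key")["dynamic"]
        rev = classify_dynamics(rpost, rpre).set_index("clone_key")["dynamic"]
        swap = {"expanded": "contracted", "contracted": "expanded", "persistent": "persistent"}
        assert (fwd.map(swap) == rev[fwd.index]).all()


class TestFates:
    def test_fate_labels_and_partition(self):
        # kept: expanded both; lost: expanded pre only; new: expanded post only
        pre = {"kept": 30, "lost": 30}
        pre.update({f"f{i}": 1 for i in range(940)})
        post = {"kept": 30, "lost": 1, "new": 30}
        post.update({f"f{i}": 1 for i in range(939)})
        rpre = make_repertoire(pre, timepoint="pre")
        rpost = make_repertoire(post, timepoint="post")
        fates, summary = label_fates(rpre, rpost)
        by_key = fates.set_index("clone_key")["fate"]
        assert by_key["kept"] == "maintained"
        assert by_key["lost"] == "replaced"
        assert by_key["new"] == "novel"
        # maintained + replaced partition the pre-expanded set
        exp_pre = classify_expanded(rpre)
        labelled = set(by_key[by_key.isin(["maintained", "replaced"])].index)
        assert labelled == exp_pre
        assert summary["prop_maintained"] == pytest.approx(0.5)

    def test_pre_expanded_clone_absent_post_is_replaced(self):
        pre = {"gone": 30}
        pre.update({f"f{i}": 1 for i in range(970)})
        post = {f"f{i}": 1 for i in range(1000)}
        fates, _ = label_fates(
            make_repertoire(pre, timepoint="pre"), make_repertoire(post, timepoint="post")
        )
        gone = fates.set_index("clone_key")["fate"]["gone"]
        assert gone == "replaced"


class TestMeanFrequencyRatio:
    def test_unchanged_frequencies_give_ratio_one(self):
        pre = {"big": 30}
        pre.update({f"f{i}": 1 for i in range(970)})
        rpre = make_repertoire(pre, timepoint="pre")
        rpost = make_repertoire(pre, timepoint="post")
        assert mean_frequency_ratio(rpre, rpost) == pytest.approx(1.0)

    def test_halving_frequency_gives_ratio_two(self):
        pre = {"big": 20}
        pre.update({f"f{i}": 1 for i in range(980)})  # big at 0.02
        post = {"big": 20}
        post.update({f"f{i}": 1 for i in range(1980)})  # big at 0.01
        ratio = mean_frequency_ratio(
            make_repertoire(pre, timepoint="pre"), make_repertoire(post, timepoint="post")
        )
        assert ratio == pytest.approx(2.0)

    def test_undetected_post_clone_is_excluded(self):
        pre = {"big": 30, "gone": 30}
        pre.update({f"f{i}": 1 for i in range(940)})
        post = {"big": 30}
        post.update({f"f{i}": 1 for i in range(970)})
        ratio = mean_frequency_ratio(
            make_repertoire(pre, timepoint="pre"), make_repertoire(post, timepoint="post")
        )
        assert ratio == pytest.approx(1.0)  # only "big" qualifies, unchanged

    def test_no_qualifying_clone_is_undefined(self):
        pre = {"gone": 30}
        pre.update({f"f{i}": 1 for i in range(970)})
        post = {f"g{i}": 1 for i in range(1000)}
        assert mean_frequency_ratio(
            make_repertoire(pre, timepoint="pre"), make_repertoire(post, timepoint="post")
        ) is None
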