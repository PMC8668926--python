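import numpy as np
import pandas as pd
import pytest

from pitx1tools.composition import LabelSet, dpa_test, pairwise_dpa


def naive_dpa_p(labels_a, labels_b, cluster, n_perm, p_mix, seed):
    """Straightforward per-cell re-implementation of the permutation null."""
    rng = np.random.default_rng(seed)
    labels_a = np.asarray(labels_a, dtype=object)
    labels_b = np.asarray(labels_b, dtype=object)
    pooled = np.concatenate([labels_a, labels_b])
    n_a, n_b = len(labels_a), len(labels_b)
    obs = (labels_b == cluster).mean() - (labels_a == cluster).mean()
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        la, lb = perm[:n_a].copy(), perm[n_a:].copy()
        redraw_a = rng.random(n_a) < p_mix
        redraw_b = rng.random(n_b) < p_mix
        la[redraw_a] = rng.choice(pooled, int(redraw_a.sum()))
        lb[redraw_b] = rng.choice(pooled, int(redraw_b.sum()))
        null = (lb == cluster).mean() - (la == cluster).mean()
        if abs(null) >= abs(obs):
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


class TestDPATest:
    def test_identical_multisets_give_zero_statistic_and_p_one(self):
        labels = ["X"] * 30 + ["Y"] * 20 + ["Z"] * 10
        res = dpa_test(
            LabelSet("A", labels), LabelSet("B", list(labels)),
            n_perm=200, p_mix=0.1, seed=0,
        )
        assert (res.table["statistic"] == 0.0).all()
        assert (res.table["p_value"] == 1.0).all()

    def test_strong_shift_detected_and_confirmed_by_naive_oracle(self):
        a = ["X"] * 200
        b = ["X"] * 100 + ["Y"] * 100
        res = dpa_test(
            LabelSet("A", a), LabelSet("B", b),
            n_perm=10_000, p_mix=0.1, seed=1,
        )
        assert res.table.loc["Y", "p_value"] < 0.01
        assert naive_dpa_p(a, b, "Y", n_perm=2000, p_mix=0.1, seed=1) < 0.01

    def test_observed_proportions_and_statistic(self):
        res = dpa_test(
            LabelSet("A", ["X"] * 3 + ["Y"]), LabelSet("B", ["X"] + ["Y"] * 3),
            n_perm=100, p_mix=0.1, seed=0,
        )
        assert res.table.loc["Y", "obs_prop_a"] == pytest.approx(0.25)
        assert res.table.loc["Y", "obs_prop_b"] == pytest.approx(0.75)
        assert res.table.loc["Y", "statistic"] == pytest.approx(0.5)
        for col in ("obs_prop_a", "obs_prop_b"):
            assert res.table[col].sum() == pytest.approx(1.0)

    def test_same_seed_reproduces_identical_result(self, rng):
        a = LabelSet("A", rng.choice(["X", "Y", "Z"], 300))
        b = LabelSet("B", rng.choice(["X", "Y", "Z"], 250))
        r1 = dpa_test(a, b, n_perm=500, p_mix=0.1, seed=9)
        r2 = dpa_test(a, b, n_perm=500, p_mix=0.1, seed=9)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_swap_negates_statistics_and_preserves_p_values(self, rng):
        a = LabelSet("A", rng.choice(["X", "Y", "Z"], 400, p=[0.5, 0.3, 0.2]))
        b = LabelSet("B", rng.choice(["X", "Y", "Z"], 300, p=[0.3, 0.4, 0.3]))
        fwd = dpa_test(a, b, n_perm=800, p_mix=0.1, seed=4)
        rev = dpa_test(b, a, n_perm=800, p_mix=0.1, seed=4)
        np.testing.assert_array_equal(
            fwd.table["statistic"].to_numpy(), -rev.table["statistic"].to_numpy()
        )
        np.testing.assert_array_equal(
            fwd.table["p_value"].to_numpy(), rev.table["p_value"].to_numpy()
        )

    def test_p_values_never_zero(self, rng):
        a = LabelSet("A", ["X"] * 500)
        b = LabelSet("B", ["Y"] * 500)
        res = dpa_test(a, b, n_perm=1000, p_mix=0.1, seed=0)
        assert (res.table["p_value"] > 0).all()
        assert res.table["p_value"].min() == pytest.approx(1 / 1001)

    def test_power_increases_with_cell_count(self):
        # fixed 10-point shift in one of three clusters
        base, shifted = [0.4, 0.4, 0.2], [0.3, 0.4, 0.3]
        medians = []
        for n in (200, 1000, 5000):
            ps = []
            for rep in range(5):
                gen = np.random.default_rng(100 + rep)
                la = gen.choice(["X", "Y", "Z"], n, p=base)
                lb = gen.choice(["X", "Y", "Z"], n, p=shifted)
                res = dpa_test(
                    LabelSet("A", la), LabelSet("B", lb),
                    n_perm=1000, p_mix=0.1, seed=rep,
                )
                ps.append(res.table.loc["Z", "p_value"])
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]

    def test_log_ratio_statistic_flag(self):
        a = LabelSet("A", ["X"] * 90 + ["Y"] * 10)
        b = LabelSet("B", ["X"] * 60 + ["Y"] * 40)
        res = dpa_test(a, b, n_perm=500, p_mix=0.1, seed=2, statistic="log-ratio")
        assert res.table.loc["Y", "statistic"] > 0
        assert res.settings.statistic == "log-ratio"

    @pytest.mark.parametrize(
        "kwargs", [{"n_perm": 0}, {"p_mix": -0.1}, {"p_mix": 1.5}]
    )
    def test_invalid_settings_rejected(self, kwargs):
        a = LabelSet("A", ["X"] * 10)
        b = LabelSet("B", ["X"] * 10)
        with pytest.raises(ValueError):
            dpa_test(a, b, seed=0, **{"n_perm": 100, "p_mix": 0.1, **kwargs})

    def test_label_outside_vocabulary_rejected(self):
        a = LabelSet("A", ["X", "W"])
        b = LabelSet("B", ["X"])
        with pytest.raises(ValueError, match="vocabulary"):
            dpa_test(a, b, n_perm=10, p_mix=0.1, seed=0, clusters=["X", "Y"])

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            LabelSet("A", [])


class TestPairwiseDPA:
    def _sets(self, k, rng):
        return [
            LabelSet(f"C{i}", rng.choice(["X", "Y", "Z"], 200)) for i in range(k)
        ]

    def test_two_conditions_one_result(self, rng):
        out = pairwise_dpa(self._sets(2, rng), n_perm=100, p_mix=0.1, seed=0)
        assert len(out) == 1

    def test_four_conditions_six_results(self, rng):
        out = pairwise_dpa(self._sets(4, rng), n_perm=100, p_mix=0.1, seed=0)
        assert len(out) == 6

    def test_pair_matches_isolated_run_with_derived_seed(self, rng):
        sets = self._sets(3, rng)
        out = pairwise_dpa(sets, n_perm=300, p_mix=0.1, seed=10)
        # (C1, C2) is the third pair in combinations order -> seed 10 + 2
        solo = dpa_test(sets[1], sets[2], n_perm=300, p_mix=0.1, seed=12)
        pd.testing.assert_frame_equal(out[("C1", "C2")].table, solo.table)

    def test_duplicate_condition_labels_rejected(self, rng):
        sets = self._sets(2, rng)
        sets[1] = LabelSet("C0", sets[1].labels)
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_dpa(sets, n_perm=10, p_mix=0.1, seed=0)

    def test_fewer_than_two_conditions_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_dpa(self._sets(1, rng), n_perm=10, p_mix=0.1, seed=0)
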