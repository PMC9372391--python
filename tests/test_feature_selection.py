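"""RReliefF, forest importances, top-N selection, correlation screen."""

import numpy as np
import pandas as pd
import pytest

from oracles import pearson_textbook
from uavagb.feature_selection import (
    correlation_screen,
    feature_columns,
    rf_gini_importance,
    rf_oob_importance,
    rrelieff,
    select_top,
)


def make_table(rng, n=30, p_noise=5, target_feature=True):
    """Table with an AGB-mirroring feature plus independent noise features."""
    cols = {}
    agb = rng.uniform(100, 600, size=n)
    if target_feature:
        cols["signal"] = agb.copy()
    for i in range(p_noise):
        cols[f"noise{i}"] = rng.normal(size=n)
    cols["AGB"] = agb
    return pd.DataFrame(cols)


class TestRRelieff:
    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(0)
        table = make_table(rng)
        table["flat"] = 3.14
        ranking = rrelieff(table)
        idx = ranking.features.index("flat")
        assert ranking.weights[idx] == 0.0

    def test_duplicated_feature_equal_weights(self):
        rng = np.random.default_rng(1)
        table = make_table(rng)
        table["copy"] = table["signal"]
        ranking = rrelieff(table)
        w = dict(zip(ranking.features, ranking.weights))
        assert w["signal"] == pytest.approx(w["copy"], abs=1e-12)

    def test_signal_feature_beats_noise(self):
        """A feature identical to the target outranks independent noise."""
        hits = 0
        for seed in range(20):
            table = make_table(np.random.default_rng(seed))
            ranking = rrelieff(table, seed=seed)
            ranks = dict(zip(ranking.features, ranking.ranks))
            if ranks["signal"] == 1:
                hits += 1
        assert hits >= 19

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        table = make_table(rng, n=40)
        shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        w1 = dict(zip(*[rrelieff(table).features, rrelieff(table).weights]))
        r2 = rrelieff(shuffled)
        w2 = dict(zip(r2.features, r2.weights))
        for k in w1:
            assert w1[k] == pytest.approx(w2[k], abs=1e-10)

    def test_k_at_least_n_rejected(self):
        table = make_table(np.random.default_rng(3), n=8)
        with pytest.raises(ValueError):
            rrelieff(table, k_neighbors=8)


class TestRfGini:
    def test_threshold_target_recovery(self):
        """The single generative feature ranks first in ≥19/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            x = rng.normal(size=(n, 6))
            y = np.where(x[:, 2] > 0, 500.0, 100.0) + rng.normal(0, 5, n)
            table = pd.DataFrame({f"f{i}": x[:, i] for i in range(6)})
            table["AGB"] = y
            ranking = rf_gini_importance(table, seed=seed)
            if ranking.top(1) == ["f2"]:
                hits += 1
        assert hits >= 19

    def test_collapsed_quantiles_warn(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"x": rng.normal(size=24),
                              "y": rng.normal(size=24),
                              "AGB": np.repeat([100.0, 500.0], 12)})
        with pytest.warns(UserWarning):
            rf_gini_importance(table, n_classes=4, seed=0)

    def test_variance_mode_also_recovers(self):
        rng = np.random.default_rng(5)
        n = 60
        x = rng.normal(size=(n, 5))
        table = pd.DataFrame({f"f{i}": x[:, i] for i in range(5)})
        table["AGB"] = 300 + 80 * x[:, 1] + rng.normal(0, 5, n)
        ranking = rf_gini_importance(table, seed=0, mode="variance")
        assert ranking.top(1) == ["f1"]

    def test_duplicated_feature_copies_share_importance_evenly(self):
        """Duplicating a feature splits its impurity importance between the
        two copies: averaged over seeds the copies weigh the same, and each
        keeps a substantial part of the pair's combined weight."""
        first, second = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            n = 80
            x = rng.normal(size=(n, 4))
            y = 300 + 100 * x[:, 0] + 20 * x[:, 1] + rng.normal(0, 10, n)
            dup = pd.DataFrame({f"f{i}": x[:, i] for i in range(4)})
            dup.insert(1, "f0_copy", dup["f0"])
            dup["AGB"] = y
            r = rf_gini_importance(dup, seed=seed)
            w = dict(zip(r.features, r.weights))
            first.append(w["f0"])
            second.append(w["f0_copy"])
        assert np.mean(first) == pytest.approx(np.mean(second), rel=0.15)
        assert min(np.mean(first), np.mean(second)) > 0


class TestRfOob:
    def test_exact_copy_is_most_important(self):
        """A feature the target copies exactly is ranked first, always."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            x = rng.normal(size=(n, 5))
            table = pd.DataFrame({f"f{i}": x[:, i] for i in range(5)})
            table["AGB"] = 100 + 50 * x[:, 3]
            ranking = rf_oob_importance(table, seed=seed)
            assert ranking.top(1) == ["f3"]

    def test_independent_feature_near_zero(self):
        """Permuting an irrelevant feature barely moves the OOB error."""
        null_imps, signal_imps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed + 30)
            n = 60
            x = rng.normal(size=(n, 4))
            table = pd.DataFrame({f"f{i}": x[:, i] for i in range(4)})
            table["AGB"] = 200 + 60 * x[:, 0] + rng.normal(0, 5, n)
            ranking = rf_oob_importance(table, seed=seed)
            w = dict(zip(ranking.features, ranking.weights))
            signal_imps.append(w["f0"])
            null_imps.append(abs(w["f2"]))
        assert np.mean(null_imps) < np.mean(signal_imps) / 10

    def test_duplicated_copies_get_similar_importance(self):
        rng = np.random.default_rng(6)
        n = 80
        x = rng.normal(size=(n, 3))
        table = pd.DataFrame({"f0": x[:, 0], "f0_copy": x[:, 0],
                              "f1": x[:, 1], "f2": x[:, 2]})
        table["AGB"] = 300 + 100 * x[:, 0] + rng.normal(0, 10, n)
        vals = []
        for seed in range(10):
            ranking = rf_oob_importance(table, seed=seed)
            w = dict(zip(ranking.features, ranking.weights))
            vals.append((w["f0"], w["f0_copy"]))
        a = np.mean([v[0] for v in vals])
        b = np.mean([v[1] for v in vals])
        assert a == pytest.approx(b, rel=0.5)

    def test_gaussian_corruption_mode_runs(self):
        table = make_table(np.random.default_rng(7), n=40)
        ranking = rf_oob_importance(table, seed=0, corruption="gaussian")
        assert ranking.top(1) == ["signal"]


class TestSelectTop:
    def _ranking(self, p):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {f"f{i}": rng.normal(size=30) for i in range(p)})
        table["AGB"] = rng.uniform(0, 700, 30)
        return rrelieff(table)

    def test_top_ten_of_many(self):
        assert len(select_top(self._ranking(39), 10)) == 10

    def test_all_selected_when_fewer(self):
        assert len(select_top(self._ranking(8), 10)) == 8

    def test_ties_break_by_feature_order(self):
        table = pd.DataFrame({"a": [1.0] * 30, "b": [2.0] * 30,
                              "AGB": np.linspace(0, 700, 30)})
        ranking = rrelieff(table)  # both constant → both weight 0
        assert select_top(ranking, 1) == ["a"]


class TestCorrelationScreen:
    def test_perfect_correlations(self):
        agb = np.linspace(100, 600, 20)
        table = pd.DataFrame({"pos": 2 * agb, "neg": -agb, "AGB": agb})
        screen = correlation_screen(table).set_index("feature")
        assert screen.loc["pos", "r"] == pytest.approx(1.0)
        assert screen.loc["neg", "r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({"x": rng.normal(size=25),
                              "AGB": rng.uniform(0, 700, 25)})
        screen = correlation_screen(table)
        expected = pearson_textbook(table["x"].to_numpy(),
                                    table["AGB"].to_numpy())
        assert screen["r"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        table = pd.DataFrame({"flat": [1.0] * 12,
                              "AGB": np.linspace(0, 700, 12)})
        screen = correlation_screen(table).set_index("feature")
        assert screen.loc["flat", "r"] == 0.0
        assert bool(screen.loc["flat", "zero_variance"])


def test_feature_columns_excludes_metadata(feature_table):
    cols = feature_columns(feature_table["table"])
    assert len(cols) == 39
    assert "AGB" not in cols and "stage" not in cols
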