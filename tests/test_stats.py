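"""Balanced three-way ANOVA, Tukey HSD letter display, correlation and
performance matrices — checked against independent textbook-formula oracles."""

import numpy as np
import pandas as pd
import pytest

from melonopt import pearson_matrix, performance_matrix, three_way_anova, tukey_hsd
from melonopt.exceptions import DomainError, ValidationError
from melonopt.stats import block_means, significance_stars

FACTORS = ["cultivar", "substrate_volume", "plants_per_slab"]


def balanced_frame(rng, reps=5, effects=None):
    """Balanced 3x2x2 factorial with optional injected main effects."""
    effects = effects or {}
    rows = []
    for c in ("Dalgona", "Hero", "Kingstar"):
        for s in (10.0, 20.0):
            for d in (3, 4):
                mu = (
                    10.0
                    + effects.get(("cultivar", c), 0.0)
                    + effects.get(("substrate", s), 0.0)
                    + effects.get(("density", d), 0.0)
                )
                for i in range(reps):
                    rows.append(
                        {
                            "cultivar": c, "substrate_volume": s, "plants_per_slab": d,
                            "block": 1 + i % 3, "weight": 1.5, "length": 14.0,
                            "diameter": 13.5, "flesh_thickness": 40.0,
                            "brix": mu + rng.normal(0, 1.0), "net_score": 1.3,
                        }
                    )
    return pd.DataFrame(rows)


def anova_oracle(df: pd.DataFrame, response: str) -> dict:
    """Direct cell/marginal-mean SS formulas for a balanced three-way design."""
    y = df[response]
    grand = y.mean()
    n = df.groupby(FACTORS).size().iloc[0]
    levels = {f: sorted(df[f].unique()) for f in FACTORS}
    a, b, c = (len(levels[f]) for f in FACTORS)

    def m(cols):
        return df.groupby(cols)[response].mean()

    ss_a = n * b * c * ((m([FACTORS[0]]) - grand) ** 2).sum()
    ss_b = n * a * c * ((m([FACTORS[1]]) - grand) ** 2).sum()
    ss_c = n * a * b * ((m([FACTORS[2]]) - grand) ** 2).sum()

    def ss_two(f1, f2, other_len):
        mm = m([f1, f2])
        m1, m2 = m([f1]), m([f2])
        dev = mm - m1.reindex(mm.index.get_level_values(0)).to_numpy() - m2.reindex(
            mm.index.get_level_values(1)).to_numpy() + grand
        return n * other_len * (dev ** 2).sum()

    ss_ab = ss_two(FACTORS[0], FACTORS[1], c)
    ss_ac = ss_two(FACTORS[0], FACTORS[2], b)
    ss_bc = ss_two(FACTORS[1], FACTORS[2], a)
    cell = m(FACTORS)
    ss_cells = n * ((cell - grand) ** 2).sum()
    ss_abc = ss_cells - ss_a - ss_b - ss_c - ss_ab - ss_ac - ss_bc
    ss_res = ((y - cell.reindex(pd.MultiIndex.from_frame(df[FACTORS])).to_numpy()) ** 2).sum()
    return {
        "C": ss_a, "S": ss_b, "D": ss_c, "C x S": ss_ab, "C x D": ss_ac,
        "S x D": ss_bc, "C x S x D": ss_abc, "Residual": ss_res,
    }


class TestThreeWayAnova:
    def test_matches_cell_means_oracle(self, rng):
        df = balanced_frame(rng, reps=5)
        table = three_way_anova(df, "brix").table
        expected = anova_oracle(df, "brix")
        for term, ss in expected.items():
            assert table.loc[term, "sum_sq"] == pytest.approx(ss, rel=1e-8), term

    def test_ss_additivity(self, rng):
        df = balanced_frame(rng, reps=4)
        anova = three_way_anova(df, "brix")
        total = ((df["brix"] - df["brix"].mean()) ** 2).sum()
        assert anova.total_ss == pytest.approx(total, rel=1e-8)
        assert anova.table["df"].sum() == len(df) - 1

    def test_constant_response_all_zero_ss(self, rng):
        df = balanced_frame(rng, reps=3)
        df["brix"] = 12.0
        table = three_way_anova(df, "brix").table
        assert np.allclose(table["sum_sq"], 0.0, atol=1e-18)

    def test_pure_cultivar_effect(self, rng):
        df = balanced_frame(rng, reps=3)
        df["brix"] = df["cultivar"].map({"Dalgona": 14.0, "Hero": 12.0, "Kingstar": 10.0})
        table = three_way_anova(df, "brix").table
        total = ((df["brix"] - df["brix"].mean()) ** 2).sum()
        assert table.loc["C", "sum_sq"] == pytest.approx(total, rel=1e-12)
        others = [t for t in table.index if t != "C"]
        assert np.allclose(table.loc[others, "sum_sq"], 0.0, atol=1e-18)

    def test_unbalanced_rejected(self, rng):
        df = balanced_frame(rng, reps=3).iloc[:-1]
        with pytest.raises(ValidationError, match="balanced"):
            three_way_anova(df, "brix")

    def test_block_means_balance_uneven_counts(self, default_sim):
        fruits, _ = default_sim  # 503 fruits: cells differ by one fruit
        reps = block_means(fruits)
        counts = reps.groupby(FACTORS).size()
        assert (counts == 3).all()
        three_way_anova(reps, "brix")  # must not raise

    def test_star_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "NS"


class TestTukeyHsd:
    def test_identical_groups_share_letter(self, rng):
        base = rng.normal(10, 1, 20)
        res = tukey_hsd({"g1": base, "g2": base.copy()})
        assert set(res.letters["g1"]) & set(res.letters["g2"])

    def test_separated_groups_differ(self, rng):
        res = tukey_hsd(
            {"lo": rng.normal(0, 0.1, 15), "hi": rng.normal(50, 0.1, 15)}
        )
        assert not set(res.letters["lo"]) & set(res.letters["hi"])

    def test_three_group_decisions_match_independent_implementation(self, rng):
        groups = {
            "a": rng.normal(10.0, 1, 12),
            "b": rng.normal(10.5, 1, 12),
            "c": rng.normal(14.0, 1, 12),
        }
        res = tukey_hsd(groups)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm_res = pairwise_tukeyhsd(values, labels, alpha=0.05)
        for (g1, g2), reject in zip(
            [tuple(r[:2]) for r in sm_res.summary().data[1:]], sm_res.reject
        ):
            assert bool(res.significant.loc[g1, g2]) == bool(reject), (g1, g2)

    def test_letters_consistent_with_decisions(self, rng):
        groups = {f"g{i}": rng.normal(mu, 1.0, 10) for i, mu in
                  enumerate([0, 0.5, 1.0, 3.0, 3.2, 8.0])}
        res = tukey_hsd(groups)
        names = list(groups)
        for i, g1 in enumerate(names):
            for g2 in names[i + 1:]:
                shared = set(res.letters[g1]) & set(res.letters[g2])
                if res.significant.loc[g1, g2]:
                    assert not shared, (g1, g2)
                else:
                    assert shared, (g1, g2)

    def test_singleton_group_rejected(self):
        with pytest.raises(DomainError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})

    def test_two_groups_required(self):
        with pytest.raises(DomainError):
            tukey_hsd({"a": [1.0, 2.0]})


class TestPearsonMatrix:
    def test_self_and_anticorrelation(self, rng):
        y = rng.normal(size=12)
        df = pd.DataFrame({"m1": y, "m2": -y, "m3": rng.normal(size=12)})
        corr = pearson_matrix(df, ["m1", "m2", "m3"])
        assert corr.loc["m1", "m1"] == 1.0
        assert corr.loc["m1", "m2"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)

    def test_matches_covariance_formula(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 2)), columns=["x", "y"])
        corr = pearson_matrix(df, ["x", "y"])
        x, y = df["x"] - df["x"].mean(), df["y"] - df["y"].mean()
        expected = (x * y).sum() / np.sqrt((x ** 2).sum() * (y ** 2).sum())
        assert corr.loc["x", "y"] == pytest.approx(expected, rel=1e-12)

    def test_positive_semidefinite(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        corr = pearson_matrix(df, list("abcd"))
        assert np.linalg.eigvalsh(corr.to_numpy()).min() > -1e-10

    def test_constant_metric_flagged_not_zero(self, rng, caplog):
        df = pd.DataFrame({"x": rng.normal(size=5), "c": 3.0})
        with caplog.at_level("WARNING"):
            corr = pearson_matrix(df, ["x", "c"])
        assert np.isnan(corr.loc["x", "c"])
        assert "constant" in caplog.text

    def test_needs_three_rows(self, rng):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(DomainError):
            pearson_matrix(df, ["x", "y"])


class TestPerformanceMatrix:
    def test_best_and_worst_entries(self, rng):
        df = pd.DataFrame(
            {"roi": [268.0, 42.9, 100.0], "total_yield": [4339.0, 2477.0, 3466.0]},
            index=["hero", "king", "dal"],
        )
        perf = performance_matrix(df, ["roi", "total_yield"])
        assert perf.loc["hero", "roi"] == 100.0
        assert perf.loc["king", "roi"] == 0.0
        assert perf.loc["king", "total_yield"] == 0.0

    def test_delegation_identity(self, rng):
        from melonopt.pareto import ObjectiveMatrix, minmax_normalize

        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        perf = performance_matrix(df, ["a", "b", "c"])
        direct = minmax_normalize(ObjectiveMatrix(values=df)).normalized
        assert np.allclose(perf, direct)

    def test_missing_metric(self):
        with pytest.raises(ValidationError):
            performance_matrix(pd.DataFrame({"a": [1.0]}), ["a", "b"])
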