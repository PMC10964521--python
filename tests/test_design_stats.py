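"""Balanced factorial ANOVA and Duncan grouping against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_anova, brute_duncan_share
from droughtscreen.design_stats import (
    ANOVA_SOURCES,
    anova_two_factor,
    cv_percent,
    duncan_groups,
    format_anova,
    stars,
)
from droughtscreen.errors import ComputationError, InputError


def make_balanced(rng, g, s, r, effects=None, noise=1.0):
    """Tidy table for a g x s x r layout; returns (frame, nested value lists)."""
    rows, cells = [], []
    for i in range(g):
        cells.append([])
        for j in range(s):
            vals = []
            for k in range(r):
                mu = 10.0 if effects is None else effects(i, j)
                v = mu + (rng.normal(0, noise) if noise else 0.0)
                vals.append(v)
                rows.append((f"g{i}", f"s{j}", k + 1, v))
            cells[i].append(vals)
    frame = pd.DataFrame(rows, columns=["genotype", "stress_level", "replicate", "value"])
    return frame, cells


class TestAnova:
    def test_df_structure_three_replicates(self, rng):
        frame, _ = make_balanced(rng, 2, 3, 3)
        assert anova_two_factor(frame).df_column() == (1, 2, 2, 12)

    def test_df_structure_four_replicates(self, rng):
        frame, _ = make_balanced(rng, 2, 3, 4)
        assert anova_two_factor(frame).df_column() == (1, 2, 2, 18)

    def test_all_equal_observations(self, rng):
        frame, _ = make_balanced(rng, 2, 3, 3, noise=0.0)
        res = anova_two_factor(frame)
        assert (res.table["sum_sq"] == 0).all()
        assert res.cv_percent == 0.0

    def test_brute_force_oracle_equivalence(self, rng):
        """50 random balanced layouts agree with explicit-loop ANOVA to 1e-8."""
        for _ in range(50):
            g = int(rng.integers(2, 5))
            s = int(rng.integers(2, 4))
            r = int(rng.integers(2, 5))
            frame, cells = make_balanced(rng, g, s, r, noise=2.0)
            res = anova_two_factor(frame)
            expect = brute_anova(cells)
            for source, key in zip(ANOVA_SOURCES, ("G", "S", "GxS", "E")):
                assert res.table.loc[source, "df"] == expect["df"][key]
                assert res.table.loc[source, "sum_sq"] == pytest.approx(
                    expect["ss"][key], rel=1e-8, abs=1e-10
                )
            ss_total = float(((frame["value"] - frame["value"].mean()) ** 2).sum())
            assert res.table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-8)

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        frame, _ = make_balanced(rng, 3, 3, 3, noise=1.5)
        res = anova_two_factor(frame)
        fit = smf.ols("value ~ C(genotype) * C(stress_level)", data=frame).fit()
        ref = anova_lm(fit, typ=1)
        np.testing.assert_allclose(
            res.table["sum_sq"].to_numpy(), ref["sum_sq"].to_numpy(), rtol=1e-8
        )
        np.testing.assert_allclose(
            res.table["F"].to_numpy()[:3], ref["F"].to_numpy()[:3], rtol=1e-8
        )
        np.testing.assert_allclose(
            res.table["p"].to_numpy()[:3], ref["PR(>F)"].to_numpy()[:3], atol=1e-10
        )

    def test_pure_additive_effects_have_zero_interaction(self, rng):
        frame, _ = make_balanced(
            rng, 3, 3, 2, effects=lambda i, j: 5.0 + 2.0 * i - 1.5 * j, noise=0.0
        )
        res = anova_two_factor(frame)
        assert res.table.loc["G x S", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert res.table.loc["Error", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_unbalanced_layout_rejected(self, rng):
        frame, _ = make_balanced(rng, 2, 3, 3)
        with pytest.raises(InputError, match="unbalanced"):
            anova_two_factor(frame.iloc[:-1])

    def test_single_replicate_rejected(self, rng):
        frame, _ = make_balanced(rng, 2, 3, 1)
        with pytest.raises(InputError, match="error term"):
            anova_two_factor(frame)

    def test_format_report_contains_cv_and_stars(self, rng):
        frame, _ = make_balanced(
            rng, 2, 3, 3, effects=lambda i, j: 10 + 3.0 * i, noise=0.3
        )
        text = format_anova(anova_two_factor(frame), trait="demo")
        assert "CV%" in text and "Genotype (G)" in text and "**" in text


class TestCvPercent:
    def test_hand_values(self):
        assert cv_percent(4.0, 10.0) == pytest.approx(20.0)
        assert cv_percent(0.0, 3.0) == 0.0

    def test_oracle(self, rng):
        for _ in range(20):
            mse = float(rng.uniform(0.01, 5.0))
            mean = float(rng.uniform(0.5, 20.0))
            assert cv_percent(mse, mean) == pytest.approx(
                100.0 * np.sqrt(mse) / mean, rel=1e-12
            )

    def test_zero_grand_mean(self):
        with pytest.raises(ComputationError, match="zero grand mean"):
            cv_percent(1.0, 0.0)


class TestDuncan:
    def test_identical_means_share_one_letter(self):
        g = duncan_groups({"a1": 5.0, "a2": 5.0, "a3": 5.0}, 1.0, 12, 3)
        assert set(g.means["letters"]) == {"a"}

    def test_widely_separated_means_get_distinct_letters(self):
        g = duncan_groups({"hi": 100.0, "lo": 0.0}, 1.0, 12, 3)
        assert g.letters_for("hi") == "a"
        assert g.letters_for("lo") == "b"

    def test_never_separates_means_closer_than_r2(self, rng):
        for _ in range(20):
            means = {f"m{i}": float(v) for i, v in enumerate(rng.normal(10, 2, 5))}
            g = duncan_groups(means, float(rng.uniform(0.5, 4.0)), 12, 3)
            tab = g.means
            for i in range(len(tab) - 1):
                gap = tab["mean"].iloc[i] - tab["mean"].iloc[i + 1]
                if gap <= g.lsr[2]:
                    shared = set(tab["letters"].iloc[i]) & set(tab["letters"].iloc[i + 1])
                    assert shared, f"adjacent means {gap=} below R_2 were separated"

    def test_exhaustive_pairs_oracle(self, rng):
        """Letter-sharing matches the literal every-containing-range check."""
        for trial in range(50):
            k = int(rng.integers(3, 7))
            means = {f"m{i}": float(v) for i, v in enumerate(rng.normal(10, 1.5, k))}
            mse = float(rng.uniform(0.2, 3.0))
            df_error = int(rng.choice([6, 12, 18]))
            g = duncan_groups(means, mse, df_error, 3)
            tab = g.means
            vals = tab["mean"].to_list()
            share_oracle = brute_duncan_share(vals, g.lsr)
            for i in range(k):
                for j in range(k):
                    impl = bool(set(tab["letters"].iloc[i]) & set(tab["letters"].iloc[j]))
                    assert impl == share_oracle[i][j], (trial, i, j)

    def test_letters_respect_mean_ordering(self, rng):
        means = {f"m{i}": float(v) for i, v in enumerate(rng.normal(0, 3, 6))}
        g = duncan_groups(means, 0.5, 12, 3)
        assert list(g.means["mean"]) == sorted(g.means["mean"], reverse=True)
        firsts = [t[0] for t in g.means["letters"]]
        assert firsts == sorted(firsts)

    def test_nonpositive_mse_is_an_error(self):
        with pytest.raises(ComputationError):
            duncan_groups({"a": 1.0, "b": 2.0}, 0.0, 12, 3)


@pytest.mark.parametrize(
    "p,expected", [(0.001, "**"), (0.01, "**"), (0.03, "*"), (0.05, "*"), (0.2, "")]
)
def test_stars(p, expected):
    assert stars(p) == expected


def test_stars_rejects_out_of_range():
    with pytest.raises(InputError):
        stars(1.5)
    with pytest.raises(InputError):
        stars(-0.1)
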