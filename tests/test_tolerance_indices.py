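"""Tolerance indices, Finlay-Wilkinson slope, STS composition and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from _oracles import brute_indices, brute_slope
from droughtscreen.errors import ComputationError, InputError
from droughtscreen.tolerance_indices import (
    TrialSummary,
    classify_extremes,
    compute_b,
    compute_basic_indices,
    compute_sts,
    rank_genotypes,
    score_trial,
    trial_summary,
)


def records(*rows):
    return pd.DataFrame(rows, columns=["genotype", "yp", "ys"])


class TestBasicIndices:
    def test_hand_example(self):
        """yp=4, ys=1 against population means (2, 1): all six by hand."""
        out = compute_basic_indices(records((1, 4.0, 1.0)), TrialSummary(2.0, 1.0))
        row = out.iloc[0]
        assert row["tol"] == 3.0
        assert row["mp"] == 2.5
        assert row["gmp"] == 2.0
        assert row["hm"] == pytest.approx(1.6)
        assert row["sti"] == pytest.approx(1.0)
        assert row["ssi"] == pytest.approx(1.5)  # SI = 0.5

    def test_equal_yields_symmetry(self):
        out = compute_basic_indices(records((1, 3.0, 3.0)), TrialSummary(3.0, 2.0))
        row = out.iloc[0]
        assert row["tol"] == 0.0
        assert row["ssi"] == 0.0
        assert row["mp"] == row["gmp"] == row["hm"] == 3.0

    def test_oracle_equivalence(self, rng):
        """Every index equals an independent cell-by-cell recomputation."""
        for _ in range(100):
            n = int(rng.integers(3, 20))
            yp = rng.uniform(0.5, 20.0, n)
            ys = rng.uniform(0.1, 15.0, n)
            df = records(*[(i + 1, yp[i], ys[i]) for i in range(n)])
            summary = trial_summary(df)
            if summary.stress_intensity == 0:
                continue
            out = compute_basic_indices(df)
            for i in range(n):
                expect = brute_indices(yp[i], ys[i], summary.mean_yp, summary.mean_ys)
                for name, val in expect.items():
                    assert out.iloc[i][name] == pytest.approx(val, rel=1e-12), name

    @given(
        yp=st.floats(0.1, 100.0),
        ys=st.floats(0.1, 100.0),
    )
    def test_am_gm_hm_chain(self, yp, ys):
        """MP >= GMP >= HM for positive yields, equal iff yp == ys."""
        out = compute_basic_indices(records((1, yp, ys)), TrialSummary(10.0, 5.0))
        row = out.iloc[0]
        assert row["mp"] >= row["gmp"] - 1e-12 * row["mp"]
        assert row["gmp"] >= row["hm"] - 1e-12 * max(row["gmp"], 1)
        if yp == ys:
            assert row["mp"] == pytest.approx(row["hm"], rel=1e-12)
        assert row["gmp"] ** 2 == pytest.approx(yp * ys, rel=1e-9)
        assert row["sti"] == pytest.approx(row["gmp"] ** 2 / 10.0**2, rel=1e-9)

    def test_ssi_is_one_for_population_matching_reduction(self):
        """A genotype losing exactly the population's relative yield has SSI 1."""
        yp = np.array([4.0, 8.0, 16.0])
        df = records(*[(i + 1, p, p * 0.5) for i, p in enumerate(yp)])
        out = compute_basic_indices(df)
        assert (out["ssi"] == 1.0).all()

    def test_rejects_nonpositive_yp(self):
        with pytest.raises(InputError, match="yp"):
            compute_basic_indices(records((1, 0.0, 1.0)), TrialSummary(2.0, 1.0))

    def test_rejects_negative_ys(self):
        with pytest.raises(InputError, match="ys"):
            compute_basic_indices(records((1, 2.0, -0.1)), TrialSummary(2.0, 1.0))

    def test_zero_stress_intensity_is_an_error(self):
        df = records((1, 3.0, 3.0), (2, 5.0, 5.0))
        with pytest.raises(ComputationError, match="SSI"):
            compute_basic_indices(df)


class TestSensitivitySlope:
    def test_two_environment_closed_form(self):
        """Env means (3, 1): genotype (4, 2) tracks the mean one-to-one."""
        wide = pd.DataFrame({"genotype": [1, 2], "yp": [4.0, 2.0], "ys": [2.0, 0.0]})
        b = compute_b(wide)
        assert b[1] == pytest.approx((4.0 - 2.0) / (3.0 - 1.0))
        assert b[1] == pytest.approx(1.0)

    def test_flat_genotype_has_zero_slope(self):
        wide = pd.DataFrame(
            {"genotype": [1, 2], "e1": [2.0, 1.0], "e2": [2.0, 5.0], "e3": [2.0, 9.0]}
        )
        assert compute_b(wide)[1] == pytest.approx(0.0)

    def test_four_environment_oracle(self, rng):
        for _ in range(20):
            y = rng.uniform(1.0, 10.0, size=(6, 4))
            wide = pd.DataFrame(y, columns=["e1", "e2", "e3", "e4"])
            wide.insert(0, "genotype", range(1, 7))
            env_means = y.mean(axis=0)
            if np.ptp(env_means) < 1e-9:
                continue
            b = compute_b(wide)
            for i in range(6):
                assert b[i + 1] == pytest.approx(
                    brute_slope(list(env_means), list(y[i])), rel=1e-9
                )

    def test_identical_environment_means_error(self):
        wide = pd.DataFrame({"genotype": [1, 2], "e1": [4.0, 2.0], "e2": [2.0, 4.0]})
        with pytest.raises(ComputationError, match="undefined"):
            compute_b(wide)


class TestSts:
    def _table(self, **comp):
        base = {"genotype": [1], "yp": [4.0], "ys": [1.0]}
        base.update({k: [v] for k, v in comp.items()})
        return pd.DataFrame(base)

    def test_direct_arithmetic(self):
        t = self._table(gmp=2.0, sti=0.5, hm=1.6, mp=2.5, tol=3.0, ssi=1.0, b=0.8)
        assert compute_sts(t)["sts"].iloc[0] == pytest.approx(1.8)

    def test_zero_components(self):
        t = self._table(gmp=0.0, sti=0.0, hm=0.0, mp=0.0, tol=0.0, ssi=0.0, b=0.0)
        assert compute_sts(t)["sts"].iloc[0] == 0.0

    def test_chained_hand_evaluation(self):
        """yp=4/ys=1 indices vs means (2, 1); b from the two-env closed form."""
        idx = compute_basic_indices(records((1, 4.0, 1.0)), TrialSummary(2.0, 1.0))
        idx["b"] = (4.0 - 1.0) / (2.0 - 1.0)  # = 3
        sts = compute_sts(idx)["sts"].iloc[0]
        # 2 + 1 + 1.6 + 2.5 - 3 - 1.5 - 3
        assert sts == pytest.approx(-0.4)

    def test_missing_component_is_an_error(self):
        t = self._table(gmp=2.0, sti=0.5, hm=1.6, mp=2.5, tol=3.0, ssi=1.0)
        with pytest.raises(InputError, match="b"):
            compute_sts(t)

    def test_nan_component_is_an_error(self):
        t = self._table(gmp=2.0, sti=0.5, hm=1.6, mp=2.5, tol=3.0, ssi=1.0, b=np.nan)
        with pytest.raises(InputError, match="genotype"):
            compute_sts(t)


class TestRanking:
    def test_tie_broken_by_ascending_genotype(self):
        t = pd.DataFrame({"genotype": [5, 3], "sts": [1.0, 1.0]})
        out = rank_genotypes(t)
        assert out.set_index("genotype")["rank"].to_dict() == {3: 1, 5: 2}

    def test_single_genotype(self):
        out = rank_genotypes(pd.DataFrame({"genotype": [7], "sts": [0.3]}))
        assert out["rank"].tolist() == [1]

    def test_empty_input(self):
        out = rank_genotypes(pd.DataFrame({"genotype": [], "sts": []}))
        assert len(out) == 0 and "rank" in out.columns

    def test_rank_map_invariant_under_row_permutation(self, rng):
        n = 40
        t = pd.DataFrame({"genotype": range(1, n + 1), "sts": rng.normal(size=n)})
        base = rank_genotypes(t).set_index("genotype")["rank"]
        for _ in range(5):
            shuffled = t.sample(frac=1.0, random_state=int(rng.integers(1 << 30)))
            out = rank_genotypes(shuffled).set_index("genotype")["rank"]
            assert out.sort_index().equals(base.sort_index())
        assert sorted(base) == list(range(1, n + 1))  # bijection onto 1..n

    def test_classify_extremes_ordering_and_bounds(self):
        t = pd.DataFrame({"genotype": [1, 2, 3, 4], "sts": [4.0, 3.0, 2.0, 1.0]})
        tol, sen = classify_extremes(t, k_tolerant=2, k_sensitive=2)
        assert tol == [1, 2]
        assert sen == [4, 3]  # most sensitive first
        assert classify_extremes(t, 0, 2)[0] == []
        with pytest.raises(InputError):
            classify_extremes(t, 3, 2)


class TestScoreTrial:
    def test_columns_and_monotone_structure(self, rng):
        n = 30
        yp = rng.uniform(5, 15, n)
        df = records(*[(i + 1, yp[i], yp[i] * rng.uniform(0.2, 0.9)) for i in range(n)])
        out = score_trial(df)
        for col in ("ssi", "tol", "mp", "gmp", "sti", "hm", "b", "sts", "rank"):
            assert col in out.columns
        assert sorted(out["rank"]) == list(range(1, n + 1))
        top = out.loc[out["rank"] == 1].iloc[0]
        assert top["sts"] == out["sts"].max()
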