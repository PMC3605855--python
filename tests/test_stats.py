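"""Factorial ANOVA, Tukey–Kramer post hoc, letters, Bonferroni."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from phycoflux.stats import (DegenerateDataError, FactorialAnova,
                             FactorialDataset, bonferroni_alpha,
                             check_assumptions, compact_letters,
                             tukey_posthoc, two_way_anova)


def _dataset(cells, response="y", season="summer"):
    """cells: dict {(pco2, temp): values}"""
    vals, pco2, temp = [], [], []
    for (p, t), v in cells.items():
        vals.extend(v)
        pco2.extend([p] * len(v))
        temp.extend([t] * len(v))
    return FactorialDataset(response=response, values=np.array(vals),
                            pco2=np.array(pco2), temp=np.array(temp),
                            season=season)


def _random_dataset(rng, n=(5, 5, 5, 4), effects=(0.0, 0.0, 0.0)):
    a_eff, b_eff, ab_eff = effects
    cells = {}
    for i, (p, t) in enumerate(itertools.product(("400", "700"),
                                                 ("T", "T+3"))):
        sa = 1.0 if p == "400" else -1.0
        sb = 1.0 if t == "T" else -1.0
        mu = 1.0 + a_eff * sa + b_eff * sb + ab_eff * sa * sb
        cells[(p, t)] = mu + rng.normal(0, 0.3, n[i])
    return _dataset(cells)


# --- brute-force Type III oracle (effect-coded regression) ---

def _type3_oracle(data):
    df = data.to_frame()
    a = np.where(df["pco2"] == "400", 1.0, -1.0)
    b = np.where(df["temp"] == "T", 1.0, -1.0)
    X_full = np.column_stack([np.ones(len(df)), a, b, a * b])
    y = df["y"].to_numpy()

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(X_full)
    df_resid = len(y) - 4
    mse = rss_full / df_resid
    out = {}
    for name, col in (("pco2", 1), ("temp", 2), ("interaction", 3)):
        X_red = np.delete(X_full, col, axis=1)
        ss = rss(X_red) - rss_full
        out[name] = ss / mse
    return out, df_resid


def test_anova_matches_brute_force_oracle(rng):
    """Type III F statistics equal the hand-coded sums-of-squares
    computation on random unbalanced 2x2 datasets."""
    for _ in range(10):
        data = _random_dataset(rng, effects=tuple(rng.normal(0, 0.3, 3)))
        table = two_way_anova(data)
        oracle, df_resid = _type3_oracle(data)
        assert table.df_resid == df_resid
        for eff, f_ref in oracle.items():
            assert table.effects.loc[eff, "F"] == pytest.approx(f_ref,
                                                                abs=1e-9)


def test_anova_df_match_unbalanced_design(rng):
    # n = 5,5,5,4 gives df = (1, 15)
    data = _random_dataset(rng)
    table = two_way_anova(data)
    assert (table.effects["df1"] == 1).all()
    assert (table.effects["df2"] == 15).all()


def test_pure_main_effect_no_interaction(rng):
    cells = {("400", "T"): np.array([1.0, 1.1, 0.9, 1.0, 1.05]),
             ("400", "T+3"): np.array([1.0, 1.1, 0.9, 1.0, 1.05]),
             ("700", "T"): np.array([2.0, 2.1, 1.9, 2.0, 2.05]),
             ("700", "T+3"): np.array([2.0, 2.1, 1.9, 2.0, 2.05])}
    table = two_way_anova(_dataset(cells))
    assert table.effects.loc["interaction", "F"] == pytest.approx(0.0,
                                                                  abs=1e-9)
    assert table.effects.loc["pco2", "p"] < 1e-6


def test_constant_response_degenerate():
    cells = {(p, t): np.full(5, 3.0)
             for p, t in itertools.product(("400", "700"), ("T", "T+3"))}
    with pytest.raises(DegenerateDataError):
        two_way_anova(_dataset(cells))


def test_f_invariant_to_constant_shift(rng):
    data = _random_dataset(rng, effects=(0.2, 0.1, 0.0))
    shifted = FactorialDataset(response="y", values=data.values + 57.0,
                               pco2=data.pco2, temp=data.temp)
    f1 = two_way_anova(data).effects["F"]
    f2 = two_way_anova(shifted).effects["F"]
    assert np.allclose(f1, f2, atol=1e-8)


class TestAssumptions:
    def test_normal_cells_usually_pass(self, rng):
        sh = lev = 0
        for _ in range(100):
            data = _random_dataset(rng)
            rep = check_assumptions(data)
            sh += rep.shapiro_p >= 0.05
            lev += rep.levene_p >= 0.05
        # each test rejects well-behaved data at its 5% level
        assert sh >= 90 and lev >= 90

    def test_lognormal_cells_trigger_transform(self, rng):
        flagged = 0
        for _ in range(50):
            cells = {(p, t): np.exp(rng.normal(0, 1.3, 6))
                     for p, t in itertools.product(("400", "700"),
                                                   ("T", "T+3"))}
            rep = check_assumptions(_dataset(cells))
            flagged += rep.log_transformed
        assert flagged > 25

    def test_constant_data_degenerate(self):
        cells = {(p, t): np.full(5, 1.0)
                 for p, t in itertools.product(("400", "700"), ("T", "T+3"))}
        with pytest.raises(DegenerateDataError):
            check_assumptions(_dataset(cells))

    def test_nonpositive_values_cannot_be_logged(self, rng):
        cells = {(p, t): np.concatenate([[-1.0], 100 * rng.lognormal(0, 2, 5)])
                 for p, t in itertools.product(("400", "700"), ("T", "T+3"))}
        with pytest.raises(ValueError):
            check_assumptions(_dataset(cells))


class TestTukey:
    def test_identical_cells_nd(self, rng):
        base = rng.normal(0, 1, 5)
        cells = {(p, t): base.copy()
                 for p, t in itertools.product(("400", "700"), ("T", "T+3"))}
        data = _dataset(cells)
        # add a hair of noise so the ANOVA is not degenerate
        data = FactorialDataset("y", data.values + rng.normal(0, 1e-6, 20),
                                data.pco2, data.temp)
        res = tukey_posthoc(data, two_way_anova(data), alpha=0.0125)
        assert set(res.letters.values()) == {"nd"}

    def test_extreme_cell_gets_own_letter(self, rng):
        cells = {(p, t): rng.normal(0, 1, 5)
                 for p, t in itertools.product(("400", "700"), ("T", "T+3"))}
        cells[("700", "T+3")] = cells[("700", "T+3")] + 10.0
        data = _dataset(cells)
        res = tukey_posthoc(data, two_way_anova(data), alpha=0.0125)
        shifted = res.letters["700 T+3"]
        others = {v for k, v in res.letters.items() if k != "700 T+3"}
        assert all(set(shifted).isdisjoint(set(o)) for o in others)

    def test_equal_n_reduces_to_classic_hsd(self, rng):
        """With equal n the Tukey–Kramer q equals classic Tukey HSD;
        cross-checked against statsmodels."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        data = _random_dataset(rng, n=(5, 5, 5, 5),
                               effects=(0.3, 0.1, 0.05))
        res = tukey_posthoc(data, two_way_anova(data), alpha=0.05)
        df = data.to_frame()
        sm_res = pairwise_tukeyhsd(df["y"], df["cell"], alpha=0.05)
        ours = {tuple(sorted((r.group1, r.group2))): r.p
                for r in res.pairwise.itertuples()}
        rows = sm_res.summary().data[1:]
        for row, p_sm in zip(rows, sm_res.pvalues):
            g1, g2 = str(row[0]), str(row[1])
            assert ours[tuple(sorted((g1, g2)))] == pytest.approx(
                p_sm, abs=1e-6)

    def test_letters_consistent_with_pvalues(self, rng):
        for _ in range(5):
            data = _random_dataset(rng, effects=tuple(rng.normal(0, 0.4, 3)))
            res = tukey_posthoc(data, two_way_anova(data), alpha=0.05)
            for r in res.pairwise.itertuples():
                l1 = res.letters[r.group1]
                l2 = res.letters[r.group2]
                if l1 == "nd":
                    continue
                if r.p < 0.05:
                    assert set(l1).isdisjoint(set(l2))
                else:
                    assert set(l1) & set(l2)


class TestCompactLetters:
    def test_no_significance(self):
        assert compact_letters(["a", "b"], set()) == {"a": "nd", "b": "nd"}

    def test_one_outlier(self):
        groups = ["g1", "g2", "g3", "g4"]
        sig = {("g4", "g1"), ("g4", "g2"), ("g4", "g3")}
        letters = compact_letters(groups, sig)
        assert letters["g1"] == letters["g2"] == letters["g3"]
        assert set(letters["g4"]).isdisjoint(set(letters["g1"]))

    def test_chain(self):
        # g1 < g3 significant, g2 overlaps both -> a, ab, b
        letters = compact_letters(["g1", "g2", "g3"], {("g1", "g3")})
        assert set(letters["g2"]) == set(letters["g1"]) | set(letters["g3"])


class TestBonferroni:
    @pytest.mark.parametrize("n,expected", [(4, 0.0125), (1, 0.05),
                                            (2, 0.025)])
    def test_family_thresholds(self, n, expected):
        assert bonferroni_alpha(0.05, n) == pytest.approx(expected)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


def test_type_one_error_controlled(rng):
    """Null simulations: rejection rate of the pCO2 effect at the
    Bonferroni-adjusted alpha stays at or below nominal (binomial
    band, 1000 reps)."""
    alpha_adj = bonferroni_alpha(0.05, 4)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        data = _random_dataset(rng)
        table = two_way_anova(data)
        rejections += table.effects.loc["pco2", "p"] < alpha_adj
    # 3 sigma above nominal 0.0125
    bound = alpha_adj + 3 * np.sqrt(alpha_adj * (1 - alpha_adj) / reps)
    assert rejections / reps <= bound


def test_model_results_facade(rng):
    data = _random_dataset(rng, effects=(0.5, 0.0, 0.0))
    res = FactorialAnova(data, n_analyses=4).fit()
    assert res.alpha_adjusted == pytest.approx(0.0125)
    text = res.summary()
    assert "Two-way ANOVA" in text and "Tukey" in text
    assert res.anova.effects.loc["pco2", "p"] < 0.05
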