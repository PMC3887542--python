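"""Effect-table models, Levene, FDR, genetic correlation, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import matepref as mp
from matepref.components import cell_means, choosiness, global_attractiveness
from matepref.inference import (discriminate_models, fdr_adjust,
                                fit_copulation_model, fit_courtship_model,
                                fit_duration_model, genetic_correlation,
                                kendalls_w, levene_choosiness, rank_concordance)

from _bruteforce import bf_bh_adjust, bf_kendalls_w
from conftest import null_line_effects


def _signal_trials(male_court_shift=0.0, female_resp_shift=0.0, seed=0,
                   n_lines=4, n_per_cell=8, noise=0.5):
    """Null trials plus an injected log-scale offset on line 1 of one sex.

    ``male_court_shift`` moves male line 1's courtship latency (and its
    copulation-duration propensity); ``female_resp_shift`` moves female
    line 1's copulation latency.
    """
    effects = null_line_effects(n_lines, n_lines)
    male_prop = np.zeros(n_lines)
    male_prop[0] = male_court_shift
    fem_resp = np.zeros(n_lines)
    fem_resp[0] = female_resp_shift
    effects = mp.LineEffects(
        male_ids=effects.male_ids, female_ids=effects.female_ids,
        male_traits=effects.male_traits,
        male_courtship_propensity=male_prop,
        male_duration_propensity=male_prop,
        female_prefs=effects.female_prefs,
        female_responsiveness=fem_resp,
        female_attractiveness=effects.female_attractiveness,
        female_duration_offset=effects.female_duration_offset,
    )
    design = mp.DesignConfig(n_male_lines=n_lines, n_female_lines=n_lines,
                             min_matings_per_cell=n_per_cell,
                             max_trials_per_cell=3 * n_per_cell,
                             stimulus_scale=0.0, noise_sd=noise,
                             baseline_log_copulation=7.2, seed=seed)
    return mp.generate_trials(design, effects)


class TestLinearModels:
    def test_courtship_detects_injected_male_effect(self):
        trials = _signal_trials(male_court_shift=1.0, seed=101)
        eff = fit_courtship_model(trials)
        p = eff.pvalues()
        assert p["male_line"] < 0.01
        assert p["male_line:female_line"] > 0.01  # no interaction injected

    def test_duration_detects_injected_male_effect(self):
        trials = _signal_trials(male_court_shift=1.0, seed=102)
        eff = fit_duration_model(trials)
        assert eff.pvalues()["male_line"] < 0.01
        assert set(eff.table["effect"]) >= {"male_line", "female_line",
                                            "male_line:female_line",
                                            "courtship_latency",
                                            "copulation_latency"}

    def test_single_line_degenerate_input_rejected(self):
        trials = _signal_trials(seed=103)
        one_male = trials[trials["male_line"] == "M1"]
        with pytest.raises(ValueError, match="fewer than two levels"):
            fit_courtship_model(one_male)

    def test_missing_cell_named_in_error(self):
        trials = _signal_trials(seed=104)
        holed = trials[~((trials["male_line"] == "M2") &
                         (trials["female_line"] == "F3"))]
        with pytest.raises(ValueError, match=r"M2.*F3"):
            fit_courtship_model(holed)

    def test_effects_invariant_to_line_relabeling(self):
        trials = _signal_trials(male_court_shift=0.8, seed=105)
        relabeled = trials.assign(
            male_line=trials["male_line"].map(lambda s: "X" + s[::-1]),
            female_line=trials["female_line"].map(lambda s: "Y" + s[::-1]))
        a = fit_courtship_model(trials).table.set_index("effect")
        b = fit_courtship_model(relabeled).table.set_index("effect")
        for effect in a.index:
            assert a.loc[effect, "statistic"] == pytest.approx(
                b.loc[effect, "statistic"], rel=1e-8)


class TestCopulationModel:
    def test_detects_injected_female_effect_not_male(self):
        trials = _signal_trials(female_resp_shift=1.0, seed=111)
        eff = fit_copulation_model(trials, effects=("male_line", "female_line"))
        p = eff.pvalues()
        assert p["female_line"] < 0.001
        assert p["male_line"] > 0.01
        tab = eff.table
        assert (tab["statistic"] >= 0).all()
        assert tab.loc[tab["effect"] == "female_line", "df"].iloc[0] == 3

    def test_duplicated_data_doubles_lr(self):
        trials = _signal_trials(female_resp_shift=0.8, seed=112)
        doubled = pd.concat([trials, trials], ignore_index=True)
        lr1 = fit_copulation_model(trials, effects=("female_line",))
        lr2 = fit_copulation_model(doubled, effects=("female_line",))
        s1 = lr1.table["statistic"].iloc[0]
        s2 = lr2.table["statistic"].iloc[0]
        assert 1.6 <= s2 / s1 <= 2.4

    def test_no_censoring_flagged_in_metadata(self):
        trials = _signal_trials(seed=113, noise=0.2)  # baseline far from censor
        eff = fit_copulation_model(trials, effects=("male_line",))
        assert eff.metadata["all_events"] == bool(trials[trials["courted"]]["mated"].all())
        assert eff.metadata["n_events"] == int(trials["mated"].sum())


class TestLevene:
    def test_identical_groups_zero_statistic(self):
        trials = _trials_two_female_lines([10.0, 50.0, 20.0], [10.0, 50.0, 20.0])
        res = levene_choosiness(trials, "copulation_latency", mated_only=True)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_classic_levene(self):
        # groups {1,5,3} and {2,4,3}: |dev| -> {2,2,0} and {1,1,0};
        # ANOVA on those gives F = (2/3) / ((10/3)/4) = 0.8 with df (1, 4)
        trials = _trials_two_female_lines([1.0, 5.0, 3.0], [2.0, 4.0, 3.0])
        res = levene_choosiness(trials, "copulation_latency", mated_only=True)
        assert res.statistic == pytest.approx(0.8, rel=1e-12)
        assert (res.df1, res.df2) == (1, 4)

    def test_median_center_is_brown_forsythe(self):
        rng = np.random.default_rng(0)
        a, b = rng.exponential(100, 30).tolist(), rng.exponential(300, 30).tolist()
        trials = _trials_two_female_lines(a, b)
        res = levene_choosiness(trials, "copulation_latency", center="median",
                                mated_only=True)
        ref = stats.levene(np.array(a), np.array(b), center="median")
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_needs_two_groups(self):
        trials = _trials_two_female_lines([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="two chooser lines"):
            levene_choosiness(trials[trials["female_line"] == "F1"],
                              "copulation_latency", mated_only=True)


def _trials_two_female_lines(vals_f1, vals_f2):
    rows = []
    for f, vals in (("F1", vals_f1), ("F2", vals_f2)):
        for v in vals:
            rows.append({
                "male_line": "M1", "female_line": f, "male_age": 4, "female_age": 4,
                "courted": True, "mated": True, "courtship_latency": 30.0,
                "copulation_latency": v, "copulation_duration": 900.0})
    return pd.DataFrame(rows)


class TestFdr:
    def test_bh_by_hand(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_bh_properties_and_brute_force(self, ps):
        adj = fdr_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # order-preserving
        assert adj == pytest.approx(bf_bh_adjust(list(ps)), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestGeneticCorrelation:
    def test_collinear_points_r2_one(self):
        lines = [f"L{i}" for i in range(5)]
        x = pd.Series([100.0, 200.0, 300.0, 400.0, 500.0], index=lines)
        y = pd.Series(2.0 - 3.0 / x, index=lines)  # exact in 1/x
        res = genetic_correlation(y, x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-3.0)

    def test_exact_negative_slope_without_transform(self):
        lines = [f"L{i}" for i in range(10)]
        x = pd.Series(np.arange(10.0), index=lines)
        res = genetic_correlation(-x, x, inverse_transform=False)
        assert res.slope == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_lines == 10

    def test_r2_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(4)
        lines = [f"L{i}" for i in range(8)]
        x = pd.Series(rng.uniform(100, 900, 8), index=lines)
        y = pd.Series(rng.uniform(10, 90, 8), index=lines)
        base = genetic_correlation(y, x, inverse_transform=False)
        scaled = genetic_correlation(5.0 * y + 7.0, x, inverse_transform=False)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-12)

    def test_mismatched_line_sets_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["L1", "L2", "L3"])
        b = pd.Series([1.0, 2.0, 3.0], index=["L1", "L2", "L4"])
        with pytest.raises(ValueError, match="line sets differ"):
            genetic_correlation(a, b)

    def test_too_few_lines_rejected(self):
        a = pd.Series([1.0, 2.0], index=["L1", "L2"])
        with pytest.raises(ValueError, match="three"):
            genetic_correlation(a, a)


class TestConcordance:
    def test_identical_rankings_w_one(self):
        cells = _cells_matrix([[1, 2, 3], [10, 20, 30], [5, 6, 7]])
        res = rank_concordance(cells, n_permutations=300, seed=1)
        assert res.kendall_w == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_known_rank_matrix_oracle(self):
        # rankings (1,2,3), (2,1,3), (3,2,1): S = 2, W = 12*2/(9*24) = 1/9
        ranks = np.array([[1, 2, 3], [2, 1, 3], [3, 2, 1]], dtype=float)
        assert kendalls_w(ranks) == pytest.approx(1.0 / 9.0, rel=1e-12)
        assert bf_kendalls_w(ranks.tolist()) == pytest.approx(1.0 / 9.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_w_matches_friedman_statistic(self, seed):
        # Friedman chi-square = m (n - 1) W, including tie correction
        rng = np.random.default_rng(seed)
        m, n = rng.integers(3, 7), rng.integers(3, 7)
        data = rng.standard_normal((m, n))
        ranks = np.apply_along_axis(stats.rankdata, 1, data)
        w = kendalls_w(ranks)
        chi2 = stats.friedmanchisquare(*[data[:, j] for j in range(n)]).statistic
        assert w == pytest.approx(chi2 / (m * (n - 1)), rel=1e-10)
        assert w == pytest.approx(bf_kendalls_w(ranks.tolist()), rel=1e-12)

    def test_incomplete_matrix_names_missing_cells(self):
        cells = _cells_matrix([[1, 2, 3], [10, 20, 30]])
        cells = cells[~((cells["chooser_line"] == "F1") &
                        (cells["partner_line"] == "M2"))]
        with pytest.raises(ValueError, match=r"F1.*M2"):
            rank_concordance(cells)

    def test_full_pipeline_open_ended_concordance_high(self):
        design = mp.DesignConfig(n_male_lines=5, n_female_lines=5,
                                 noise_sd=0.15, seed=71)
        effects = mp.line_effects_from_population(
            design, mp.PopulationSpec.open_ended(seed=71))
        trials = mp.generate_trials(design, effects)
        cells = cell_means(trials, "copulation_latency")
        res = rank_concordance(cells, n_permutations=500, seed=71)
        assert res.kendall_w >= 0.9


def _cells_matrix(mat):
    rows = []
    for i, row in enumerate(mat):
        for j, mean in enumerate(row):
            rows.append({"chooser_line": f"F{i}", "partner_line": f"M{j}",
                         "channel": "copulation_latency", "n": 5,
                         "mean": float(mean), "sd": 1.0})
    return pd.DataFrame(rows)


class TestDiscriminateModels:
    def _trials(self, model, seed):
        design = mp.DesignConfig(n_male_lines=5, n_female_lines=5,
                                 noise_sd=0.2, seed=seed)
        pop = (mp.PopulationSpec.open_ended(seed=seed) if model == "open"
               else mp.PopulationSpec.unimodal(y_sd=2.0, nu_mean=15.0,
                                               nu_sd=7.0, seed=seed))
        effects = mp.line_effects_from_population(design, pop)
        return mp.generate_trials(design, effects)

    def test_open_ended_data_labeled_concordant(self):
        res = discriminate_models(self._trials("open", 201),
                                  n_permutations=500, seed=201)
        assert res.label == "open_ended_or_shared_peak"
        assert res.kendall_w >= 0.9

    def test_variable_peak_data_labeled_discordant(self):
        res = discriminate_models(self._trials("uni", 202),
                                  n_permutations=500, seed=202)
        assert res.label == "variable_peak_unimodal"
        assert res.kendall_w < 0.9
        assert res.interaction_p < 0.05

    def test_single_cell_input_rejected(self):
        trials = self._trials("open", 203)
        single = trials[(trials["male_line"] == "M01") &
                        (trials["female_line"] == "F01")]
        with pytest.raises(ValueError):
            discriminate_models(single)
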