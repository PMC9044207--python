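import numpy as np
import pandas as pd
import pytest

from pulsekit.errors import ResultsFormatError, StatsError
from pulsekit.stats import (
    Assumptions,
    ResultsTable,
    akinshin_gamma,
    cd_diagram_data,
    check_assumptions,
    cohens_d,
    effect_magnitude,
    run_comparison,
    select_test,
)


def _df(mat, names=None):
    names = names or [f"m{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, columns=names)


class TestAssumptions:
    def test_gaussian_samples_retain_normality(self):
        # both groups pass Shapiro at alpha=0.05 with probability ~0.95^2;
        # threshold sits 3 binomial sd below that expectation
        kept = 0
        n_runs = 200
        for s in range(n_runs):
            mat = np.random.default_rng(s).normal(0, 1, (50, 2))
            a = check_assumptions(_df(mat))
            kept += a.all_normal
        assert kept / n_runs >= 0.84

    def test_exponential_samples_reject_normality(self):
        rejected = 0
        for s in range(100):
            mat = np.random.default_rng(s).exponential(1, (50, 2))
            a = check_assumptions(_df(mat))
            rejected += not a.all_normal
        assert rejected >= 95

    def test_constant_group_flagged_degenerate_not_crashing(self):
        mat = np.column_stack([np.full(20, 3.0),
                               np.random.default_rng(0).normal(size=20)])
        a = check_assumptions(_df(mat, ["const", "var"]))
        assert "const" in a.degenerate
        assert np.isnan(a.normality_p["const"])

    def test_homogeneity_test_depends_on_normality(self):
        rng = np.random.default_rng(1)
        a_norm = check_assumptions(_df(rng.normal(0, 1, (60, 2))))
        assert a_norm.homogeneity_test == ("bartlett" if a_norm.all_normal else "levene")
        a_exp = check_assumptions(_df(rng.exponential(1, (60, 2))))
        assert a_exp.homogeneity_test == "levene"

    def test_too_few_samples_rejected(self):
        with pytest.raises(StatsError):
            check_assumptions(np.ones((3, 2)))


class TestSelectTest:
    @staticmethod
    def _assume(all_normal, homo=True):
        return Assumptions({}, {}, all_normal, homo, "bartlett", 0.5, ())

    @pytest.mark.parametrize(
        "k,normal,homo,expected",
        [
            (2, True, True, "paired_t"),
            (2, False, True, "wilcoxon"),
            (3, True, True, "rm_anova"),
            (3, False, True, "friedman"),
            (3, True, False, "friedman"),
            (5, False, False, "friedman"),
        ],
    )
    def test_decision_table(self, k, normal, homo, expected):
        assert select_test(k, self._assume(normal, homo)) == expected


class TestEffectSizes:
    def test_cohens_d_known_value(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a - 1.0  # constant difference of 1, sd 0
        assert cohens_d(a, b) == 0.0  # degenerate guard
        b2 = np.array([0.0, 2.0, 2.0, 4.0])
        d = (a - b2).mean() / (a - b2).std(ddof=1)
        assert cohens_d(a, b2) == pytest.approx(d)

    def test_akinshin_gamma_sign_and_scale(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 2.0
        g = akinshin_gamma(a, b)
        assert g < 0
        assert akinshin_gamma(b, a) == pytest.approx(-g)

    @pytest.mark.parametrize("v,label", [(0.1, "negligible"), (0.3, "small"),
                                         (0.6, "medium"), (1.5, "large")])
    def test_magnitude_labels(self, v, label):
        assert effect_magnitude(v) == label


class TestComparison:
    def test_null_calibration_paired_t_path(self):
        rng = np.random.default_rng(11)
        rej, t_selected = 0, 0
        n_sim = 300
        for _ in range(n_sim):
            rep = run_comparison(_df(rng.normal(0, 1, (20, 2))), metric="x")
            rej += rep.rejected
            t_selected += rep.test == "paired_t"
        assert t_selected / n_sim > 0.85  # shapiro occasionally trips on noise
        assert 0.02 <= rej / n_sim <= 0.09

    def test_power_against_one_sd_shift(self):
        rng = np.random.default_rng(12)
        rej = 0
        for _ in range(200):
            mat = rng.normal(0, 1, (20, 2))
            mat[:, 1] += 1.0
            rej += run_comparison(_df(mat), metric="x").rejected
        assert rej / 200 > 0.8

    def test_exponential_two_groups_use_wilcoxon(self):
        mat = np.random.default_rng(3).exponential(1, (30, 2))
        rep = run_comparison(_df(mat), metric="x")
        assert rep.test == "wilcoxon"
        assert rep.effect_sizes["name"].iloc[0] == "gamma"

    def test_ordered_nonnormal_groups_friedman_nemenyi(self):
        rng = np.random.default_rng(4)
        mat = np.column_stack([m + 0.1 * rng.exponential(1, 30) for m in (1, 2, 3)])
        rep = run_comparison(_df(mat, ["lo", "mid", "hi"]), metric="x")
        assert rep.test == "friedman"
        assert rep.rejected
        assert rep.posthoc.loc["lo", "hi"] < 0.05
        assert rep.cd is not None

    def test_normal_homoskedastic_three_groups_rm_anova_tukey(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 40)
        mat = np.column_stack([base + rng.normal(0, 1, 40),
                               base + rng.normal(0, 1, 40) + 2.0,
                               base + rng.normal(0, 1, 40)])
        rep = run_comparison(_df(mat, ["a", "b", "c"]), metric="x")
        if rep.test == "rm_anova":  # shapiro may reject by chance
            assert rep.rejected
            assert rep.posthoc.loc["a", "b"] < 0.05
            assert rep.posthoc.loc["a", "c"] > 0.05

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        mat = rng.exponential(1, (25, 3)) + np.array([0.0, 0.5, 1.0])
        rep1 = run_comparison(_df(mat, ["a", "b", "c"]), metric="x")
        rep2 = run_comparison(_df(mat[:, [2, 0, 1]], ["c", "a", "b"]), metric="x")
        assert rep1.test == rep2.test
        assert rep1.p_value == pytest.approx(rep2.p_value)
        for m in ["a", "b", "c"]:
            assert rep1.group_stats.loc[m, "MR"] == pytest.approx(
                rep2.group_stats.loc[m, "MR"]
            )

    def test_mean_ranks_average_to_half_k_plus_one(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(30, 4))
        rep = run_comparison(_df(mat), metric="x")
        assert rep.group_stats["MR"].mean() == pytest.approx((4 + 1) / 2.0)

    def test_identical_groups_report_no_variance(self):
        mat = np.full((10, 3), 5.0)
        rep = run_comparison(_df(mat), metric="x")
        assert rep.no_variance
        assert "no test" in rep.summary() or "no variance" in rep.summary().lower()

    def test_summary_and_json_render(self):
        mat = np.random.default_rng(8).exponential(1, (20, 3))
        rep = run_comparison(_df(mat), metric="CCC")
        text = rep.summary()
        assert "Shapiro" in text and "MD=" in text
        import json

        payload = json.loads(rep.to_json())
        assert payload["metric"] == "CCC"


class TestCD:
    def test_two_group_cd_matches_pairwise_conclusion(self):
        rng = np.random.default_rng(9)
        mat = rng.exponential(1, (40, 2))
        mat[:, 1] += 2.0  # strongly separated
        rep = run_comparison(_df(mat, ["a", "b"]), metric="x")
        ranks = {"a": 1.0, "b": 2.0}
        cd, groups = cd_diagram_data(ranks, 40, 2, test="friedman")
        separated = all(len(g) == 1 for g in groups)
        assert separated == rep.rejected

    def test_equal_ranks_single_group(self):
        cd, groups = cd_diagram_data({"a": 2.0, "b": 2.0, "c": 2.0}, 10, 3)
        assert groups == [("a", "b", "c")]

    def test_widely_separated_ranks_all_singletons(self):
        cd, groups = cd_diagram_data({"a": 1.0, "b": 5.0, "c": 9.0}, 200, 3)
        assert all(len(g) == 1 for g in groups)

    def test_not_applicable_outside_friedman_path(self):
        with pytest.raises(StatsError):
            cd_diagram_data({"a": 1.0, "b": 2.0}, 10, 2, test="rm_anova")


class TestResultsTable:
    @staticmethod
    def _table(n=6):
        t = ResultsTable()
        rng = np.random.default_rng(0)
        for v in range(n):
            for m in ("POS", "GREEN"):
                for metric in ("MAE", "CCC"):
                    t.add("synth", f"v{v}", m, metric, rng.uniform())
        return t

    def test_matrix_shape_and_complete_cases(self):
        t = self._table()
        mat = t.matrix("CCC")
        assert mat.shape == (6, 2)
        t.add("synth", "v9", "POS", "CCC", 0.5)  # GREEN missing for v9
        assert t.matrix("CCC").shape == (6, 2)

    @pytest.mark.parametrize("ext", ["h5", "csv"])
    def test_round_trip(self, tmp_path, ext):
        t = self._table()
        path = tmp_path / f"results.{ext}"
        t.save(path)
        back = ResultsTable.load(path)
        pd.testing.assert_frame_equal(
            back.records, t.records, check_dtype=False
        )

    def test_empty_round_trip(self, tmp_path):
        t = ResultsTable()
        t.save(tmp_path / "empty.h5")
        assert len(ResultsTable.load(tmp_path / "empty.h5")) == 0

    def test_wrong_schema_rejected(self, tmp_path):
        import h5py

        bad = tmp_path / "bad.h5"
        with h5py.File(bad, "w") as f:
            f.attrs["format_version"] = 99
        with pytest.raises(ResultsFormatError):
            ResultsTable.load(bad)
        bad_csv = tmp_path / "bad.csv"
        pd.DataFrame({"x": [1]}).to_csv(bad_csv, index=False)
        with pytest.raises(ResultsFormatError):
            ResultsTable.load(bad_csv)


def test_figure_export_smoke(tmp_path):
    from pulsekit.plots import boxplot_metric, cd_diagram

    t = TestResultsTable._table(12)
    rng = np.random.default_rng(1)
    for v in range(12):
        t.add("synth", f"v{v}", "CHROM", "CCC", 0.3 + 0.2 * rng.exponential())
    boxplot_metric(t, "CCC", tmp_path / "box.png")
    rep = run_comparison(t, "CCC")
    if rep.cd is not None:
        cd_diagram(rep, tmp_path / "cd.png")
        assert (tmp_path / "cd.png").exists()
    assert (tmp_path / "box.png").exists()
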