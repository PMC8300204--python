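"""Aggregation, confidence intervals, Tukey letters and the report bundle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hensight.stats import (
    aggregate_units,
    anova_tukey,
    compact_letter_display,
    mean_ci,
    report,
)


def _index_table(recording_id, treatment, cluster_vals, unrest_vals, period="morning"):
    n = len(cluster_vals)
    return pd.DataFrame(
        {
            "recording_id": recording_id,
            "treatment": treatment,
            "date": "2021-05-01",
            "period": period,
            "frame": range(n),
            "cluster_index": cluster_vals,
            "unrest_index_cm": unrest_vals,
        }
    )


class TestAggregateUnits:
    def test_constant_recording_mean(self):
        idx = _index_table("r0", "blue", [3.0] * 10, [1.0] * 10)
        labels = pd.DataFrame({"recording_id": ["r0"], "comfort": ["comfort"]})
        units = aggregate_units(idx, labels)
        assert len(units) == 1
        assert units["cluster_index"].iloc[0] == 3.0
        assert units["n_frames"].iloc[0] == 10

    def test_invalid_frames_excluded_from_mean(self):
        vals = [2.0] * 5 + [np.nan] * 5
        idx = _index_table("r0", "blue", vals, vals)
        labels = pd.DataFrame({"recording_id": ["r0"], "comfort": ["heat"]})
        units = aggregate_units(idx, labels)
        assert units["cluster_index"].iloc[0] == 2.0

    def test_unlabelled_recording_dropped(self):
        idx = pd.concat(
            [
                _index_table("r0", "blue", [1.0], [1.0]),
                _index_table("r1", "blue", [9.0], [9.0]),
            ]
        )
        labels = pd.DataFrame(
            {"recording_id": ["r0", "r1"], "comfort": ["comfort", "missing"]}
        )
        units = aggregate_units(idx, labels)
        assert list(units["recording_id"]) == ["r0"]


class TestMeanCi:
    def test_zero_variance_collapses(self):
        assert mean_ci([5, 5, 5, 5]) == (5.0, 5.0, 5.0)

    def test_coverage_of_true_mean(self, rng):
        draws = rng.normal(3.0, 1.0, 10000)
        m, lo, hi = mean_ci(draws)
        assert lo < 3.0 < hi
        assert hi - lo < 0.1  # ~4 sem at n=10000

    def test_linear_in_scale(self, rng):
        vals = rng.normal(10, 2, 50)
        a = mean_ci(vals)
        b = mean_ci(2 * vals)
        assert b == pytest.approx(tuple(2 * np.array(a)))

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            mean_ci([1.0])


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        cld = compact_letter_display(
            ["a", "b", "c"], set(), {"a": 3.0, "b": 2.0, "c": 1.0}
        )
        assert set(cld.values()) == {"a"}

    def test_all_different_distinct_letters(self):
        groups = ["x", "y", "z"]
        sig = {frozenset(p) for p in itertools.combinations(groups, 2)}
        cld = compact_letter_display(groups, sig, {"x": 3.0, "y": 2.0, "z": 1.0})
        assert cld == {"x": "a", "y": "b", "z": "c"}

    def test_top_mean_gets_first_letter(self):
        sig = {frozenset(("lo", "hi"))}
        cld = compact_letter_display(["lo", "mid", "hi"], sig, {"lo": 1, "mid": 5, "hi": 9})
        assert "a" in cld["hi"] and "a" not in cld["lo"]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_consistent_with_decision_matrix(self, data):
        # groups share a letter iff allowed: never when significantly
        # different, always at least one letter each
        groups = [f"g{i}" for i in range(data.draw(st.integers(2, 6)))]
        pairs = list(itertools.combinations(groups, 2))
        sig = {
            frozenset(p)
            for p in pairs
            if data.draw(st.booleans(), label=str(p))
        }
        means = {g: float(i) for i, g in enumerate(groups)}
        cld = compact_letter_display(groups, sig, means)
        assert all(cld[g] for g in groups)
        for x, y in pairs:
            shared = set(cld[x]) & set(cld[y])
            if frozenset((x, y)) in sig:
                assert not shared
            else:
                assert shared


def _units_from_normal(rng, means, n_per_cell=6):
    rows = []
    for trt, mu in means.items():
        for period in ("morning", "afternoon"):
            for i in range(n_per_cell):
                rows.append(
                    (
                        f"{trt}_{period}_{i}",
                        trt,
                        f"2021-05-{i+1:02d}",
                        period,
                        "comfort",
                        rng.normal(mu, 1.0),
                        rng.normal(mu, 1.0),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["recording_id", "treatment", "date", "period", "comfort",
                 "cluster_index", "unrest_index_cm"],
    )


class TestAnovaTukey:
    def test_identical_groups_share_a_letter(self, rng):
        units = _units_from_normal(rng, {"blue": 0.0, "green": 0.0, "red": 0.0})
        tab = anova_tukey(units, "unrest", "period")
        for lev in tab.letters_lower.index:
            letters = [set(tab.letters_lower.loc[lev, t]) for t in tab.letters_lower.columns]
            assert set.intersection(*letters)

    def test_five_sigma_shift_separates(self, rng):
        units = _units_from_normal(rng, {"blue": 0.0, "green": 0.0, "red": 5.0})
        tab = anova_tukey(units, "unrest", "period")
        assert tab.treatment_pvalue < 0.001
        for lev in tab.letters_lower.index:
            red = set(tab.letters_lower.loc[lev, "red"])
            others = set(tab.letters_lower.loc[lev, "blue"]) | set(
                tab.letters_lower.loc[lev, "green"]
            )
            assert not red & others

    def test_season_recovers_ground_truth_orderings(self, small_season):
        units = small_season["units"]
        unrest = anova_tukey(units, "unrest", "period")
        # motility ordered blue > green > red: all letters distinct
        for lev in unrest.letters_lower.index:
            row = unrest.letters_lower.loc[lev]
            assert len({row["blue"], row["green"], row["red"]}) == 3
            assert unrest.cell_means.loc[lev, "blue"] > unrest.cell_means.loc[lev, "green"] > unrest.cell_means.loc[lev, "red"]
        cluster = anova_tukey(units, "cluster", "period")
        # attraction only under red: red separated, blue/green share
        for lev in cluster.letters_lower.index:
            row = cluster.letters_lower.loc[lev]
            assert not set(row["red"]) & (set(row["blue"]) | set(row["green"]))
            assert set(row["blue"]) & set(row["green"])
            assert cluster.cell_means.loc[lev, "red"] > cluster.cell_means.loc[lev, "blue"]


class TestReport:
    def test_bundle_files_written(self, small_season, tmp_path):
        out = report(small_season["units"], tmp_path / "rep", seed=11)
        for key in ("unrest_by_period", "cluster_by_comfort"):
            assert (tmp_path / "rep" / "tables" / f"{key}_letters.csv").exists()
        assert (tmp_path / "rep" / "manifest.json").exists()
        assert (tmp_path / "rep" / "figures" / "ci_means.png").exists()
        assert out["manifest"]["n_units"] == len(small_season["units"])

    def test_rerun_is_byte_identical(self, small_season, tmp_path):
        report(small_season["units"], tmp_path / "a", seed=11)
        report(small_season["units"], tmp_path / "b", seed=11)
        for rel in ("tables/unrest_by_period_letters.csv", "manifest.json", "tables/units.csv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_empty_units_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            report(pd.DataFrame(), tmp_path / "rep")
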