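import numpy as np
import pandas as pd
import pytest

from rhizonet.datasets import AbundanceTable, SampleMetadata
from rhizonet.errors import InsufficientDataError, ValidationError
from rhizonet.keystones import (
    FunctionCatalog,
    GroupTestResult,
    KeystoneCriteria,
    anova_tukey,
    classify_functions,
    compact_letters,
    identify_keystones,
    keystone_abundance_by_group,
    tukey_hsd,
)


def metrics_row(degree=7, weighted_degree=6.5, closeness=0.2, clustering=0.1,
                betweenness=0.01):
    return {
        "degree": degree,
        "weighted_degree": weighted_degree,
        "closeness": closeness,
        "clustering": clustering,
        "betweenness": betweenness,
    }


class TestIdentifyKeystones:
    def test_all_criteria_pass(self):
        metrics = pd.DataFrame({"n1": metrics_row()}).T
        assert list(identify_keystones(metrics).index) == ["n1"]

    @pytest.mark.parametrize(
        "override",
        [
            {"degree": 6},  # strict >, boundary fails
            {"weighted_degree": 6.0},
            {"closeness": 0.14},
            {"clustering": 0.09},
            {"betweenness": 0.05},  # strict <, boundary fails
        ],
    )
    def test_boundaries_excluded(self, override):
        metrics = pd.DataFrame({"n1": metrics_row(**override)}).T
        assert identify_keystones(metrics).empty

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(1)
        metrics = pd.DataFrame(
            {
                "degree": rng.integers(0, 15, 100),
                "weighted_degree": rng.uniform(0, 12, 100),
                "closeness": rng.uniform(0, 0.4, 100),
                "betweenness": rng.uniform(0, 0.1, 100),
                "clustering": rng.uniform(0, 0.3, 100),
            },
            index=[f"n{i}" for i in range(100)],
        )
        got = set(identify_keystones(metrics).index)
        expected = set()
        for node, row in metrics.iterrows():
            if (
                row["degree"] > 6
                and row["weighted_degree"] > 6
                and row["closeness"] > 0.14
                and row["clustering"] > 0.09
                and row["betweenness"] < 0.05
            ):
                expected.add(node)
        assert got == expected

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(2)
        metrics = pd.DataFrame(
            {
                "degree": rng.integers(0, 15, 50),
                "weighted_degree": rng.uniform(0, 12, 50),
                "closeness": rng.uniform(0, 0.4, 50),
                "betweenness": rng.uniform(0, 0.1, 50),
                "clustering": rng.uniform(0, 0.3, 50),
            },
            index=[f"n{i}" for i in range(50)],
        )
        strict = set(identify_keystones(metrics, KeystoneCriteria()).index)
        relaxed = set(
            identify_keystones(
                metrics,
                KeystoneCriteria(min_degree=3, max_betweenness=0.08),
            ).index
        )
        assert strict <= relaxed

    def test_missing_metric_names_node(self):
        metrics = pd.DataFrame({"n1": metrics_row()}).T
        metrics.loc["n1", "closeness"] = np.nan
        with pytest.raises(ValidationError, match="n1"):
            identify_keystones(metrics)

    def test_missing_column(self):
        metrics = pd.DataFrame({"n1": metrics_row()}).T.drop(columns="degree")
        with pytest.raises(ValidationError, match="degree"):
            identify_keystones(metrics)


class TestClassifyFunctions:
    def make_presence(self, rows):
        catalog = FunctionCatalog()
        frame = pd.DataFrame(0, index=list(rows), columns=catalog.all_ecs)
        for taxon, ecs in rows.items():
            for ec in ecs:
                frame.loc[taxon, ec] = 1
        return frame

    def test_single_ec(self):
        presence = self.make_presence({"t1": ["3.1.3.1"]})
        assert classify_functions(["t1"], presence) == {"t1": {"P decomposition"}}

    def test_multi_category(self):
        presence = self.make_presence({"t1": ["3.2.1.20", "3.5.1.5"]})
        assert classify_functions(["t1"], presence) == {
            "t1": {"C decomposition", "N decomposition"}
        }

    def test_all_zero_row_empty(self):
        presence = self.make_presence({"t1": []})
        assert classify_functions(["t1"], presence) == {"t1": set()}

    def test_absent_taxon_warns_empty(self, caplog):
        presence = self.make_presence({"t1": ["3.1.3.1"]})
        import logging

        with caplog.at_level(logging.WARNING):
            out = classify_functions(["t1", "ghost"], presence)
        assert out["ghost"] == set()
        assert "absent" in caplog.text

    def test_unknown_ec_rejected(self):
        presence = pd.DataFrame({"9.9.9.9": [1]}, index=["t1"])
        with pytest.raises(ValidationError, match="9.9.9.9"):
            classify_functions(["t1"], presence)

    def test_copy_numbers_binarized(self):
        catalog = FunctionCatalog()
        presence = pd.DataFrame(0, index=["t1"], columns=catalog.all_ecs)
        presence.loc["t1", "3.2.1.21"] = 3  # copy number >= 1 counts
        assert classify_functions(["t1"], presence)["t1"] == {"C decomposition"}

    def test_catalog_has_nine_categories(self):
        assert len(FunctionCatalog().category_enzymes) == 9


class TestKeystoneAbundance:
    def make_data(self):
        counts = pd.DataFrame(
            [[10, 90], [30, 70], [20, 80], [40, 60]],
            index=["s1", "s2", "s3", "s4"],
            columns=["k1", "other"],
        )
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "domestication_group": ["wild", "wild", "modern", "modern"],
                    "fertilization": ["unfertilized"] * 4,
                },
                index=counts.index,
            )
        )
        return AbundanceTable(counts), meta

    def test_hand_computed_mean_se(self):
        table, meta = self.make_data()
        per_sample, summary = keystone_abundance_by_group(table, meta, ["k1"])
        # wild: rel abundances 0.1 and 0.3 -> mean 0.2, se 0.1
        assert summary.loc["wild", "mean"] == pytest.approx(0.2)
        assert summary.loc["wild", "se"] == pytest.approx(0.1)

    def test_no_keystones_zero(self):
        table, meta = self.make_data()
        per_sample, summary = keystone_abundance_by_group(table, meta, [])
        assert (per_sample == 0).all()
        assert (summary["mean"] == 0).all()

    def test_all_taxa_sum_to_one(self):
        table, meta = self.make_data()
        per_sample, _ = keystone_abundance_by_group(table, meta, ["k1", "other"])
        np.testing.assert_allclose(per_sample, 1.0)

    def test_unknown_keystone_rejected(self):
        table, meta = self.make_data()
        with pytest.raises(ValidationError):
            keystone_abundance_by_group(table, meta, ["nope"])

    def test_single_sample_group_errors(self):
        counts = pd.DataFrame(
            [[10, 90], [30, 70], [20, 80]],
            index=["s1", "s2", "s3"],
            columns=["k1", "other"],
        )
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "domestication_group": ["wild", "wild", "modern"],
                    "fertilization": ["unfertilized"] * 3,
                },
                index=counts.index,
            )
        )
        with pytest.raises(InsufficientDataError, match="modern"):
            keystone_abundance_by_group(AbundanceTable(counts), meta, ["k1"])


def balanced_metadata(n_per_cell=4):
    rows = []
    for g in ("wild", "traditional", "modern"):
        for f in ("unfertilized", "fertilized"):
            for i in range(n_per_cell):
                rows.append((f"{g}_{f}_{i}", g, f))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "domestication_group", "fertilization"]
    ).set_index("sample_id")
    return SampleMetadata(frame)


class TestAnovaTukey:
    def test_identical_groups_f_zero_shared_letter(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "domestication_group": ["wild"] * 3 + ["modern"] * 3,
                    "fertilization": ["unfertilized"] * 6,
                },
                index=[f"s{i}" for i in range(6)],
            )
        )
        values = pd.Series([1, 2, 3, 1, 2, 3], index=meta.frame.index, dtype=float)
        res = anova_tukey(values, meta, design="one-way")
        assert res.anova.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.anova.loc["group", "p"] == pytest.approx(1.0)
        assert res.letters["wild"] == res.letters["modern"]

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(0)
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "domestication_group": ["wild"] * 3 + ["modern"] * 3,
                    "fertilization": ["unfertilized"] * 6,
                },
                index=[f"s{i}" for i in range(6)],
            )
        )
        values = pd.Series(
            np.concatenate([rng.normal(0, 1e-4, 3), 10 + rng.normal(0, 1e-4, 3)]),
            index=meta.frame.index,
        )
        res = anova_tukey(values, meta, design="one-way")
        assert res.anova.loc["group", "p"] < 1e-6
        assert res.letters["wild"] != res.letters["modern"]

    def test_two_way_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(42)
        meta = balanced_metadata()
        frame = meta.frame.copy()
        frame["y"] = rng.normal(size=len(frame)) + (
            frame["domestication_group"] == "wild"
        ).astype(float)
        res = anova_tukey(
            pd.Series(frame["y"], index=frame.index), meta, design="two-way"
        )
        model = ols(
            "y ~ C(domestication_group) * C(fertilization)", data=frame
        ).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        assert res.anova.loc["domestication", "F"] == pytest.approx(
            ref.loc["C(domestication_group)", "F"], rel=1e-9
        )
        assert res.anova.loc["fertilization", "F"] == pytest.approx(
            ref.loc["C(fertilization)", "F"], rel=1e-9
        )
        assert res.anova.loc["interaction", "F"] == pytest.approx(
            ref.loc["C(domestication_group):C(fertilization)", "F"], rel=1e-9
        )

    def test_two_way_matches_explicit_ss_oracle(self):
        rng = np.random.default_rng(7)
        meta = balanced_metadata()
        y = pd.Series(rng.normal(size=24), index=meta.frame.index)
        res = anova_tukey(y, meta, design="two-way")
        # independent oracle: explicit sums-of-squares decomposition
        frame = meta.frame.copy()
        frame["y"] = y
        grand = frame["y"].mean()
        ss_a = sum(
            len(sub) * (sub["y"].mean() - grand) ** 2
            for _, sub in frame.groupby("domestication_group")
        )
        ss_b = sum(
            len(sub) * (sub["y"].mean() - grand) ** 2
            for _, sub in frame.groupby("fertilization")
        )
        ss_cells = sum(
            len(sub) * (sub["y"].mean() - grand) ** 2
            for _, sub in frame.groupby(["domestication_group", "fertilization"])
        )
        ss_err = sum(
            ((sub["y"] - sub["y"].mean()) ** 2).sum()
            for _, sub in frame.groupby(["domestication_group", "fertilization"])
        )
        f_a = (ss_a / 2) / (ss_err / 18)
        assert res.anova.loc["domestication", "F"] == pytest.approx(f_a, abs=1e-9)
        assert res.anova.loc["interaction", "ss"] == pytest.approx(
            ss_cells - ss_a - ss_b, abs=1e-9
        )

    def test_tukey_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 1.0, 8) for loc in (0.0, 0.5, 2.0)]
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 8)
        got = tukey_hsd(values, labels)
        ref = stats.tukey_hsd(*groups)
        lookup = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for row in got.itertuples(index=False):
            i, j = lookup[(row.level_1, row.level_2)]
            assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_unbalanced_two_way_falls_back(self, caplog):
        import logging

        meta_frame = balanced_metadata().frame.iloc[:-1]  # drop one sample
        meta = SampleMetadata(meta_frame)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=len(meta_frame)), index=meta_frame.index)
        with caplog.at_level(logging.WARNING):
            res = anova_tukey(y, meta, design="two-way")
        assert "unbalanced" in caplog.text
        assert "group" in res.anova.index  # one-way layout

    def test_letters_consistent_with_pairwise_significance(self):
        rng = np.random.default_rng(13)
        for trial in range(10):
            groups = {
                level: rng.normal(rng.uniform(0, 3), 1.0, 6)
                for level in ("a", "b", "c", "d")
            }
            values = np.concatenate(list(groups.values()))
            labels = np.repeat(list(groups), 6)
            tuk = tukey_hsd(values, labels)
            letters = compact_letters(tuk, sorted(groups))
            for row in tuk.itertuples(index=False):
                share = bool(
                    set(letters[row.level_1]) & set(letters[row.level_2])
                )
                assert share == (row.p_adj >= 0.05)

    def test_too_few_groups(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "domestication_group": ["wild"] * 4,
                    "fertilization": ["unfertilized"] * 4,
                },
                index=[f"s{i}" for i in range(4)],
            )
        )
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=meta.frame.index)
        with pytest.raises(InsufficientDataError):
            anova_tukey(values, meta)
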