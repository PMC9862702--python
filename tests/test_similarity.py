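import numpy as np
import pytest

import premirdist as pm
from premirdist.distance import condensed_index
from premirdist.distfit import DistanceDistribution, FAMILIES
from premirdist.reference import (PUBLISHED_PANEL_SUMMARIES,
                                  reference_quantile_table)


class TestQuantileTable:
    def test_row_count_and_monotonicity(self, study_distances):
        model = DistanceDistribution(study_distances.values)
        for family in FAMILIES:
            fit = model.fit(family)
            table = pm.quantile_table(fit, np.arange(5, 101, 5))
            assert len(table) == 20
            assert np.all(np.diff(table.values) >= 0)

    def test_q100_is_observed_maximum(self, study_distances):
        model = DistanceDistribution(study_distances.values)
        fit = model.fit("ecdf")
        table = pm.quantile_table(fit, [50.0, 100.0])
        assert table.value_at(100.0) == fit.data_max

    def test_ecdf_maximum_convention(self):
        fit = pm.fit_ecdf([1.0, 2.0, 3.0, 4.0])
        table = pm.quantile_table(fit, [100.0])
        assert table.value_at(100.0) == 4.0

    def test_invalid_q_rejected(self):
        fit = pm.fit_ecdf([1.0, 2.0])
        with pytest.raises(ValueError):
            pm.quantile_table(fit, [0.0, 50.0])

    def test_tsv_roundtrip(self, tmp_path):
        fit = pm.fit_ecdf([1.0, 2.0, 3.0])
        table = pm.quantile_table(fit, np.arange(10, 101, 10))
        path = tmp_path / "q.tsv"
        table.to_tsv(path)
        back = pm.QuantileTable.from_tsv(path)
        np.testing.assert_array_equal(back.qs, table.qs)
        np.testing.assert_array_equal(back.values, table.values)


class TestPercentileOf:
    def test_worked_example_nearest_table(self):
        """A distance of 0.81 sits nearest the published 15th percentile."""
        table = reference_quantile_table()
        assert pm.percentile_of(None, 0.81, mode="nearest-table",
                                table=table) == 15.0

    def test_nearest_table_ties_take_smaller_q(self):
        table = pm.QuantileTable(np.array([10.0, 20.0]),
                                 np.array([1.0, 3.0]))
        assert table.nearest_q(2.0) == 10.0

    def test_continuous_lower_tail(self, study_distances):
        model = DistanceDistribution(study_distances.values)
        fit = model.fit("kde")
        d = fit.quantile(0.0005)
        assert pm.percentile_of(fit, d) < 0.1

    def test_continuous_round_trip(self, study_distances):
        model = DistanceDistribution(study_distances.values)
        for family in ("normal", "ecdf", "kde"):
            fit = model.fit(family)
            for q in range(5, 100, 5):
                d = fit.quantile(q / 100)
                assert pm.percentile_of(fit, d) == pytest.approx(q, abs=0.5)

    def test_nearest_table_requires_table(self):
        with pytest.raises(ValueError):
            pm.percentile_of(None, 0.5, mode="nearest-table")


class TestIsSimilar:
    @pytest.mark.parametrize(
        "percentile,threshold,expected",
        [(15, 16, True), (15, 15, False), (27, 30, True)],
    )
    def test_strict_threshold(self, percentile, threshold, expected):
        assert pm.is_similar(percentile, threshold) is expected


class TestReferenceTable:
    def test_published_panel_means_rank_near_published_percentiles(self):
        """Interpolating the published percentile table at each published
        panel mean reproduces the published percentile ranks."""
        table = reference_quantile_table()
        for summary in PUBLISHED_PANEL_SUMMARIES.values():
            interp = table.interp_percentile(summary["mean"])
            assert interp == pytest.approx(summary["percentile"], abs=2.0)


@pytest.fixture(scope="module")
def study_setup(study_distances):
    catalog = pm.study_catalog()
    model = DistanceDistribution(study_distances.values).fit("kde")
    return catalog, model


class TestAnalyzePanel:
    def test_identical_pair_panel(self, study_setup):
        _, model = study_setup
        seq = "ACGUGGCUAGCUAGGCUAUCGA"
        catalog = pm.Catalog([
            pm.HairpinRecord("hsa-mir-1", "x", seq),
            pm.HairpinRecord("hsa-mir-2", "x", seq),
        ])
        report = pm.analyze_panel(["miR-1", "miR-2"], catalog, model,
                                  threshold_p=5.0)
        assert report.mean == 0.0
        assert report.percentile_of_mean < 1.0
        assert report.similar is True

    def test_pair_count_and_mean_against_independent_sum(self, study_setup):
        catalog, model = study_setup
        names = [r.identifier for r in catalog.records[:10]]
        report = pm.analyze_panel(names, catalog, model,
                                  species_prefix="syn-mir-")
        assert report.pair_count == 45
        records = [catalog[i] for i in report.resolved]
        total, count = 0.0, 0
        for i in range(10):
            for j in range(i + 1, 10):
                d = pm.jukes_cantor(
                    pm.align_pair(records[i], records[j]).p_hat)
                if np.isfinite(d):
                    total += d
                    count += 1
        assert report.mean == pytest.approx(total / count, abs=1e-12)

    def test_panel_of_one_rejected(self, study_setup):
        catalog, model = study_setup
        with pytest.raises(ValueError):
            pm.analyze_panel([catalog.ids[0]], catalog, model)

    def test_saturated_pairs_excluded_or_capped(self, study_setup):
        _, model = study_setup
        catalog = pm.Catalog([
            pm.HairpinRecord("hsa-mir-1", "x", "A" * 80),
            pm.HairpinRecord("hsa-mir-2", "x", "C" * 80),
            pm.HairpinRecord("hsa-mir-3", "x", "A" * 79 + "C"),
        ])
        names = ["miR-1", "miR-2", "miR-3"]
        report = pm.analyze_panel(names, catalog, model)
        assert report.n_saturated >= 1
        assert np.isfinite(report.mean)
        capped = pm.analyze_panel(names, catalog, model, saturated="cap",
                                  cap=10.0)
        assert capped.mean > report.mean

    def test_random_panel_means_are_distribution_consistent(
        self, study_distances
    ):
        """Random panel means scatter around the catalog-wide mean."""
        rng = np.random.default_rng(21)
        finite_overall = study_distances.finite_values()
        overall_mean = finite_overall.mean()
        n = study_distances.n
        means = []
        for _ in range(200):
            members = rng.choice(n, size=10, replace=False)
            vals = [study_distances.values[condensed_index(min(i, j),
                                                           max(i, j), n)]
                    for k, i in enumerate(members)
                    for j in members[k + 1:]]
            vals = np.array(vals)
            means.append(vals[np.isfinite(vals)].mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - overall_mean) < 3 * se + 0.02

    def test_report_json_roundtrip(self, study_setup, tmp_path):
        catalog, model = study_setup
        names = [r.identifier for r in catalog.records[:4]]
        report = pm.analyze_panel(names, catalog, model,
                                  species_prefix="syn-mir-",
                                  threshold_p=50.0)
        path = tmp_path / "report.json"
        report.to_json(path)
        import json
        payload = json.loads(path.read_text())
        assert payload["pair_count"] == 6
        assert payload["mean"] == report.mean
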