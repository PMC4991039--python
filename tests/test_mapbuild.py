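"""Map assembly, summary statistics, correlations and collinearity."""

import numpy as np
import pandas as pd
import pytest

from ptxmap import grouping, linkage, mapbuild, ordering, reference_tables
from ptxmap.grouping import LinkageGroup
from ptxmap.mapbuild import (
    OrderedMap,
    anchored_fraction,
    build_map,
    collinearity_points,
    group_stat_correlations,
    map_summary,
    mean_adjacent_interval,
    per_mb_length_difference,
)
from ptxmap.ordering import MarkerOrder


def simple_map(r_adjacent, ids=None):
    m = len(r_adjacent) + 1
    ids = ids or [f"m{i}" for i in range(m)]
    rf = np.zeros((m, m))
    for i, r in enumerate(r_adjacent):
        rf[i, i + 1] = rf[i + 1, i] = r
    groups = [LinkageGroup(tuple(ids), 6.0, "LG1")]
    orders = {"LG1": MarkerOrder(tuple(range(m)), float(sum(r_adjacent)))}
    coupling = np.ones((m, m), dtype=bool)
    return build_map(groups, orders, rf, ids, coupling=coupling)


class TestBuildMap:
    def test_kosambi_intervals_and_cumulative_positions(self):
        omap = simple_map([0.1, 0.2])
        intervals = omap.table["interval_cm"].dropna().to_numpy()
        assert intervals == pytest.approx([10.14, 21.18], abs=5e-3)
        assert omap.group_length("LG1") == pytest.approx(31.32, abs=1e-2)
        assert np.all(np.diff(omap.table["cum_cm"]) >= 0)

    def test_single_interval_zero_length(self):
        omap = simple_map([0.0])
        assert omap.group_length("LG1") == 0.0

    def test_phases_copied_from_pairwise(self):
        omap = simple_map([0.1, 0.2])
        assert list(omap.table["phase_next"][:-1]) == ["coupling", "coupling"]

    def test_broken_chain_rejected(self):
        with pytest.raises(ValueError):
            simple_map([0.1, 0.5])


class TestMapSummary:
    def test_mean_interval_identity(self):
        omap = simple_map([0.1, 0.2, 0.05])
        summary = map_summary(omap)
        total = summary.iloc[-1]
        want = total["length_cm"] / (total["n_markers"] - 1)
        assert total["mean_interval_cm"] == pytest.approx(want, abs=5e-3)

    def test_published_totals_reproduce_mean_intervals(self):
        """The published 19-group totals give the printed mean adjacent
        intervals: 2.04 cM (maternal) and 3.09 cM (paternal)."""
        totals = reference_tables.populus_totals()
        assert mean_adjacent_interval(
            totals["maternal_len_cm"], totals["maternal_snps"], 19
        ) == 2.04
        assert mean_adjacent_interval(
            totals["paternal_len_cm"], totals["paternal_snps"], 19
        ) == 3.09

    def test_two_marker_group(self):
        omap = simple_map([linkage.kosambi_inverse(10.0)])
        summary = map_summary(omap)
        assert summary.iloc[-1]["mean_interval_cm"] == pytest.approx(10.0, abs=1e-2)


class TestPerMbDifference:
    @pytest.mark.parametrize(
        "a,b,size,want",
        [
            (106.87, 159.97, 15.94, 3.33),  # group with suppressed maternal recombination
            (135.89, 197.88, 16.08, 3.86),
            (100.0, 100.0, 10.0, 0.0),
        ],
    )
    def test_values(self, a, b, size, want):
        assert per_mb_length_difference(a, b, size) == want

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            per_mb_length_difference(1, 2, 0)


class TestCorrelations:
    def test_published_group_statistics(self):
        table = reference_tables.populus_group_table()
        corr = group_stat_correlations(table)
        assert corr.loc["maternal_snps", "maternal_len_cm"] == 0.9731
        assert corr.loc["paternal_snps", "paternal_len_cm"] == 0.9406
        assert corr.loc["paternal_len_cm", "chrom_size_mb"] == 0.9231
        assert corr.loc["maternal_len_cm", "chrom_size_mb"] == 0.9202

    def test_proportional_vectors(self):
        table = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        corr = group_stat_correlations(table)
        assert corr.loc["x", "y"] == 1.0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            group_stat_correlations(pd.DataFrame({"x": [1.0, 2]}))

    def test_bounded(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(19, 4)), columns=list("abcd"))
        corr = group_stat_correlations(table).to_numpy()
        assert np.all(corr <= 1.0) and np.all(corr >= -1.0)


class TestCollinearity:
    def test_published_anchored_fraction(self):
        n, total = reference_tables.POPULUS_ANCHORED["maternal"]
        assert anchored_fraction(n, total) == 82.2
        n, total = reference_tables.POPULUS_ANCHORED["paternal"]
        assert anchored_fraction(n, total) == 80.9

    def test_empty_anchor_table(self):
        omap = simple_map([0.1])
        points, per_group = collinearity_points(omap, pd.DataFrame())
        assert points.empty and per_group.empty

    def test_clean_simulation_perfectly_collinear(self, clean_dataset):
        """With true physical positions as anchors, genetic and physical
        order agree exactly: per-group Spearman rho = +/-1."""
        ds = clean_dataset
        mat = ds.observed.by_seg_type("abxaa")
        rf, lod, _, coupling = linkage.pairwise_matrix(mat)
        ids = list(mat.marker_ids)
        _, groups = grouping.auto_threshold(lod, 3, marker_ids=ids)
        idx_of = {m: i for i, m in enumerate(ids)}
        orders = {}
        for grp in groups:
            gi = np.array([idx_of[m] for m in grp.members])
            orders[grp.label] = ordering.order_group(rf[np.ix_(gi, gi)], seed=0)
        omap = build_map(groups, orders, rf, ids, coupling=coupling)
        anchors = pd.DataFrame(
            {
                "chrom": mat.markers["chrom"],
                "bp": mat.markers["chrom_pos"],
            }
        )
        points, per_group = collinearity_points(omap, anchors)
        assert (per_group["anchored_pct"] == 100.0).all()
        assert np.allclose(np.abs(per_group["spearman"]), 1.0)

    def test_all_coupling_phases_on_clean_simulation(self, clean_dataset):
        """The simulator places the informative allele on one homolog, so
        every adjacent phase prediction on clean data is coupling."""
        ds = clean_dataset
        mat = ds.observed.by_seg_type("abxaa")
        rf, lod, _, coupling = linkage.pairwise_matrix(mat)
        ids = list(mat.marker_ids)
        _, groups = grouping.auto_threshold(lod, 3, marker_ids=ids)
        orders = {
            g.label: ordering.order_group(
                rf[np.ix_([ids.index(m) for m in g.members],
                          [ids.index(m) for m in g.members])], seed=0
            )
            for g in groups
        }
        omap = build_map(groups, orders, rf, ids, coupling=coupling)
        phases = omap.table["phase_next"]
        assert set(phases[phases != ""]) == {"coupling"}


class TestPipeline:
    def test_rerun_with_same_seed_identical(self, tmp_path):
        import filecmp

        results = []
        for sub in ("r1", "r2"):
            cfg = mapbuild.PipelineConfig(
                outdir=str(tmp_path / sub), simulate=True, seed=11,
                sim_chromosomes=2, sim_markers_per_parent=5,
            )
            results.append(mapbuild.run_pipeline(cfg))
        for name, path in results[0].artifacts.items():
            other = results[1].artifacts[name]
            assert filecmp.cmp(path, other, shallow=False), name

    def test_missing_inputs_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            mapbuild.run_pipeline(
                mapbuild.PipelineConfig(outdir=str(tmp_path))
            )

    def test_small_noisy_run_completes(self, tmp_path):
        cfg = mapbuild.PipelineConfig(
            outdir=str(tmp_path / "noisy"), simulate=True, seed=13,
            sim_chromosomes=2, sim_markers_per_parent=8,
            sim_missing_rate=0.05, sim_error_rate=0.01,
            expected_groups=2,
        )
        result = mapbuild.run_pipeline(cfg)
        for parent in ("maternal", "paternal"):
            summary = result.summaries[parent]
            total = summary.iloc[-1]
            # mean-interval identity holds for every built map
            n_groups = len(summary) - 1
            want = total["length_cm"] / (total["n_markers"] - n_groups)
            assert total["mean_interval_cm"] == pytest.approx(want, abs=5e-3)
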