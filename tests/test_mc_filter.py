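"""Roulette normalization, interval mapping, sampling and path selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kgmatch as km
from kgmatch.errors import DegenerateWeightsError


@pytest.fixture
def example_paths():
    pathlist, cfg = km.worked_example_paths()
    return pathlist, cfg


def counts_for(pathlist, dc_counts, cv_counts):
    keys = [p.key for p in pathlist.paths]
    return (
        km.SampleCounts(dict(zip(keys, dc_counts))),
        km.SampleCounts(dict(zip(keys, cv_counts))),
    )


class TestNormalize:
    def test_cycle_value_proportions(self):
        assert km.normalize_proportions([0.7, 0.6, 0.48], 2) == [0.39, 0.34, 0.27]

    def test_cost_benefit_proportions(self):
        # 0.54/1.64 rounds to 0.33, not the 0.30 sometimes quoted alongside
        # an interval of width 0.33; the arithmetic is authoritative here.
        assert km.normalize_proportions([0.5, 0.6, 0.54], 2) == [0.30, 0.37, 0.33]

    def test_singleton_and_full_precision(self):
        assert km.normalize_proportions([0.42], 2) == [1.0]
        props = km.normalize_proportions([1, 3], None)
        assert props == [0.25, 0.75]

    def test_degenerate_and_negative_weights(self):
        with pytest.raises(DegenerateWeightsError):
            km.normalize_proportions([0.0, 0.0])
        with pytest.raises(ValueError):
            km.normalize_proportions([0.5, -0.1])


class TestIntervals:
    def test_cumulative_bounds_match_proportions(self):
        part = km.build_intervals([0.39, 0.34, 0.27], keys=["e1", "e2", "e3"])
        (k1, lo1, hi1), (k2, lo2, hi2), (k3, lo3, hi3) = part.items
        assert (k1, lo1) == ("e1", 0.0) and hi1 == pytest.approx(0.39)
        assert (lo2, hi2) == (pytest.approx(0.39), pytest.approx(0.73))
        assert (lo3, hi3) == (pytest.approx(0.73), 1.0)

    def test_cost_benefit_bounds(self):
        part = km.build_intervals([0.30, 0.37, 0.33])
        assert part.items[1][2] == pytest.approx(0.67)
        assert part.items[2][1:] == (pytest.approx(0.67), 1.0)

    def test_single_proportion_spans_unit_interval(self):
        part = km.build_intervals([1.0], keys=["only"])
        assert part.items == (("only", 0.0, 1.0),)

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            km.build_intervals([0.5, -0.5, 1.0])

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
    def test_partition_is_contiguous_and_covers_unit_interval(self, values):
        props = km.normalize_proportions(values, None)
        part = km.build_intervals(props)
        assert part.items[0][1] == 0.0
        assert part.items[-1][2] == 1.0
        for (_, _, hi_prev), (_, lo, _) in zip(part.items, part.items[1:]):
            assert hi_prev == lo
        # binning any value hits exactly one interval
        for x in (0.0, 0.25, 0.5, 0.75, 0.999999):
            assert part.bin(x) in part.keys


class TestSampling:
    @given(st.lists(st.floats(0.05, 1.0), min_size=1, max_size=6), st.integers(0, 2**20))
    def test_counts_are_conserved(self, values, seed):
        part = km.build_intervals(km.normalize_proportions(values, None))
        cfg = km.MCConfig(n_draws=137, seed=0)
        counts = km.mc_sample_counts(part, cfg, np.random.default_rng(seed))
        assert counts.total == 137

    def test_single_interval_absorbs_all_draws(self):
        part = km.build_intervals([1.0], keys=["only"])
        cfg = km.MCConfig(n_draws=50)
        counts = km.mc_sample_counts(part, cfg, np.random.default_rng(0))
        assert counts.counts == {"only": 50}

    def test_hit_frequencies_track_interval_widths(self):
        part = km.build_intervals([0.39, 0.34, 0.27], keys=["e1", "e2", "e3"])
        cfg = km.MCConfig(n_draws=20_000)
        counts = km.mc_sample_counts(part, cfg, np.random.default_rng(5))
        for key, width in zip(["e1", "e2", "e3"], [0.39, 0.34, 0.27]):
            assert counts.counts[key] / 20_000 == pytest.approx(width, abs=0.02)


class TestSelection:
    def test_reported_counts_select_first_two_paths(self, example_paths):
        pathlist, _ = example_paths
        counts_dc, counts_cv = counts_for(pathlist, (431, 330, 239), (378, 511, 111))
        selected = km.select_candidate_paths(pathlist, counts_dc, counts_cv, top_n=2)
        assert [p.node_sequence for p in selected] == [
            ("SLCLIA", "Drug"),
            ("SLCLIA", "Operation"),
        ]

    def test_top_n_at_least_pool_returns_everything(self, example_paths):
        pathlist, _ = example_paths
        counts_dc, counts_cv = counts_for(pathlist, (0, 0, 0), (0, 0, 0))
        assert km.select_candidate_paths(pathlist, counts_dc, counts_cv, 3) == pathlist.paths

    def test_empty_crossing_falls_back_to_rank_sum(self, example_paths):
        pathlist, _ = example_paths
        e1, e2, e3 = pathlist.paths
        # top-1 by dc = {e1}, top-1 by cv = {e2}: crossing empty
        counts_dc, counts_cv = counts_for(pathlist, (10, 5, 1), (3, 9, 1))
        selected = km.select_candidate_paths(pathlist, counts_dc, counts_cv, 1)
        # oracle: enumerate both rankings and sum positions
        rank_dc = {e1.key: 0, e2.key: 1, e3.key: 2}
        rank_cv = {e2.key: 0, e1.key: 1, e3.key: 2}
        sums = {k: rank_dc[k] + rank_cv[k] for k in rank_dc}
        assert sums[e1.key] == sums[e2.key] == 1  # tie on rank sum
        # tie broken by the larger a_dc * a_cv: e2 (0.36) beats e1 (0.35)
        assert [p.node_sequence for p in selected] == [("SLCLIA", "Operation")]


class TestMembership:
    def test_thresholds_filter_aggregates(self, example_paths):
        pathlist, _ = example_paths
        spec = km.MembershipSpec(0.2)
        pe = km.PatternEdge(
            source="TC", target="TM", dt_membership=spec, dc_membership=spec, cv_membership=spec
        )
        assert km.apply_membership_constraints(pathlist.paths, pe) == pathlist.paths
        tight = km.MembershipSpec(0.5)
        pe_tight = km.PatternEdge(
            source="TC", target="TM", dt_membership=spec, dc_membership=tight, cv_membership=spec
        )
        kept = km.apply_membership_constraints(pathlist.paths, pe_tight)
        assert [p.node_sequence for p in kept] == [
            ("SLCLIA", "Drug"),
            ("SLCLIA", "Operation"),
        ]  # a_dc 0.48 < 0.5 drops the two-hop path

    def test_zero_thresholds_keep_everything(self, example_paths):
        pathlist, _ = example_paths
        pe = km.PatternEdge(source="TC", target="TM")
        assert km.apply_membership_constraints(pathlist.paths, pe) == pathlist.paths


class TestEdgeAttributeFilter:
    def edge(self, threshold=0.2):
        spec = km.MembershipSpec(threshold)
        return km.PatternEdge(
            source="TC", target="TM", dt_membership=spec, dc_membership=spec, cv_membership=spec
        )

    def test_worked_example_keeps_at_most_top_n(self, example_paths):
        pathlist, cfg = example_paths
        out = km.edge_attribute_filter([pathlist], self.edge(), cfg, np.random.default_rng(cfg.seed))
        survivors = [p for pl in out for p in pl.paths]
        assert 1 <= len(survivors) <= 2
        assert set(survivors) <= set(pathlist.paths)

    def test_vacuous_top_n_equals_membership_filtering(self, example_paths):
        pathlist, _ = example_paths
        cfg = km.MCConfig(n_draws=1000, top_n=3)
        out = km.edge_attribute_filter(
            [pathlist], self.edge(0.0), cfg, np.random.default_rng(0)
        )
        assert [p for pl in out for p in pl.paths] == pathlist.paths

    def test_single_path_group_passes_untouched(self):
        pe = self.edge()
        path = km.PathMatch(pe.key, ("SLCLIA", "Drug"), 0.5, 0.7, 0.5)
        pl = km.PathList(("SLCLIA", "Drug"), pe.key, [path])
        out = km.edge_attribute_filter([pl], pe, km.MCConfig(), np.random.default_rng(0))
        assert [p for group in out for p in group.paths] == [path]

    def test_failing_group_is_dropped(self):
        pe = self.edge(0.9)
        path = km.PathMatch(pe.key, ("SLCLIA", "Drug"), 0.5, 0.7, 0.5)
        pl = km.PathList(("SLCLIA", "Drug"), pe.key, [path])
        assert km.edge_attribute_filter([pl], pe, km.MCConfig(), np.random.default_rng(0)) == []

    def test_seed_determinism(self, example_paths):
        pathlist, cfg = example_paths
        runs = [
            [
                p.node_sequence
                for pl in km.edge_attribute_filter(
                    [pathlist], self.edge(), cfg, np.random.default_rng(99)
                )
                for p in pl.paths
            ]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]
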