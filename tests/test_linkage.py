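"""Breakpoint counting, Haldane mapping, interval stats, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ril_atlas import linkage
from ril_atlas.genotypes import CALL_MISSING
from ril_atlas.linkage import (IntervalStats, LinkageMap, MapError,
                               breakpoint_summary, build_map,
                               count_breakpoints, estimate_rf, haldane,
                               interval_stats, inverse_haldane, map_from_positions,
                               normalize_map)

from conftest import make_marker_table, make_matrix


@pytest.mark.parametrize("calls, expected", [
    (["A", "A", "B", "B", "A"], 2),
    (["A", "?", "B", "B"], 1),
    (["A", "H", "B"], 2),  # heterozygous call contributes a breakpoint per flank
    (["?", "?", "?"], 0),
    (["A", "A", "A"], 0),
    (["A", "?", "A", "B", "?", "B", "A"], 2),
])
def test_count_breakpoints(calls, expected):
    assert count_breakpoints(calls) == expected


class TestEstimateRF:
    def test_identical_vectors_r_zero(self):
        est = estimate_rf(["A"] * 10, ["A"] * 10)
        assert est.r == 0.0 and not est.unlinked

    def test_discordant_fraction(self):
        a = ["A"] * 10
        b = ["B", "B"] + ["A"] * 8
        est = estimate_rf(a, b)
        assert est.r == pytest.approx(0.2)
        assert est.n_informative == 10 and est.n_discordant == 2

    def test_fully_discordant_flags_unlinked(self):
        est = estimate_rf(["A"] * 6, ["B"] * 6)
        assert est.unlinked and est.r == 1.0

    def test_het_and_missing_not_informative(self):
        est = estimate_rf(["A", "H", "A", "?"], ["A", "A", "B", "B"])
        assert est.n_informative == 2 and est.r == pytest.approx(0.5)

    def test_no_informative_lines_errors(self):
        with pytest.raises(MapError):
            estimate_rf(["H", "?"], ["A", "A"])


class TestHaldane:
    def test_zero(self):
        assert haldane(0.0) == 0.0

    def test_closed_form(self):
        assert haldane(0.2) == pytest.approx(-50.0 * np.log(0.6), abs=1e-9)
        assert haldane(0.2) == pytest.approx(25.541, abs=1e-3)

    @pytest.mark.parametrize("r", [0.5, 0.7, -0.1])
    def test_domain_error(self, r):
        with pytest.raises(ValueError):
            haldane(r)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.499))
    def test_inverse_on_domain(self, r):
        assert inverse_haldane(haldane(r)) == pytest.approx(r, abs=1e-12)
        assert haldane(r) >= -0.0  # non-negative on its domain


class TestBuildMap:
    def _matrix_with_rf(self):
        # 10 lines; m1/m2 discordant in 1 line (r=0.1); m2/m3 identical (r=0)
        m1 = ["A"] * 5 + ["B"] * 5
        m2 = ["B"] + ["A"] * 4 + ["B"] * 5
        m3 = list(m2)
        rows = {f"l{i}": [m1[i], m2[i], m3[i]] for i in range(10)}
        m = make_matrix(rows, markers=["m1", "m2", "m3"])
        k = make_marker_table(["m1", "m2", "m3"])
        return m, k

    def test_perfectly_correlated_markers_at_zero(self):
        rows = {f"l{i}": [c, c] for i, c in enumerate(["A"] * 4 + ["B"] * 4)}
        m = make_matrix(rows, markers=["m1", "m2"])
        k = make_marker_table(["m1", "m2"])
        lmap = build_map(m, k)
        assert list(lmap.positions["genetic_cM"]) == [0.0, 0.0]

    def test_cumulative_haldane_positions(self):
        m, k = self._matrix_with_rf()
        lmap = build_map(m, k)
        d = -50.0 * np.log(1 - 0.2)  # haldane(0.1)
        assert lmap.positions["genetic_cM"].tolist() == pytest.approx(
            [0.0, d, d], abs=1e-9)
        assert d == pytest.approx(11.157, abs=1e-3)

    def test_unlinked_adjacent_pair_raises(self):
        rows = {f"l{i}": [a, b] for i, (a, b) in
                enumerate(zip(["A"] * 6, ["B"] * 6))}
        m = make_matrix(rows, markers=["m1", "m2"])
        k = make_marker_table(["m1", "m2"])
        with pytest.raises(MapError, match="unlinked"):
            build_map(m, k)


class TestBreakpointSummary:
    def test_single_line_single_chromosome(self):
        m = make_matrix({"l1": ["A", "A", "B"]})
        k = make_marker_table(m.markers)
        bsum = breakpoint_summary(m, k)
        assert bsum.genome_total == 1
        assert bsum.per_chromosome["mean_per_line"].iloc[0] == 1.0

    def test_genome_total_is_sum_over_lines(self, medium_sim):
        m, k = medium_sim.matrix, medium_sim.marker_table
        bsum = breakpoint_summary(m, k)
        manual = 0
        for _, grp in k.groupby("chromosome", sort=False):
            sub = m.calls[list(grp["marker"])]
            manual += sum(count_breakpoints(row) for row in
                          sub.to_numpy(dtype=object))
        assert bsum.genome_total == manual

    def test_totals_match_simulator_truth_at_marker_resolution(self, medium_sim):
        """Observed breakpoints equal truth junctions collapsed to marker pairs."""
        m, k = medium_sim.matrix, medium_sim.marker_table
        values = m.calls.to_numpy(dtype=object)
        has_het = (values == "H").any(axis=1)
        lines = [l for l, h in zip(m.line_ids, has_het) if not h]
        for line in lines[:40]:
            observed = 0
            expected = 0
            for chrom, grp in k.groupby("chromosome", sort=False):
                calls = m.calls.loc[line, list(grp["marker"])]
                observed += count_breakpoints(calls)
                bp = grp["physical_bp"].to_numpy(dtype=float)
                truth = np.asarray(medium_sim.breakpoints[line][chrom])
                # junctions between adjacent markers, collapsed by parity
                for lo, hi in zip(bp[:-1], bp[1:]):
                    n_junctions = int(((truth > lo) & (truth <= hi)).sum())
                    expected += n_junctions % 2
            assert observed == expected


class TestIntervalStats:
    def test_stated_definition(self):
        k = make_marker_table(["a", "b", "c"], genetic=[0.0, 0.0, 5.0])
        lmap = map_from_positions(k)
        stats = interval_stats(lmap)
        assert stats.n_intervals == 1
        assert stats.mean_bp == pytest.approx(1_000_000)
        assert stats.mean_cm == pytest.approx(5.0)

    def test_no_intervals_on_flat_map(self):
        k = make_marker_table(["a", "b"], genetic=[0.0, 0.0])
        stats = interval_stats(map_from_positions(k))
        assert stats.n_intervals == 0


class TestNormalizeMap:
    def test_scale_to_target(self):
        k = make_marker_table(["a", "b", "c"], genetic=[0.0, 100.0, 171.7])
        lmap = map_from_positions(k)
        norm = normalize_map(lmap, target=50.0)
        assert norm.cumulative_lengths.iloc[0] == pytest.approx(50.0)

    def test_domain_sum_normalization(self):
        # major domains of 30/10/60 cM -> factor 0.5
        k = make_marker_table(["a", "b", "c", "d"],
                              genetic=[0.0, 30.0, 40.0, 100.0])
        lmap = map_from_positions(k)
        norm = normalize_map(lmap, target=50.0,
                             domain_lengths=pd.Series({"I": 100.0}))
        assert norm.positions["genetic_cM"].tolist() == pytest.approx(
            [0.0, 15.0, 20.0, 50.0])

    def test_idempotent(self):
        k = make_marker_table(["a", "b", "c"], genetic=[0.0, 20.0, 80.0])
        lmap = map_from_positions(k)
        once = normalize_map(lmap)
        twice = normalize_map(once)
        pd.testing.assert_frame_equal(once.positions, twice.positions)

    def test_zero_length_chromosome_errors(self):
        k = make_marker_table(["a", "b"], genetic=[0.0, 0.0])
        with pytest.raises(MapError):
            normalize_map(map_from_positions(k))


def test_expected_x_length_design_arithmetic():
    """2/3 of the mean published autosomal cumulative length, to one decimal."""
    from ril_atlas.reference import expected_x_map_length
    assert round(expected_x_map_length(), 1) == 110.5
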