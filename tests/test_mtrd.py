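"""Allele fractions, autocorrelation-corrected tests, cross-direction tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ril_atlas import reference
from ril_atlas.domains import domain_set_from_geometry
from ril_atlas.genotypes import DIRECTION_FWD, DIRECTION_REV
from ril_atlas.mtrd import (EffectiveTests, allele_fraction_track, chisq_gof,
                            cross_direction_test, effective_tests,
                            lag1_autocorrelation, mtrd_scan,
                            threshold_fraction, x_expected_fraction)

from conftest import make_marker_table, make_matrix

CB4_DOMAINS = domain_set_from_geometry(reference.CB4_DOMAIN_GEOMETRY)


class TestAlleleFractions:
    def test_fraction_of_informative_lines(self):
        rows = {f"l{i}": [c] for i, c in
                enumerate(["B"] * 7 + ["A"] * 3 + ["H", "?"])}
        m = make_matrix(rows, markers=["m0"])
        k = make_marker_table(["m0"])
        track = allele_fraction_track(m, k, directions=(DIRECTION_FWD,))
        row = track.table.iloc[0]
        assert row["n"] == 10 and row["fraction"] == pytest.approx(0.7)
        assert row["expected"] == 0.5

    def test_x_expectations_by_direction(self):
        assert x_expected_fraction(DIRECTION_FWD) == pytest.approx(2 / 3)
        assert x_expected_fraction(DIRECTION_REV) == pytest.approx(1 / 3)
        m = make_matrix({"l1": ["A"], "l2": ["B"]},
                        directions={"l1": DIRECTION_FWD, "l2": DIRECTION_FWD})
        k = make_marker_table(["m0"], chromosome="X")
        track = allele_fraction_track(m, k, directions=(DIRECTION_FWD,))
        assert track.table["expected"].iloc[0] == pytest.approx(2 / 3)

    def test_zero_informative_flagged_nan(self):
        m = make_matrix({"l1": ["H"], "l2": ["?"]})
        k = make_marker_table(["m0"])
        track = allele_fraction_track(m, k, directions=(DIRECTION_FWD,))
        assert np.isnan(track.table["fraction"].iloc[0])


class TestLag1Autocorrelation:
    def test_alternating_series_near_minus_one(self):
        n = 100
        rho = lag1_autocorrelation([0, 1] * (n // 2))
        assert rho == pytest.approx(-1.0, abs=2.0 / n)

    def test_constant_series_zero(self):
        assert lag1_autocorrelation([0.5] * 10) == 0.0

    def test_ar1_estimate(self):
        """AR(1) with rho = 0.6, N = 10,000: estimate within 0.03."""
        rng = np.random.default_rng(42)
        n, rho = 10_000, 0.6
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.normal() * np.sqrt(1 - rho ** 2)
        assert lag1_autocorrelation(x) == pytest.approx(rho, abs=0.03)

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            lag1_autocorrelation([0.1, 0.2])


class TestEffectiveTests:
    def _track(self, fractions, chromosome="I", bp0=4.0e6, direction=DIRECTION_FWD):
        rows = []
        for i, f in enumerate(fractions):
            rows.append((f"m{i}", chromosome, bp0 + i * 1e4, direction,
                         100, int(round(f * 100)), f, 0.5, np.nan, np.nan, False))
        from ril_atlas.mtrd import MTRDTrack
        return MTRDTrack(pd.DataFrame(rows, columns=[
            "marker", "chromosome", "physical_bp", "cross_direction", "n",
            "count_b", "fraction", "expected", "chisq", "p", "significant"]))

    def test_iid_like_series_keeps_n(self):
        rng = np.random.default_rng(0)
        track = self._track(rng.uniform(0.3, 0.7, 60))
        eff = effective_tests(track, CB4_DOMAINS)
        row = eff.per_domain.iloc[0]
        # weak empirical rho; N_eff within clamp and near N
        assert 1 <= row["n_eff"] <= row["n_markers"]
        assert row["n_eff"] > 0.5 * row["n_markers"]

    def test_formula_value(self):
        # N = 100, rho = 0.5 -> N (1-rho)/(1+rho) = 33.33
        assert 100 * (1 - 0.5) / (1 + 0.5) == pytest.approx(33.333, abs=1e-2)
        track = self._track([0.5] * 5)
        eff = effective_tests(track, CB4_DOMAINS)
        assert eff.per_domain["n_eff"].iloc[0] == 5  # constant -> rho 0 -> N

    def test_negative_rho_clamped_at_n(self):
        track = self._track([0.2, 0.8] * 10)
        eff = effective_tests(track, CB4_DOMAINS)
        row = eff.per_domain.iloc[0]
        assert row["rho"] < 0 and row["n_eff"] == row["n_markers"]


class TestScan:
    def test_chisq_example(self):
        # n = 100, count 50 against expected 2/3: chi-square 12.5
        chisq, p = chisq_gof(50, 100, 2 / 3)
        assert chisq == pytest.approx(12.5, abs=1e-9)

    def test_at_expectation_not_significant(self):
        chisq, p = chisq_gof(50, 100, 0.5)
        assert chisq == 0.0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("n, count", [(50, 20), (50, 33), (80, 30),
                                          (100, 35), (100, 65), (200, 80),
                                          (400, 150)])
    def test_corrected_chisq_tracks_exact_binomial(self, n, count):
        """Continuity-corrected chi-square p within 0.01 of the exact binomial."""
        _, p_chi = chisq_gof(count, n, 0.5, continuity=True)
        p_exact = sps.binomtest(count, n, 0.5).pvalue
        assert abs(p_chi - p_exact) < 0.01

    @pytest.mark.parametrize("n, count", [(50, 15), (100, 30), (100, 70),
                                          (200, 70), (400, 150)])
    def test_plain_chisq_tracks_binomial_in_significance_regime(self, n, count):
        """The scan's uncorrected statistic agrees where distortion is strong."""
        _, p_chi = chisq_gof(count, n, 0.5)
        p_exact = sps.binomtest(count, n, 0.5).pvalue
        assert abs(p_chi - p_exact) < 0.01

    def test_scan_fills_flags_and_thresholds(self):
        rows = {}
        rng = np.random.default_rng(1)
        for i in range(40):
            # one extreme marker among neutral ones
            frac = 0.95 if i == 20 else 0.5
            rows[f"m{i}"] = frac
        lines = {}
        for j in range(60):
            lines[f"l{j}"] = ["B" if rng.random() < rows[f"m{i}"] else "A"
                              for i in range(40)]
        m = make_matrix(lines, markers=list(rows))
        k = make_marker_table(list(rows), start_bp=4_000_000, step_bp=50_000)
        track = allele_fraction_track(m, k, directions=(DIRECTION_FWD,))
        eff = effective_tests(track, CB4_DOMAINS)
        scanned = mtrd_scan(track, eff)
        t = scanned.table
        assert t.loc[t["marker"] == "m20", "significant"].iloc[0]
        assert t["significant"].sum() <= 3
        thr = t.attrs["thresholds"]
        assert ((thr["threshold_fraction"] > 0.5) |
                thr["threshold_fraction"].isna()).all()


class TestCrossDirectionTest:
    def _eff(self):
        per = pd.DataFrame([
            (DIRECTION_FWD, "V", "center", 10, 0.0, 8.0),
            (DIRECTION_REV, "V", "center", 10, 0.0, 6.0),
        ], columns=["cross_direction", "chromosome", "domain", "n_markers",
                    "rho", "n_eff"])
        return EffectiveTests(per_domain=per, alpha=0.05)

    def _tracks(self, fwd_counts, rev_counts, n=20):
        def tab(direction, counts):
            rows = [(f"m{i}", "V", 8e6 + i * 1e4, direction, n, c, c / n, 0.5,
                     np.nan, np.nan, False) for i, c in enumerate(counts)]
            return pd.DataFrame(rows, columns=[
                "marker", "chromosome", "physical_bp", "cross_direction", "n",
                "count_b", "fraction", "expected", "chisq", "p", "significant"])
        return tab(DIRECTION_FWD, fwd_counts), tab(DIRECTION_REV, rev_counts)

    def test_identical_counts_p_one(self):
        fwd, rev = self._tracks([10], [10])
        out = cross_direction_test(fwd, rev, ["m0"], self._eff())
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_extreme_table_exact_p(self):
        # [[10,0],[0,10]] -> p = 2 / C(20,10)
        fwd, rev = self._tracks([0], [10], n=10)
        out = cross_direction_test(fwd, rev, ["m0"], self._eff())
        from math import comb
        assert out["p"].iloc[0] == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert out.attrs["alpha_corrected"] == pytest.approx(0.05 / 14.0)

    def test_empty_region_errors(self):
        fwd, rev = self._tracks([5], [5])
        with pytest.raises(ValueError):
            cross_direction_test(fwd, rev, [], self._eff())


def test_threshold_fraction_walks_to_significance():
    thr = threshold_fraction(100, 0.5, 1e-3)
    assert 0.5 < thr <= 1.0
    _, p = chisq_gof(int(thr * 100), 100, 0.5)
    assert p <= 1e-3
    _, p_below = chisq_gof(int(thr * 100) - 1, 100, 0.5)
    assert p_below > 1e-3
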