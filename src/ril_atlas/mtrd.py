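"""Marker transmission ratio distortion (MTRD) scans.

In a neutral cross, each parent contributes half the alleles fixed at any
autosomal locus.  On the X the expectation is asymmetric: males are
hemizygous, so under the advanced-intercross design two thirds of X
chromosomes descend from the hermaphrodite P0 and the expected fixed-allele
fraction of the hermaphrodite parent's strain is 2/3 per cross direction.
Departures from these expectations (MTRD) signal selection on hybrid
genotypes.

Significance is genome-wide: linked markers are not independent tests, so
the effective number of tests per recombination domain is estimated from
the lag-1 autocorrelation of the allele-fraction series (first-order
autoregressive correction, N_eff = N (1-rho)/(1+rho), clamped to [1, N])
and the 0.05 threshold is Bonferroni-corrected by the genome-wide sum of
effective tests per cross direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .domains import DomainSet
from .genotypes import (CALL_A, CALL_B, DIRECTION_FWD, DIRECTION_REV,
                        GenotypeMatrix)

X_CHROMOSOME = "X"


@dataclass
class MTRDTrack:
    """Per marker x cross direction allele fractions and test results.

    ``table`` columns: marker, chromosome, physical_bp, cross_direction, n,
    count_b, fraction, expected, chisq, p, significant.  ``fraction`` is the
    share of informative (fixed A or B) lines fixed for the parent-2 (B)
    allele; H and missing calls enter neither numerator nor denominator.
    """

    table: pd.DataFrame

    def direction(self, direction: str) -> pd.DataFrame:
        return self.table[self.table["cross_direction"] == direction].reset_index(drop=True)


@dataclass
class EffectiveTests:
    """Effective-test bookkeeping per recombination domain and direction."""

    per_domain: pd.DataFrame  # cross_direction, chromosome, domain, n_markers, rho, n_eff
    alpha: float = 0.05
    thresholds: pd.DataFrame | None = None  # direction, expected, n, threshold fraction

    @property
    def genome_wide(self) -> pd.Series:
        return self.per_domain.groupby("cross_direction")["n_eff"].sum()

    def corrected_alpha(self, direction: str) -> float:
        total = float(self.genome_wide.get(direction, np.nan))
        return self.alpha / total


def x_expected_fraction(direction: str) -> float:
    """Expected B-allele fraction on the X for one cross direction.

    By convention the first-listed strain of a direction label provides the
    male, so in ``P1xP2`` the hermaphrodite is parent 2 (B): its strain is
    expected at 2/3 on the X.  In ``P2xP1`` the hermaphrodite is parent 1
    and the B expectation drops to 1/3.
    """
    if direction == DIRECTION_FWD:
        return 2.0 / 3.0
    if direction == DIRECTION_REV:
        return 1.0 / 3.0
    raise ValueError(f"no X expectation for cross direction {direction!r}")


def allele_fraction_track(m: GenotypeMatrix, k: pd.DataFrame,
                          directions=(DIRECTION_FWD, DIRECTION_REV)) -> MTRDTrack:
    """Fraction of informative lines fixed for the B allele, per direction."""
    rows = []
    meta = k.set_index("marker")
    for direction in directions:
        lines = m.lines_for_direction(direction)
        if not lines:
            continue
        sub = m.calls.loc[lines]
        values = sub.to_numpy(dtype=object)
        is_a = values == CALL_A
        is_b = values == CALL_B
        n = (is_a | is_b).sum(axis=0)
        count_b = is_b.sum(axis=0)
        for j, marker in enumerate(sub.columns):
            chrom = meta.loc[marker, "chromosome"]
            expected = x_expected_fraction(direction) if chrom == X_CHROMOSOME else 0.5
            frac = count_b[j] / n[j] if n[j] > 0 else np.nan
            rows.append((marker, chrom, meta.loc[marker, "physical_bp"], direction,
                         int(n[j]), int(count_b[j]), frac, expected,
                         np.nan, np.nan, False))
    table = pd.DataFrame(rows, columns=["marker", "chromosome", "physical_bp",
                                        "cross_direction", "n", "count_b",
                                        "fraction", "expected", "chisq", "p",
                                        "significant"])
    return MTRDTrack(table=table)


def lag1_autocorrelation(series) -> float:
    """Standard lag-1 sample autocorrelation (mean-centered, N-normalized).

    A constant series has no defined autocorrelation; it is reported as 0
    (callers treating N_eff = N for such a series are conservative).
    """
    x = np.asarray(list(series), dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("need at least three observations")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return 0.0
    return float((xc[:-1] @ xc[1:]) / denom)


def effective_tests(track: MTRDTrack, domains: DomainSet,
                    alpha: float = 0.05) -> EffectiveTests:
    """Effective number of tests per domain via the AR(1) correction.

    N_eff = N (1 - rho) / (1 + rho), clamped to [1, N]; negative rho clamps
    at N (independence is the ceiling).  The genome-wide corrected alpha per
    cross direction is ``alpha`` divided by the summed N_eff.
    """
    rows = []
    t = track.table
    for direction, dsub in t.groupby("cross_direction", sort=False):
        for chrom, csub in dsub.groupby("chromosome", sort=False):
            csub = csub.sort_values("physical_bp")
            labels = [domains.domain_of(chrom, bp) for bp in csub["physical_bp"]]
            csub = csub.assign(_domain=labels)
            for dom, gsub in csub.groupby("_domain", sort=False):
                series = gsub["fraction"].to_numpy(dtype=float)
                n = len(series)
                if n >= 3:
                    rho = lag1_autocorrelation(series)
                else:
                    rho = 0.0
                if rho >= 1.0:
                    n_eff = 1.0
                else:
                    n_eff = n * (1.0 - rho) / (1.0 + rho)
                n_eff = float(np.clip(n_eff, 1.0, n))
                rows.append((direction, chrom, dom, n, rho, n_eff))
    per_domain = pd.DataFrame(rows, columns=["cross_direction", "chromosome",
                                             "domain", "n_markers", "rho", "n_eff"])
    return EffectiveTests(per_domain=per_domain, alpha=alpha)


def chisq_gof(count_b: int, n: int, expected: float, continuity: bool = False):
    """1-df chi-square goodness of fit of (count_b, n-count_b) vs expectation.

    The default is the plain large-sample statistic, used by the scan.  With
    ``continuity=True`` the Yates-corrected form is computed; that variant
    tracks the exact binomial two-sided p closely (within ~0.01 for n >= 50
    at moderate fractions) and serves as the small-sample approximation.
    """
    exp_b = n * expected
    exp_a = n * (1.0 - expected)
    dev = abs(count_b - exp_b)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    chisq = dev ** 2 / exp_b + dev ** 2 / exp_a
    p = float(stats.chi2.sf(chisq, df=1))
    return float(chisq), p


def threshold_fraction(n: int, expected: float, alpha_corrected: float,
                       side: str = "B") -> float:
    """Smallest allele fraction reaching genome-wide significance at size n.

    ``side='B'`` walks up from the expectation toward B fixation (the
    distortion direction plotted by default); ``side='A'`` walks down.
    Returns NaN when no count reaches significance.
    """
    counts = np.arange(0, n + 1)
    if side == "B":
        counts = counts[counts >= int(np.ceil(n * expected))]
    elif side == "A":
        counts = counts[counts <= int(np.floor(n * expected))][::-1]
    else:
        raise ValueError("side must be 'A' or 'B'")
    for c in counts:
        _, p = chisq_gof(int(c), n, expected)
        if p <= alpha_corrected:
            return float(c) / n
    return np.nan


def mtrd_scan(track: MTRDTrack, eff: EffectiveTests) -> MTRDTrack:
    """Fill chi-square statistics and genome-wide significance flags.

    Also attaches per-direction threshold fractions (the dashed lines of an
    allele-fraction plot) in ``table.attrs['thresholds']``, computed at each
    distinct (expected, n) pair toward the B-biased side.
    """
    t = track.table.copy()
    thr_rows = []
    for direction, dsub in t.groupby("cross_direction", sort=False):
        alpha_c = eff.corrected_alpha(direction)
        for idx in dsub.index:
            n = int(t.at[idx, "n"])
            if n == 0:
                continue
            chisq, p = chisq_gof(int(t.at[idx, "count_b"]), n,
                                 float(t.at[idx, "expected"]))
            t.at[idx, "chisq"] = chisq
            t.at[idx, "p"] = p
            t.at[idx, "significant"] = p <= alpha_c
        for (expected, n), _ in dsub.groupby(["expected", "n"]):
            if n == 0:
                continue
            thr_rows.append((direction, expected, int(n),
                             threshold_fraction(int(n), float(expected), alpha_c)))
    out = MTRDTrack(table=t)
    out.table.attrs["thresholds"] = pd.DataFrame(
        thr_rows, columns=["cross_direction", "expected", "n", "threshold_fraction"])
    return out


def cross_direction_test(track_fwd: pd.DataFrame, track_rev: pd.DataFrame,
                         region_markers, eff: EffectiveTests,
                         center_domains=("center",)) -> pd.DataFrame:
    """Fisher's exact test of allele counts between cross directions.

    For each marker in the region, a 2x2 exact test of (A count, B count) x
    cross direction.  The 0.05 threshold is Bonferroni-corrected by the sum
    over both cross directions of the largest center-domain effective test
    count.
    """
    region = list(region_markers)
    if not region:
        raise ValueError("empty marker region")
    fwd = track_fwd.set_index("marker")
    rev = track_rev.set_index("marker")
    centers = eff.per_domain[eff.per_domain["domain"].isin(center_domains)]
    denom = float(centers.groupby("cross_direction")["n_eff"].max().sum())
    if denom <= 0:
        raise ValueError("no center-domain effective tests available")
    alpha_c = eff.alpha / denom
    rows = []
    for marker in region:
        f, r = fwd.loc[marker], rev.loc[marker]
        table = np.array([
            [f["n"] - f["count_b"], f["count_b"]],
            [r["n"] - r["count_b"], r["count_b"]],
        ], dtype=int)
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((marker, float(p), p <= alpha_c))
    out = pd.DataFrame(rows, columns=["marker", "p", "significant"])
    out.attrs["alpha_corrected"] = alpha_c
    return out
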