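"""Genetic maps from ordered RIL genotypes.

Breakpoint counting, recombination-fraction estimation, Haldane map
construction, interval statistics, and normalization of linkage groups to a
50 cM per-meiosis scale.

Marker order is taken from physical assembly order within each chromosome;
the cumulative map treats every breakpoint accumulated over the cross as if
it occurred in a single meiosis, so distances between adjacent markers are
Haldane transforms of the fraction of lines discordant at the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .genotypes import CALL_A, CALL_B, CALL_H, CALL_MISSING, GenotypeMatrix


class MapError(ValueError):
    """Raised when a genetic map cannot be constructed."""


class RFEstimate(NamedTuple):
    r: float
    n_informative: int
    n_discordant: int
    unlinked: bool


@dataclass
class LinkageMap:
    """Per-chromosome marker order with cumulative genetic positions.

    ``positions`` has columns marker, chromosome, physical_bp, genetic_cM
    (0 at the first marker of each linkage group, non-decreasing);
    ``pair_rf`` holds the adjacent-pair recombination fractions the map was
    built from (may be empty for maps assembled from published positions).
    """

    positions: pd.DataFrame
    pair_rf: pd.DataFrame

    def __post_init__(self) -> None:
        for chrom, grp in self.positions.groupby("chromosome", sort=False):
            d = np.diff(grp["genetic_cM"].to_numpy())
            if len(d) and d.min() < -1e-9:
                raise MapError(f"genetic positions decrease on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.positions["chromosome"]))

    def chromosome_slice(self, chrom: str) -> pd.DataFrame:
        return self.positions[self.positions["chromosome"] == chrom].reset_index(drop=True)

    @property
    def cumulative_lengths(self) -> pd.Series:
        return self.positions.groupby("chromosome", sort=False)["genetic_cM"].max()

    @property
    def total_length(self) -> float:
        return float(self.cumulative_lengths.sum())


@dataclass
class BreakpointSummary:
    per_chromosome: pd.DataFrame  # chromosome, total, mean_per_line
    genome_total: int
    n_lines: int


@dataclass
class IntervalStats:
    n_intervals: int
    mean_bp: float
    median_bp: float
    max_bp: float
    mean_cm: float
    median_cm: float
    max_cm: float


def count_breakpoints(calls: Iterable[str]) -> int:
    """Number of transitions between consecutive non-missing calls.

    Any change of state between flanking informative calls counts one
    breakpoint; a heterozygous call therefore contributes one breakpoint per
    flanking transition (A,H,B counts two).  Missing calls are skipped, so
    the nearest flanking informative calls are compared.
    """
    n = 0
    prev = None
    for c in calls:
        if c == CALL_MISSING:
            continue
        if prev is not None and c != prev:
            n += 1
        prev = c
    return n


def breakpoint_summary(m: GenotypeMatrix, k: pd.DataFrame) -> BreakpointSummary:
    """Per-chromosome breakpoint totals and per-line means over all lines."""
    values = m.calls
    rows = []
    genome_total = 0
    for chrom, grp in k.groupby("chromosome", sort=False):
        markers = list(grp["marker"])
        sub = values[markers].to_numpy(dtype=object)
        total = sum(count_breakpoints(row) for row in sub)
        genome_total += total
        rows.append((chrom, total, total / m.n_lines if m.n_lines else np.nan))
    return BreakpointSummary(
        per_chromosome=pd.DataFrame(rows, columns=["chromosome", "total", "mean_per_line"]),
        genome_total=int(genome_total),
        n_lines=m.n_lines,
    )


def estimate_rf(calls_i, calls_j) -> RFEstimate:
    """Recombination fraction between two markers from homozygous calls.

    Only lines homozygous (A or B) at both markers are informative; the
    discordant fraction is the cumulative recombination fraction between the
    pair.  ``unlinked`` is flagged when r >= 0.5.
    """
    ci = np.asarray(list(calls_i), dtype=object)
    cj = np.asarray(list(calls_j), dtype=object)
    if ci.shape != cj.shape:
        raise ValueError("call vectors must be aligned")
    hom_i = (ci == CALL_A) | (ci == CALL_B)
    hom_j = (cj == CALL_A) | (cj == CALL_B)
    informative = hom_i & hom_j
    n = int(informative.sum())
    if n == 0:
        raise MapError("no lines informative at the marker pair")
    discordant = int((ci[informative] != cj[informative]).sum())
    r = discordant / n
    return RFEstimate(r=r, n_informative=n, n_discordant=discordant, unlinked=r >= 0.5)


def haldane(r: float) -> float:
    """Haldane map distance d = -50 ln(1 - 2r), in cM (no interference)."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"r must be in [0, 0.5); got {r}")
    return -50.0 * np.log(1.0 - 2.0 * r)


def inverse_haldane(d_cm: float) -> float:
    """Recombination fraction r(d) = (1 - exp(-d/50)) / 2 for d in cM."""
    if d_cm < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-d_cm / 50.0))


def build_map(m: GenotypeMatrix, k: pd.DataFrame) -> LinkageMap:
    """Cumulative Haldane map per chromosome from adjacent-pair r estimates."""
    pos_rows = []
    rf_rows = []
    for chrom, grp in k.groupby("chromosome", sort=False):
        markers = list(grp["marker"])
        phys = grp["physical_bp"].to_numpy()
        cum = 0.0
        pos_rows.append((markers[0], chrom, phys[0], 0.0))
        for left, right, bp in zip(markers[:-1], markers[1:], phys[1:]):
            est = estimate_rf(m.calls[left], m.calls[right])
            rf_rows.append((chrom, left, right, est.r, est.unlinked))
            if est.unlinked:
                raise MapError(
                    f"adjacent markers {left}/{right} on {chrom} appear unlinked "
                    f"(r = {est.r:.3f}); map distance undefined"
                )
            cum += haldane(est.r)
            pos_rows.append((right, chrom, bp, cum))
    positions = pd.DataFrame(pos_rows,
                             columns=["marker", "chromosome", "physical_bp", "genetic_cM"])
    pair_rf = pd.DataFrame(rf_rows,
                           columns=["chromosome", "left", "right", "r", "unlinked"])
    return LinkageMap(positions=positions, pair_rf=pair_rf)


def map_from_positions(k: pd.DataFrame) -> LinkageMap:
    """Wrap an existing marker table (with genetic_cM) as a LinkageMap."""
    positions = k[["marker", "chromosome", "physical_bp", "genetic_cM"]].copy()
    for chrom, grp in positions.groupby("chromosome", sort=False):
        first = grp["genetic_cM"].iloc[0]
        positions.loc[grp.index, "genetic_cM"] = grp["genetic_cM"] - first
    return LinkageMap(positions=positions.reset_index(drop=True),
                      pair_rf=pd.DataFrame(columns=["chromosome", "left", "right",
                                                    "r", "unlinked"]))


def interval_stats(lmap: LinkageMap, k: pd.DataFrame | None = None) -> IntervalStats:
    """Statistics over genetic intervals (adjacent marker pairs with d > 0).

    Runs of completely linked markers collapse into a single map position, so
    only marker pairs flanking a positive genetic distance define intervals.
    Physical size is measured marker-to-marker across each interval.
    """
    sizes_bp: list[float] = []
    sizes_cm: list[float] = []
    for _, grp in lmap.positions.groupby("chromosome", sort=False):
        d_cm = np.diff(grp["genetic_cM"].to_numpy())
        d_bp = np.diff(grp["physical_bp"].to_numpy())
        pos = d_cm > 0
        sizes_cm.extend(d_cm[pos])
        sizes_bp.extend(d_bp[pos])
    if not sizes_cm:
        return IntervalStats(0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
    sizes_bp_arr = np.asarray(sizes_bp, dtype=float)
    sizes_cm_arr = np.asarray(sizes_cm, dtype=float)
    return IntervalStats(
        n_intervals=len(sizes_cm_arr),
        mean_bp=float(sizes_bp_arr.mean()),
        median_bp=float(np.median(sizes_bp_arr)),
        max_bp=float(sizes_bp_arr.max()),
        mean_cm=float(sizes_cm_arr.mean()),
        median_cm=float(np.median(sizes_cm_arr)),
        max_cm=float(sizes_cm_arr.max()),
    )


def normalize_map(lmap: LinkageMap, target: float = 50.0,
                  domain_lengths: pd.Series | None = None) -> LinkageMap:
    """Rescale each linkage group by a single factor to ``target`` cM.

    By default the factor normalizes the cumulative length; when
    ``domain_lengths`` (a Series of per-chromosome cM sums, e.g. of the three
    major recombination domains) is given, that sum is normalized instead.
    """
    positions = lmap.positions.copy()
    for chrom, grp in positions.groupby("chromosome", sort=False):
        length = float(domain_lengths[chrom]) if domain_lengths is not None \
            else float(grp["genetic_cM"].max())
        if length <= 0:
            raise MapError(f"cannot normalize zero-length linkage group {chrom}")
        positions.loc[grp.index, "genetic_cM"] = grp["genetic_cM"] * (target / length)
    return LinkageMap(positions=positions, pair_rf=lmap.pair_rf.copy())
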