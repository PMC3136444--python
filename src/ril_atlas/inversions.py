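"""Inversion-like signals from paired genetic maps.

A heterozygous inversion suppresses crossing over within its span, so a
rearrangement segregating in one cross but not another manifests as a block
of markers recombinant in one linkage map and nonrecombinant in the other.
With maps normalized to a common 50 cM per chromosome, the expected number
of breakpoints a nonrecombinant block *should* have captured is the block's
cM span in the recombinant map times the local breakpoint density of the
nonrecombinant map's RIL set; observing zero is tested against a Poisson
with that mean (P(0 | lambda) = exp(-lambda)), Bonferroni-corrected over
candidate blocks.

Blocks whose genetic order is strictly reversed between maps (negative
Marey slope in one map only) are reported separately as order inversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import DomainSet
from .linkage import BreakpointSummary, LinkageMap, normalize_map


@dataclass
class PairedMap:
    """Shared markers with both maps' normalized genetic positions.

    ``table`` columns: marker, chromosome, physical_bp, cm1, cm2 (each
    chromosome normalized to ``target`` cM; physical order common).
    """

    table: pd.DataFrame
    target: float = 50.0
    dropped_chromosomes: tuple = ()

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom].reset_index(drop=True)


@dataclass
class SuppressionCandidate:
    chromosome: str
    markers: list
    start_bp: float
    end_bp: float
    cm_map1: float
    cm_map2: float
    nonrecombinant_in: str  # "map1" or "map2"
    density: float | None
    lam: float | None
    p: float | None
    p_corrected: float | None
    significant: bool


def pair_maps(map1: LinkageMap, map2: LinkageMap, shared=None,
              target: float = 50.0) -> PairedMap:
    """Restrict two maps to shared markers, normalized per chromosome."""
    p1 = map1.positions.set_index("marker")
    p2 = map2.positions.set_index("marker")
    if shared is None:
        shared = [m for m in p1.index if m in set(p2.index)]
    else:
        shared = [m for m in shared if m in set(p1.index) and m in set(p2.index)]
    if not shared:
        raise ValueError("maps share no markers")
    rows = []
    dropped = []
    sub1 = p1.loc[shared]
    for chrom, grp in sub1.groupby("chromosome", sort=False):
        markers = list(grp.sort_values("physical_bp").index)
        if len(markers) < 2:
            dropped.append(chrom)
            continue
        cm1 = p1.loc[markers, "genetic_cM"].to_numpy(dtype=float)
        cm2 = p2.loc[markers, "genetic_cM"].to_numpy(dtype=float)

        def norm(v):
            v = v - v.min()
            span = v.max()
            return v * (target / span) if span > 0 else v
        cm1, cm2 = norm(cm1), norm(cm2)
        for mk, c1, c2 in zip(markers, cm1, cm2):
            rows.append((mk, chrom, float(p1.loc[mk, "physical_bp"]), c1, c2))
    if not rows:
        raise ValueError("no chromosome retains two shared markers")
    table = pd.DataFrame(rows, columns=["marker", "chromosome", "physical_bp",
                                        "cm1", "cm2"])
    return PairedMap(table=table, target=target, dropped_chromosomes=tuple(dropped))


def domain_breakpoint_density(bsummary: BreakpointSummary, lmap: LinkageMap,
                              domains: DomainSet):
    """Per-(chromosome, domain) breakpoint density of a RIL set, in bp/cM.

    Breakpoint totals are apportioned to domains by the normalized genetic
    length each domain occupies; the density divides the apportioned count
    by the domain's normalized cM.  Returns a lookup callable
    ``density(chromosome, bp) -> breakpoints/cM`` (NaN for 0-cM tips).
    """
    per_chrom = bsummary.per_chromosome.set_index("chromosome")["total"]
    tab = domains.table

    def density(chrom: str, bp: float) -> float:
        sub = tab[tab["chromosome"] == chrom]
        total_cm = float(sub["cm_norm"].sum())
        hit = sub[(sub["start_bp"] <= bp) & (bp < sub["end_bp"])]
        if hit.empty:
            hit = sub.iloc[[-1]]
        cm = float(hit.iloc[0]["cm_norm"])
        if cm <= 0 or total_cm <= 0:
            return np.nan
        dom_breakpoints = float(per_chrom.get(chrom, np.nan)) * (cm / total_cm)
        return dom_breakpoints / cm

    return density


def observed_domain_density(m, k: pd.DataFrame, domains: DomainSet):
    """Observed per-domain breakpoint density of a RIL set, in bp/cM.

    Counts genotype transitions between adjacent informative markers across
    all lines, assigns each to the domain containing the marker-pair
    midpoint, and divides by the domain's normalized genetic length.
    Returns a callable ``density(chromosome, bp) -> breakpoints/cM``.
    """
    from .genotypes import CALL_MISSING

    tab = domains.table
    counts: dict[tuple[str, str], int] = {}
    for chrom, grp in k.groupby("chromosome", sort=False):
        markers = list(grp["marker"])
        bp = grp["physical_bp"].to_numpy(dtype=float)
        values = m.calls[markers].to_numpy(dtype=object)
        for row in values:
            prev_call, prev_idx = None, None
            for idx, call in enumerate(row):
                if call == CALL_MISSING:
                    continue
                if prev_call is not None and call != prev_call:
                    mid = 0.5 * (bp[prev_idx] + bp[idx])
                    dom = domains.domain_of(chrom, mid)
                    counts[(chrom, dom)] = counts.get((chrom, dom), 0) + 1
                prev_call, prev_idx = call, idx

    def density(chrom: str, pos: float) -> float:
        sub = tab[tab["chromosome"] == chrom]
        hit = sub[(sub["start_bp"] <= pos) & (pos < sub["end_bp"])]
        if hit.empty:
            hit = sub.iloc[[-1]]
        dom = str(hit.iloc[0]["domain"])
        cm = float(hit.iloc[0]["cm_norm"])
        if cm <= 0:
            return np.nan
        return counts.get((chrom, dom), 0) / cm

    return density


def _nonrecombinant_blocks(cm_zero: np.ndarray, cm_pos: np.ndarray, atol: float):
    """Maximal runs of adjacent pairs with ~0 cM in one map and > 0 in the other."""
    flags = (np.abs(np.diff(cm_zero)) <= atol) & (np.diff(cm_pos) > atol)
    blocks = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            blocks.append((start, i))  # markers start..i inclusive
            start = None
    if start is not None:
        blocks.append((start, len(flags)))
    return blocks


def scan_suppression(paired: PairedMap, density_map1=None, density_map2=None,
                     alpha: float = 0.05, atol: float = 1e-9) -> list[SuppressionCandidate]:
    """Poisson test of blocks nonrecombinant in one map only.

    ``density_map1``/``density_map2`` are callables ``(chrom, bp) ->
    breakpoints/cM`` for the respective RIL sets (see
    :func:`domain_breakpoint_density`); the density of the *nonrecombinant*
    map's set multiplies the block's cM span in the *recombinant* map to
    give the expected breakpoint count lambda.  Candidates lacking a density
    are emitted flagged, without a p-value.  Bonferroni correction is over
    the number of candidates emitted.
    """
    candidates = []
    for chrom in pd.unique(paired.table["chromosome"]):
        sub = paired.chromosome(chrom)
        bp = sub["physical_bp"].to_numpy(dtype=float)
        cm1 = sub["cm1"].to_numpy(dtype=float)
        cm2 = sub["cm2"].to_numpy(dtype=float)
        markers = list(sub["marker"])
        for zero_map, cm_zero, cm_pos, dens in (
                ("map2", cm2, cm1, density_map2),
                ("map1", cm1, cm2, density_map1)):
            for i0, i1 in _nonrecombinant_blocks(cm_zero, cm_pos, atol):
                span_pos = float(cm_pos[i1] - cm_pos[i0])
                mid = 0.5 * (bp[i0] + bp[i1])
                if dens is not None:
                    rho = float(dens(chrom, mid))
                else:
                    rho = np.nan
                if np.isfinite(rho):
                    lam = span_pos * rho
                    p = float(np.exp(-lam))
                else:
                    lam, p = None, None
                candidates.append(SuppressionCandidate(
                    chromosome=chrom, markers=markers[i0:i1 + 1],
                    start_bp=float(bp[i0]), end_bp=float(bp[i1]),
                    cm_map1=float(cm1[i1] - cm1[i0]),
                    cm_map2=float(cm2[i1] - cm2[i0]),
                    nonrecombinant_in=zero_map,
                    density=rho if np.isfinite(rho) else None,
                    lam=lam, p=p, p_corrected=None, significant=False))
    n_tests = len(candidates)
    for c in candidates:
        if c.p is not None and n_tests:
            c.p_corrected = min(1.0, c.p * n_tests)
            c.significant = c.p_corrected < alpha
    return candidates


def poisson_zero_p(lam: float) -> float:
    """P(X = 0 | lambda) = exp(-lambda); lambda = 0 gives p = 1."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return float(np.exp(-lam))


@dataclass
class InvertedBlock:
    chromosome: str
    markers: list
    inverted_map: str  # which map shows the reversed order
    cm_map1: tuple
    cm_map2: tuple


def detect_order_inversions(paired: PairedMap, atol: float = 1e-9) -> list[InvertedBlock]:
    """Runs of >= 2 markers whose genetic order reverses in one map only.

    A run qualifies when one map's positions strictly decrease along the
    shared physical order while the other map's strictly increase (negative
    vs positive local Marey slope).
    """
    out = []
    for chrom in pd.unique(paired.table["chromosome"]):
        sub = paired.chromosome(chrom)
        markers = list(sub["marker"])
        cm1 = sub["cm1"].to_numpy(dtype=float)
        cm2 = sub["cm2"].to_numpy(dtype=float)
        for inverted, cm_inv, cm_con in (("map2", cm2, cm1), ("map1", cm1, cm2)):
            flags = (np.diff(cm_inv) < -atol) & (np.diff(cm_con) > atol)
            start = None
            runs = []
            for i, f in enumerate(flags):
                if f and start is None:
                    start = i
                elif not f and start is not None:
                    runs.append((start, i))
                    start = None
            if start is not None:
                runs.append((start, len(flags)))
            for i0, i1 in runs:
                out.append(InvertedBlock(
                    chromosome=chrom, markers=markers[i0:i1 + 1],
                    inverted_map=inverted,
                    cm_map1=tuple(cm1[i0:i1 + 1]),
                    cm_map2=tuple(cm2[i0:i1 + 1])))
    return out


def suppression_report(candidates) -> pd.DataFrame:
    rows = [(c.chromosome, c.start_bp, c.end_bp, len(c.markers), c.nonrecombinant_in,
             c.cm_map1, c.cm_map2, c.density, c.lam, c.p, c.p_corrected, c.significant)
            for c in candidates]
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp",
                                       "n_markers", "nonrecombinant_in",
                                       "cm_map1", "cm_map2", "density",
                                       "lambda", "p", "p_corrected", "significant"])
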