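"""Pairwise linkage disequilibrium (D') across RIL genotypes.

Inbred lines are effectively haploid gametes: each line fixed at two loci
contributes one observed two-locus haplotype, so D and Lewontin's D' can be
computed directly from haplotype counts without phasing or Hardy-Weinberg
assumptions.  Heterozygous or missing calls drop a line from a pair.

Interchromosomal blocks of high D' restricted to one cross direction are
the genetic signature of epistatic selection interacting with a
cross-polarized factor (cytoplasm or X dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import CALL_A, CALL_B, GenotypeMatrix


@dataclass
class LDMatrix:
    """Symmetric D/D' matrices over markers for one cross direction.

    Entries are NaN where a pair is undefined (a marker monomorphic among
    the lines scored at both markers).
    """

    markers: list
    d: np.ndarray
    dprime: np.ndarray
    freq_b: np.ndarray  # marginal B frequency per marker (over all its informative lines)
    direction: str
    n_pairs: np.ndarray  # informative line count per pair

    def pair(self, marker_i, marker_j) -> float:
        i = self.markers.index(marker_i)
        j = self.markers.index(marker_j)
        return float(self.dprime[i, j])


@dataclass
class LDBlock:
    chrom_a: str
    chrom_b: str
    markers_a: list
    markers_b: list
    min_dprime: float
    max_dprime: float
    representative: tuple


def dprime_from_counts(n_ab: int, n_aB: int, n_Ab: int, n_BB: int):
    """Closed-form D and D' from the four two-locus haplotype counts.

    Counts are (A,A), (A,B), (B,A), (B,B) at markers i,j.  Returns
    ``(D, Dprime)``; D' is NaN when either marker is monomorphic.
    """
    n = n_ab + n_aB + n_Ab + n_BB
    if n == 0:
        return np.nan, np.nan
    p_b_i = (n_Ab + n_BB) / n  # B frequency at marker i
    p_b_j = (n_aB + n_BB) / n
    if p_b_i in (0.0, 1.0) or p_b_j in (0.0, 1.0):
        return np.nan, np.nan
    p_bb = n_BB / n
    d = p_bb - p_b_i * p_b_j
    q_i, q_j = 1.0 - p_b_i, 1.0 - p_b_j
    if d > 0:
        d_max = min(p_b_i * q_j, q_i * p_b_j)
    elif d < 0:
        d_max = min(p_b_i * p_b_j, q_i * q_j)
    else:
        return 0.0, 0.0
    return d, abs(d) / d_max


def dprime_matrix(m: GenotypeMatrix, direction: str) -> LDMatrix:
    """All-pairs D' for the lines of one cross direction (vectorized)."""
    lines = m.lines_for_direction(direction)
    if not lines:
        raise ValueError(f"no lines with cross direction {direction!r}")
    values = m.calls.loc[lines].to_numpy(dtype=object)
    a = (values == CALL_A).astype(float)
    b = (values == CALL_B).astype(float)
    valid = a + b  # 1 where the line is fixed at the marker
    n = valid.T @ valid                      # informative lines per pair
    n_bb = b.T @ b
    n_b_i = b.T @ valid                      # B at i among pair-informative lines
    n_b_j = valid.T @ b
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = n_b_i / n
        p_j = n_b_j / n
        d = n_bb / n - p_i * p_j
        q_i, q_j = 1.0 - p_i, 1.0 - p_j
        d_max = np.where(d > 0, np.minimum(p_i * q_j, q_i * p_j),
                         np.minimum(p_i * p_j, q_i * q_j))
        dprime = np.abs(d) / d_max
    dprime = np.where(np.isclose(d, 0.0), 0.0, dprime)
    mono = (p_i <= 0) | (p_i >= 1) | (p_j <= 0) | (p_j >= 1) | (n == 0)
    dprime[mono] = np.nan
    d[mono] = np.nan
    np.fill_diagonal(dprime, np.nan)
    np.fill_diagonal(d, np.nan)
    n_inf = valid.sum(axis=0)
    count_b = b.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq_b = np.where(n_inf > 0, count_b / np.maximum(n_inf, 1), np.nan)
    return LDMatrix(markers=list(m.calls.columns), d=d, dprime=dprime,
                    freq_b=freq_b, direction=direction, n_pairs=n.astype(int))


def _maximal_rectangles(mask: np.ndarray):
    """Greedy enumeration of maximal all-true contiguous rectangles."""
    rects = set()
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0]:
                continue
            # grow rows first, then columns, and vice versa; keep both
            for order in ("rows_first", "cols_first"):
                r1, c1 = r0, c0
                if order == "rows_first":
                    while r1 + 1 < rows and mask[r1 + 1, c0:c1 + 1].all():
                        r1 += 1
                    while c1 + 1 < cols and mask[r0:r1 + 1, c1 + 1].all():
                        c1 += 1
                else:
                    while c1 + 1 < cols and mask[r0, c1 + 1]:
                        c1 += 1
                    while r1 + 1 < rows and mask[r1 + 1, c0:c1 + 1].all():
                        r1 += 1
                # extend upward/leftward to maximality
                rr0, cc0 = r0, c0
                while rr0 - 1 >= 0 and mask[rr0 - 1, cc0:c1 + 1].all():
                    rr0 -= 1
                while cc0 - 1 >= 0 and mask[rr0:r1 + 1, cc0 - 1].all():
                    cc0 -= 1
                rects.add((rr0, r1, cc0, c1))
    # drop rectangles contained in another
    out = []
    for rect in rects:
        if not any(o != rect and o[0] <= rect[0] and o[1] >= rect[1]
                   and o[2] <= rect[2] and o[3] >= rect[3] for o in rects):
            out.append(rect)
    return sorted(out)


def find_blocks(ld: LDMatrix, k: pd.DataFrame, min_dprime: float = 0.8,
                interchromosomal_only: bool = True) -> list[LDBlock]:
    """Maximal rectangles of contiguous markers with all pairwise D' >= cutoff.

    Markers are taken in map order per chromosome; a block pairs a
    contiguous run on one chromosome with a contiguous run on another such
    that every cross pair meets the threshold.  Ties in greedy extension
    resolve toward the larger block.  The representative pair is the
    highest-D' pair of the block.
    """
    meta = k.set_index("marker")
    order = {mk: i for i, mk in enumerate(ld.markers)}
    by_chrom: dict[str, list[str]] = {}
    for mk in k["marker"]:
        if mk in order:
            by_chrom.setdefault(str(meta.loc[mk, "chromosome"]), []).append(mk)
    chroms = list(by_chrom)
    blocks = []
    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1:] if interchromosomal_only else chroms[i:]:
            if interchromosomal_only and ca == cb:
                continue
            rows_m = by_chrom[ca]
            cols_m = by_chrom[cb]
            sub = ld.dprime[np.ix_([order[x] for x in rows_m],
                                   [order[x] for x in cols_m])]
            mask = np.nan_to_num(sub, nan=-1.0) >= min_dprime
            if not mask.any():
                continue
            for r0, r1, c0, c1 in _maximal_rectangles(mask):
                vals = sub[r0:r1 + 1, c0:c1 + 1]
                flat = np.unravel_index(np.nanargmax(vals), vals.shape)
                blocks.append(LDBlock(
                    chrom_a=ca, chrom_b=cb,
                    markers_a=rows_m[r0:r1 + 1], markers_b=cols_m[c0:c1 + 1],
                    min_dprime=float(np.nanmin(vals)),
                    max_dprime=float(np.nanmax(vals)),
                    representative=(rows_m[r0 + flat[0]], cols_m[c0 + flat[1]]),
                ))
    return blocks


def gametic_association_test(m: GenotypeMatrix, marker_i: str, marker_j: str,
                             direction: str):
    """Chi-square of observed two-locus fixed classes vs allele-frequency products.

    Expected counts of lines fixed for each two-locus class are the products
    of the marginal allele frequencies times the number of doubly-fixed
    lines.  Returns ``(chisq, p, warning)`` where ``warning`` is True when
    any expected cell falls below 1.
    """
    lines = m.lines_for_direction(direction)
    ci = m.calls.loc[lines, marker_i]
    cj = m.calls.loc[lines, marker_j]
    fixed = ci.isin([CALL_A, CALL_B]) & cj.isin([CALL_A, CALL_B])
    ci, cj = ci[fixed], cj[fixed]
    n = len(ci)
    if n == 0:
        raise ValueError("no doubly-fixed lines for the pair")
    p_b_i = float((ci == CALL_B).mean())
    p_b_j = float((cj == CALL_B).mean())
    if p_b_i in (0.0, 1.0) or p_b_j in (0.0, 1.0):
        raise ValueError("marker monomorphic among scored lines")
    obs = np.array([
        [((ci == CALL_A) & (cj == CALL_A)).sum(), ((ci == CALL_A) & (cj == CALL_B)).sum()],
        [((ci == CALL_B) & (cj == CALL_A)).sum(), ((ci == CALL_B) & (cj == CALL_B)).sum()],
    ], dtype=float)
    exp = n * np.outer([1 - p_b_i, p_b_i], [1 - p_b_j, p_b_j])
    chisq = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chisq, df=1))
    return chisq, p, bool((exp < 1).any())


def ld_table(ld: LDMatrix, k: pd.DataFrame) -> pd.DataFrame:
    """Flat TSV-ready table of all computed pairs (upper triangle)."""
    meta = k.set_index("marker")
    rows = []
    n = len(ld.markers)
    for i in range(n):
        for j in range(i + 1, n):
            rows.append((ld.markers[i], ld.markers[j],
                         str(meta.loc[ld.markers[i], "chromosome"]),
                         str(meta.loc[ld.markers[j], "chromosome"]),
                         ld.d[i, j], ld.dprime[i, j]))
    return pd.DataFrame(rows, columns=["marker_i", "marker_j", "chrom_i",
                                       "chrom_j", "D", "Dprime"])
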