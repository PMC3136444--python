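"""End-to-end study analyses built from the library modules.

Each function here runs one self-contained computation of the kind the
package exists for — design arithmetic, neutral-simulation calibration
checks, planted-selection recovery, inversion recovery — and returns plain
numbers.  They are shared by the test suite and the reproduction script so
that every reported quantity is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import reference
from .domains import domain_set_from_geometry
from .genotypes import (CALL_A, CALL_B, DIRECTION_FWD, DIRECTION_REV,
                        GenotypeMatrix)
from .inversions import (detect_order_inversions, observed_domain_density,
                         pair_maps, scan_suppression)
from .linkage import breakpoint_summary, build_map, interval_stats
from .ld import dprime_matrix, find_blocks
from .mtrd import allele_fraction_track, effective_tests, mtrd_scan
from .sim import (CYTONUCLEAR_TERM, DELAY_LOCUS, INVERSION_SPAN, NEUTRAL,
                  SelectionModel, airil_design, default_genome, f2_design,
                  merge_results, simulate_cross)

CB4_DOMAINS = domain_set_from_geometry(reference.CB4_DOMAIN_GEOMETRY)


def design_arithmetic() -> dict:
    """Closed-form design expectations from the published map summary."""
    return {
        "expected_x_map_length_cm": reference.expected_x_map_length(),
        "airil_genotype_call_total": reference.AIRIL_N_LINES * reference.AIRIL_N_MARKERS,
    }


def _fractions(matrix: GenotypeMatrix, k: pd.DataFrame, chromosomes, direction):
    markers = k[k["chromosome"].isin(chromosomes)]["marker"]
    lines = matrix.lines_for_direction(direction)
    values = matrix.calls.loc[lines, list(markers)].to_numpy(dtype=object)
    is_a = values == CALL_A
    is_b = values == CALL_B
    n = (is_a | is_b).sum(axis=0)
    return (is_b.sum(axis=0) / np.maximum(n, 1), n)


def neutral_design_check(seed: int, n_lines_per_direction: int = 2000,
                         markers_per_chromosome: int = 12) -> dict:
    """Mean fixed-allele fractions of a neutral AI-RIL simulation.

    The hermaphrodite P0's strain is expected at 2/3 on the X and each
    strain at 1/2 on autosomes.  Reported fractions are pooled over the
    reciprocal directions (B on the X for P1xP2, A for P2xP1, i.e. the
    hermaphrodite strain in both); Monte-Carlo standard errors accompany
    the estimates.
    """
    genome = default_genome(markers_per_chromosome=markers_per_chromosome)
    a = simulate_cross(genome, airil_design(DIRECTION_FWD, n_lines_per_direction),
                       NEUTRAL, seed)
    b = simulate_cross(genome, airil_design(DIRECTION_REV, n_lines_per_direction),
                       NEUTRAL, seed + 1)
    res = merge_results(a, b)
    k = res.marker_table
    autosomes = [c.name for c in genome.chromosomes if not c.is_x]

    frac_fwd, _ = _fractions(res.matrix, k, autosomes, DIRECTION_FWD)
    frac_rev, _ = _fractions(res.matrix, k, autosomes, DIRECTION_REV)
    auto_frac = float(np.concatenate([frac_fwd, frac_rev]).mean())

    xf_fwd, _ = _fractions(res.matrix, k, ["X"], DIRECTION_FWD)  # B = herm strain
    xf_rev, _ = _fractions(res.matrix, k, ["X"], DIRECTION_REV)  # herm strain = A
    herm_x = np.concatenate([xf_fwd, 1.0 - xf_rev])
    # per-line SE: each line contributes one (nearly) independent fixation
    n_lines = 2 * n_lines_per_direction
    se = float(np.sqrt(0.5 * 0.5 / n_lines))
    se_x = float(np.sqrt((2 / 3) * (1 / 3) / n_lines))
    return {
        "autosomal_b_fraction": auto_frac,
        "x_hermaphrodite_fraction": float(herm_x.mean()),
        "se_autosomal": se,
        "se_x": se_x,
        "n_lines": n_lines,
    }


def _scan_sim(res, domains):
    track = allele_fraction_track(res.matrix, res.marker_table)
    eff = effective_tests(track, domains)
    return mtrd_scan(track, eff), eff


def mtrd_type1_rate(seed: int, n_replicates: int = 100, n_lines: int = 80,
                    markers_per_chromosome: int = 12) -> dict:
    """Familywise false-positive rate of the corrected MTRD scan, no selection.

    Each replicate simulates one neutral AI-RIL set (single direction),
    scans it genome-wide with the N_eff-Bonferroni-corrected chi-square
    test, and records whether any marker reached significance.
    """
    genome = default_genome(markers_per_chromosome=markers_per_chromosome)
    hits = 0
    markers_flagged = 0
    markers_total = 0
    for rep in range(n_replicates):
        res = simulate_cross(genome, airil_design(DIRECTION_FWD, n_lines),
                             NEUTRAL, seed + 17 * rep + 1)
        scanned, _ = _scan_sim(res, CB4_DOMAINS)
        sig = scanned.table["significant"].to_numpy(dtype=bool)
        hits += bool(sig.any())
        markers_flagged += int(sig.sum())
        markers_total += len(sig)
    return {
        "familywise_rate": hits / n_replicates,
        "marker_rate": markers_flagged / markers_total,
        "n_replicates": n_replicates,
    }


def delay_locus_recovery(seed: int, n_lines_per_direction: int = 150,
                         markers_per_chromosome: int = 30) -> dict:
    """Planted viability penalty at a ChrIII center locus: scan recovery.

    A hybrid-incompatibility viability model (AA homozygotes at a ChrIII
    center locus disfavoured in both directions) should produce significant
    B-biased distortion whose maximum sits in the ChrIII center domain.
    """
    genome = default_genome(markers_per_chromosome=markers_per_chromosome)
    sel = SelectionModel(viability=[DELAY_LOCUS])
    res = merge_results(
        simulate_cross(genome, airil_design(DIRECTION_FWD, n_lines_per_direction),
                       sel, seed),
        simulate_cross(genome, airil_design(DIRECTION_REV, n_lines_per_direction),
                       sel, seed + 1))
    scanned, _ = _scan_sim(res, CB4_DOMAINS)
    t = scanned.table
    locus_chrom = DELAY_LOCUS[0]
    chr3 = t[t["chromosome"] == locus_chrom]
    peak = chr3.loc[chr3["fraction"].idxmax()]
    dom = CB4_DOMAINS.table
    center = dom[(dom["chromosome"] == locus_chrom) & (dom["domain"] == "center")]
    lo, hi = float(center["start_bp"].iloc[0]), float(center["end_bp"].iloc[0])
    sig_both = (chr3[chr3["significant"]].groupby("marker")["cross_direction"]
                .nunique() == 2)
    return {
        "max_fraction": float(chr3["fraction"].max()),
        "peak_bp": float(peak["physical_bp"]),
        "peak_in_center": bool(lo <= peak["physical_bp"] < hi),
        "n_significant_markers": int(chr3["significant"].sum()),
        "any_marker_significant_both_directions": bool(sig_both.any()),
        "locus_bp": float(DELAY_LOCUS[1]),
    }


def cytonuclear_recovery(seed: int, n_lines_per_direction: int = 150,
                         markers_per_chromosome: int = 30) -> dict:
    """Planted cytonuclear penalty: distortion in one cross direction only.

    The penalty pairs AA homozygotes at a ChrIV locus with B-strain mtDNA,
    which only the P1xP2 direction carries (its hermaphrodite P0 is the B
    strain), so significant ChrIV distortion should appear there and not in
    the reciprocal direction.
    """
    genome = default_genome(markers_per_chromosome=markers_per_chromosome)
    sel = SelectionModel(cytonuclear=[CYTONUCLEAR_TERM])
    res = merge_results(
        simulate_cross(genome, airil_design(DIRECTION_FWD, n_lines_per_direction),
                       sel, seed),
        simulate_cross(genome, airil_design(DIRECTION_REV, n_lines_per_direction),
                       sel, seed + 1))
    scanned, _ = _scan_sim(res, CB4_DOMAINS)
    t = scanned.table
    chr4 = t[t["chromosome"] == CYTONUCLEAR_TERM[0]]
    sig = chr4[chr4["significant"]]
    n_fwd = int((sig["cross_direction"] == DIRECTION_FWD).sum())
    n_rev = int((sig["cross_direction"] == DIRECTION_REV).sum())
    return {
        "n_significant_fwd": n_fwd,
        "n_significant_rev": n_rev,
        "direction_specific": bool(n_fwd > 0 and n_rev == 0),
        "max_fraction_fwd": float(
            chr4[chr4["cross_direction"] == DIRECTION_FWD]["fraction"].max()),
    }


def inversion_recovery(seed: int, n_airil_per_direction: int = 125,
                       n_f2: int = 150, markers_per_chromosome=None) -> dict:
    """Planted heterozygous-inversion suppression recovered by the map scan.

    The AI-RIL simulation carries a crossover-suppressed span on ChrIV arm
    B; the F2-design simulation does not.  Markers inside the span stay
    nonrecombinant in the AI-RIL map but separate in the F2 map; the Poisson
    test against the AI-RIL breakpoint density should flag the block.  The
    default marker density is the study's (sub-inversion marker spacing);
    a sparser grid cannot resolve a sub-Mbp suppressed span.
    """
    genome = default_genome(markers_per_chromosome=markers_per_chromosome)
    sel = SelectionModel(inversions=[INVERSION_SPAN])
    airil = merge_results(
        simulate_cross(genome, airil_design(DIRECTION_FWD, n_airil_per_direction),
                       sel, seed),
        simulate_cross(genome, airil_design(DIRECTION_REV, n_airil_per_direction),
                       sel, seed + 1))
    f2 = simulate_cross(genome, f2_design(DIRECTION_FWD, n_f2), NEUTRAL, seed + 2)

    map_airil = build_map(airil.matrix, airil.marker_table)
    map_f2 = build_map(f2.matrix, f2.marker_table)
    paired = pair_maps(map_airil, map_f2)
    density_airil = observed_domain_density(airil.matrix, airil.marker_table,
                                            CB4_DOMAINS)
    density_f2 = observed_domain_density(f2.matrix, f2.marker_table, CB4_DOMAINS)
    candidates = scan_suppression(paired, density_map1=density_airil,
                                  density_map2=density_f2)
    chrom, lo, hi = INVERSION_SPAN
    overlapping = [c for c in candidates
                   if c.chromosome == chrom and c.nonrecombinant_in == "map1"
                   and c.end_bp > lo and c.start_bp < hi]
    best = min(overlapping, key=lambda c: (c.p_corrected if c.p_corrected is not None
                                           else np.inf), default=None)
    return {
        "n_candidates": len(candidates),
        "planted_recovered": best is not None and best.significant,
        "planted_lambda": float(best.lam) if best and best.lam is not None else np.nan,
        "planted_p_corrected": float(best.p_corrected)
        if best and best.p_corrected is not None else np.nan,
    }


def simulated_airil_map_statistics(seed: int, n_lines_per_direction: int = 84,
                                   markers_per_chromosome=None) -> dict:
    """Full map pipeline on one simulated AI-RIL set of the study's size."""
    genome = default_genome(markers_per_chromosome=markers_per_chromosome)
    res = merge_results(
        simulate_cross(genome, airil_design(DIRECTION_FWD, n_lines_per_direction),
                       NEUTRAL, seed),
        simulate_cross(genome, airil_design(DIRECTION_REV,
                                            n_lines_per_direction - 1),
                       NEUTRAL, seed + 1))
    lmap = build_map(res.matrix, res.marker_table)
    bsum = breakpoint_summary(res.matrix, res.marker_table)
    stats = interval_stats(lmap)
    per_chrom = bsum.per_chromosome.set_index("chromosome")["mean_per_line"]
    autosomes = [c.name for c in genome.chromosomes if not c.is_x]
    return {
        "total_map_length_cm": lmap.total_length,
        "x_over_autosome_length": float(
            lmap.cumulative_lengths["X"] /
            lmap.cumulative_lengths[autosomes].mean()),
        "genome_breakpoints": bsum.genome_total,
        "mean_autosomal_breakpoints_per_line": float(per_chrom[autosomes].mean()),
        "n_intervals": stats.n_intervals,
        "mean_interval_cm": stats.mean_cm,
        "n_lines": res.matrix.n_lines,
    }


def supplementary_recomputation(matrix: GenotypeMatrix, k: pd.DataFrame) -> dict:
    """Recompute the headline statistics from a real genotype matrix.

    Given the AI-RIL supplementary worksheet imported into the native
    containers, recomputes call-class totals, breakpoint counts, map
    lengths, interval statistics and the ChrIII allele-fraction maximum.
    """
    from .genotypes import genotype_counts

    counts = genotype_counts(matrix)
    bsum = breakpoint_summary(matrix, k)
    lmap = build_map(matrix, k)
    stats = interval_stats(lmap)
    track = allele_fraction_track(matrix, k)
    t = track.table
    chr3 = t[t["chromosome"] == "III"]
    per_chrom = bsum.per_chromosome.set_index("chromosome")["mean_per_line"]
    autosomes = [c for c in per_chrom.index if c != "X"]
    return {
        "count_a": counts.a,
        "count_b": counts.b,
        "count_total": counts.total,
        "genome_breakpoints": bsum.genome_total,
        "mean_autosomal_breakpoints_per_line": float(per_chrom[autosomes].mean()),
        "n_intervals": stats.n_intervals,
        "mean_interval_kbp": stats.mean_bp / 1e3,
        "mean_marker_spacing_cm": stats.mean_cm,
        "chr3_max_b_fraction": float(chr3["fraction"].max()),
        "total_map_length_cm": lmap.total_length,
    }
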