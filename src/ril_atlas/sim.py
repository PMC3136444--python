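"""Forward simulation of advanced-intercross and F2 RIL cross designs.

The simulator reproduces the statistical structure the analysis modules
assume: reciprocal crosses between two inbred strains, six generations of
sib-mating followed by ten generations of selfing (or a plain F2-selfing
design), X hemizygosity in males (so two thirds of X copies descend from
the hermaphrodite P0), strictly maternal mtDNA, and domain-structured
recombination via a per-chromosome Marey curve totalling 50 cM per meiosis.
Each meiosis places exactly one crossover per chromosome pair (complete
interference), uniform on the genetic scale and mapped to bp through the
inverse Marey curve; a Poisson-crossover option exists but is off by
default.  Selection is pluggable: viability penalties on nuclear genotypes,
cytonuclear terms keyed to mtDNA origin, and crossover suppression inside
heterozygous inversion spans.

Haplotypes are segment lists (breakpoint positions + parental origins), so
the emitted genotype matrix is exactly derivable from the recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .genotypes import (CALL_A, CALL_B, CALL_H, DIRECTION_FWD, DIRECTION_REV,
                        GenotypeMatrix)

ORIGIN_A = 0  # parent-1 allele
ORIGIN_B = 1  # parent-2 allele


@dataclass
class ChromosomeModel:
    """One chromosome: physical length, marker grid, per-meiosis Marey curve.

    ``marey_bp``/``marey_cm`` are the nodes of a monotone piecewise-linear
    map from bp to cumulative cM, 0 at bp 0 and 50 cM at the chromosome end
    (hermaphrodite meiosis).
    """

    name: str
    length_bp: float
    marey_bp: np.ndarray
    marey_cm: np.ndarray
    marker_bp: np.ndarray
    is_x: bool = False

    def __post_init__(self) -> None:
        self.marey_bp = np.asarray(self.marey_bp, dtype=float)
        self.marey_cm = np.asarray(self.marey_cm, dtype=float)
        self.marker_bp = np.asarray(self.marker_bp, dtype=float)
        if self.marey_bp[0] != 0 or self.marey_cm[0] != 0:
            raise ValueError(f"{self.name}: Marey curve must start at (0, 0)")
        if np.any(np.diff(self.marey_bp) < 0) or np.any(np.diff(self.marey_cm) < -1e-12):
            raise ValueError(f"{self.name}: Marey curve must be monotone")

    @property
    def total_cm(self) -> float:
        return float(self.marey_cm[-1])

    def cm_to_bp(self, cm: float) -> float:
        return float(np.interp(cm, self.marey_cm, self.marey_bp))

    def bp_to_cm(self, bp: float) -> float:
        return float(np.interp(bp, self.marey_bp, self.marey_cm))


@dataclass
class GenomeModel:
    chromosomes: list

    def chromosome(self, name: str) -> ChromosomeModel:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def x_name(self) -> str | None:
        for c in self.chromosomes:
            if c.is_x:
                return c.name
        return None


@dataclass
class CrossDesign:
    """Pedigree schedule of a RIL cross.

    ``direction`` follows the male-first convention: P1xP2 means parent 1
    provides the male P0 and parent 2 the hermaphrodite (hence the mtDNA
    and two thirds of X copies).
    """

    direction: str = DIRECTION_FWD
    n_sibmating_generations: int = 6
    n_selfing_generations: int = 10
    hermaphrodites_per_generation: int = 3
    n_lines: int = 1

    def __post_init__(self) -> None:
        if self.direction not in (DIRECTION_FWD, DIRECTION_REV):
            raise ValueError(f"invalid direction {self.direction!r}")
        if min(self.n_sibmating_generations, self.n_selfing_generations) < 0:
            raise ValueError("generation counts must be >= 0")


@dataclass
class SelectionModel:
    """Fitness model applied as viability at each offspring draw.

    ``viability``: (chromosome, bp, genotype, w) with genotype in
    {"AA","BB","AB"}; ``cytonuclear``: (chromosome, bp, genotype,
    mt_origin, w) with mt_origin in {0 (A strain), 1 (B strain)};
    ``inversions``: (chromosome, start_bp, end_bp) spans inside which
    crossovers are suppressed in heterozygotes.
    """

    viability: list = field(default_factory=list)
    cytonuclear: list = field(default_factory=list)
    inversions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for entry in self.viability:
            if not 0.0 <= entry[3] <= 1.0:
                raise ValueError("viability fitness must be in [0, 1]")
        for entry in self.cytonuclear:
            if not 0.0 <= entry[4] <= 1.0:
                raise ValueError("cytonuclear fitness must be in [0, 1]")


NEUTRAL = SelectionModel()


# --- haplotypes: (ends, origins) with ends[-1] == chromosome length --------

def _homozygous_haplotype(length: float, origin: int):
    return ([length], [origin])


def _origin_at(hap, bp: float) -> int:
    ends, origins = hap
    for end, origin in zip(ends, origins):
        if bp < end:
            return origin
    return origins[-1]


def _crossover(hap_a, hap_b, x: float):
    """Gamete taking hap_a before x and hap_b from x on."""
    ends_a, orig_a = hap_a
    ends_b, orig_b = hap_b
    if x >= ends_a[-1]:
        return list(ends_a), list(orig_a)
    if x <= 0:
        return list(ends_b), list(orig_b)
    ends, origins = [], []
    for end, origin in zip(ends_a, orig_a):
        if end <= x:
            ends.append(end)
            origins.append(origin)
        else:
            break
    # segment of hap_a spanning x
    if not ends or ends[-1] < x:
        ends.append(x)
        origins.append(_origin_at(hap_a, x))
    i = 0
    ends_b_arr = ends_b
    while ends_b_arr[i] <= x:
        i += 1
    for end, origin in zip(ends_b[i:], orig_b[i:]):
        if origins and origin == origins[-1]:
            ends[-1] = end  # merge identical neighbours
        else:
            ends.append(end)
            origins.append(origin)
    return ends, origins


def _is_heterozygous_in(hap_a, hap_b, start: float, end: float) -> bool:
    probes = np.linspace(start, end, 8)
    return any(_origin_at(hap_a, p) != _origin_at(hap_b, p) for p in probes)


@dataclass
class Individual:
    sex: str  # "hermaphrodite" | "male"
    haplotypes: dict  # chrom name -> (hap, hap) or (hap,) for male X
    mt_origin: int

    def genotype_code(self, chrom: str, bp: float) -> str:
        haps = self.haplotypes[chrom]
        origins = sorted(_origin_at(h, bp) for h in haps)
        if len(origins) == 1:  # hemizygous X
            return "AA" if origins[0] == ORIGIN_A else "BB"
        pair = tuple(origins)
        return {(0, 0): "AA", (1, 1): "BB", (0, 1): "AB"}[pair]


def simulate_meiosis(parent: Individual, chrom: ChromosomeModel, rng,
                     selection: SelectionModel = NEUTRAL,
                     obligate_single: bool = True):
    """One gamete haplotype for one chromosome.

    With obligate single crossover (default), the crossover lands at a
    genetic position uniform on [0, 50] cM, mapped to bp by the inverse
    Marey curve; inside a heterozygous inversion span the position is
    resampled outside (suppression).  The optional non-default Poisson mode
    draws Poisson(map length in Morgans) crossovers instead.  A hemizygous
    male X is transmitted intact, without recombination.
    """
    haps = parent.haplotypes[chrom.name]
    if len(haps) == 1:  # male X: no pairing partner
        ends, origins = haps[0]
        return list(ends), list(origins)
    hap_a, hap_b = haps
    suppressed = [(s, e) for c, s, e in selection.inversions
                  if c == chrom.name and _is_heterozygous_in(hap_a, hap_b, s, e)]

    def draw_position():
        for _ in range(200):
            x = chrom.cm_to_bp(rng.uniform(0.0, chrom.total_cm))
            if not any(s <= x < e for s, e in suppressed):
                return x
        return None  # span covers essentially the whole recombining length

    first = hap_a if rng.random() < 0.5 else hap_b
    second = hap_b if first is hap_a else hap_a
    if obligate_single:
        x = draw_position()
        if x is None:
            return list(first[0]), list(first[1])
        return _crossover(first, second, x)
    n_co = rng.poisson(chrom.total_cm / 100.0)
    gamete = (list(first[0]), list(first[1]))
    sources = (second, first)
    for i, cm in enumerate(np.sort(rng.uniform(0.0, chrom.total_cm, size=n_co))):
        x = chrom.cm_to_bp(cm)
        if any(s <= x < e for s, e in suppressed):
            continue
        gamete = _crossover(gamete, sources[i % 2], x)
    return gamete


def _fitness(ind: Individual, selection: SelectionModel) -> float:
    w = 1.0
    for chrom, bp, genotype, fw in selection.viability:
        if ind.genotype_code(chrom, bp) == genotype:
            w *= fw
    for chrom, bp, genotype, mt, fw in selection.cytonuclear:
        if ind.mt_origin == mt and ind.genotype_code(chrom, bp) == genotype:
            w *= fw
    return w


def _make_offspring(genome: GenomeModel, mother: Individual, father: Individual,
                    sex: str, rng, selection: SelectionModel) -> Individual:
    haplotypes = {}
    for chrom in genome.chromosomes:
        oocyte = simulate_meiosis(mother, chrom, rng, selection)
        if chrom.is_x:
            if sex == "male":
                haplotypes[chrom.name] = (oocyte,)  # X0: maternal X only
            else:
                sperm = simulate_meiosis(father, chrom, rng, selection)
                haplotypes[chrom.name] = (oocyte, sperm)
        else:
            sperm = simulate_meiosis(father, chrom, rng, selection)
            haplotypes[chrom.name] = (oocyte, sperm)
    return Individual(sex=sex, haplotypes=haplotypes, mt_origin=mother.mt_origin)


def _make_selfed(genome: GenomeModel, parent: Individual, rng,
                 selection: SelectionModel) -> Individual:
    haplotypes = {}
    for chrom in genome.chromosomes:
        haplotypes[chrom.name] = (simulate_meiosis(parent, chrom, rng, selection),
                                  simulate_meiosis(parent, chrom, rng, selection))
    return Individual(sex="hermaphrodite", haplotypes=haplotypes,
                      mt_origin=parent.mt_origin)


def _viable_draw(make, rng, selection: SelectionModel, max_tries: int = 60):
    """Draw offspring until one survives; returns (individual|None, n_rejected)."""
    for i in range(max_tries):
        cand = make()
        if rng.random() < _fitness(cand, selection):
            return cand, i
    return None, max_tries


def _founders(genome: GenomeModel, direction: str):
    """P0 pair: hermaphrodite and male, homozygous for their strains."""
    male_origin = ORIGIN_A if direction == DIRECTION_FWD else ORIGIN_B
    herm_origin = ORIGIN_B if direction == DIRECTION_FWD else ORIGIN_A
    herm_h, male_h = {}, {}
    for chrom in genome.chromosomes:
        L = chrom.length_bp
        herm_h[chrom.name] = (_homozygous_haplotype(L, herm_origin),
                              _homozygous_haplotype(L, herm_origin))
        if chrom.is_x:
            male_h[chrom.name] = (_homozygous_haplotype(L, male_origin),)
        else:
            male_h[chrom.name] = (_homozygous_haplotype(L, male_origin),
                                  _homozygous_haplotype(L, male_origin))
    herm = Individual("hermaphrodite", herm_h, mt_origin=herm_origin)
    male = Individual("male", male_h, mt_origin=male_origin)
    return herm, male


def _simulate_line(genome: GenomeModel, design: CrossDesign,
                   selection: SelectionModel, rng):
    """One line through the full pedigree; returns (individual|None, n_rejected)."""
    herm_p0, male_p0 = _founders(genome, design.direction)
    mother, father = herm_p0, male_p0
    rejected = 0
    # outcrossing phase: F1 plus sib-mating generations
    for gen in range(design.n_sibmating_generations + 1):
        herm, rej = _viable_draw(
            lambda: _make_offspring(genome, mother, father, "hermaphrodite",
                                    rng, selection), rng, selection)
        rejected += rej
        if herm is None:
            return None, rejected
        if gen < design.n_sibmating_generations:
            male, rej = _viable_draw(
                lambda: _make_offspring(genome, mother, father, "male",
                                        rng, selection), rng, selection)
            rejected += rej
            if male is None:
                return None, rejected
            mother, father = herm, male
        else:
            mother = herm
    # inbreeding phase: selfing a single hermaphrodite per generation
    current = mother
    for _ in range(design.n_selfing_generations):
        nxt, rej = _viable_draw(lambda: _make_selfed(genome, current, rng, selection),
                                rng, selection)
        rejected += rej
        if nxt is None:
            return None, rejected
        current = nxt
    return current, rejected


@dataclass
class SimResult:
    matrix: GenotypeMatrix
    marker_table: pd.DataFrame
    truth: pd.DataFrame  # line_id, cross_direction, mt_origin, extinct, n_rejected
    breakpoints: dict  # line_id -> {chrom: sorted breakpoint bp list}
    seed: int
    genome: GenomeModel


def _genotype_line(genome: GenomeModel, ind: Individual):
    calls = {}
    breakpoints = {}
    for chrom in genome.chromosomes:
        haps = ind.haplotypes[chrom.name]
        tokens = []
        for bp in chrom.marker_bp:
            origins = sorted(_origin_at(h, bp) for h in haps)
            if len(set(origins)) > 1:
                tokens.append(CALL_H)
            else:
                tokens.append(CALL_A if origins[0] == ORIGIN_A else CALL_B)
        calls[chrom.name] = tokens
        bps = set()
        for ends, origins in haps:
            for i in range(len(ends) - 1):
                if origins[i] != origins[i + 1]:
                    bps.add(ends[i])
        breakpoints[chrom.name] = sorted(bps)
    return calls, breakpoints


def marker_table_for(genome: GenomeModel) -> pd.DataFrame:
    rows = []
    for chrom in genome.chromosomes:
        for i, bp in enumerate(chrom.marker_bp):
            rows.append((f"{chrom.name}_m{i:04d}", chrom.name, int(bp),
                         chrom.bp_to_cm(bp), f"sctg_{chrom.name}", int(bp)))
    return pd.DataFrame(rows, columns=["marker", "chromosome", "physical_bp",
                                       "genetic_cM", "supercontig",
                                       "supercontig_bp"])


def simulate_cross(genome: GenomeModel, design: CrossDesign,
                   selection: SelectionModel = NEUTRAL,
                   seed: int = 0) -> SimResult:
    """Simulate ``design.n_lines`` RIL; extinct lines are recorded, not raised."""
    rng = np.random.default_rng(seed)
    k = marker_table_for(genome)
    marker_names = list(k["marker"])
    rows = {}
    truth_rows = []
    breakpoints = {}
    for i in range(design.n_lines):
        line_id = f"{design.direction}_L{i:04d}"
        ind, rejected = _simulate_line(genome, design, selection, rng)
        if ind is None:
            truth_rows.append((line_id, design.direction, -1, True, rejected))
            continue
        calls, bps = _genotype_line(genome, ind)
        tokens = []
        for chrom in genome.chromosomes:
            tokens.extend(calls[chrom.name])
        rows[line_id] = tokens
        truth_rows.append((line_id, design.direction, ind.mt_origin, False, rejected))
        breakpoints[line_id] = bps
    calls_df = pd.DataFrame.from_dict(rows, orient="index", columns=marker_names)
    direction = pd.Series(design.direction, index=calls_df.index, dtype=object)
    truth = pd.DataFrame(truth_rows, columns=["line_id", "cross_direction",
                                              "mt_origin", "extinct", "n_rejected"])
    return SimResult(matrix=GenotypeMatrix(calls_df, direction), marker_table=k,
                     truth=truth, breakpoints=breakpoints, seed=seed,
                     genome=genome)


def merge_results(a: SimResult, b: SimResult) -> SimResult:
    """Pool two simulations over the same genome (e.g. reciprocal directions)."""
    calls = pd.concat([a.matrix.calls, b.matrix.calls])
    direction = pd.concat([a.matrix.cross_direction, b.matrix.cross_direction])
    truth = pd.concat([a.truth, b.truth], ignore_index=True)
    bps = {**a.breakpoints, **b.breakpoints}
    return SimResult(matrix=GenotypeMatrix(calls, direction),
                     marker_table=a.marker_table, truth=truth, breakpoints=bps,
                     seed=a.seed, genome=a.genome)


# --- default genome -------------------------------------------------------

def default_genome(markers_per_chromosome=None) -> GenomeModel:
    """Genome mirroring the published cb4 domain organization.

    Chromosome lengths and five-domain spans follow the published geometry;
    each per-meiosis Marey curve is flat over the tips and piecewise linear
    over arms and center with the published normalized genetic lengths
    (summing to 50 cM).  Markers are placed uniformly per chromosome; the
    default counts follow the genotyped SNP counts per chromosome.
    """
    chroms = []
    geometry = reference.CB4_DOMAIN_GEOMETRY
    for _, g in geometry.iterrows():
        name = g["chromosome"]
        spans = np.array([g["tipA_mbp"], g["armA_mbp"], g["center_mbp"],
                          g["armB_mbp"], g["tipB_mbp"]]) * 1e6
        length = float(spans.sum())
        nodes_bp = np.concatenate([[0.0], np.cumsum(spans)])
        cms = np.array([0.0, 0.0, g["armA_cm"], g["armA_cm"] + g["center_cm"],
                        50.0, 50.0])
        if markers_per_chromosome is None:
            n_mark = reference.CB4_SNPS_PER_CHROMOSOME[name]
        elif isinstance(markers_per_chromosome, dict):
            n_mark = markers_per_chromosome[name]
        else:
            n_mark = int(markers_per_chromosome)
        marker_bp = np.linspace(0.015 * length, 0.985 * length, n_mark)
        chroms.append(ChromosomeModel(name=name, length_bp=length,
                                      marey_bp=nodes_bp, marey_cm=cms,
                                      marker_bp=marker_bp, is_x=(name == "X")))
    return GenomeModel(chromosomes=chroms)


def airil_design(direction: str, n_lines: int) -> CrossDesign:
    return CrossDesign(direction=direction, n_sibmating_generations=6,
                       n_selfing_generations=10, n_lines=n_lines)


def f2_design(direction: str, n_lines: int) -> CrossDesign:
    """F2-derived RIL: no sib-mating beyond F1; ten rounds of selfing."""
    return CrossDesign(direction=direction, n_sibmating_generations=0,
                       n_selfing_generations=10, n_lines=n_lines)


# --- presets ---------------------------------------------------------------

#: Center-domain viability locus on ChrIII expressing the hybrid
#: developmental-delay incompatibility: AA homozygotes are strongly
#: disfavoured during line construction in both cross directions.
DELAY_LOCUS = ("III", 5.5e6, "AA", 0.2)

#: Cytonuclear epistasis on ChrIV: AA homozygotes suffer when combined with
#: B-strain mtDNA, distorting only the direction whose hermaphrodite P0 is
#: the B strain.
CYTONUCLEAR_TERM = ("IV", 9.5e6, "AA", ORIGIN_B, 0.25)

#: Inversion span (ChrIV arm B) with crossover suppression in heterozygotes.
INVERSION_SPAN = ("IV", 14.1e6, 14.75e6)


def make_fixture(preset: str, seed: int = 0) -> SimResult:
    """Deterministic study-condition fixtures.

    Presets: ``tiny`` (8 lines x 24 markers, shrunk genome),
    ``neutral_airil`` (167 lines over reciprocal directions),
    ``delay_chrIII`` (viability penalty at a ChrIII center locus),
    ``cytonuclear`` (mtDNA-keyed penalty on ChrIV, one direction distorted),
    ``inversion_f2`` (AI-RIL with a heterozygote-suppressed inversion),
    ``neutral_f2`` (89 F2-design lines).
    """
    if preset == "tiny":
        genome = default_genome(markers_per_chromosome=4)
        a = simulate_cross(genome, airil_design(DIRECTION_FWD, 4), NEUTRAL, seed)
        b = simulate_cross(genome, airil_design(DIRECTION_REV, 4), NEUTRAL, seed + 1)
        return merge_results(a, b)
    if preset == "neutral_airil":
        genome = default_genome()
        a = simulate_cross(genome, airil_design(DIRECTION_FWD, 84), NEUTRAL, seed)
        b = simulate_cross(genome, airil_design(DIRECTION_REV, 83), NEUTRAL, seed + 1)
        return merge_results(a, b)
    if preset == "delay_chrIII":
        genome = default_genome(markers_per_chromosome=30)
        sel = SelectionModel(viability=[DELAY_LOCUS])
        a = simulate_cross(genome, airil_design(DIRECTION_FWD, 150), sel, seed)
        b = simulate_cross(genome, airil_design(DIRECTION_REV, 150), sel, seed + 1)
        return merge_results(a, b)
    if preset == "cytonuclear":
        genome = default_genome(markers_per_chromosome=30)
        sel = SelectionModel(cytonuclear=[CYTONUCLEAR_TERM])
        a = simulate_cross(genome, airil_design(DIRECTION_FWD, 150), sel, seed)
        b = simulate_cross(genome, airil_design(DIRECTION_REV, 150), sel, seed + 1)
        return merge_results(a, b)
    if preset == "inversion_f2":
        genome = default_genome(markers_per_chromosome=30)
        sel = SelectionModel(inversions=[INVERSION_SPAN])
        a = simulate_cross(genome, airil_design(DIRECTION_FWD, 125), sel, seed)
        b = simulate_cross(genome, airil_design(DIRECTION_REV, 125), sel, seed + 1)
        return merge_results(a, b)
    if preset == "neutral_f2":
        genome = default_genome(markers_per_chromosome=30)
        return simulate_cross(genome, f2_design(DIRECTION_FWD, 89), NEUTRAL, seed)
    raise ValueError(f"unknown preset {preset!r}")
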