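"""Genetic-map-guided ordering and orientation of sequence supercontigs.

A supercontig carrying at least one mapped marker can be assigned to a
chromosome; two markers at distinct genetic positions suffice to both order
and orient it.  Supercontigs whose internal marker order contradicts the
genetic map, or whose markers interleave with another supercontig's span,
are discrepancies; they are resolved by splitting the supercontig at a
sequence gap chosen by a fixed decision tree:

* donor marker recombinant with both recipient flanks -> interpolate its
  expected physical position from the local cM/Mbp rate and split at the
  nearest unsupported gap;
* donor nonrecombinant with one flank -> split at the gap closest to that
  flank's marker;
* split needed only to reorder/invert -> choose the gap producing the
  largest + smallest fragment pair;
* no informative site -> split on both sides of the single discrepant
  sequence contig.

Distance ties break toward the lower coordinate.  Output is an AGP-like
layout (ordered, oriented supercontigs with offsets); sequence handling is
out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import LinkageMap


@dataclass
class Gap:
    position: int  # bp offset within the supercontig
    supported: bool = False  # spanned by a physical-map clone


@dataclass
class Supercontig:
    name: str
    length: int
    gaps: list = field(default_factory=list)  # list[Gap]
    markers: list = field(default_factory=list)  # list[(marker_name, supercontig_bp)]

    def __post_init__(self) -> None:
        for g in self.gaps:
            if not 0 < g.position < self.length:
                raise ValueError(f"{self.name}: gap at {g.position} outside (0, {self.length})")
        for name, bp in self.markers:
            if not 0 <= bp <= self.length:
                raise ValueError(f"{self.name}: marker {name} at {bp} out of bounds")

    def unsupported_gaps(self) -> list:
        return [g for g in self.gaps if not g.supported]


@dataclass
class Placement:
    name: str
    orientation: int  # +1 forward, -1 flipped, 0 unoriented
    offset: int
    length: int


@dataclass
class ChromosomeAssembly:
    """Ordered, oriented supercontigs per chromosome plus leftover bins."""

    chromosomes: dict  # chrom -> list[Placement]
    random_bin: dict  # chrom -> list of un-orderable supercontig names
    unassembled: list  # supercontigs with no mapped markers
    conflicts: list = field(default_factory=list)  # multi-chromosome contigs

    def total_placed_bp(self) -> int:
        return sum(p.length for pls in self.chromosomes.values() for p in pls)


@dataclass
class Discrepancy:
    kind: str  # "internal_order" | "insertion" | "multi_chromosome"
    supercontig: str  # the contig to split (recipient for insertions)
    donor: str | None = None
    donor_marker: tuple | None = None  # (name, genetic_cM)
    flanks: tuple | None = None  # ((name, cM, sctg_bp), (name, cM, sctg_bp))
    details: str = ""


@dataclass
class SplitDecision:
    supercontig: str
    positions: tuple  # one or two split coordinates (bp)
    rule: str  # use_site | interpolate | minimize_distance | smallest_fragment | move_discrepant_contig
    fragment_names: tuple = ()


def _marker_map_info(lmap: LinkageMap) -> pd.DataFrame:
    return lmap.positions.set_index("marker")


def assign_and_order(supercontigs, lmap: LinkageMap, k: pd.DataFrame) -> ChromosomeAssembly:
    """Assign supercontigs to chromosomes and order/orient them by the map.

    Ordering key is the (min, max) genetic span of a contig's markers;
    contigs whose genetic spans are identical zero-width points shared with
    another contig cannot be ordered and fall into the per-chromosome
    "random" bin.  Orientation requires two markers at distinct genetic
    positions; single-marker contigs are placed unoriented.
    """
    info = _marker_map_info(lmap)
    by_name = {s.name: s for s in supercontigs}
    per_chrom: dict[str, list] = {}
    unassembled = []
    conflicts = []
    for s in supercontigs:
        mapped = [(mn, bp) for mn, bp in s.markers if mn in info.index]
        if not mapped:
            unassembled.append(s.name)
            continue
        chroms = {str(info.loc[mn, "chromosome"]) for mn, _ in mapped}
        if len(chroms) > 1:
            conflicts.append((s.name, sorted(chroms)))
        # majority chromosome
        counts: dict[str, int] = {}
        for mn, _ in mapped:
            c = str(info.loc[mn, "chromosome"])
            counts[c] = counts.get(c, 0) + 1
        chrom = max(sorted(counts), key=lambda c: counts[c])
        cms = np.array([float(info.loc[mn, "genetic_cM"]) for mn, _ in mapped
                        if str(info.loc[mn, "chromosome"]) == chrom])
        phys = np.array([float(info.loc[mn, "physical_bp"]) for mn, _ in mapped
                         if str(info.loc[mn, "chromosome"]) == chrom])
        # orientation from genetic position vs within-contig coordinate
        orient = 0
        pairs = [(bp, float(info.loc[mn, "genetic_cM"])) for mn, bp in mapped
                 if str(info.loc[mn, "chromosome"]) == chrom]
        pairs.sort()
        cms_by_sctg = [cm for _, cm in pairs]
        if len(set(cms_by_sctg)) >= 2:
            orient = 1 if cms_by_sctg[-1] >= cms_by_sctg[0] else -1
        per_chrom.setdefault(chrom, []).append(
            (s.name, float(cms.min()), float(cms.max()), float(phys.mean()), orient))

    chromosomes = {}
    random_bin = {}
    for chrom, entries in per_chrom.items():
        # un-orderable ties: identical zero-width genetic spans shared by >= 2
        span_count: dict[tuple, int] = {}
        for name, lo, hi, _, _ in entries:
            if hi == lo:
                span_count[(lo, hi)] = span_count.get((lo, hi), 0) + 1
        placed, random_names = [], []
        for name, lo, hi, mean_phys, orient in entries:
            if hi == lo and span_count.get((lo, hi), 0) > 1:
                random_names.append(name)
            else:
                placed.append((lo, hi, mean_phys, name, orient))
        placed.sort()
        offset = 0
        placements = []
        for lo, hi, _, name, orient in placed:
            length = by_name[name].length
            placements.append(Placement(name=name, orientation=orient,
                                        offset=offset, length=length))
            offset += length
        chromosomes[chrom] = placements
        if random_names:
            random_bin[chrom] = sorted(random_names)
    return ChromosomeAssembly(chromosomes=chromosomes, random_bin=random_bin,
                              unassembled=sorted(unassembled), conflicts=conflicts)


def detect_discrepancies(assembly: ChromosomeAssembly, lmap: LinkageMap,
                         k: pd.DataFrame, supercontigs) -> list[Discrepancy]:
    """Find genetic/physical order conflicts in an assembled layout."""
    info = _marker_map_info(lmap)
    by_name = {s.name: s for s in supercontigs}
    out = []
    for name, chroms in assembly.conflicts:
        out.append(Discrepancy(kind="multi_chromosome", supercontig=name,
                               details=f"markers map to {chroms}"))
    for chrom, placements in assembly.chromosomes.items():
        spans = {}
        for pl in placements:
            s = by_name[pl.name]
            mapped = [(mn, bp) for mn, bp in s.markers
                      if mn in info.index and str(info.loc[mn, "chromosome"]) == chrom]
            if not mapped:
                continue
            mapped.sort(key=lambda t: t[1])
            cms = [float(info.loc[mn, "genetic_cM"]) for mn, _ in mapped]
            if pl.orientation == -1:
                cms = cms[::-1]
            diffs = np.diff(cms)
            if len(diffs) and (diffs < 0).any():
                out.append(Discrepancy(kind="internal_order", supercontig=pl.name,
                                       details="marker genetic order contradicts "
                                               "within-contig physical order"))
            spans[pl.name] = (min(cms), max(cms), mapped)
        names = list(spans)
        for qi, q in enumerate(names):
            qlo, qhi, qmarkers = spans[q]
            for p in names:
                if p == q:
                    continue
                plo, phi, pmarkers = spans[p]
                for mn, _ in qmarkers:
                    cm = float(info.loc[mn, "genetic_cM"])
                    if plo < cm < phi:
                        flank_lo = max(((n, float(info.loc[n, "genetic_cM"]), bp)
                                        for n, bp in pmarkers
                                        if float(info.loc[n, "genetic_cM"]) <= cm),
                                       key=lambda t: t[1])
                        flank_hi = min(((n, float(info.loc[n, "genetic_cM"]), bp)
                                        for n, bp in pmarkers
                                        if float(info.loc[n, "genetic_cM"]) >= cm),
                                       key=lambda t: t[1])
                        out.append(Discrepancy(
                            kind="insertion", supercontig=p, donor=q,
                            donor_marker=(mn, cm), flanks=(flank_lo, flank_hi),
                            details=f"marker {mn} of {q} lies genetically inside {p}"))
                        break
    return out


def _nearest(positions, target):
    """Closest coordinate; ties break toward the lower coordinate."""
    positions = sorted(positions)
    best = min(positions, key=lambda p: (abs(p - target), p))
    return best


def _segment_bounds(sctg: Supercontig, bp: float):
    """Sequence-contig segment (between gaps) containing ``bp``."""
    cuts = [0] + sorted(g.position for g in sctg.gaps) + [sctg.length]
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if lo <= bp <= hi:
            return lo, hi
    return cuts[-2], cuts[-1]


def choose_split(d: Discrepancy, sctg: Supercontig,
                 local_rate: float | None = None) -> SplitDecision:
    """Select the split site for one discrepancy per the decision tree."""
    if d.supercontig != sctg.name:
        raise ValueError("discrepancy does not reference this supercontig")
    gaps = [g.position for g in sctg.unsupported_gaps()]

    if d.kind == "insertion" and d.flanks is not None and d.donor_marker is not None:
        (n_lo, cm_lo, bp_lo), (n_hi, cm_hi, bp_hi) = d.flanks
        cm_d = d.donor_marker[1]
        recomb_lo = cm_d > cm_lo
        recomb_hi = cm_d < cm_hi
        if recomb_lo and recomb_hi:
            rate = local_rate if local_rate is not None else \
                (cm_hi - cm_lo) / (bp_hi - bp_lo)
            expected = bp_lo + (cm_d - cm_lo) / rate
            if gaps:
                return SplitDecision(sctg.name, (_nearest(gaps, expected),),
                                     rule="interpolate")
        elif recomb_lo != recomb_hi:
            anchor = bp_lo if not recomb_lo else bp_hi
            if gaps:
                return SplitDecision(sctg.name, (_nearest(gaps, anchor),),
                                     rule="minimize_distance")
        # fall through to moving only the discrepant sequence contig
        lo, hi = _segment_bounds(sctg, d.donor_marker[1] if d.flanks is None
                                 else 0.5 * (bp_lo + bp_hi))
        return SplitDecision(sctg.name, (lo, hi) if 0 < lo else (hi,),
                             rule="move_discrepant_contig")

    if d.kind == "internal_order":
        if gaps:
            best = min(gaps, key=lambda g: (min(g, sctg.length - g), g))
            return SplitDecision(sctg.name, (best,), rule="smallest_fragment")
        # no unsupported gap: isolate the offending sequence contig
        bp_anchor = sctg.markers[0][1] if sctg.markers else sctg.length / 2
        lo, hi = _segment_bounds(sctg, bp_anchor)
        positions = tuple(p for p in (lo, hi) if 0 < p < sctg.length)
        return SplitDecision(sctg.name, positions or (sctg.length // 2,),
                             rule="move_discrepant_contig")

    raise ValueError(f"no split rule for discrepancy kind {d.kind!r}")


_SUFFIX_RE = re.compile(r"^(?P<base>.*?\d)(?P<letter>[a-z])(?P<digit>\d*)$")


def _fragment_names(name: str, n_fragments: int, lengths) -> list[str]:
    """Fragment naming: a/b/... for first splits; letter+digit for re-splits.

    Splitting an unsuffixed supercontig appends sequential letters in
    coordinate order.  Re-splitting an already-suffixed supercontig keeps
    the letter on the largest fragment with a digit appended (``c`` ->
    ``c2``) and gives the remaining fragments the following letters.
    """
    m = _SUFFIX_RE.match(name)
    if m is None:
        return [f"{name}{chr(ord('a') + i)}" for i in range(n_fragments)]
    base, letter, digit = m.group("base"), m.group("letter"), m.group("digit")
    new_digit = str(int(digit) + 1) if digit else "2"
    largest = int(np.argmax(lengths))
    names = []
    next_letter = ord(letter) + 1
    for i in range(n_fragments):
        if i == largest:
            names.append(f"{base}{letter}{new_digit}")
        else:
            names.append(f"{base}{chr(next_letter)}")
            next_letter += 1
    return names


def split_supercontig(sctg: Supercontig, positions) -> list[Supercontig]:
    """Cut a supercontig at the given internal coordinates.

    Fragment lengths sum to the original; gaps and markers are reassigned
    by coordinate (a gap used as a cut point vanishes into the junction).
    """
    cuts = sorted(set(int(p) for p in positions))
    for p in cuts:
        if not 0 < p < sctg.length:
            raise ValueError(f"split position {p} outside {sctg.name} (0, {sctg.length})")
    bounds = [0] + cuts + [sctg.length]
    lengths = [hi - lo for lo, hi in zip(bounds[:-1], bounds[1:])]
    names = _fragment_names(sctg.name, len(lengths), lengths)
    frags = []
    for fname, lo, hi in zip(names, bounds[:-1], bounds[1:]):
        gaps = [Gap(g.position - lo, g.supported) for g in sctg.gaps
                if lo < g.position < hi]
        markers = [(mn, bp - lo) for mn, bp in sctg.markers if lo <= bp < hi] + \
                  [(mn, bp - lo) for mn, bp in sctg.markers
                   if bp == hi == sctg.length]
        frags.append(Supercontig(name=fname, length=hi - lo, gaps=gaps,
                                 markers=markers))
    assert sum(f.length for f in frags) == sctg.length
    return frags


def apply_splits(supercontigs, decisions, lmap: LinkageMap, k: pd.DataFrame):
    """Execute split decisions and reassemble.

    Returns ``(new_supercontigs, new_assembly)``; the discrepancy count of
    the new assembly should not exceed the old one's.
    """
    by_name = {s.name: s for s in supercontigs}
    new_list = list(supercontigs)
    for dec in decisions:
        if dec.supercontig not in by_name:
            raise KeyError(f"unknown supercontig {dec.supercontig}")
        target = by_name.pop(dec.supercontig)
        new_list.remove(target)
        frags = split_supercontig(target, dec.positions)
        dec.fragment_names = tuple(f.name for f in frags)
        for f in frags:
            by_name[f.name] = f
            new_list.append(f)
    assembly = assign_and_order(new_list, lmap, k)
    return new_list, assembly


def assembly_report(assembly: ChromosomeAssembly) -> pd.DataFrame:
    """AGP-like flat table of the layout."""
    rows = []
    for chrom, placements in assembly.chromosomes.items():
        for pl in placements:
            rows.append((chrom, pl.name,
                         {1: "+", -1: "-", 0: "?"}[pl.orientation],
                         pl.offset, pl.offset + pl.length))
    for chrom, names in assembly.random_bin.items():
        for name in names:
            rows.append((f"{chrom}_random", name, "?", -1, -1))
    for name in assembly.unassembled:
        rows.append(("unassembled", name, "?", -1, -1))
    return pd.DataFrame(rows, columns=["chromosome", "supercontig", "orientation",
                                       "start", "end"])
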