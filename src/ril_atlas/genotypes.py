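"""ABH genotype matrices: reading, writing, QC, and call summaries.

Recombinant-inbred-line genotypes are stored in the ABH convention: ``A``
homozygous for the parent-1 allele, ``B`` homozygous for parent 2, ``H``
heterozygous, ``?`` missing.  The native on-disk format is plain TSV: one
matrix file (row per line: ``line_id``, ``cross_direction``, then one column
per marker) and one companion marker file with physical and genetic
coordinates.  An importer for the supplementary XLSX worksheets is provided
as a thin optional adapter.

Quality control mirrors the filters applied to the original data set:
lines with excess residual heterozygosity are dropped; markers are dropped
when monomorphic, when both parents share a genotype, when under-called, or
when over-heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_A = "A"
CALL_B = "B"
CALL_H = "H"
CALL_MISSING = "?"
VALID_CALLS = frozenset({CALL_A, CALL_B, CALL_H, CALL_MISSING})

DIRECTION_FWD = "P1xP2"  # parent 1 provides the male
DIRECTION_REV = "P2xP1"
DIRECTION_UNKNOWN = "unknown"
VALID_DIRECTIONS = frozenset({DIRECTION_FWD, DIRECTION_REV, DIRECTION_UNKNOWN})

MARKER_COLUMNS = [
    "marker",
    "chromosome",
    "physical_bp",
    "genetic_cM",
    "supercontig",
    "supercontig_bp",
]


class ParseError(ValueError):
    """Raised when a genotype or marker file violates the format contract."""


@dataclass
class GenotypeMatrix:
    """Lines x ordered markers of ABH calls with per-line cross direction.

    ``calls`` is a string DataFrame indexed by line id with one column per
    marker; ``cross_direction`` is a Series aligned to the same index.
    """

    calls: pd.DataFrame
    cross_direction: pd.Series

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dupes = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate line ids: {dupes}")
        if self.calls.columns.has_duplicates:
            dupes = self.calls.columns[self.calls.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate marker ids: {dupes}")
        observed = set(pd.unique(self.calls.values.ravel())) if self.calls.size else set()
        bad = observed - VALID_CALLS
        if bad:
            raise ParseError(f"invalid genotype tokens: {sorted(bad)}")
        self.cross_direction = self.cross_direction.reindex(self.calls.index)
        if self.cross_direction.isna().any():
            missing = self.calls.index[self.cross_direction.isna()].tolist()
            raise ParseError(f"lines without cross_direction: {missing}")
        bad_dir = set(self.cross_direction) - VALID_DIRECTIONS
        if bad_dir:
            raise ParseError(f"invalid cross_direction labels: {sorted(bad_dir)}")
        self.calls.index.name = "line_id"
        self.calls.columns.name = None
        self.cross_direction.index.name = "line_id"
        self.cross_direction.name = "cross_direction"

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def lines_for_direction(self, direction: str) -> list[str]:
        return list(self.calls.index[self.cross_direction == direction])

    def select_lines(self, line_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(line_ids)].copy(),
                              self.cross_direction.loc[list(line_ids)].copy())

    def select_markers(self, markers) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[list(markers)].copy(),
                              self.cross_direction.copy())


@dataclass
class QCReport:
    """Record of removed lines/markers with reasons; counts reconcile."""

    removed_lines: pd.DataFrame  # columns: line_id, reason, value
    removed_markers: pd.DataFrame  # columns: marker, reason, value
    n_lines_before: int
    n_lines_after: int
    n_markers_before: int
    n_markers_after: int

    def __post_init__(self) -> None:
        assert self.n_lines_before - len(self.removed_lines) == self.n_lines_after
        assert self.n_markers_before - len(self.removed_markers) == self.n_markers_after


@dataclass
class CountSummary:
    a: int
    b: int
    h: int
    missing: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.h + self.missing


def _validate_tokens(df: pd.DataFrame, path) -> None:
    values = df.to_numpy(dtype=object)
    ok = np.isin(values, list(VALID_CALLS))
    if not ok.all():
        row, col = np.argwhere(~ok)[0]
        raise ParseError(
            f"{path}: invalid genotype token {values[row, col]!r} at line "
            f"{df.index[row]!r}, marker {df.columns[col]!r}"
        )


def read_marker_table(marker_path) -> pd.DataFrame:
    """Read a marker table TSV, sorted by chromosome then physical position."""
    k = pd.read_csv(marker_path, sep="\t", dtype={"marker": str, "chromosome": str,
                                                  "supercontig": str})
    missing_cols = [c for c in MARKER_COLUMNS[:4] if c not in k.columns]
    if missing_cols:
        raise ParseError(f"{marker_path}: missing marker columns {missing_cols}")
    for col in ("supercontig", "supercontig_bp"):
        if col not in k.columns:
            k[col] = "" if col == "supercontig" else np.nan
    if k["marker"].duplicated().any():
        dupes = k.loc[k["marker"].duplicated(), "marker"].tolist()
        raise ParseError(f"{marker_path}: duplicate markers {dupes}")
    if (k["physical_bp"] < 1).any():
        raise ParseError(f"{marker_path}: physical_bp must be >= 1 (1-based)")
    chrom_order = {c: i for i, c in enumerate(pd.unique(k["chromosome"]))}
    k = k.sort_values(["chromosome", "physical_bp"],
                      key=lambda s: s.map(chrom_order) if s.name == "chromosome" else s,
                      kind="stable").reset_index(drop=True)
    return k[MARKER_COLUMNS]


def read_genotype_matrix(matrix_path, marker_path=None):
    """Read a genotype matrix TSV (and optional marker table).

    Returns ``(GenotypeMatrix, MarkerTable | None)``.  Marker columns of the
    matrix are reordered to the marker table's (physical) order and the two
    files must describe the same marker set.
    """
    df = pd.read_csv(matrix_path, sep="\t", dtype=str).fillna(CALL_MISSING)
    if "line_id" not in df.columns or "cross_direction" not in df.columns:
        raise ParseError(f"{matrix_path}: first columns must be line_id, cross_direction")
    if df["line_id"].duplicated().any():
        dupes = df.loc[df["line_id"].duplicated(), "line_id"].tolist()
        raise ParseError(f"{matrix_path}: duplicate line ids {dupes}")
    calls = df.set_index("line_id").drop(columns=["cross_direction"])
    _validate_tokens(calls, matrix_path)
    direction = df.set_index("line_id")["cross_direction"]
    marker_table = None
    if marker_path is not None:
        marker_table = read_marker_table(marker_path)
        table_markers = list(marker_table["marker"])
        if set(table_markers) != set(calls.columns):
            only_m = sorted(set(calls.columns) - set(table_markers))[:5]
            only_k = sorted(set(table_markers) - set(calls.columns))[:5]
            raise ParseError(
                f"marker sets differ between {matrix_path} and {marker_path} "
                f"(matrix-only: {only_m}, table-only: {only_k})"
            )
        calls = calls[table_markers]
    return GenotypeMatrix(calls, direction), marker_table


def write_genotype_matrix(m: GenotypeMatrix, matrix_path) -> None:
    out = m.calls.copy()
    out.insert(0, "cross_direction", m.cross_direction)
    out.index.name = "line_id"
    out.to_csv(matrix_path, sep="\t")


def write_marker_table(k: pd.DataFrame, marker_path) -> None:
    k[MARKER_COLUMNS].to_csv(marker_path, sep="\t", index=False)


def genotype_counts(m: GenotypeMatrix) -> CountSummary:
    """Totals of A/B/H/missing calls; total always equals lines x markers."""
    if m.calls.size == 0:
        return CountSummary(0, 0, 0, 0)
    values = m.calls.to_numpy(dtype=object)
    return CountSummary(
        a=int((values == CALL_A).sum()),
        b=int((values == CALL_B).sum()),
        h=int((values == CALL_H).sum()),
        missing=int((values == CALL_MISSING).sum()),
    )


def apply_line_qc(m: GenotypeMatrix, max_het_frac: float = 0.05):
    """Drop lines whose H fraction (over non-missing calls) exceeds the cutoff.

    Residual heterozygosity in a finished RIL should be rare (of order
    ``2**-n_selfing``); an excess indicates contamination, non-inbred stock,
    or genotyping failure.
    """
    if not 0.0 <= max_het_frac <= 1.0:
        raise ValueError("max_het_frac must be in [0, 1]")
    if m.n_lines == 0 or m.n_markers == 0:
        raise ValueError("cannot QC an empty genotype matrix")
    values = m.calls.to_numpy(dtype=object)
    informative = (values != CALL_MISSING).sum(axis=1)
    het = (values == CALL_H).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het_frac = np.where(informative > 0, het / np.maximum(informative, 1), 0.0)
    drop = het_frac > max_het_frac
    removed = pd.DataFrame({
        "line_id": m.calls.index[drop],
        "reason": "excess_heterozygosity",
        "value": het_frac[drop],
    })
    kept = m.select_lines(m.calls.index[~drop])
    report = QCReport(
        removed_lines=removed.reset_index(drop=True),
        removed_markers=pd.DataFrame(columns=["marker", "reason", "value"]),
        n_lines_before=m.n_lines,
        n_lines_after=kept.n_lines,
        n_markers_before=m.n_markers,
        n_markers_after=kept.n_markers,
    )
    return kept, report


def apply_marker_qc(
    m: GenotypeMatrix,
    parent1_calls,
    parent2_calls,
    min_call_freq: float = 0.95,
    max_het_frac: float = 0.05,
):
    """Drop markers failing the marker-level filters.

    Reasons, checked in order (first match recorded): ``monomorphic`` (only
    one homozygous class observed across lines and parents),
    ``parents_identical`` (both parents called the same), ``low_call_frequency``
    (non-missing fraction among lines below ``min_call_freq``), and
    ``excess_heterozygosity`` (H fraction over non-missing above
    ``max_het_frac``).
    """
    p1 = pd.Series(parent1_calls).reindex(m.markers)
    p2 = pd.Series(parent2_calls).reindex(m.markers)
    if p1.isna().any() or p2.isna().any():
        raise ValueError("parent call vectors must cover every marker")
    values = m.calls.to_numpy(dtype=object)
    n_lines = m.n_lines
    removed = []
    for j, marker in enumerate(m.markers):
        col = values[:, j]
        observed = set(col[col != CALL_MISSING])
        for p in (p1[marker], p2[marker]):
            if p != CALL_MISSING:
                observed.add(p)
        homozygous = observed & {CALL_A, CALL_B}
        call_freq = float((col != CALL_MISSING).sum()) / n_lines if n_lines else 0.0
        n_inf = (col != CALL_MISSING).sum()
        het_frac = float((col == CALL_H).sum()) / n_inf if n_inf else 0.0
        if len(homozygous) <= 1 and CALL_H not in observed:
            removed.append((marker, "monomorphic", len(homozygous)))
        elif p1[marker] == p2[marker] and p1[marker] != CALL_MISSING:
            removed.append((marker, "parents_identical", p1[marker]))
        elif call_freq < min_call_freq:
            removed.append((marker, "low_call_frequency", call_freq))
        elif het_frac > max_het_frac:
            removed.append((marker, "excess_heterozygosity", het_frac))
    removed_df = pd.DataFrame(removed, columns=["marker", "reason", "value"])
    kept_markers = [mk for mk in m.markers if mk not in set(removed_df["marker"])]
    kept = m.select_markers(kept_markers)
    report = QCReport(
        removed_lines=pd.DataFrame(columns=["line_id", "reason", "value"]),
        removed_markers=removed_df,
        n_lines_before=m.n_lines,
        n_lines_after=kept.n_lines,
        n_markers_before=m.n_markers,
        n_markers_after=kept.n_markers,
    )
    return kept, report


def import_supplementary_xlsx(path, sheet, parent_rows=("AF16", "HK104"),
                              chromosome_labels=("I", "II", "III", "IV", "V", "X")):
    """Best-effort importer for the supplementary XLSX genotype worksheets.

    The worksheet layout is assumed to carry one row per SNP with columns for
    the SNP name, supercontig name, chromosome assignment (1-6; 6 = X),
    position within the supercontig and within the chromosome assembly, and
    the genetic map position in Morgans (converted here to cM, x100), followed
    by one column per parent strain and per line of ABH genotype calls.

    Returns ``(GenotypeMatrix, MarkerTable, parent_calls)`` where
    ``parent_calls`` maps parent name -> pandas Series of calls per marker.
    Requires ``openpyxl``.
    """
    raw = pd.read_excel(path, sheet_name=sheet, dtype=object)
    raw.columns = [str(c).strip() for c in raw.columns]

    def find_col(*candidates):
        for cand in candidates:
            for c in raw.columns:
                if cand.lower() in c.lower():
                    return c
        return None

    name_col = find_col("snp", "marker")
    sctg_col = find_col("supercontig", "sctg")
    chrom_col = find_col("chromosome", "chrom", "linkage")
    chrom_pos_col = find_col("chromosome position", "assembly position", "chr pos")
    sctg_pos_col = find_col("position of the snp within the supercontig",
                            "supercontig position", "sctg pos")
    genetic_col = find_col("morgan", "genetic")
    if name_col is None or chrom_col is None or genetic_col is None:
        raise ParseError(f"{path}:{sheet}: could not locate marker metadata columns")

    meta_cols = [c for c in (name_col, sctg_col, chrom_col, chrom_pos_col,
                             sctg_pos_col, genetic_col) if c is not None]
    geno_cols = [c for c in raw.columns if c not in meta_cols]
    # genotype columns hold only ABH tokens
    geno_cols = [
        c for c in geno_cols
        if set(raw[c].dropna().astype(str).str.strip()) <= VALID_CALLS
        and raw[c].notna().any()
    ]

    def as_chrom(v):
        try:
            return chromosome_labels[int(v) - 1]
        except (ValueError, TypeError, IndexError):
            return str(v)

    markers = pd.DataFrame({
        "marker": raw[name_col].astype(str),
        "chromosome": raw[chrom_col].map(as_chrom),
        "physical_bp": pd.to_numeric(raw[chrom_pos_col], errors="coerce")
        if chrom_pos_col else np.nan,
        "genetic_cM": pd.to_numeric(raw[genetic_col], errors="coerce") * 100.0,
        "supercontig": raw[sctg_col].astype(str) if sctg_col else "",
        "supercontig_bp": pd.to_numeric(raw[sctg_pos_col], errors="coerce")
        if sctg_pos_col else np.nan,
    })

    calls = raw[geno_cols].astype(str).apply(lambda s: s.str.strip())
    calls = calls.where(calls.isin(list(VALID_CALLS)), CALL_MISSING)
    calls.index = markers["marker"]
    calls = calls.T  # -> lines x markers
    parents = {}
    for pr in parent_rows:
        match = [c for c in calls.index if pr.lower() in str(c).lower()]
        if match:
            parents[pr] = calls.loc[match[0]]
            calls = calls.drop(index=match)
    direction = pd.Series(DIRECTION_UNKNOWN, index=calls.index)
    chrom_order = {c: i for i, c in enumerate(chromosome_labels)}
    markers = markers.sort_values(
        ["chromosome", "physical_bp"],
        key=lambda s: s.map(chrom_order) if s.name == "chromosome" else s,
        kind="stable",
    ).reset_index(drop=True)
    calls = calls[list(markers["marker"])]
    return GenotypeMatrix(calls, direction), markers[MARKER_COLUMNS], parents
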