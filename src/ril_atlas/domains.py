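"""Recombination-rate domains: tips, arms, and centers.

Caenorhabditis chromosomes are holocentric and show a stereotyped Marey-map
profile: zero-recombination tips, high-rate arms, and a low-rate center.
Tips are defined combinatorially (assembly terminus to the most internal
marker of the terminal non-recombinant block).  The two arm/center
boundaries are estimated by three-segment continuous piecewise-linear
("broken-line") regression of genetic on physical position over the non-tip
span, via Muggeo-style iterative linearization with a deterministic
grid-search fallback.  The three major domains are normalized to 50 cM per
chromosome (the expected per-meiosis length under selfing) with a single
factor, from which per-domain rates and arm ratios follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import LinkageMap

DOMAIN_ORDER = ("tipA", "armA", "center", "armB", "tipB")
MAJOR_DOMAINS = ("armA", "center", "armB")


@dataclass
class SegmentedFit:
    """Three-segment continuous piecewise-linear fit y(x).

    ``psi`` are the two interior breakpoints (bp), ``slopes`` the three
    segment slopes in cM/Mbp.  ``converged`` is False for degenerate inputs
    (no detectable slope change) or when neither the iterative fit nor the
    grid fallback produced an admissible fit (center slope smallest).
    """

    psi1: float
    psi2: float
    slopes: tuple[float, float, float]
    intercept: float
    rss: float
    converged: bool
    method: str  # "iterative" | "grid" | "degenerate"


@dataclass
class DomainSet:
    """Five-domain partition per chromosome with spans, lengths and rates.

    ``table`` columns: chromosome, domain, start_bp, end_bp, cm_raw, cm_norm,
    rate_cm_per_mbp.  Spans tile [0, chromosome length); tips carry 0 cM; the
    normalized major-domain lengths sum to 50 cM per chromosome.
    """

    table: pd.DataFrame
    factors: dict = field(default_factory=dict)  # chromosome -> normalization factor
    arm_ratios: pd.DataFrame | None = None

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom].reset_index(drop=True)

    def domain_of(self, chrom: str, bp: float) -> str:
        sub = self.chromosome(chrom)
        hit = sub[(sub["start_bp"] <= bp) & (bp < sub["end_bp"])]
        if hit.empty:  # right edge of the chromosome
            return str(sub.iloc[-1]["domain"])
        return str(hit.iloc[0]["domain"])

    def center_fractions(self) -> pd.Series:
        t = self.table
        total = t.groupby("chromosome", sort=False).apply(
            lambda g: g["end_bp"].max() - g["start_bp"].min(), include_groups=False)
        center = t[t["domain"] == "center"].set_index("chromosome")
        span = center["end_bp"] - center["start_bp"]
        return span / total


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate: bool = False


def detect_tip_domains(chrom_map: pd.DataFrame, chrom_length: float,
                       atol: float = 1e-9):
    """Physical spans of the two tip domains of one chromosome.

    Each tip runs from the assembly terminus to the most internal marker
    sharing the terminal marker's genetic position (the terminal
    non-recombinant block).  Tips have recombination rate zero by definition.
    Returns ``((0, tipA_end), (tipB_start, chrom_length))``.
    """
    if len(chrom_map) < 2:
        raise ValueError("need at least two markers to define tips")
    cm = chrom_map["genetic_cM"].to_numpy(dtype=float)
    bp = chrom_map["physical_bp"].to_numpy(dtype=float)
    i = 0
    while i + 1 < len(cm) and abs(cm[i + 1] - cm[0]) <= atol:
        i += 1
    j = len(cm) - 1
    while j - 1 >= 0 and abs(cm[j - 1] - cm[-1]) <= atol:
        j -= 1
    return (0.0, float(bp[i])), (float(bp[j]), float(chrom_length))


def _hinge_design(x: np.ndarray, psi) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.clip(x - p, 0.0, None))
    return np.column_stack(cols)


def _fit_fixed_breakpoints(x: np.ndarray, y: np.ndarray, psi):
    X = _hinge_design(x, psi)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _slopes_from_coef(coef) -> tuple[float, float, float]:
    b1 = coef[1]
    return (float(b1), float(b1 + coef[2]), float(b1 + coef[2] + coef[3]))


def _admissible(slopes, tol=1e-9) -> bool:
    s1, s2, s3 = slopes
    return s2 <= s1 + tol and s2 <= s3 + tol


def _grid_search(x: np.ndarray, y: np.ndarray, min_seg: int = 2):
    """Deterministic fallback: breakpoints at midpoints between markers."""
    xs = np.unique(x)
    mids = 0.5 * (xs[:-1] + xs[1:])
    best = None
    best_any = None
    for a in range(len(mids)):
        p1 = mids[a]
        if (x < p1).sum() < min_seg:
            continue
        for b in range(a + 1, len(mids)):
            p2 = mids[b]
            if ((x >= p1) & (x < p2)).sum() < min_seg or (x >= p2).sum() < min_seg:
                continue
            coef, rss = _fit_fixed_breakpoints(x, y, (p1, p2))
            slopes = _slopes_from_coef(coef)
            entry = (rss, p1, p2, coef, slopes)
            if best_any is None or rss < best_any[0]:
                best_any = entry
            if _admissible(slopes) and (best is None or rss < best[0]):
                best = entry
    return best, best_any


def fit_domain_boundaries(chrom_map: pd.DataFrame,
                          init: tuple[float, float] = (0.25, 0.75),
                          tol: float = 1e-8,
                          max_iter: int = 100) -> SegmentedFit:
    """Estimate the two arm/center boundaries of one chromosome.

    ``chrom_map`` is a per-chromosome slice with physical_bp and genetic_cM,
    tip markers already excluded (tips are defined separately, not by
    regression).  Breakpoints are initialized at the ``init`` physical
    quantiles and refined by iterative linearization; if the iteration fails
    to converge, leaves the admissible region (center slope must be the
    smallest), or collapses, a grid search over marker midpoints is used.
    """
    x = chrom_map["physical_bp"].to_numpy(dtype=float)
    y = chrom_map["genetic_cM"].to_numpy(dtype=float)
    if len(x) < 6:
        raise ValueError("need at least six non-tip markers for a 3-segment fit")
    if np.any(np.diff(x) <= 0):
        raise ValueError("physical positions must be strictly increasing")

    # Degenerate input: a single line already explains the data.
    lin = stats.linregress(x, y)
    rss_line = float(np.sum((y - (lin.intercept + lin.slope * x)) ** 2))
    scale = float(np.sum((y - y.mean()) ** 2))
    if scale <= 0 or rss_line <= 1e-12 * max(scale, 1.0):
        return SegmentedFit(psi1=np.nan, psi2=np.nan,
                            slopes=(lin.slope * 1e6,) * 3, intercept=lin.intercept,
                            rss=rss_line, converged=False, method="degenerate")

    psi = np.quantile(x, init).astype(float)
    span = x.max() - x.min()
    result = None
    for _ in range(max_iter):
        U = [np.clip(x - p, 0.0, None) for p in psi]
        V = [-(x > p).astype(float) for p in psi]
        X = np.column_stack([np.ones_like(x), x] + U + V)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            break
        beta = coef[2:4]
        gamma = coef[4:6]
        if np.any(np.abs(beta) < 1e-15):
            break
        step = gamma / beta
        new_psi = psi + step
        if not (x.min() < new_psi[0] < new_psi[1] < x.max()):
            break
        psi = new_psi
        if np.max(np.abs(step)) < tol * span:
            coef_f, rss = _fit_fixed_breakpoints(x, y, psi)
            slopes = _slopes_from_coef(coef_f)
            if _admissible(slopes):
                result = SegmentedFit(
                    psi1=float(psi[0]), psi2=float(psi[1]),
                    slopes=tuple(s * 1e6 for s in slopes),
                    intercept=float(coef_f[0]), rss=rss,
                    converged=True, method="iterative")
            break

    if result is None:
        best, best_any = _grid_search(x, y)
        if best is not None:
            rss, p1, p2, coef_f, slopes = best
            result = SegmentedFit(psi1=float(p1), psi2=float(p2),
                                  slopes=tuple(s * 1e6 for s in slopes),
                                  intercept=float(coef_f[0]), rss=rss,
                                  converged=True, method="grid")
        elif best_any is not None:
            rss, p1, p2, coef_f, slopes = best_any
            result = SegmentedFit(psi1=float(p1), psi2=float(p2),
                                  slopes=tuple(s * 1e6 for s in slopes),
                                  intercept=float(coef_f[0]), rss=rss,
                                  converged=False, method="grid")
        else:
            raise ValueError("segmented fit failed: no admissible breakpoint pair")
    return result


def _interp_cm(chrom_map: pd.DataFrame, bp: float) -> float:
    """Genetic position at ``bp`` by linear interpolation between flanking markers."""
    x = chrom_map["physical_bp"].to_numpy(dtype=float)
    y = chrom_map["genetic_cM"].to_numpy(dtype=float)
    if not (x.min() <= bp <= x.max()):
        raise ValueError(f"boundary {bp} lies outside the marker span")
    return float(np.interp(bp, x, y))


def domain_table(fit: SegmentedFit, tips, chrom_map: pd.DataFrame,
                 chrom_length: float, chromosome: str,
                 target_cm: float = 50.0) -> pd.DataFrame:
    """Assemble the five-domain rows for one chromosome.

    Boundary genetic positions are interpolated between flanking markers; the
    three major domains are normalized by a single factor so their genetic
    lengths sum to ``target_cm``; rates are normalized cM per Mbp.
    """
    (tipa_lo, tipa_hi), (tipb_lo, tipb_hi) = tips
    if not np.isfinite(fit.psi1) or not np.isfinite(fit.psi2):
        raise ValueError("cannot build a domain table from a degenerate fit")
    cm_at = {
        "tipA_end": _interp_cm(chrom_map, tipa_hi) if tipa_hi >= chrom_map["physical_bp"].min()
        else chrom_map["genetic_cM"].iloc[0],
        "psi1": _interp_cm(chrom_map, fit.psi1),
        "psi2": _interp_cm(chrom_map, fit.psi2),
        "tipB_start": _interp_cm(chrom_map, tipb_lo),
    }
    spans = {
        "tipA": (0.0, tipa_hi),
        "armA": (tipa_hi, fit.psi1),
        "center": (fit.psi1, fit.psi2),
        "armB": (fit.psi2, tipb_lo),
        "tipB": (tipb_lo, chrom_length),
    }
    cm_raw = {
        "tipA": 0.0,
        "armA": cm_at["psi1"] - cm_at["tipA_end"],
        "center": cm_at["psi2"] - cm_at["psi1"],
        "armB": cm_at["tipB_start"] - cm_at["psi2"],
        "tipB": 0.0,
    }
    major_sum = sum(cm_raw[d] for d in MAJOR_DOMAINS)
    if major_sum <= 0:
        raise ValueError(f"no recombination in the major domains of {chromosome}")
    factor = target_cm / major_sum
    rows = []
    for dom in DOMAIN_ORDER:
        lo, hi = spans[dom]
        if hi < lo - 1e-6:
            raise ValueError(f"domain {dom} on {chromosome} has negative span")
        cm_norm = cm_raw[dom] * factor
        mbp = (hi - lo) / 1e6
        rate = cm_norm / mbp if mbp > 0 else 0.0
        rows.append((chromosome, dom, lo, hi, cm_raw[dom], cm_norm, rate))
    out = pd.DataFrame(rows, columns=["chromosome", "domain", "start_bp", "end_bp",
                                      "cm_raw", "cm_norm", "rate_cm_per_mbp"])
    out.attrs["factor"] = factor
    return out


def _arm_ratio_row(sub: pd.DataFrame) -> tuple[float, float, float]:
    arms = sub[sub["domain"].isin(("armA", "armB"))]
    phys = (arms["end_bp"] - arms["start_bp"]).to_numpy(dtype=float)
    gen = arms["cm_norm"].to_numpy(dtype=float)
    rate = arms["rate_cm_per_mbp"].to_numpy(dtype=float)

    def ratio(v):
        lo, hi = min(v), max(v)
        return float(hi / lo) if lo > 0 else np.inf

    return ratio(phys), ratio(gen), ratio(rate)


def build_domain_set(lmap: LinkageMap, chrom_lengths: dict,
                     target_cm: float = 50.0) -> DomainSet:
    """Segment every chromosome of a map into the five standard domains."""
    tables = []
    factors = {}
    ratio_rows = []
    for chrom in lmap.chromosomes:
        sl = lmap.chromosome_slice(chrom)
        tips = detect_tip_domains(sl, chrom_lengths[chrom])
        (_, tipa_hi), (tipb_lo, _) = tips
        interior = sl[(sl["physical_bp"] >= tipa_hi) & (sl["physical_bp"] <= tipb_lo)]
        fit = fit_domain_boundaries(interior)
        tab = domain_table(fit, tips, sl, chrom_lengths[chrom], chrom, target_cm)
        factors[chrom] = tab.attrs["factor"]
        tables.append(tab)
        ratio_rows.append((chrom, *_arm_ratio_row(tab)))
    table = pd.concat(tables, ignore_index=True)
    ratios = pd.DataFrame(ratio_rows, columns=["chromosome", "physical_ratio",
                                               "genetic_ratio", "rate_ratio"])
    return DomainSet(table=table, factors=factors, arm_ratios=ratios)


def domain_set_from_geometry(geometry: pd.DataFrame) -> DomainSet:
    """Build a DomainSet from a published per-chromosome geometry table.

    ``geometry`` follows the layout of ``reference.CB4_DOMAIN_GEOMETRY``
    (physical spans in Mbp; normalized major-domain cM summing to 50).
    """
    rows = []
    for _, g in geometry.iterrows():
        offset = 0.0
        cms = {"tipA": 0.0, "armA": g["armA_cm"], "center": g["center_cm"],
               "armB": g["armB_cm"], "tipB": 0.0}
        for dom in DOMAIN_ORDER:
            span = float(g[f"{dom}_mbp"]) * 1e6
            mbp = span / 1e6
            rate = cms[dom] / mbp if mbp > 0 else 0.0
            rows.append((g["chromosome"], dom, offset, offset + span,
                         np.nan, cms[dom], rate))
            offset += span
    table = pd.DataFrame(rows, columns=["chromosome", "domain", "start_bp", "end_bp",
                                        "cm_raw", "cm_norm", "rate_cm_per_mbp"])
    ratio_rows = [(c, *_arm_ratio_row(table[table["chromosome"] == c]))
                  for c in pd.unique(table["chromosome"])]
    ratios = pd.DataFrame(ratio_rows, columns=["chromosome", "physical_ratio",
                                               "genetic_ratio", "rate_ratio"])
    return DomainSet(table=table, factors={}, arm_ratios=ratios)


def compare_center_fraction(domains_a: DomainSet, domains_b: DomainSet) -> RegressionSummary:
    """Regress center-domain physical fractions of set A on those of set B.

    The fraction of a chromosome's physical length occupied by the central
    low-recombination domain is a candidate conserved feature; R-squared of
    this regression quantifies how predictive one map's state is of the
    other's.
    """
    fa = domains_a.center_fractions()
    fb = domains_b.center_fractions()
    shared = fa.index.intersection(fb.index)
    if len(shared) < 3:
        raise ValueError("need at least three shared chromosomes")
    y = fa.loc[shared].to_numpy(dtype=float)
    x = fb.loc[shared].to_numpy(dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return RegressionSummary(np.nan, np.nan, np.nan, len(shared), degenerate=True)
    res = stats.linregress(x, y)
    return RegressionSummary(slope=float(res.slope), intercept=float(res.intercept),
                             r_squared=float(res.rvalue ** 2), n=len(shared))
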