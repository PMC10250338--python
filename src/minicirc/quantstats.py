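"""qPCR absolute quantification, GC statistics and contour-length conversion.

Copy number per reaction from DNA mass: ``x * N_A / (l * 660e9)`` with x in
ng and l in bp (660 g/mol/bp double-stranded DNA).  PCR efficiency from a
standard-curve slope k (cycles per log10 copies): ``10**(-1/k) - 1``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seq import gc_fraction

AVOGADRO = 6.02214076e23
DSDNA_G_PER_MOL_BP = 660.0
BDNA_RISE_NM = 0.34


# ---------------------------------------------------------------------------
# copy number and standard curves


def copies_from_mass(x_ng: float, length_bp: float) -> float:
    """Molecule count in ``x_ng`` nanograms of dsDNA of ``length_bp`` bp."""
    if x_ng < 0:
        raise ValueError("DNA mass must be non-negative")
    if length_bp < 1:
        raise ValueError("template length must be >= 1 bp")
    return x_ng * AVOGADRO / (length_bp * DSDNA_G_PER_MOL_BP * 1e9)


@dataclass(frozen=True)
class QPCRMeasurement:
    sample_id: str
    gene: str
    cq: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.cq <= 0:
            raise ValueError(f"Cq must be positive, got {self.cq}")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10 copies for one gene."""

    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    cq_range: tuple[float, float]

    def copies_at(self, cq: float) -> float:
        """Interpolate absolute copies from a measured Cq."""
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def in_range(self, cq: float) -> bool:
        lo, hi = self.cq_range
        return lo <= cq <= hi


def efficiency_from_slope(slope: float) -> float:
    """PCR efficiency ``10**(-1/k) - 1``; 1.0 (100%) at k ~ -3.32."""
    if slope == 0:
        raise ValueError("slope must be non-zero")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    points: Sequence[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Fit a dilution series of (log10 copies, Cq) pairs by least squares."""
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("dilution series has zero variance in log10 copies")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope >= 0:
        warnings.warn(
            f"standard curve for {gene or 'gene'} has non-negative slope "
            f"{slope:.3f}; efficiency undefined",
            stacklevel=2,
        )
        efficiency = float("nan")
    else:
        efficiency = efficiency_from_slope(slope)
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=efficiency,
        cq_range=(float(y.min()), float(y.max())),
    )


@dataclass
class CopyRatioResult:
    per_gene: pd.DataFrame  # gene, mean_cq, copies, ratio, extrapolated
    mean_ratio: float
    sd_ratio: float
    nuclear_reference: str

    def summary(self) -> str:
        return f"{self.mean_ratio:.1f} ± {self.sd_ratio:.1f}-fold"


def copy_ratio(
    measurements: Sequence[QPCRMeasurement],
    curves: dict[str, StandardCurve],
    nuclear_reference: str,
) -> CopyRatioResult:
    """Mito:nuclear fold ratios from measured Cq values and per-gene curves.

    Replicate Cq values are averaged per gene before interpolation; the
    summary is mean +/- sample (n-1) standard deviation over the
    non-reference genes.  Cq values outside a curve's calibrated range are
    flagged as extrapolated.
    """
    genes = {m.gene for m in measurements}
    if nuclear_reference not in genes:
        raise ValueError(f"nuclear reference {nuclear_reference!r} not measured")
    missing = sorted(g for g in genes if g not in curves)
    if missing:
        raise ValueError(f"no standard curve for: {missing}")

    rows = []
    copies: dict[str, float] = {}
    for gene in sorted(genes):
        cqs = [m.cq for m in measurements if m.gene == gene]
        mean_cq = float(np.mean(cqs))
        curve = curves[gene]
        extrapolated = not curve.in_range(mean_cq)
        if extrapolated:
            warnings.warn(
                f"{gene}: mean Cq {mean_cq:.2f} outside calibrated range "
                f"{curve.cq_range}; extrapolating",
                stacklevel=2,
            )
        copies[gene] = curve.copies_at(mean_cq)
        rows.append(
            {
                "gene": gene,
                "mean_cq": mean_cq,
                "copies": copies[gene],
                "extrapolated": extrapolated,
            }
        )
    ref_copies = copies[nuclear_reference]
    per_gene = pd.DataFrame(rows)
    per_gene["ratio"] = per_gene["copies"] / ref_copies
    mito = per_gene[per_gene["gene"] != nuclear_reference]["ratio"].to_numpy()
    mean_ratio = float(np.mean(mito)) if mito.size else float("nan")
    sd_ratio = float(np.std(mito, ddof=1)) if mito.size > 1 else float("nan")
    return CopyRatioResult(per_gene, mean_ratio, sd_ratio, nuclear_reference)


# ---------------------------------------------------------------------------
# GC content and rank-sum comparison


def gc_content(seq: str) -> float:
    """GC fraction; N/ambiguity codes excluded, all-N flagged as nan."""
    if not seq:
        raise ValueError("empty sequence")
    value = gc_fraction(seq)
    if math.isnan(value):
        warnings.warn("sequence has no unambiguous bases; GC undefined", stacklevel=2)
    return value


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum W of group A (midranks)
    u_statistic: float
    pvalue: float
    method: str  # "exact" | "normal"


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 16,
    exact_max_min: int = 8,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The null distribution is enumerated exactly (all label assignments of
    the pooled midranks) when ``min(n) <= 8`` and ``n_a + n_b <= 16``;
    otherwise a normal approximation with tie correction and a 0.5
    continuity correction is used.  The exact two-sided p-value counts
    assignments at least as far from the mean rank sum as observed.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:na].sum())
    u_obs = w_obs - na * (na + 1) / 2.0
    mean_w = na * (na + nb + 1) / 2.0

    if min(na, nb) <= exact_max_min and na + nb <= exact_max_n:
        dev = abs(w_obs - mean_w)
        hits = 0
        total = 0
        for combo in itertools.combinations(range(na + nb), na):
            w = ranks[list(combo)].sum()
            if abs(w - mean_w) >= dev - 1e-9:
                hits += 1
            total += 1
        return RankSumResult(w_obs, u_obs, hits / total, "exact")

    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return RankSumResult(w_obs, u_obs, 1.0, "normal")
    mean_u = na * nb / 2.0
    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(stats.norm.sf(z)))
    return RankSumResult(w_obs, u_obs, p, "normal")


def gc_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankSumResult:
    """Rank-sum comparison of two sets of GC fractions."""
    return rank_sum_test(group_a, group_b)


# ---------------------------------------------------------------------------
# contour-length conversion


@dataclass(frozen=True)
class ContourResult:
    nm_per_bp: float | None
    bp_estimate: float | None
    fractional_extension: float | None

    def rounded_nm_per_bp(self, ndigits: int = 2) -> float:
        if self.nm_per_bp is None:
            raise ValueError("nm_per_bp not determined")
        return round(self.nm_per_bp, ndigits)


def contour_conversions(
    length_nm: float | None = None,
    bp: float | None = None,
    nm_per_bp: float | None = None,
    canonical_rise: float = BDNA_RISE_NM,
) -> ContourResult:
    """Convert between measured contour length, size in bp and nm/bp.

    Any two of the three quantities determine the third; fractional
    extension is the effective nm/bp over the canonical B-DNA rise of
    0.34 nm/bp.
    """
    provided = sum(v is not None for v in (length_nm, bp, nm_per_bp))
    if provided < 2:
        raise ValueError("need at least two of length_nm, bp, nm_per_bp")
    for name, v in (("length_nm", length_nm), ("bp", bp), ("nm_per_bp", nm_per_bp)):
        if v is not None and v <= 0:
            raise ValueError(f"{name} must be positive")
    if nm_per_bp is None:
        assert length_nm is not None and bp is not None
        nm_per_bp = length_nm / bp
    if bp is None and length_nm is not None:
        bp = length_nm / nm_per_bp
    return ContourResult(
        nm_per_bp=nm_per_bp,
        bp_estimate=bp,
        fractional_extension=nm_per_bp / canonical_rise,
    )
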