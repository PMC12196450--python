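"""Comparative statistics between candidate biomarkers.

Two complementary comparisons of biomarker performance:

* **Differential enrichment score.**  Treating the enrichment score as a
  correlation-like effect size, two biomarkers' scores are compared with the
  classic difference-of-correlations test: ``z = (atanh(es1) - atanh(es2)) /
  sqrt(1/(n1-3) + 1/(n2-3))`` with a two-sided normal p value, followed by
  Benjamini–Hochberg adjustment over the family of biomarker pairs.

* **Gene set enrichment fraction (GSEF).**  For each drug gene module, the
  fraction of its members present in a biomarker's enriched-gene list; the
  paired per-module fractions of two biomarkers are compared with the
  Wilcoxon signed-rank test (exact enumeration up to 25 informative pairs,
  normal approximation with continuity correction above).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "fisher_z",
    "differential_es_test",
    "bh_adjust",
    "gsef_fraction",
    "compare_gsef",
    "wilcoxon_signed_rank",
    "DifferentialESResult",
    "GSEFResult",
]

EXACT_WILCOXON_MAX_N = 25


def fisher_z(es: float) -> float:
    """Fisher z-transform (atanh) of a correlation-like score in (-1, 1)."""
    if abs(es) >= 1:
        raise ValueError(f"|es| must be < 1, got {es}")
    return math.atanh(es)


def differential_es_test(
    es1: float, n1: int, es2: float, n2: int
) -> tuple[float, float]:
    """Difference-of-correlations z test between two enrichment scores.

    Returns ``(z, raw_p)`` with a two-sided normal p value.  Positive z
    means the first score is the stronger association.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (fisher_z(es1) - fisher_z(es2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    raw_p = 2 * stats.norm.sf(abs(z))
    return z, float(raw_p)


@dataclass
class DifferentialESResult:
    biomarker_pair: tuple[str, str]
    es_ref: float
    es_other: float
    n_ref: int
    n_other: int
    z: float
    raw_p: float
    adjusted_p: float | None = None


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p values to adjust")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gsef_fraction(module: GeneSet, enriched_genes) -> float:
    """Fraction of a gene module's members found in an enriched-gene list."""
    if len(module) == 0:
        raise ValueError("empty module")
    enriched = set(enriched_genes)
    return sum(g in enriched for g in module.members) / len(module)


def _signed_rank_parts(diffs: np.ndarray, zero_method: str) -> tuple[np.ndarray, np.ndarray]:
    """Ranks of |differences| and their signs after zero handling.

    "wilcox" drops zero differences before ranking; "pratt" ranks them but
    excludes their ranks from both sums.
    """
    diffs = np.asarray(diffs, dtype=float)
    if zero_method == "wilcox":
        diffs = diffs[diffs != 0]
        ranks = stats.rankdata(np.abs(diffs))
        return ranks, np.sign(diffs)
    if zero_method == "pratt":
        ranks = stats.rankdata(np.abs(diffs))
        keep = diffs != 0
        return ranks[keep], np.sign(diffs[keep])
    raise ValueError(f"unknown zero_method {zero_method!r}")


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for the signed-rank statistic by full enumeration.

    Dynamic program over the 2^n equally likely sign assignments of the
    observed ranks (ranks doubled so midranks become integers); equivalent
    to enumerating every assignment but polynomial in total rank sum.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_pos))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def _approx_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = len(ranks)
    mean = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48
    if var <= 0:
        return 1.0
    num = abs(w_pos - mean) - 0.5
    z = max(num, 0.0) / math.sqrt(var)
    return float(min(1.0, 2 * stats.norm.sf(z)))


def wilcoxon_signed_rank(
    diffs,
    method: str = "auto",
    zero_method: str = "wilcox",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Returns ``(w_plus, two_sided_p)``.  ``method`` is "exact" (full
    enumeration of sign assignments), "approx" (normal approximation with
    continuity correction) or "auto" (exact up to 25 informative pairs).
    """
    ranks, signs = _signed_rank_parts(np.asarray(diffs, dtype=float), zero_method)
    n = len(ranks)
    if n == 0:
        raise ValueError("all differences are zero; test is degenerate")
    w_pos = float(ranks[signs > 0].sum())
    if method == "auto":
        method = "exact" if n <= EXACT_WILCOXON_MAX_N else "approx"
    if method == "exact":
        return w_pos, _exact_signed_rank_p(ranks, w_pos)
    if method == "approx":
        return w_pos, _approx_signed_rank_p(ranks, w_pos)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class GSEFResult:
    """Paired GSEF comparison between a reference and another biomarker."""

    biomarker_pair: tuple[str, str]
    module_names: list[str]
    fractions_ref: list[float]
    fractions_other: list[float]
    statistic: float
    p_value: float
    degenerate: bool
    fdr_value: float | None = None
    method: str = "auto"

    @property
    def per_module_fractions(self) -> list[tuple[float, float]]:
        return list(zip(self.fractions_ref, self.fractions_other))


def compare_gsef(
    modules: GeneSetCollection,
    enriched_ref,
    enriched_other,
    pair: tuple[str, str] = ("reference", "other"),
    method: str = "auto",
    zero_method: str = "wilcox",
) -> GSEFResult:
    """Compare two biomarkers' enriched-gene lists across drug gene modules.

    For every module the pair of enrichment fractions is computed; the
    paired differences go into the Wilcoxon signed-rank test.  When every
    difference is zero the result carries a degenerate flag and p = 1.
    """
    names = [m.name for m in modules]
    f_ref = [gsef_fraction(m, enriched_ref) for m in modules]
    f_other = [gsef_fraction(m, enriched_other) for m in modules]
    diffs = np.asarray(f_ref) - np.asarray(f_other)
    if np.all(diffs == 0):
        return GSEFResult(pair, names, f_ref, f_other, 0.0, 1.0, True, method=method)
    stat, p = wilcoxon_signed_rank(diffs, method=method, zero_method=zero_method)
    return GSEFResult(pair, names, f_ref, f_other, stat, p, False, method=method)
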