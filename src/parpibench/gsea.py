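"""Gene set enrichment analysis: ranking, enrichment score, permutation null.

The enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov–Smirnov-style running sum over a ranked gene list: walking the
list from top to bottom, the sum increases by ``|metric|^p`` (normalized over
set members) at each gene-set hit and decreases by ``1/(N - N_H)`` at each
miss.  Significance comes from a permutation null — either relabeling
samples ("phenotype") or drawing random member sets of equal size
("gene_set") — with the normalized ES (NES) scaled by the mean of the
same-signed null scores.  With a single gene set per run, the FDR q value
equals the nominal permutation p value.

ES behaves like a correlation-type effect size between phenotype and gene
set, which is what licenses the Fisher-z differential comparison in
:mod:`parpibench.compare`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix, PhenotypeLabels
from .genesets import GeneSet

__all__ = [
    "GSEAConfig",
    "RankedList",
    "GSEAResult",
    "rank_by_signal_to_noise",
    "enrichment_score",
    "permutation_null",
    "score_gene_set",
]

_PERM_BATCH = 256  # permutations scored per vectorized block


@dataclass
class GSEAConfig:
    """Settings for one enrichment run.

    n_perm: size of the permutation null (1000 reproduces tool defaults).
    permutation_type: "phenotype" (relabel samples) or "gene_set" (random
        member sets of equal size).
    weight_p: running-sum weight exponent; 1 is the standard weighted form,
        0 the classic Kolmogorov–Smirnov statistic.
    min_class_size: smallest class allowed for the signal-to-noise metric.
    """

    n_perm: int = 1000
    permutation_type: str = "phenotype"
    weight_p: float = 1.0
    seed: int = 0
    min_class_size: int = 3

    def __post_init__(self) -> None:
        if self.permutation_type not in {"phenotype", "gene_set"}:
            raise ValueError(f"unknown permutation type {self.permutation_type!r}")
        if self.n_perm < 10:
            raise ValueError("n_perm must be at least 10")


@dataclass
class RankedList:
    """Genes ordered by ranking metric, descending; ties broken by gene id."""

    gene_ids: list[str]
    metric_values: np.ndarray

    def __post_init__(self) -> None:
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if len(self.gene_ids) != len(self.metric_values):
            raise ValueError("gene_ids and metric_values differ in length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.metric_values) > 0):
            raise ValueError("metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GSEAResult:
    """One gene set x one phenotype enrichment outcome."""

    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str]
    n_permutations: int
    permutation_type: str
    seed: int
    gene_set_size: int
    n_samples: int
    running_sum: np.ndarray = field(repr=False, default=None)

    def p_display(self) -> str:
        """Nominal p formatted as in standard enrichment reports."""
        floor = 1.0 / (self.n_permutations + 1)
        return "<0.001" if self.nominal_p <= floor and floor < 0.001 else f"{self.nominal_p:.3f}"


def _signal_to_noise(
    values: np.ndarray, masks: np.ndarray, sd_floor_frac: float = 0.2, sd_floor_abs: float = 0.2
) -> np.ndarray:
    """Signal-to-noise ratio for each gene under each class assignment.

    values: genes x samples; masks: k x samples boolean (True = class A).
    Returns genes x k.  Each class standard deviation is floored at
    ``max(sd_floor_frac * |mean|, sd_floor_abs)``, the convention of the
    reference GSEA implementation, which keeps low-variance genes from
    dominating the ranking.
    """
    masks = np.atleast_2d(masks)
    n_a = masks.sum(axis=1, dtype=float)
    n_b = masks.shape[1] - n_a
    sum_a = values @ masks.T
    sumsq_a = (values**2) @ masks.T
    sum_all = values.sum(axis=1, keepdims=True)
    sumsq_all = (values**2).sum(axis=1, keepdims=True)
    mean_a = sum_a / n_a
    mean_b = (sum_all - sum_a) / n_b
    var_a = (sumsq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (sumsq_all - sumsq_a - n_b * mean_b**2) / (n_b - 1)
    sd_a = np.sqrt(np.clip(var_a, 0.0, None))
    sd_b = np.sqrt(np.clip(var_b, 0.0, None))
    sd_a = np.maximum(sd_a, np.maximum(sd_floor_frac * np.abs(mean_a), sd_floor_abs))
    sd_b = np.maximum(sd_b, np.maximum(sd_floor_frac * np.abs(mean_b), sd_floor_abs))
    return (mean_a - mean_b) / (sd_a + sd_b)


def rank_by_signal_to_noise(
    matrix: ExpressionMatrix, labels: PhenotypeLabels, min_class_size: int = 3
) -> RankedList:
    """Rank genes by signal-to-noise between the two phenotype classes.

    The positive class is the numerator, so a positive metric means higher
    expression in the positive class.  Ties are broken lexicographically by
    gene id for determinism.
    """
    labels = labels.subset_to(matrix.sample_ids)
    counts = labels.n_per_class
    small = [c for c, k in counts.items() if k < min_class_size]
    if small:
        raise ValueError(
            f"class(es) {small} have fewer than {min_class_size} samples; "
            "use gene_set permutation with a correlation metric instead"
        )
    values = matrix.values[labels.sample_ids].to_numpy(dtype=float)
    metric = _signal_to_noise(values, labels.mask())[:, 0]
    gene_ids = np.asarray(matrix.gene_ids)
    lex = np.argsort(gene_ids, kind="stable")
    order = lex[np.argsort(-metric[lex], kind="stable")]
    return RankedList(list(gene_ids[order]), metric[order])


def _es_from_ordered(
    metric: np.ndarray, member: np.ndarray, weight_p: float
) -> tuple[np.ndarray, np.ndarray]:
    """ES and running sums for already-ordered metric/membership columns.

    metric, member: N x k arrays, rows in ranked order.  Returns (es[k],
    running_sum[N x k]).
    """
    n, k = metric.shape
    n_hit = member.sum(axis=0)
    n_miss = n - n_hit
    weights = np.where(member, np.abs(metric) ** weight_p, 0.0)
    hit_totals = weights.sum(axis=0)
    if np.any(hit_totals == 0):
        raise ValueError(
            "all in-set metric values are zero; the weighted running sum "
            "is undefined (use weight_p = 0)"
        )
    p_hit = np.cumsum(weights, axis=0) / hit_totals
    p_miss = np.cumsum(~member, axis=0) / n_miss
    running = p_hit - p_miss
    idx = np.argmax(np.abs(running), axis=0)
    es = running[idx, np.arange(k)]
    return es, running


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted running-sum enrichment score for one ranked list and set.

    Returns ``(es, running_sum, hit_indices)`` where ``running_sum[i]`` is
    the deviation after position i and ``hit_indices`` are the 0-based ranks
    of gene-set members.
    """
    members = set(gene_set.members)
    member = np.asarray([g in members for g in ranked.gene_ids])
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ranked list")
    if n_hit == len(ranked):
        raise ValueError("gene set covers the entire ranked list (no misses)")
    es, running = _es_from_ordered(
        ranked.metric_values[:, None], member[:, None], weight_p
    )
    return float(es[0]), running[:, 0], np.flatnonzero(member)


def _phenotype_null(
    values: np.ndarray,
    gene_order_lex: np.ndarray,
    observed_mask: np.ndarray,
    member_by_gene: np.ndarray,
    n_perm: int,
    weight_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES sample from random relabelings of samples."""
    n_samples = values.shape[1]
    n_pos = int(observed_mask.sum())
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_PERM_BATCH, n_perm - done)
        masks = np.zeros((k, n_samples), dtype=bool)
        for i in range(k):
            masks[i, rng.choice(n_samples, size=n_pos, replace=False)] = True
        metric = _signal_to_noise(values, masks)  # genes x k
        metric = metric[gene_order_lex]
        order = np.argsort(-metric, axis=0, kind="stable")
        metric_sorted = np.take_along_axis(metric, order, axis=0)
        member_sorted = member_by_gene[gene_order_lex][order]
        es, _ = _es_from_ordered(metric_sorted, member_sorted, weight_p)
        out[done : done + k] = es
        done += k
    return out


def _gene_set_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    weight_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES sample from random member sets of equal size."""
    n = len(ranked)
    metric = np.repeat(ranked.metric_values[:, None], 1, axis=1)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_PERM_BATCH, n_perm - done)
        member = np.zeros((n, k), dtype=bool)
        for i in range(k):
            member[rng.choice(n, size=set_size, replace=False), i] = True
        es, _ = _es_from_ordered(np.broadcast_to(metric, (n, k)), member, weight_p)
        out[done : done + k] = es
        done += k
    return out


def permutation_null(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_set: GeneSet,
    config: GSEAConfig,
) -> np.ndarray:
    """Generate the null ES sample for one run; reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    labels = labels.subset_to(matrix.sample_ids)
    if config.permutation_type == "phenotype":
        if labels.degenerate:
            raise ValueError("degenerate phenotype: one class is empty")
        values = matrix.values[labels.sample_ids].to_numpy(dtype=float)
        gene_ids = np.asarray(matrix.gene_ids)
        lex = np.argsort(gene_ids, kind="stable")
        members = set(gene_set.members)
        member_by_gene = np.asarray([g in members for g in gene_ids])
        return _phenotype_null(
            values, lex, labels.mask(), member_by_gene,
            config.n_perm, config.weight_p, rng,
        )
    ranked = rank_by_signal_to_noise(matrix, labels, config.min_class_size)
    members = set(gene_set.members)
    set_size = sum(g in members for g in ranked.gene_ids)
    if set_size == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")
    return _gene_set_null(ranked, set_size, config.n_perm, config.weight_p, rng)


def score_gene_set(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_set: GeneSet,
    config: GSEAConfig | None = None,
) -> GSEAResult:
    """Full enrichment analysis of one gene set against one phenotype.

    The nominal p value is the add-one fraction of same-signed null scores
    at least as extreme as the observed ES; NES divides the ES by the mean
    magnitude of the same-signed null scores.  With a single gene set the
    FDR q value equals the nominal p value.
    """
    config = config or GSEAConfig()
    labels = labels.subset_to(matrix.sample_ids)
    ranked = rank_by_signal_to_noise(matrix, labels, config.min_class_size)
    es, running, hit_idx = enrichment_score(ranked, gene_set, config.weight_p)
    null = permutation_null(matrix, labels, gene_set, config)
    same_sign = null[null > 0] if es >= 0 else null[null < 0]
    r = int(np.sum(np.abs(same_sign) >= abs(es)))
    nominal_p = (r + 1) / (len(same_sign) + 1)
    nes = es / np.mean(np.abs(same_sign)) if len(same_sign) else float("nan")
    extremum = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = [ranked.gene_ids[i] for i in hit_idx if i <= extremum]
    else:
        leading = [ranked.gene_ids[i] for i in hit_idx if i >= extremum]
    return GSEAResult(
        es=float(es),
        nes=float(nes),
        nominal_p=float(nominal_p),
        fdr_q=float(nominal_p),
        leading_edge=leading,
        n_permutations=config.n_perm,
        permutation_type=config.permutation_type,
        seed=config.seed,
        gene_set_size=len(hit_idx),
        n_samples=labels.n,
        running_sum=running,
    )
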