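"""Synthetic cohorts with known ground truth.

The generator produces the three substrates of the analysis — copy-number
segment profiles, an expression matrix with a mean-shifted planted gene set,
and binary biomarker labels with a controllable association to the planted
enrichment — so that every stage of the pipeline can be exercised and its
recovery of the planted signal verified.

Segment profiles are planted so that each scar scorer recovers its count
exactly, by construction:

* an LST arm carries exactly one qualifying breakpoint (two flanks >= 10 Mb
  in different copy states);
* a TAI arm is a whole-arm allelic imbalance (major 2 / minor 1) touching
  its telomere and stopping at the centromere;
* an LOH arm carries one interstitial copy-neutral LOH region (major 2 /
  minor 0) flanked by short (< 10 Mb) heterozygous pieces so it creates no
  large-scale transition and reaches no telomere;
* the remaining arms receive short (< 10 Mb) "filler" gains that tune the
  fraction of genome altered to a target without touching any count.

Only autosomes are simulated.  The construction is deliberately schematic —
no purity/ploidy mixtures, no breakpoint clustering — which is exactly what
makes the ground truth unambiguous.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, PhenotypeLabels
from .genesets import GeneSet, GeneSetCollection
from .genome import GenomeBuild, load_hg19
from .segments import Segment, SegmentProfile

__all__ = [
    "BiomarkerSpec",
    "SegmentSpec",
    "CohortSpec",
    "simulate_expression",
    "simulate_biomarker_labels",
    "simulate_segments",
    "simulate_drug_modules",
]

MB = 1_000_000

# feature geometry (bp): sizes chosen so each feature qualifies for exactly
# the score it plants and disqualifies for every other rule
_LST_ALTERED_LEN = 12 * MB      # >= 10 Mb flank on the gained side
_LST_MIN_ARM = 24 * MB          # both flanks >= 10 Mb after a 12 Mb gain
_TAI_MIN_ARM = int(11.5 * MB)   # whole-arm imbalance >= 11 Mb
_LOH_FLANK = 5 * MB             # < 10 Mb: no LST; >= 3 Mb: survives smoothing
_LOH_MIN_ARM = 26 * MB          # interstitial LOH > 15 Mb plus two flanks
_FILLER_LEN = int(9.5 * MB)     # < 10 Mb: never an LST flank
_FILLER_GAP = 3 * MB            # >= 3 Mb: smoothing keeps the gap
_FILLER_MIN = 3 * MB


@dataclass
class BiomarkerSpec:
    """One synthetic biomarker: name, prevalence and link to enrichment.

    ``association`` in [0, 1]: with this probability a sample's biomarker
    label copies its enrichment-class label; otherwise it is drawn
    independently with ``positive_fraction``.  1 gives a perfect surrogate,
    0 an uninformative label.
    """

    name: str
    positive_fraction: float = 0.5
    association: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0 <= self.association <= 1:
            raise ValueError("association must be in [0, 1]")


@dataclass
class SegmentSpec:
    """Planted scar counts and altered-fraction target for one class."""

    k_lst: int = 0
    k_tai: int = 0
    k_loh: int = 0
    fga_target: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k_lst, self.k_tai, self.k_loh) < 0:
            raise ValueError("planted counts must be non-negative")
        if not 0 <= self.fga_target < 1:
            raise ValueError("fga_target must be in [0, 1)")


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 120
    n_genes: int = 1000
    planted_gene_set_size: int = 50
    enrichment_shift: float = 1.0
    positive_fraction: float = 0.5
    class_names: tuple[str, str] = ("enriched", "other")
    biomarker_specs: list[BiomarkerSpec] = field(default_factory=list)
    segment_specs: dict[str, SegmentSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_gene_set_size > self.n_genes:
            raise ValueError("planted gene set larger than the gene universe")
        if self.enrichment_shift < 0:
            raise ValueError("enrichment_shift must be >= 0")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")


def _class_labels(spec: CohortSpec) -> PhenotypeLabels:
    n_pos = round(spec.positive_fraction * spec.n_samples)
    pos, neg = spec.class_names
    labels = [pos] * n_pos + [neg] * (spec.n_samples - n_pos)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    return PhenotypeLabels(samples, labels, (pos, neg))


def simulate_expression(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, GeneSet, PhenotypeLabels]:
    """Expression matrix with a planted mean-shifted gene set.

    Baseline values are i.i.d. standard normal; members of the planted set
    are shifted by ``enrichment_shift`` (in SD units) in the positive class.
    Ground-truth gene set and class labels are returned for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _class_labels(spec)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    values = rng.standard_normal((spec.n_genes, spec.n_samples))
    planted_idx = rng.choice(spec.n_genes, size=spec.planted_gene_set_size, replace=False)
    pos_mask = labels.mask()
    values[np.ix_(planted_idx, np.flatnonzero(pos_mask))] += spec.enrichment_shift
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=labels.sample_ids)
    )
    planted = GeneSet(
        "planted_set", "ground-truth shifted genes", sorted(genes[i] for i in planted_idx)
    )
    return matrix, planted, labels


def simulate_biomarker_labels(
    spec: CohortSpec, enrichment_labels: PhenotypeLabels
) -> dict[str, PhenotypeLabels]:
    """Binary biomarker labels tied to the enrichment class.

    Per biomarker, each sample copies its enrichment label with probability
    ``association`` and otherwise draws an independent Bernoulli label.
    The random stream is derived from the cohort seed and the biomarker
    name, so adding a biomarker does not perturb the others.
    """
    out: dict[str, PhenotypeLabels] = {}
    enriched_mask = enrichment_labels.mask()
    for bm in spec.biomarker_specs:
        rng = np.random.default_rng(
            [spec.seed, zlib.crc32(bm.name.encode()) % (2**31)]
        )
        copy = rng.random(enrichment_labels.n) < bm.association
        indep = rng.random(enrichment_labels.n) < bm.positive_fraction
        positive = np.where(copy, enriched_mask, indep)
        pos, neg = f"{bm.name}_pos", f"{bm.name}_neg"
        out[bm.name] = PhenotypeLabels(
            enrichment_labels.sample_ids,
            [pos if x else neg for x in positive],
            (pos, neg),
        )
    return out


# --- segment profiles ------------------------------------------------------

def _neutral(chrom: str, start: int, end: int) -> Segment:
    return Segment(chrom, start, end, 0.0, 1, 1)


def _plant_arm_lst(chrom: str, astart: int, aend: int) -> tuple[list[Segment], int]:
    """Two-segment arm with one qualifying breakpoint; returns altered bp."""
    split = aend - _LST_ALTERED_LEN
    return (
        [
            _neutral(chrom, astart, split),
            Segment(chrom, split + 1, aend, 1.0, 2, 2),
        ],
        _LST_ALTERED_LEN,
    )


def _plant_arm_tai(chrom: str, astart: int, aend: int) -> tuple[list[Segment], int]:
    """Whole-arm telomeric allelic imbalance (major 2 / minor 1)."""
    return [Segment(chrom, astart, aend, 0.585, 2, 1)], aend - astart + 1


def _plant_arm_loh(chrom: str, astart: int, aend: int) -> tuple[list[Segment], int]:
    """Interstitial copy-neutral LOH flanked by short heterozygous pieces."""
    return (
        [
            _neutral(chrom, astart, astart + _LOH_FLANK - 1),
            Segment(chrom, astart + _LOH_FLANK, aend - _LOH_FLANK, 0.0, 2, 0),
            _neutral(chrom, aend - _LOH_FLANK + 1, aend),
        ],
        0,
    )


def _plant_arm_filler(
    chrom: str, astart: int, aend: int, budget: int
) -> tuple[list[Segment], int]:
    """Short interleaved gains on one arm, consuming up to ``budget`` bp."""
    segs: list[Segment] = []
    altered = 0
    pos = astart
    lead = pos + _FILLER_GAP - 1
    segs.append(_neutral(chrom, pos, lead))
    pos = lead + 1
    while budget - altered >= _FILLER_MIN and pos + _FILLER_MIN - 1 + _FILLER_GAP <= aend:
        flen = min(_FILLER_LEN, budget - altered, aend - pos + 1 - _FILLER_GAP)
        if flen < _FILLER_MIN:
            break
        segs.append(Segment(chrom, pos, pos + flen - 1, 1.0, 2, 2))
        altered += flen
        pos += flen
        gap_end = min(pos + _FILLER_GAP - 1, aend)
        segs.append(_neutral(chrom, pos, gap_end))
        pos = gap_end + 1
    if pos <= aend:
        segs.append(_neutral(chrom, pos, aend))
    return segs, altered


def _simulate_one_profile(
    sample_id: str,
    seg_spec: SegmentSpec,
    build: GenomeBuild,
    rng: np.random.Generator,
    fga_tolerance: float = 0.02,
) -> SegmentProfile:
    arms = build.arms(autosomes_only=True)
    total_assayed = sum(e - s + 1 for _, _, s, e in arms)
    order = rng.permutation(len(arms))
    arms = [arms[i] for i in order]

    plan: list[tuple[str, tuple]] = []
    remaining = list(arms)

    def take(min_len: int, feature: str):
        # smallest adequate arm, so long arms stay available as FGA filler
        fits = [i for i, (_, _, s, e) in enumerate(remaining) if e - s + 1 >= min_len]
        if fits:
            i = min(fits, key=lambda i: remaining[i][3] - remaining[i][2])
            return remaining.pop(i)
        raise ValueError(
            f"{sample_id}: no arm of at least {min_len / MB:.0f} Mb left "
            f"for planting a {feature} event"
        )

    for _ in range(seg_spec.k_loh):
        plan.append(("loh", take(_LOH_MIN_ARM, "LOH")))
    for _ in range(seg_spec.k_lst):
        plan.append(("lst", take(_LST_MIN_ARM, "LST")))
    for _ in range(seg_spec.k_tai):
        plan.append(("tai", take(_TAI_MIN_ARM, "TAI")))

    segments: list[Segment] = []
    altered = 0
    for feature, (chrom, arm, s, e) in plan:
        planter = {"lst": _plant_arm_lst, "tai": _plant_arm_tai, "loh": _plant_arm_loh}[feature]
        segs, alt = planter(chrom, s, e)
        segments.extend(segs)
        altered += alt

    target_altered = int(seg_spec.fga_target * total_assayed)
    budget = target_altered - altered
    if budget < -fga_tolerance * total_assayed:
        raise ValueError(
            f"{sample_id}: planted events alter {altered / total_assayed:.3f} "
            f"of the genome, above fga_target {seg_spec.fga_target}"
        )
    for chrom, arm, s, e in remaining:
        if budget >= _FILLER_MIN:
            segs, alt = _plant_arm_filler(chrom, s, e, budget)
            budget -= alt
        else:
            segs = [_neutral(chrom, s, e)]
        segments.extend(segs)
    if budget > fga_tolerance * total_assayed:
        raise ValueError(
            f"{sample_id}: filler capacity exhausted {budget / total_assayed:.3f} "
            f"short of fga_target {seg_spec.fga_target}"
        )
    return SegmentProfile(sample_id, segments, build)


def simulate_segments(
    spec: CohortSpec,
    class_of_sample: dict[str, str] | None = None,
    build: GenomeBuild | None = None,
) -> tuple[list[SegmentProfile], pd.DataFrame]:
    """Segment profiles with planted scar counts, plus a ground-truth table.

    ``class_of_sample`` maps sample ids to the class names keyed in
    ``spec.segment_specs``; by default the cohort's enrichment classes are
    used.  The returned table records the planted (k_lst, k_tai, k_loh,
    fga_target) per sample.
    """
    if spec.segment_specs is None:
        raise ValueError("spec.segment_specs is not set")
    build = build or load_hg19()
    if class_of_sample is None:
        labels = _class_labels(spec)
        class_of_sample = dict(zip(labels.sample_ids, labels.labels))
    rng = np.random.default_rng([spec.seed, 7])
    profiles = []
    truth_rows = []
    for sample_id, cls in class_of_sample.items():
        if cls not in spec.segment_specs:
            raise ValueError(f"no SegmentSpec for class {cls!r}")
        seg_spec = spec.segment_specs[cls]
        profiles.append(_simulate_one_profile(sample_id, seg_spec, build, rng))
        truth_rows.append(
            {
                "sample_id": sample_id,
                "class": cls,
                "k_lst": seg_spec.k_lst,
                "k_tai": seg_spec.k_tai,
                "k_loh": seg_spec.k_loh,
                "fga_target": seg_spec.fga_target,
            }
        )
    return profiles, pd.DataFrame(truth_rows).set_index("sample_id")


def simulate_drug_modules(
    planted: GeneSet,
    universe: list[str],
    n_modules: int = 22,
    module_size_range: tuple[int, int] = (20, 60),
    overlap_with_planted: float = 0.5,
    seed: int = 0,
) -> GeneSetCollection:
    """Drug gene modules drawing a controlled fraction from the planted set.

    Emulates a panel of drug-perturbation signatures: each module takes
    ``overlap_with_planted`` of its members from the planted gene set and
    the rest from the remaining gene universe.
    """
    rng = np.random.default_rng([seed, 11])
    outside = sorted(set(universe) - set(planted.members))
    lo, hi = module_size_range
    if hi > len(planted.members) + len(outside):
        raise ValueError("module size exceeds the gene universe")
    sets = []
    for i in range(n_modules):
        size = int(rng.integers(lo, hi + 1))
        n_in = round(overlap_with_planted * size)
        n_in = min(n_in, len(planted.members))
        n_out = min(size - n_in, len(outside))
        members = list(rng.choice(planted.members, size=n_in, replace=False)) + list(
            rng.choice(outside, size=n_out, replace=False)
        )
        sets.append(GeneSet(f"parpi_module_{i + 1:02d}", "synthetic drug module", members))
    return GeneSetCollection(sets)
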