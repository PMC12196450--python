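"""Genomic scar scores from copy-number segment profiles.

These scores quantify the chromosomal-instability footprint of a tumour
genome and are the standard surrogates for homologous-recombination
deficiency (HRD):

* **LST** — large-scale state transitions: breakpoints between adjacent
  segments that each span at least 10 Mb, counted per chromosome arm after
  smoothing away segments shorter than 3 Mb.
* **TAI** — telomeric allelic imbalance: regions of unequal major/minor
  allele copy number that reach a telomere without crossing the centromere.
* **LOH** — loss-of-heterozygosity regions (minor copy number 0) longer than
  15 Mb but shorter than a whole chromosome.
* **HRD** — the sum LST + TAI + LOH.
* **FGA** — fraction of the assayed genome whose |log2 ratio| exceeds a
  threshold (cBioPortal-style definition).
* **Aneuploidy** — number of chromosome arms altered over at least half of
  their assayed length.

TAI and LOH require allele-specific (e.g. ASCAT) copy numbers; without them
only LST, FGA and aneuploidy are available and HRD cannot be formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import PhenotypeLabels
from .segments import Segment, SegmentProfile, smooth_segments

__all__ = [
    "ScarScores",
    "compute_lst",
    "compute_tai",
    "compute_loh",
    "compute_hrd",
    "compute_fga",
    "compute_aneuploidy",
    "score_profile",
    "score_table",
    "dichotomize_score",
]

MB = 1_000_000


@dataclass
class ScarScores:
    """Per-sample scar scores; TAI/LOH/HRD are None without allele data."""

    sample_id: str
    lst: int
    fga: float
    aneuploidy: int | None = None
    tai: int | None = None
    loh: int | None = None

    @property
    def hrd(self) -> int | None:
        if self.tai is None or self.loh is None:
            return None
        return self.lst + self.tai + self.loh


def _require_allele(profile: SegmentProfile) -> None:
    if not profile.has_allele_data:
        raise ValueError(
            f"{profile.sample_id}: allele-specific data required "
            "(major_cn/minor_cn missing on some segments)"
        )


def _clip_to_arm(seg: Segment, start: int, end: int) -> Segment | None:
    """Restrict a segment to an arm interval, or None if disjoint."""
    if seg.end < start or seg.start > end:
        return None
    if seg.start >= start and seg.end <= end:
        return seg
    from dataclasses import replace

    return replace(seg, start=max(seg.start, start), end=min(seg.end, end))


def compute_lst(
    profile: SegmentProfile,
    min_segment_mb: float = 10.0,
    smoothing_mb: float = 3.0,
    cn_equivalence_tolerance: float = 0.1,
) -> int:
    """Count large-scale state transitions.

    Segments are clipped to chromosome arms (a breakpoint falling in the
    centromere gap is never counted), short segments are smoothed away, and
    each junction whose two flanking segments both span at least
    ``min_segment_mb`` and differ in copy state adds one to the count.
    """
    if len(profile) == 0:
        raise ValueError(f"{profile.sample_id}: empty profile")
    by_chrom = profile.by_chrom()
    count = 0
    for chrom, arm, astart, aend in profile.build.arms():
        segs = [
            c
            for s in by_chrom.get(chrom, [])
            if (c := _clip_to_arm(s, astart, aend)) is not None
        ]
        if len(segs) < 2:
            continue
        arm_profile = smooth_segments(
            SegmentProfile(profile.sample_id, segs, profile.build),
            int(smoothing_mb * MB),
            cn_equivalence_tolerance,
        )
        segs = arm_profile.segments
        for left, right in zip(segs, segs[1:]):
            if (
                left.length >= min_segment_mb * MB
                and right.length >= min_segment_mb * MB
                and not left.same_state(right, cn_equivalence_tolerance)
            ):
                count += 1
    return count


def _imbalance_runs(segs: list[Segment], predicate) -> list[tuple[int, int]]:
    """Maximal runs of consecutive segments satisfying ``predicate``."""
    runs = []
    i = 0
    while i < len(segs):
        if predicate(segs[i]):
            j = i
            while j + 1 < len(segs) and predicate(segs[j + 1]):
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def compute_tai(profile: SegmentProfile, min_mb: float = 11.0) -> int:
    """Count telomeric allelic-imbalance regions.

    A region is a maximal run of segments with unequal major/minor copy
    number that (i) includes the first or last assayed segment of its
    chromosome, (ii) does not cross the centromere, and (iii) spans at
    least ``min_mb``.
    """
    _require_allele(profile)
    count = 0
    for chrom, segs in profile.by_chrom().items():
        cen = profile.build[chrom]
        for i, j in _imbalance_runs(segs, lambda s: s.is_imbalanced):
            start, end = segs[i].start, segs[j].end
            telomeric = i == 0 or j == len(segs) - 1
            crosses_cen = start <= cen.centromere_start and end >= cen.centromere_end
            if telomeric and not crosses_cen and end - start + 1 >= min_mb * MB:
                count += 1
    return count


def compute_loh(profile: SegmentProfile, min_mb: float = 15.0) -> int:
    """Count loss-of-heterozygosity regions longer than ``min_mb``.

    LOH means minor copy number 0 with at least one copy retained; runs
    covering every assayed segment of a chromosome (whole-chromosome LOH)
    are excluded, following the HRD-LOH convention.
    """
    _require_allele(profile)
    count = 0
    for chrom, segs in profile.by_chrom().items():
        runs = _imbalance_runs(
            segs, lambda s: s.minor_cn == 0 and s.major_cn >= 1
        )
        for i, j in runs:
            if i == 0 and j == len(segs) - 1:
                continue  # whole-chromosome event
            if segs[j].end - segs[i].start + 1 > min_mb * MB:
                count += 1
    return count


def compute_hrd(lst: int | None, tai: int | None, loh: int | None) -> int:
    """Aggregate HRD score: LST + TAI + LOH; all three must be present."""
    if lst is None or tai is None or loh is None:
        raise ValueError("HRD requires LST, TAI and LOH (allele-specific data)")
    return lst + tai + loh


def compute_fga(profile: SegmentProfile, log2_threshold: float = 0.2) -> float:
    """Fraction of assayed genome altered: |log2 ratio| > threshold.

    The denominator is the total length of assayed segments, so unassayed
    chromosomes contribute to neither numerator nor denominator.
    """
    total = profile.total_length()
    if total == 0:
        raise ValueError(f"{profile.sample_id}: no assayed segments")
    altered = sum(
        s.length for s in profile.segments if abs(s.log2_ratio) > log2_threshold
    )
    return altered / total


#: p arms carrying only rDNA/heterochromatin; excluded from the standard
#: 39-arm autosomal aneuploidy score
_ACROCENTRIC_P = {"chr13p", "chr14p", "chr15p", "chr21p", "chr22p"}


def compute_aneuploidy(
    profile: SegmentProfile,
    arm_fraction: float = 0.5,
    log2_threshold: float = 0.2,
    autosomes_only: bool = True,
    exclude_acrocentric_p: bool = True,
) -> int:
    """Count chromosome arms with an arm-level gain or loss.

    An arm counts when gained length or lost length (|log2| past the
    threshold, same direction) covers at least ``arm_fraction`` of the
    arm's assayed length.  The default scope is the standard 39-arm
    autosomal convention: sex chromosomes and the five acrocentric p arms
    (chr13/14/15/21/22) are left out.
    """
    by_chrom = profile.by_chrom()
    count = 0
    for chrom, arm, astart, aend in profile.build.arms(autosomes_only=autosomes_only):
        if exclude_acrocentric_p and arm in _ACROCENTRIC_P:
            continue
        gained = lost = assayed = 0
        for s in by_chrom.get(chrom, []):
            c = _clip_to_arm(s, astart, aend)
            if c is None:
                continue
            assayed += c.length
            if c.log2_ratio > log2_threshold:
                gained += c.length
            elif c.log2_ratio < -log2_threshold:
                lost += c.length
        if assayed and max(gained, lost) >= arm_fraction * assayed:
            count += 1
    return count


def score_profile(profile: SegmentProfile, **kwargs) -> ScarScores:
    """Compute all available scar scores for one profile."""
    scores = ScarScores(
        sample_id=profile.sample_id,
        lst=compute_lst(profile),
        fga=compute_fga(profile),
        aneuploidy=compute_aneuploidy(profile),
    )
    if profile.has_allele_data:
        scores.tai = compute_tai(profile)
        scores.loh = compute_loh(profile)
    return scores


def score_table(profiles: list[SegmentProfile]) -> pd.DataFrame:
    """Per-sample scar-score table (columns: lst, tai, loh, hrd, fga, aneuploidy)."""
    rows = []
    for p in profiles:
        s = score_profile(p)
        rows.append(
            {
                "sample_id": s.sample_id,
                "lst": s.lst,
                "tai": s.tai,
                "loh": s.loh,
                "hrd": s.hrd,
                "fga": s.fga,
                "aneuploidy": s.aneuploidy,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def dichotomize_score(
    values: pd.Series,
    threshold: float,
    high_is: str = "ge",
    class_names: tuple[str, str] = ("high", "low"),
) -> PhenotypeLabels:
    """Split a continuous score into high/low phenotype classes.

    ``high_is="ge"`` assigns values >= threshold to the first (high) class;
    ``"gt"`` uses a strict inequality, which makes a median split send ties
    to "low".  A split with an empty class is flagged degenerate and is
    unusable as a GSEA phenotype.
    """
    if values.isna().any():
        raise ValueError("missing values; drop them before dichotomizing")
    if high_is not in {"ge", "gt"}:
        raise ValueError("high_is must be 'ge' or 'gt'")
    op = values.ge(threshold) if high_is == "ge" else values.gt(threshold)
    high, low = class_names
    labels = pd.Series([high if x else low for x in op], index=values.index)
    return PhenotypeLabels(
        sample_ids=list(values.index),
        labels=list(labels),
        classes=(high, low),
    )
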