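"""Copy-number segment model and SEG file I/O.

A :class:`SegmentProfile` is one sample's ordered, non-overlapping copy-number
segments on a :class:`~parpibench.genome.GenomeBuild`.  Segments carry a log2
copy ratio and, when allele-specific calls are available (e.g. from ASCAT),
integer major/minor copy numbers.  The log2 ratio drives the fraction-genome-
altered and aneuploidy scores; the allele-specific fields drive telomeric
allelic imbalance and loss-of-heterozygosity counts; large-scale state
transitions use whichever state representation is present.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .genome import GenomeBuild, normalize_chrom

__all__ = ["Segment", "SegmentProfile", "read_seg", "write_seg", "smooth_segments"]

#: merge tolerance on |delta log2| when integer copy numbers are absent
DEFAULT_CN_TOLERANCE = 0.1


@dataclass(frozen=True)
class Segment:
    """One copy-number segment; coordinates 1-based inclusive."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    major_cn: int | None = None
    minor_cn: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: start > end"
            )
        if (self.major_cn is None) != (self.minor_cn is None):
            raise ValueError("major_cn and minor_cn must be given together")
        if self.major_cn is not None:
            if self.major_cn < 0 or self.minor_cn < 0:
                raise ValueError("negative copy number")
            if self.major_cn < self.minor_cn:
                raise ValueError("major_cn < minor_cn")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def has_allele_data(self) -> bool:
        return self.major_cn is not None

    @property
    def is_imbalanced(self) -> bool:
        """Allelic imbalance: unequal major and minor copy number."""
        if not self.has_allele_data:
            raise ValueError("allele-specific data required")
        return self.major_cn != self.minor_cn

    def copy_state(self, tol: float = DEFAULT_CN_TOLERANCE):
        """Hashable copy state used for equality in smoothing/LST.

        Integer allele copy numbers when present, else the log2 ratio
        quantized at ``tol`` resolution.
        """
        if self.has_allele_data:
            return (self.major_cn, self.minor_cn)
        return round(self.log2_ratio / tol)

    def same_state(self, other: "Segment", tol: float = DEFAULT_CN_TOLERANCE) -> bool:
        if self.has_allele_data and other.has_allele_data:
            return (self.major_cn, self.minor_cn) == (other.major_cn, other.minor_cn)
        return abs(self.log2_ratio - other.log2_ratio) <= tol


class SegmentProfile:
    """One sample's segments, sorted by (chromosome, start)."""

    def __init__(self, sample_id: str, segments: list[Segment], build: GenomeBuild):
        self.sample_id = sample_id
        self.build = build
        order = {c.name: i for i, c in enumerate(build.chromosomes)}
        for seg in segments:
            if seg.chrom not in build:
                raise ValueError(f"{sample_id}: chromosome {seg.chrom} not in build")
            if seg.end > build[seg.chrom].length:
                raise ValueError(
                    f"{sample_id}: segment {seg.chrom}:{seg.start}-{seg.end} "
                    f"extends past chromosome end"
                )
        self.segments = sorted(segments, key=lambda s: (order[s.chrom], s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start <= prev.end:
                raise ValueError(
                    f"{sample_id}: overlapping segments on {seg.chrom} "
                    f"({prev.start}-{prev.end} and {seg.start}-{seg.end})"
                )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def has_allele_data(self) -> bool:
        return bool(self.segments) and all(s.has_allele_data for s in self.segments)

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def total_length(self) -> int:
        return sum(s.length for s in self.segments)


_REQUIRED = ["sample", "chrom", "start", "end", "log2"]
_COLUMN_ALIASES = {
    "id": "sample", "sample": "sample", "sample_id": "sample",
    "chrom": "chrom", "chromosome": "chrom", "chr": "chrom",
    "loc.start": "start", "start": "start", "loc_start": "start",
    "loc.end": "end", "end": "end", "loc_end": "end",
    "seg.mean": "log2", "seg_mean": "log2", "log2": "log2", "log2_ratio": "log2",
    "major_cn": "major_cn", "nmajor": "major_cn",
    "minor_cn": "minor_cn", "nminor": "minor_cn",
}


def read_seg(path: str | Path, build: GenomeBuild) -> list[SegmentProfile]:
    """Read a tab-delimited SEG file into one profile per sample.

    Accepts the cBioPortal header dialect (ID, chrom, loc.start, loc.end,
    seg.mean) plus optional ``major_cn``/``minor_cn`` columns.  Chromosome
    names are normalized so ``1`` and ``chr1`` are equivalent.  Malformed
    rows raise with the 1-based file line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {}
        for i, name in enumerate(header):
            key = _COLUMN_ALIASES.get(name.strip().lower())
            if key is not None and key not in cols:
                cols[key] = i
        missing = [c for c in _REQUIRED if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing SEG columns {missing}")
        has_allele = "major_cn" in cols and "minor_cn" in cols
        rows: dict[str, list[Segment]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                sample = fields[cols["sample"]].strip()
                seg = Segment(
                    chrom=normalize_chrom(fields[cols["chrom"]]),
                    start=int(fields[cols["start"]]),
                    end=int(fields[cols["end"]]),
                    log2_ratio=float(fields[cols["log2"]]),
                    major_cn=int(fields[cols["major_cn"]]) if has_allele else None,
                    minor_cn=int(fields[cols["minor_cn"]]) if has_allele else None,
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            rows.setdefault(sample, []).append(seg)
    return [SegmentProfile(sid, segs, build) for sid, segs in rows.items()]


def write_seg(profiles: list[SegmentProfile], path: str | Path) -> None:
    """Write profiles as a cBioPortal-style SEG file (allele columns if present)."""
    allele = all(p.has_allele_data for p in profiles) and any(len(p) for p in profiles)
    records = []
    for p in profiles:
        for s in p.segments:
            rec = {
                "ID": p.sample_id, "chrom": s.chrom,
                "loc.start": s.start, "loc.end": s.end,
                "seg.mean": f"{s.log2_ratio:.6g}",
            }
            if allele:
                rec["major_cn"] = s.major_cn
                rec["minor_cn"] = s.minor_cn
            records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def _merge(left: Segment, right: Segment) -> Segment:
    """Merge two equal-state segments, length-weighting the log2 ratio."""
    total = left.length + right.length
    log2 = (left.log2_ratio * left.length + right.log2_ratio * right.length) / total
    return replace(left, end=right.end, log2_ratio=log2)


def smooth_segments(
    profile: SegmentProfile,
    min_len_bp: int,
    cn_equivalence_tolerance: float = DEFAULT_CN_TOLERANCE,
) -> SegmentProfile:
    """Drop segments shorter than ``min_len_bp`` and re-merge equal flanks.

    Short segments are removed smallest-first; whenever the two segments
    flanking a removal share a copy state (within tolerance) they are merged
    across the gap.  Adjacent equal-state segments are merged too.  Iterated
    to a fixed point, so the result contains no short segment and no pair of
    neighbouring equal-state segments.
    """
    if min_len_bp <= 0:
        raise ValueError("min_len_bp must be positive")
    tol = cn_equivalence_tolerance
    out: list[Segment] = []
    for chrom, segs in profile.by_chrom().items():
        segs = list(segs)
        changed = True
        while changed:
            changed = False
            # coalesce equal-state neighbours first
            merged: list[Segment] = []
            for seg in segs:
                if merged and merged[-1].same_state(seg, tol):
                    merged[-1] = _merge(merged[-1], seg)
                    changed = True
                else:
                    merged.append(seg)
            segs = merged
            short = [i for i, s in enumerate(segs) if s.length < min_len_bp]
            if short:
                i = min(short, key=lambda i: segs[i].length)
                del segs[i]
                changed = True
        out.extend(segs)
    return SegmentProfile(profile.sample_id, out, profile.build)
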