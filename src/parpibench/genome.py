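"""Genome coordinate model: chromosomes, centromeres and arms.

Coordinates are 1-based and inclusive throughout (SEG convention), so the
length of an interval is ``end - start + 1``.  The packaged ``hg19`` build
carries UCSC chromosome lengths and centromere (acen) boundaries, which is
the coordinate system of typical masked copy-number segment files from
cBioPortal/GDC.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["Chromosome", "GenomeBuild", "load_hg19", "normalize_chrom"]

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)}


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to UCSC style (``"1"`` -> ``"chr1"``)."""
    name = str(name).strip()
    if not name:
        raise ValueError("empty chromosome name")
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in {"23", "x"}:
        name = "X"
    elif name in {"24", "y"}:
        name = "Y"
    return f"chr{name}"


@dataclass(frozen=True)
class Chromosome:
    """One chromosome with centromere boundaries (1-based inclusive bp)."""

    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: non-positive length")
        if not (0 <= self.centromere_start < self.centromere_end <= self.length):
            raise ValueError(f"{self.name}: centromere outside chromosome")

    @property
    def is_autosome(self) -> bool:
        return self.name in _AUTOSOMES

    def arms(self) -> list[tuple[str, int, int]]:
        """Return ``(arm_name, start, end)`` for the p and q arms.

        The centromere interval itself belongs to neither arm; a chromosome
        whose centromere starts at the origin has no p arm.
        """
        out: list[tuple[str, int, int]] = []
        if self.centromere_start >= 1:
            out.append((f"{self.name}p", 1, self.centromere_start))
        if self.centromere_end < self.length:
            out.append((f"{self.name}q", self.centromere_end + 1, self.length))
        return out


class GenomeBuild:
    """Ordered collection of chromosomes forming a reference build."""

    def __init__(self, name: str, chromosomes: list[Chromosome]):
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        self.name = name
        self.chromosomes = list(chromosomes)
        self._by_name = {c.name: c for c in chromosomes}

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._by_name

    def __getitem__(self, chrom: str) -> Chromosome:
        key = normalize_chrom(chrom)
        if key not in self._by_name:
            raise KeyError(f"chromosome {chrom!r} not in build {self.name!r}")
        return self._by_name[key]

    def __iter__(self):
        return iter(self.chromosomes)

    def arms(self, autosomes_only: bool = False) -> list[tuple[str, str, int, int]]:
        """All ``(chrom, arm_name, start, end)`` tuples in build order."""
        out = []
        for c in self.chromosomes:
            if autosomes_only and not c.is_autosome:
                continue
            for arm, s, e in c.arms():
                out.append((c.name, arm, s, e))
        return out

    @classmethod
    def from_table(cls, name: str, path: str | Path) -> "GenomeBuild":
        df = pd.read_csv(path, sep="\t")
        chroms = [
            Chromosome(
                normalize_chrom(r.chrom),
                int(r.length),
                int(r.centromere_start),
                int(r.centromere_end),
            )
            for r in df.itertuples()
        ]
        return cls(name, chroms)


def load_hg19() -> GenomeBuild:
    """Load the packaged hg19 chromosome/centromere table."""
    ref = resources.files("parpibench.data").joinpath("hg19_arms.tsv")
    with resources.as_file(ref) as path:
        return GenomeBuild.from_table("hg19", path)
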