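"""Gene sets, GMT I/O and union compilation.

Drug-perturbation gene sets (e.g. the up/down-regulated programs from PARP-
inhibitor treatment of cell lines) are combined into a single union set for
enrichment testing; the union can be restricted to the genes actually
measured in a cohort, which is why the effective gene-set size differs
between cohorts with different gene annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["GeneSet", "GeneSetCollection", "read_gmt", "write_gmt", "compile_union"]

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        members = [m.strip() for m in self.members if m.strip()]
        if not members:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        for m in members:
            if m in seen:
                logger.warning("gene set %s: duplicate member %s dropped", self.name, m)
            seen[m] = None
        self.members = list(seen)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene set names in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...)."""
    path = Path(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    f"and at least one member ({len(fields)} fields found)"
                )
            sets.append(GeneSet(fields[0], fields[1], fields[2:]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def compile_union(
    collection: GeneSetCollection,
    restrict_to: set[str] | None = None,
    name: str = "compiled_union",
) -> GeneSet:
    """Union of all member genes, optionally intersected with a gene universe.

    Restriction to a cohort's measured genes is what makes the effective
    gene-set size cohort-specific.  Member order is lexicographic for
    determinism.
    """
    if len(collection) == 0:
        raise ValueError("empty collection")
    union: set[str] = set()
    for s in collection:
        union.update(s.members)
    if restrict_to is not None:
        union &= set(restrict_to)
    if not union:
        raise ValueError("union is empty after restriction to the gene universe")
    return GeneSet(name, f"union of {len(collection)} sets", sorted(union))
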