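"""Expression matrices, phenotype labels and GCT/CLS file handling.

Expression values are held as a pandas DataFrame (genes x samples).  Per-
cohort normalization follows the two-step fractional-rank procedure: within
each gene, values are replaced by average-tie fractional ranks and the ranks
mapped to normal quantiles via the inverse normal CDF of rank/(n+1).  The
transform is monotone within a gene, which is all the rank-based enrichment
statistic downstream requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "fractional_rank_normalize",
    "make_phenotype",
    "recode_cms",
    "median_split",
    "read_gct",
    "write_gct",
    "read_cls",
    "write_cls",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a normalization flag."""

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.values.isna().any().any():
            raise ValueError("missing expression values are not supported")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeLabels:
    """Binary class assignment over samples for a GSEA phenotype.

    ``classes`` orders the two class names with the declared positive class
    first.  ``degenerate`` marks splits with an empty class, which cannot be
    used for phenotype permutation.
    """

    sample_ids: list[str]
    labels: list[str]
    classes: tuple[str, str]
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        extra = set(self.labels) - set(self.classes)
        if extra:
            raise ValueError(f"labels outside declared classes: {sorted(extra)}")
        self.degenerate = any(c not in self.labels for c in self.classes)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_per_class(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.classes}

    def mask(self, cls: str | None = None) -> np.ndarray:
        """Boolean array marking membership of ``cls`` (default: positive class)."""
        cls = self.classes[0] if cls is None else cls
        return np.asarray([lab == cls for lab in self.labels])

    def subset_to(self, sample_ids: list[str]) -> "PhenotypeLabels":
        keep = {s: l for s, l in zip(self.sample_ids, self.labels)}
        sel = [s for s in sample_ids if s in keep]
        return PhenotypeLabels(sel, [keep[s] for s in sel], self.classes)


def fractional_rank_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fractional-rank inverse-normal transform, per gene across samples.

    Ties receive their average rank; rank r over n samples maps to
    ``Phi^-1(r / (n + 1))``.  A constant gene maps to the quantile of its
    mean rank (zero), not an error.
    """
    n = matrix.n_samples
    if n == 0:
        raise ValueError("cannot normalize a matrix with zero samples")
    if n < 2:
        raise ValueError("normalization requires at least 2 samples")
    ranks = matrix.values.rank(axis=1, method="average")
    quantiles = stats.norm.ppf(ranks / (n + 1))
    out = pd.DataFrame(quantiles, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(out, normalized=True)


def make_phenotype(
    table: pd.DataFrame, column: str, positive_class: str
) -> PhenotypeLabels:
    """Build binary phenotype labels from a sample-annotation column.

    Samples with missing values are dropped; more than two remaining
    classes is an error (recode first, e.g. with :func:`recode_cms`).
    """
    if column not in table.columns:
        raise KeyError(f"column {column!r} not in table")
    col = table[column].dropna()
    classes = sorted(set(col))
    if len(classes) > 2:
        raise ValueError(
            f"column {column!r} has {len(classes)} classes {classes}; "
            "recode to two classes first"
        )
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not found in {classes}")
    other = [c for c in classes if c != positive_class]
    negative = other[0] if other else f"not_{positive_class}"
    return PhenotypeLabels(
        sample_ids=list(col.index),
        labels=list(col),
        classes=(positive_class, negative),
    )


#: CMS -> (two-tier MSI scheme, three-tier CIN scheme).  CMS1 is the
#: hypermutated/MSI subtype; CMS2 (canonical) and CMS3 (metabolic) fall in
#: the epithelial/CIN tier; CMS4 is the mesenchymal/genome-stable tier.
_CMS_MAP = {
    "CMS1": ("MSI", "Hypermutated/MSI"),
    "CMS2": ("MSS", "Epithelial/CIN"),
    "CMS3": ("MSS", "Epithelial/CIN"),
    "CMS4": ("MSS", "GS/EMT/Mesenchymal"),
}


def recode_cms(cms_label: str | None) -> tuple[str | None, str | None]:
    """Recode a consensus-molecular-subtype label into two- and three-tier schemes."""
    if cms_label is None or (isinstance(cms_label, float) and np.isnan(cms_label)):
        return (None, None)
    key = str(cms_label).strip().upper()
    if key not in _CMS_MAP:
        raise ValueError(f"unknown CMS label {cms_label!r}")
    return _CMS_MAP[key]


def median_split(
    values: pd.Series, class_names: tuple[str, str] = ("high", "low")
) -> PhenotypeLabels:
    """Median split with ties assigned to the low class."""
    from .scars import dichotomize_score

    return dichotomize_score(
        values, float(values.median()), high_is="gt", class_names=class_names
    )


# --- GCT / CLS -------------------------------------------------------------

def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a GCT v1.2 file (header ``#1.2``, dims line, Name/Description)."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in matrix.values.iterrows():
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{gene}\tna\t{vals}\n")


def read_gct(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: not a GCT 1.2 file (header {version!r})")
        n_genes, n_samples = (int(x) for x in fh.readline().split("\t")[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    df = df.drop(columns=["Description"])
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"{path}: dims line says {n_genes}x{n_samples}, data is {df.shape}"
        )
    df.index.name = None
    return ExpressionMatrix(df)


def write_cls(labels: PhenotypeLabels, path: str | Path) -> None:
    """Write a two-class categorical CLS file."""
    with open(path, "w") as fh:
        fh.write(f"{labels.n} 2 1\n")
        fh.write(f"# {labels.classes[0]} {labels.classes[1]}\n")
        fh.write(" ".join(labels.labels) + "\n")


def read_cls(path: str | Path, sample_ids: list[str] | None = None) -> PhenotypeLabels:
    path = Path(path)
    with open(path) as fh:
        n, n_classes, _ = (int(x) for x in fh.readline().split())
        header = fh.readline().split()
        if header[0] != "#" or n_classes != 2 or len(header) != 3:
            raise ValueError(f"{path}: expected a two-class categorical CLS file")
        labels = fh.readline().split()
    if len(labels) != n:
        raise ValueError(f"{path}: {len(labels)} labels, header says {n}")
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]
    return PhenotypeLabels(sample_ids, labels, (header[1], header[2]))
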