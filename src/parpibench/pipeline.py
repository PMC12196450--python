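"""End-to-end biomarker comparison workflow.

The study design this orchestrates: score every candidate biomarker's
phenotype split with the same compiled gene set (one GSEA row per
biomarker), then compare each biomarker against the reference (LST by
default) with the Fisher-z differential enrichment-score test, adjusting
over the family of pairs; when drug gene modules are supplied, also compare
leading-edge overlap fractions (GSEF) with the Wilcoxon signed-rank test.

Per-biomarker failures (degenerate phenotypes, empty gene-set intersections)
are isolated: the run records the error and continues with the remaining
biomarkers.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .compare import DifferentialESResult, GSEFResult, bh_adjust, compare_gsef, differential_es_test
from .expression import ExpressionMatrix, PhenotypeLabels
from .genesets import GeneSet, GeneSetCollection
from .gsea import GSEAConfig, GSEAResult, score_gene_set

__all__ = ["RunConfig", "ComparisonRun", "run_biomarker_comparison", "run_validation_recipe"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative settings for one comparison run."""

    reference: str = "LST"
    n_perm: int = 1000
    permutation_type: str = "phenotype"
    weight_p: float = 1.0
    seed: int = 0
    nominal_alpha: float = 0.05   # GSEA nominal significance threshold
    fdr_threshold: float = 0.25   # GSEA FDR threshold for "enriched"
    lst_threshold: float = 15.0   # dichotomization cut for LST scores
    fga_log2_threshold: float = 0.2

    def gsea_config(self, biomarker: str) -> GSEAConfig:
        """Per-biomarker GSEA settings with a name-derived sub-seed."""
        sub = (self.seed * 1000 + zlib.crc32(biomarker.encode())) % (2**31)
        return GSEAConfig(
            n_perm=self.n_perm,
            permutation_type=self.permutation_type,
            weight_p=self.weight_p,
            seed=sub,
        )


@dataclass
class ComparisonRun:
    """Result bundle: per-biomarker GSEA, differential ES, optional GSEF."""

    config: RunConfig
    gsea_results: dict[str, GSEAResult]
    differential: list[DifferentialESResult]
    gsef: list[GSEFResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def gsea_table(self) -> pd.DataFrame:
        rows = []
        for name, r in self.gsea_results.items():
            rows.append(
                {
                    "Biomarker": name,
                    "Gene Set Size": r.gene_set_size,
                    "ES": r.es,
                    "NES": r.nes,
                    "Nominal p Value": r.p_display(),
                    "FDR q Value": r.p_display(),
                }
            )
        return pd.DataFrame(rows)

    def differential_table(self) -> pd.DataFrame:
        rows = []
        for d in self.differential:
            rows.append(
                {
                    "Biomarker Pairs": f"{d.biomarker_pair[0]} vs. {d.biomarker_pair[1]}",
                    "N (ref vs. other)": f"{d.n_ref} vs. {d.n_other}",
                    "Ref ES": d.es_ref,
                    "Other ES": d.es_other,
                    "dES z-Score": d.z,
                    "Adjusted p Value": d.adjusted_p,
                }
            )
        return pd.DataFrame(rows)

    def gsef_table(self) -> pd.DataFrame:
        rows = []
        for g in self.gsef:
            rows.append(
                {
                    "Biomarker Pairs": f"{g.biomarker_pair[0]} vs. {g.biomarker_pair[1]}",
                    "Wilcoxon W": g.statistic,
                    "p Value": g.p_value,
                    "FDR Value": g.fdr_value,
                    "Degenerate": g.degenerate,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        """Serialize all tables, the config and the run log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gsea_table().to_csv(outdir / "gsea_results.tsv", sep="\t", index=False)
        self.differential_table().to_csv(
            outdir / "differential_es.tsv", sep="\t", index=False
        )
        if self.gsef:
            self.gsef_table().to_csv(outdir / "gsef.tsv", sep="\t", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self.config), fh)
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        for name, r in self.gsea_results.items():
            with open(outdir / f"leading_edge_{name}.txt", "w") as fh:
                fh.write("\n".join(r.leading_edge) + "\n")


def run_biomarker_comparison(
    matrix: ExpressionMatrix,
    phenotypes: dict[str, PhenotypeLabels],
    gene_set: GeneSet,
    config: RunConfig | None = None,
    drug_modules: GeneSetCollection | None = None,
) -> ComparisonRun:
    """Score each biomarker and compare all of them to the reference.

    ``phenotypes`` maps biomarker names to binary phenotype labels over
    (a subset of) the matrix samples; the reference biomarker must be one
    of them.  Differential-ES and GSEF p values are BH-adjusted over the
    family of reference-vs-other pairs actually computed.
    """
    config = config or RunConfig()
    if config.reference not in phenotypes:
        raise ValueError(f"reference biomarker {config.reference!r} not among phenotypes")
    run = ComparisonRun(config=config, gsea_results={}, differential=[])
    for name, labels in phenotypes.items():
        gcfg = config.gsea_config(name)
        try:
            run.gsea_results[name] = score_gene_set(matrix, labels, gene_set, gcfg)
            run.log.append(
                f"GSEA {name}: n={labels.n} perm={gcfg.permutation_type}x{gcfg.n_perm} "
                f"seed={gcfg.seed} es={run.gsea_results[name].es:.3f}"
            )
        except ValueError as exc:
            run.failures[name] = str(exc)
            run.log.append(f"GSEA {name}: FAILED ({exc})")
            logger.warning("biomarker %s failed: %s", name, exc)

    ref_name = config.reference
    if ref_name in run.gsea_results:
        ref = run.gsea_results[ref_name]
        raw_ps = []
        for name, res in run.gsea_results.items():
            if name == ref_name:
                continue
            try:
                z, raw_p = differential_es_test(
                    ref.es, ref.n_samples, res.es, res.n_samples
                )
            except ValueError as exc:
                # e.g. an ES of exactly +/-1 (perfect separation) has no
                # finite Fisher transform; skip the pair, keep the run
                run.failures[f"{ref_name} vs {name}"] = str(exc)
                run.log.append(f"dES {ref_name} vs {name}: FAILED ({exc})")
                continue
            run.differential.append(
                DifferentialESResult(
                    biomarker_pair=(ref_name, name),
                    es_ref=ref.es,
                    es_other=res.es,
                    n_ref=ref.n_samples,
                    n_other=res.n_samples,
                    z=z,
                    raw_p=raw_p,
                )
            )
            raw_ps.append(raw_p)
        if raw_ps:
            for d, adj in zip(run.differential, bh_adjust(raw_ps)):
                d.adjusted_p = float(adj)

        if drug_modules is not None:
            gsef_ps = []
            for name, res in run.gsea_results.items():
                if name == ref_name:
                    continue
                g = compare_gsef(
                    drug_modules,
                    ref.leading_edge,
                    res.leading_edge,
                    pair=(ref_name, name),
                )
                run.gsef.append(g)
                gsef_ps.append(g.p_value)
            if gsef_ps:
                for g, adj in zip(run.gsef, bh_adjust(gsef_ps)):
                    g.fdr_value = float(adj)
    return run


@dataclass
class ValidationRun:
    """Multiple scar phenotypes on one cohort plus compiled leading edges."""

    gsea_results: dict[str, GSEAResult]
    enriched_union: list[str]
    significant: list[str]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        """True when no phenotype reached significance (explicit marker)."""
        return not self.significant


def run_validation_recipe(
    matrix: ExpressionMatrix,
    phenotypes: dict[str, PhenotypeLabels],
    gene_set: GeneSet,
    config: RunConfig | None = None,
) -> ValidationRun:
    """Score several scar-derived phenotypes and compile their leading edges.

    Leading-edge genes from runs passing both the nominal and FDR
    thresholds are unioned into a derivative gene set for downstream
    analyses; when nothing is significant the union is empty, flagged via
    :attr:`ValidationRun.empty` rather than an error.
    """
    config = config or RunConfig()
    results: dict[str, GSEAResult] = {}
    failures: dict[str, str] = {}
    for name, labels in phenotypes.items():
        try:
            results[name] = score_gene_set(matrix, labels, gene_set, config.gsea_config(name))
        except ValueError as exc:
            failures[name] = str(exc)
    significant = [
        name
        for name, r in results.items()
        if r.nominal_p <= config.nominal_alpha and r.fdr_q <= config.fdr_threshold
    ]
    union: set[str] = set()
    for name in significant:
        union.update(results[name].leading_edge)
    return ValidationRun(
        gsea_results=results,
        enriched_union=sorted(union),
        significant=significant,
        failures=failures,
    )
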