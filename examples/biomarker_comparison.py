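"""Full biomarker comparison on one synthetic cohort.

Simulates an expression cohort with a planted response gene set, three
biomarkers of varying quality (two good surrogates, one uninformative), and
a panel of 22 drug gene modules; then runs per-biomarker GSEA, the
differential-ES family against the reference, and the GSEF Wilcoxon
comparison, exactly as the end-to-end pipeline does.
"""

from parpibench import RunConfig, run_biomarker_comparison
from parpibench.simulate import (
    BiomarkerSpec,
    CohortSpec,
    simulate_biomarker_labels,
    simulate_drug_modules,
    simulate_expression,
)

spec = CohortSpec(
    n_samples=120, n_genes=1000, planted_gene_set_size=50,
    enrichment_shift=0.4, seed=5,
    biomarker_specs=[
        BiomarkerSpec("MSI", association=0.9),
        BiomarkerSpec("PARP1", association=0.9),
        BiomarkerSpec("TP53", association=0.0),
    ],
)
matrix, planted, labels = simulate_expression(spec)
phenotypes = {"LST": labels, **simulate_biomarker_labels(spec, labels)}
modules = simulate_drug_modules(planted, matrix.gene_ids, seed=5)

run = run_biomarker_comparison(
    matrix, phenotypes, planted,
    RunConfig(reference="LST", n_perm=199, seed=5),
    drug_modules=modules,
)
print(run.gsea_table().round(3).to_string(index=False))
print()
print(run.differential_table().round(4).to_string(index=False))
print()
print(run.gsef_table().round(4).to_string(index=False))
print(
    "\nOn the correlation scale the two informative biomarkers are "
    "statistically\nequivalent to the reference (differential-ES adjusted "
    "p > 0.05) while the\nuninformative one is clearly weaker. The GSEF "
    "test is stricter: it compares\nthe leading-edge composition module by "
    "module, so even small leading-edge\ndifferences between good "
    "biomarkers can register."
)
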