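"""Generate a synthetic multi-tissue imputed-expression cohort.

Builds a cohort with planted tissue signatures and case/control differential
genes, writes it as PrediXcan-style tab-delimited matrices, and prints what
was planted. The planted truth is what every downstream stage is scored
against.
"""

from tivae.synthetic import CohortConfig, generate_cohort, write_dataset

config = CohortConfig(
    n_tissues=4,
    n_individuals=120,
    n_cases=78,           # ~65% cases, the imbalance of a dementia cohort
    universe_size=300,
    genes_per_tissue=240,  # each tissue carries 80% of the shared universe
    signature_genes_per_tissue=20,
    diff_genes_per_tissue=12,
    signature_effect=3.0,  # tissue mean shift, in noise standard deviations
    diff_effect=2.0,       # case-vs-control shift on planted genes
    seed=7,
)
dataset = generate_cohort(config)
manifest = write_dataset(dataset, "example-cohort")

print(f"tissues: {dataset.tissues}")
for tissue in dataset.tissues:
    matrix = dataset.matrices[tissue]
    print(
        f"  {tissue}: {matrix.shape[0]} individuals x {matrix.shape[1]} genes, "
        f"{len(dataset.truth.signature_genes[tissue])} signature genes, "
        f"{len(dataset.truth.diff_genes[tissue])} planted case/control genes"
    )
print(f"labels: {int((dataset.labels == 'case').sum())} cases / "
      f"{int((dataset.labels == 'control').sum())} controls")
print(f"files written: {sorted(manifest)}")
# Each matrix holds signed continuous values (positive = predicted
# up-regulation); the truth.json file records which genes were planted.
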