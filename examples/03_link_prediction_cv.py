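"""Cross-validated drug-target link prediction on a planted fixture.

Generates a synthetic dataset in which drug clusters preferentially bind
protein families, runs similarity -> embedding -> feature concatenation ->
boosted-tree classification, and reports the repeated-CV metrics.
"""

from dtlink import FixtureSpec, PipelineConfig, run_fixture_pipeline

fixture = FixtureSpec(
    n_drugs=40, n_proteins=30, n_drug_clusters=4, n_protein_families=3,
    sequence_length=80, seed=3,
)
config = PipelineConfig(seed=3, folds=5, repeats=2)

result = run_fixture_pipeline(fixture=fixture, config=config)

print(f"labelled pairs: {len(result.features.pairs)} "
      f"({int(result.features.labels.sum())} positive, balanced negatives)")
print(f"feature width : {result.features.features.shape[1]} "
      f"(= 2 x {config.embedding_dim}-dim embeddings)")
print("\nrepeated-CV performance (mean over folds/repeats):")
print(result.report.summary().to_string(index=False))
print(
    "\nExternal-test AUC well above 0.5 shows the concatenated embeddings"
    "\ncarry the planted cluster-family interaction signal."
)
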