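"""Balanced 5-fold cross-validation of the full model on planted data.

All known associations plus an equal number of sampled negatives are split
into five folds; embeddings come from the complete association matrix (the
protocol as originally described) and only the MLP is refitted per fold.
"""

from circdrug import (
    GATConfig,
    MLPConfig,
    NMFConfig,
    PipelineConfig,
    SAEConfig,
    cross_validate,
    generate_synthetic_dataset,
)

ds = generate_synthetic_dataset(n_circ=60, n_drug=40, n_clusters=5, seq_len=120, seed=3)

cfg = PipelineConfig(
    sae=SAEConfig(epochs=20),
    gat=GATConfig(epochs=60),
    nmf=NMFConfig(iterations=200),
    mlp=MLPConfig(epochs=60),
)
report = cross_validate(
    ds.association, ds.circ_records, ds.drug_records,
    folds=5, config=cfg, mode="paper_faithful", seed=0,
)
for name, (mean, std) in report.summary().items():
    print(f"{name:12s}: {mean:.4f} +/- {std:.4f}")
print("AUC/AUPR above 0.9 show the fused features rank most held-out positive "
      "pairs above the sampled negatives on this planted dataset")
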