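"""Compute the four base similarity networks on a small synthetic dataset.

Per side the pipeline uses three networks: a biology-driven one (sequence for
circRNAs, fingerprint Tanimoto for drugs) plus two derived from the
association matrix (Gaussian interaction profile and information entropy).
"""

import numpy as np

from circdrug import (
    circrna_sequence_similarity,
    drug_structure_similarity,
    entropy_similarity,
    generate_synthetic_dataset,
    gip_similarity,
)

ds = generate_synthetic_dataset(n_circ=60, n_drug=40, n_clusters=5, seq_len=120, seed=3)
A = ds.association

css = circrna_sequence_similarity(ds.circ_records)
cgip = gip_similarity(A, axis="circrna")
csie = entropy_similarity(A, axis="circrna")
dss = drug_structure_similarity(ds.drug_records)

same = ds.circ_clusters[:, None] == ds.circ_clusters[None, :]
off = ~np.eye(60, dtype=bool)
for name, sim in (("sequence", css), ("GIP", cgip), ("entropy", csie)):
    within = sim.values[same & off].mean()
    between = sim.values[~same].mean()
    print(f"circRNA {name:9s}: mean within-cluster {within:.3f}, between {between:.3f}")
print(f"drug Tanimoto    : mean off-diagonal {dss.values[~np.eye(40, dtype=bool)].mean():.3f}")
print("within-cluster similarity exceeding between-cluster shows each kernel "
      "recovers part of the planted structure")
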