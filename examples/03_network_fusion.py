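"""Fuse the three circRNA similarity networks by iterative cross-diffusion.

Each network is row-normalized (diagonal pinned at 1/2), reduced to a KNN
transition matrix, then repeatedly updated with the average of the other two
networks diffused through its own neighbourhood structure.
"""

from circdrug import (
    FusionConfig,
    circrna_sequence_similarity,
    default_k,
    entropy_similarity,
    fuse,
    generate_synthetic_dataset,
    gip_similarity,
    repair_isolated_rows,
)

ds = generate_synthetic_dataset(n_circ=60, n_drug=40, n_clusters=5, seq_len=120, seed=3)
A = ds.association

# repair_isolated_rows gives entities that share no associations with anyone a
# tiny uniform affinity in the entropy network, which diffusion requires
nets = [
    circrna_sequence_similarity(ds.circ_records),
    gip_similarity(A, axis="circrna"),
    repair_isolated_rows(entropy_similarity(A, axis="circrna")),
]
k = default_k(A.n_circ)
result = fuse(nets, FusionConfig(k_neighbors=k))
print(f"KNN size: {k} (one tenth of {A.n_circ} circRNAs)")
print(f"converged: {result.converged} after {result.iterations_run} iterations")
print(f"final relative change: {result.final_relative_change:.2e} (tolerance 1e-6)")
print("per-iteration relative change:",
      ", ".join(f"{c:.1e}" for c in result.relative_changes))
sym_gap = abs(result.fused.values - result.fused.values.T).max()
print(f"fused network symmetry gap: {sym_gap:.1e} (exactly symmetrized by construction)")
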