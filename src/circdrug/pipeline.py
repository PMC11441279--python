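"""End-to-end orchestration: similarities, fusion, embeddings, MLP, CV, ranking.

The full model builds, per entity side, three similarity networks (structure
or sequence, Gaussian interaction profile, information entropy), fuses them by
cross-diffusion, extracts three 128-dim embedding families (sparse autoencoder
for drugs, graph-attention autoencoder for circRNAs, masked NMF for both), and
classifies fused 256-dim pair features with a small MLP under balanced 1:1
sampling and k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, bce_with_logits
from .datasets import AssociationMatrix, CircRNARecord, DrugRecord
from .embeddings import EmbeddingMatrix, EmbeddingSource
from .errors import (
    CandidateLookupError,
    ConfigurationError,
    DimensionError,
    EvaluationError,
    SamplingError,
    TrainingError,
)
from .fusion import FusionConfig, default_k, fuse
from .gat import GATConfig, build_hetero_graph, train_gat_autoencoder
from .metrics import FoldMetrics, MetricsReport, compute_metrics
from .nmf import NMFConfig, nmf_factorize
from .nn import Adam, Linear
from .sae import SAEConfig, build_drug_inputs, train_sae
from .similarity import (
    SimilarityMatrix,
    circrna_sequence_similarity,
    drug_structure_similarity,
    entropy_similarity,
    fingerprint_from_smiles,
    gip_similarity,
)

__all__ = [
    "MLPConfig",
    "MLPClassifier",
    "PipelineConfig",
    "EmbeddingBundle",
    "PairSample",
    "VARIANTS",
    "compute_fused_networks",
    "repair_isolated_rows",
    "train_embedders",
    "fuse_pair_features",
    "sample_balanced",
    "cross_validate",
    "fit_model",
    "PredictionModel",
    "rank_candidates",
]

VARIANTS = ("full", "del_mga", "del_sae", "del_nmf")


# ---------------------------------------------------------------------------
# MLP classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (128, 64)
    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must lie in (0, 1)")


class MLPClassifier:
    """Fully connected net (input, *hidden, 1): rectifier hiddens, logistic output."""

    def __init__(self, config: MLPConfig = MLPConfig()):
        self.config = config
        self._layers: list[Linear] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        sizes = [X.shape[1], *cfg.hidden_sizes, 1]
        self._layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        params = [p for layer in self._layers for p in layer.params]
        opt = Adam(params, lr=cfg.lr)
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self._forward(X[idx])
                loss = bce_with_logits(logits, y[idx][:, None]).mean()
                if not np.isfinite(loss.data):
                    raise TrainingError(f"non-finite MLP loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def _forward(self, X: np.ndarray) -> Tensor:
        if self._layers is None:
            raise TrainingError("MLP has not been fitted")
        h = Tensor(X)
        for layer in self._layers[:-1]:
            h = layer(h).relu()
        return self._layers[-1](h)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=np.float64)).sigmoid().data.ravel()


# ---------------------------------------------------------------------------
# configuration bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    sae: SAEConfig = field(default_factory=SAEConfig)
    gat: GATConfig = field(default_factory=GATConfig)
    nmf: NMFConfig = field(default_factory=NMFConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    fusion_tol: float = 1e-6
    fusion_max_iter: int = 20
    k_circ: int | None = None  # None -> floor(N/10)
    k_drug: int | None = None  # None -> floor(M/10)
    sequence_convention: str = "ratio"
    fingerprint_bits: int = 2048


@dataclass(frozen=True)
class EmbeddingBundle:
    sae: EmbeddingMatrix  # drugs x 128
    gat: EmbeddingMatrix  # circRNAs x 128
    nmf_u: EmbeddingMatrix  # circRNAs x k
    nmf_v: EmbeddingMatrix  # drugs x k


@dataclass(frozen=True)
class PairSample:
    circ_index: int
    drug_index: int
    label: int
    features: np.ndarray


def _subseed(seed: int, role: int) -> int:
    return int(np.random.SeedSequence([seed, role]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# similarity + fusion assembly
# ---------------------------------------------------------------------------


def repair_isolated_rows(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Give entities with zero off-diagonal similarity a tiny uniform affinity.

    An entity that shares no associations with any other has an all-zero
    off-diagonal row in the entropy network, which the diffusion normalization
    cannot handle.  Such a row carries no information, so it is replaced by a
    uniform affinity at the scale of the smallest informative entry
    (symmetrically, to keep the matrix valid).
    """
    W = sim.values
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    dead = np.nonzero(off.sum(axis=1) == 0)[0]
    if dead.size == 0:
        return sim
    positive = off[off > 0]
    eps = float(positive.min()) if positive.size else 1e-6
    W = W.copy()
    for i in dead:
        W[i, :] = np.maximum(W[i, :], eps)
        W[:, i] = np.maximum(W[:, i], eps)
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(values=W, ids=sim.ids, kind=sim.kind)


def compute_fused_networks(
    A: AssociationMatrix,
    circ_records: tuple[CircRNARecord, ...],
    drug_records: tuple[DrugRecord, ...],
    config: PipelineConfig = PipelineConfig(),
    css: SimilarityMatrix | None = None,
    dss: SimilarityMatrix | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Fused circRNA network SM' and drug network SD'.

    Sequence/structure similarities do not depend on the association matrix and
    may be passed in precomputed (they are reused across CV folds).
    """
    if css is None:
        css = circrna_sequence_similarity(circ_records, convention=config.sequence_convention)
    if dss is None:
        records = drug_records
        if any(r.fingerprint is None for r in records):
            records = tuple(fingerprint_from_smiles(records, n_bits=config.fingerprint_bits))
        dss = drug_structure_similarity(records)

    cgip = gip_similarity(A, axis="circrna")
    csie = repair_isolated_rows(entropy_similarity(A, axis="circrna"))
    dgip = gip_similarity(A, axis="drug")
    dsie = repair_isolated_rows(entropy_similarity(A, axis="drug"))
    css = repair_isolated_rows(css)
    dss = repair_isolated_rows(dss)

    k_c = config.k_circ if config.k_circ is not None else default_k(A.n_circ)
    k_d = config.k_drug if config.k_drug is not None else default_k(A.n_drug)
    fc = FusionConfig(k_neighbors=k_c, tol=config.fusion_tol, max_iter=config.fusion_max_iter)
    fd = FusionConfig(k_neighbors=k_d, tol=config.fusion_tol, max_iter=config.fusion_max_iter)
    sm = fuse([css, cgip, csie], fc).fused
    sd = fuse([dss, dgip, dsie], fd).fused
    return sm, sd


def train_embedders(
    A: AssociationMatrix,
    circ_records: tuple[CircRNARecord, ...],
    drug_records: tuple[DrugRecord, ...],
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    css: SimilarityMatrix | None = None,
    dss: SimilarityMatrix | None = None,
) -> EmbeddingBundle:
    """Run all three feature extractors on one association matrix."""
    sm, sd = compute_fused_networks(A, circ_records, drug_records, config, css=css, dss=dss)

    sae_cfg = replace(config.sae, seed=_subseed(seed, 1))
    drug_inputs = build_drug_inputs(sd, A, similarity_only=sae_cfg.similarity_only_input)
    sae_emb, _ = train_sae(drug_inputs, sae_cfg, ids=A.drug_ids)

    gat_cfg = replace(config.gat, seed=_subseed(seed, 2))
    graph = build_hetero_graph(sm, A)
    gat_emb, _ = train_gat_autoencoder(graph, gat_cfg)

    k_eff = min(config.nmf.k, A.n_circ, A.n_drug)
    nmf_cfg = replace(config.nmf, k=k_eff, seed=_subseed(seed, 3))
    factors = nmf_factorize(A.values.astype(np.float64), None, nmf_cfg)
    nmf_u = EmbeddingMatrix(factors.U, A.circ_ids, EmbeddingSource.nmf_u)
    nmf_v = EmbeddingMatrix(factors.V_t, A.drug_ids, EmbeddingSource.nmf_v)
    return EmbeddingBundle(sae=sae_emb, gat=gat_emb, nmf_u=nmf_u, nmf_v=nmf_v)


# ---------------------------------------------------------------------------
# pair features and sampling
# ---------------------------------------------------------------------------


def fuse_pair_features(
    sae: EmbeddingMatrix,
    gat: EmbeddingMatrix,
    U: EmbeddingMatrix,
    V: EmbeddingMatrix,
    pairs: np.ndarray,
    variant: str = "full",
) -> np.ndarray:
    """Fused feature vectors for (circRNA index, drug index) pairs.

    ``full``: [gat_i * sae_j || U_i * V_j] (element-wise products, 2 blocks).
    Ablations: ``del_mga`` -> [sae_j || U_i * V_j]; ``del_sae`` ->
    [gat_i || U_i * V_j]; ``del_nmf`` -> [gat_i * sae_j].
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    pairs = np.asarray(pairs)
    ci, dj = pairs[:, 0], pairs[:, 1]
    blocks = []
    if variant == "full":
        if gat.dim != sae.dim:
            raise DimensionError("GAT and SAE embedding dims differ")
        blocks.append(gat.values[ci] * sae.values[dj])
    elif variant == "del_mga":
        blocks.append(sae.values[dj])
    elif variant == "del_sae":
        blocks.append(gat.values[ci])
    if variant != "del_nmf":
        if U.dim != V.dim:
            raise DimensionError("NMF U and V dims differ")
        blocks.append(U.values[ci] * V.values[dj])
    else:
        blocks.append(gat.values[ci] * sae.values[dj])
    return np.concatenate(blocks, axis=1)


def sample_balanced(A: AssociationMatrix, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """All positive pairs plus an equal number of uniform negatives.

    Returns (pairs, labels) with pairs of shape (2*AN, 2); negatives are drawn
    without replacement and never coincide with a positive.
    """
    pos = np.argwhere(A.values == 1)
    neg_all = np.argwhere(A.values == 0)
    if pos.shape[0] == 0:
        raise SamplingError("association matrix has no positives")
    if neg_all.shape[0] < pos.shape[0]:
        raise SamplingError("not enough negatives for balanced 1:1 sampling")
    rng = np.random.default_rng(seed)
    neg = neg_all[rng.choice(neg_all.shape[0], size=pos.shape[0], replace=False)]
    pairs = np.concatenate([pos, neg], axis=0)
    labels = np.concatenate([np.ones(pos.shape[0]), np.zeros(neg.shape[0])]).astype(np.int64)
    return pairs, labels


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(order, folds)):
        assignment[chunk] = f
    return assignment


def cross_validate(
    A: AssociationMatrix,
    circ_records: tuple[CircRNARecord, ...],
    drug_records: tuple[DrugRecord, ...],
    folds: int = 5,
    config: PipelineConfig = PipelineConfig(),
    mode: str = "paper_faithful",
    seed: int = 0,
    variant: str = "full",
    embeddings: EmbeddingBundle | None = None,
) -> MetricsReport:
    """Balanced k-fold cross-validation of the full pipeline.

    ``paper_faithful`` computes similarity networks and embeddings once on the
    complete association matrix (the protocol as originally described, which
    lets test-fold positives inform the association-derived inputs);
    ``strict`` recomputes them per fold with the test-fold positives zeroed.
    A precomputed ``embeddings`` bundle is only valid in paper_faithful mode.
    """
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if mode not in ("paper_faithful", "strict"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if embeddings is not None and mode == "strict":
        raise ConfigurationError("precomputed embeddings cannot be used in strict mode")

    pairs, labels = sample_balanced(A, seed=_subseed(seed, 5))
    rng = np.random.default_rng(_subseed(seed, 6))
    assignment = _fold_assignment(pairs.shape[0], folds, rng)

    # sequence/structure similarities never depend on A: compute once
    css = circrna_sequence_similarity(circ_records, convention=config.sequence_convention)
    drug_recs = drug_records
    if any(r.fingerprint is None for r in drug_recs):
        drug_recs = tuple(fingerprint_from_smiles(drug_recs, n_bits=config.fingerprint_bits))
    dss = drug_structure_similarity(drug_recs)

    if mode == "paper_faithful" and embeddings is None:
        embeddings = train_embedders(
            A, circ_records, drug_recs, config, seed=seed, css=css, dss=dss
        )

    fold_metrics: list[FoldMetrics] = []
    for f in range(folds):
        test = assignment == f
        train = ~test
        if labels[test].min() == labels[test].max():
            raise EvaluationError(f"fold {f} contains a single class")
        if mode == "strict":
            masked = A.values.copy()
            test_pos = pairs[test & (labels == 1)]
            masked[test_pos[:, 0], test_pos[:, 1]] = 0
            bundle = train_embedders(
                A.with_values(masked), circ_records, drug_recs, config,
                seed=_subseed(seed, 100 + f), css=css, dss=dss,
            )
        else:
            bundle = embeddings
        feats = fuse_pair_features(
            bundle.sae, bundle.gat, bundle.nmf_u, bundle.nmf_v, pairs, variant
        )
        mlp_cfg = replace(config.mlp, seed=_subseed(seed, 200 + f))
        clf = MLPClassifier(mlp_cfg).fit(feats[train], labels[train])
        scores = clf.predict_proba(feats[test])
        fold_metrics.append(compute_metrics(labels[test], scores, mlp_cfg.threshold))

    return MetricsReport(
        folds=tuple(fold_metrics), fold_assignment=assignment, seed=seed
    )


# ---------------------------------------------------------------------------
# fitting and candidate ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionModel:
    """A trained pipeline: association matrix, embeddings and fitted MLP."""

    A: AssociationMatrix
    bundle: EmbeddingBundle
    classifier: MLPClassifier
    variant: str

    def score_pairs(self, pairs: np.ndarray) -> np.ndarray:
        feats = fuse_pair_features(
            self.bundle.sae, self.bundle.gat, self.bundle.nmf_u, self.bundle.nmf_v,
            pairs, self.variant,
        )
        return self.classifier.predict_proba(feats)


def fit_model(
    A: AssociationMatrix,
    circ_records: tuple[CircRNARecord, ...],
    drug_records: tuple[DrugRecord, ...],
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    variant: str = "full",
) -> PredictionModel:
    """Train embedders and the MLP on the complete association matrix."""
    bundle = train_embedders(A, circ_records, drug_records, config, seed=seed)
    pairs, labels = sample_balanced(A, seed=_subseed(seed, 5))
    feats = fuse_pair_features(bundle.sae, bundle.gat, bundle.nmf_u, bundle.nmf_v, pairs, variant)
    clf = MLPClassifier(replace(config.mlp, seed=_subseed(seed, 4))).fit(feats, labels)
    return PredictionModel(A=A, bundle=bundle, classifier=clf, variant=variant)


def rank_candidates(
    model: PredictionModel,
    drug_id: str,
    top_k: int = 20,
    exclude_known: bool = True,
) -> list[tuple[str, float]]:
    """Scores for all (circRNA, drug) pairs for one drug, sorted descending.

    Ties are broken by circRNA id for determinism.
    """
    A = model.A
    if drug_id not in A.drug_ids:
        raise CandidateLookupError(f"unknown drug id {drug_id!r}")
    j = A.drug_ids.index(drug_id)
    candidates = [
        i for i in range(A.n_circ) if not (exclude_known and A.values[i, j] == 1)
    ]
    pairs = np.array([[i, j] for i in candidates])
    scores = model.score_pairs(pairs)
    ranked = sorted(
        zip((A.circ_ids[i] for i in candidates), scores),
        key=lambda t: (-t[1], t[0]),
    )
    return [(cid, float(s)) for cid, s in ranked[:top_k]]


def rank_novel_drug(
    A: AssociationMatrix,
    circ_records: tuple[CircRNARecord, ...],
    drug_records: tuple[DrugRecord, ...],
    drug_id: str,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    top_k: int = 20,
) -> list[tuple[str, float]]:
    """Novel-drug protocol: retrain with the drug's column zeroed, then rank."""
    if drug_id not in A.drug_ids:
        raise CandidateLookupError(f"unknown drug id {drug_id!r}")
    j = A.drug_ids.index(drug_id)
    masked = A.values.copy()
    masked[:, j] = 0
    model = fit_model(A.with_values(masked), circ_records, drug_records, config, seed=seed)
    return rank_candidates(model, drug_id, top_k=top_k, exclude_known=False)
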