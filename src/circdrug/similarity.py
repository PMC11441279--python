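"""The four base similarity networks per entity type.

Per side (circRNA or drug) the pipeline uses three of the four kernels:

* drug structural similarity — Tanimoto coefficient of binary topological
  fingerprints;
* circRNA sequence similarity — normalized Levenshtein "ratio" of host-gene
  sequences (edit distance with substitution cost 2);
* Gaussian interaction-profile (GIP) kernel — Gaussian of the distance between
  binary association profiles, bandwidth scaled by the mean squared profile
  norm;
* information-entropy similarity — twice the Shannon entropy of the shared
  association set over the sum of the individual set entropies.

All outputs are symmetric matrices in [0, 1] with unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seqdist import encode, lcs_len, levenshtein
from .datasets import AssociationMatrix, CircRNARecord, DrugRecord
from .errors import ComputationError, DimensionError, ParseError, RecordError

__all__ = [
    "SimilarityKind",
    "SimilarityMatrix",
    "fingerprint_from_smiles",
    "drug_structure_similarity",
    "circrna_sequence_similarity",
    "gip_similarity",
    "entropy_similarity",
    "read_similarity",
    "write_similarity",
]


class SimilarityKind(str, Enum):
    structure = "structure"
    sequence = "sequence"
    gip = "gip"
    entropy = "entropy"
    fused = "fused"


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] tied to an ordered id list."""

    values: np.ndarray
    ids: tuple[str, ...]
    kind: SimilarityKind

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "kind", SimilarityKind(self.kind))
        n = len(self.ids)
        if values.shape != (n, n):
            raise DimensionError(f"similarity shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise DimensionError("similarity matrix is not symmetric within 1e-12")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise DimensionError("similarity entries must lie in [0, 1]")
        if self.kind is not SimilarityKind.fused and not np.allclose(
            np.diag(values), 1.0, atol=1e-12
        ):
            raise DimensionError(f"{self.kind.value} similarity must have unit diagonal")

    @property
    def size(self) -> int:
        return len(self.ids)


def _finish(values: np.ndarray, ids: Sequence[str], kind: SimilarityKind) -> SimilarityMatrix:
    values = np.clip(values, 0.0, 1.0)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, ids=tuple(ids), kind=kind)


# ---------------------------------------------------------------------------
# drug structure
# ---------------------------------------------------------------------------


def fingerprint_from_smiles(records: Sequence[DrugRecord], n_bits: int = 2048) -> list[DrugRecord]:
    """Attach path-based topological fingerprints computed from SMILES."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    out = []
    for rec in records:
        if rec.smiles is None:
            raise RecordError(f"drug {rec.id!r} has no SMILES to fingerprint")
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise RecordError(f"drug {rec.id!r}: unparseable SMILES {rec.smiles!r}")
        bits = np.zeros(n_bits, dtype=np.int64)
        for b in gen.GetFingerprint(mol).GetOnBits():
            bits[b] = 1
        out.append(DrugRecord(id=rec.id, smiles=rec.smiles, fingerprint=bits))
    return out


def drug_structure_similarity(records: Sequence[DrugRecord]) -> SimilarityMatrix:
    """Tanimoto coefficient between binary fingerprints.

    ``T(a, b) = a.b / (|a| + |b| - a.b)``; a pair of all-zero fingerprints is
    defined to have similarity 0 (no shared substructure evidence), and the
    diagonal is forced to 1.
    """
    fps = []
    for rec in records:
        if rec.fingerprint is None:
            raise RecordError(f"drug {rec.id!r} has no fingerprint")
        fps.append(rec.fingerprint)
    lengths = {fp.size for fp in fps}
    if len(lengths) > 1:
        raise DimensionError(f"mixed fingerprint lengths: {sorted(lengths)}")
    F = np.asarray(fps, dtype=np.float64)
    inter = F @ F.T
    counts = F.sum(axis=1)
    denom = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    return _finish(sim, [r.id for r in records], SimilarityKind.structure)


# ---------------------------------------------------------------------------
# circRNA sequence
# ---------------------------------------------------------------------------


def circrna_sequence_similarity(
    records: Sequence[CircRNARecord], convention: str = "ratio"
) -> SimilarityMatrix:
    """Normalized edit similarity between host-gene sequences.

    With the default ``"ratio"`` convention (substitution cost 2),
    ``sim(a, b) = (|a| + |b| - D2(a, b)) / (|a| + |b|) = 2*LCS(a, b)/(|a|+|b|)``.
    ``convention="unit"`` uses the plain unit-cost Levenshtein distance in the
    same normalization instead.
    """
    if convention not in ("ratio", "unit"):
        raise ComputationError(f"unknown convention {convention!r}")
    seqs = [encode(r.host_gene_sequence) for r in records]
    n = len(seqs)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            la, lb = seqs[i].size, seqs[j].size
            if convention == "ratio":
                s = 2.0 * lcs_len(seqs[i], seqs[j]) / (la + lb)
            else:
                s = (la + lb - levenshtein(seqs[i], seqs[j])) / (la + lb)
            sim[i, j] = sim[j, i] = s
    return _finish(sim, [r.id for r in records], SimilarityKind.sequence)


# ---------------------------------------------------------------------------
# Gaussian interaction profile
# ---------------------------------------------------------------------------


def gip_similarity(
    A: AssociationMatrix, axis: str, omega_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary association profiles.

    Profiles are rows of ``A`` (circRNA axis) or columns (drug axis).  The
    bandwidth is ``omega = omega' / mean_i ||IP_i||^2`` and
    ``K_ij = exp(-omega * ||IP_i - IP_j||^2)``.
    """
    if axis == "drug":
        profiles = A.values.T.astype(np.float64)
        ids = A.drug_ids
    elif axis == "circrna":
        profiles = A.values.astype(np.float64)
        ids = A.circ_ids
    else:
        raise ComputationError(f"axis must be 'drug' or 'circrna', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise ComputationError("all-zero association matrix: GIP bandwidth undefined")
    omega = omega_prime / mean_sq
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    return _finish(np.exp(-omega * d2), ids, SimilarityKind.gip)


# ---------------------------------------------------------------------------
# information entropy
# ---------------------------------------------------------------------------


def entropy_similarity(A: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Information-entropy similarity of association sets.

    For the circRNA axis, each circRNA's set is the drugs it associates with;
    each drug ``i`` carries probability ``p_i = colsum(A)_i / AN`` and entropy
    weight ``-p_i log2 p_i``.  ``sim(A, B) = 2 F(I_A & I_B) / (F(I_A) + F(I_B))``
    with 0 when the denominator vanishes; diagonal forced to 1.
    """
    if axis == "circrna":
        member = A.values.astype(np.float64)  # (n_circ, n_drug)
        p = A.values.sum(axis=0).astype(np.float64)
        ids = A.circ_ids
    elif axis == "drug":
        member = A.values.T.astype(np.float64)  # (n_drug, n_circ)
        p = A.values.sum(axis=1).astype(np.float64)
        ids = A.drug_ids
    else:
        raise ComputationError(f"axis must be 'drug' or 'circrna', got {axis!r}")
    an = A.total_associations
    if an == 0:
        raise ComputationError("all-zero association matrix: entropy undefined")
    p = p / an
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    f_self = member @ w  # F(I_X) per entity
    f_inter = (member * w[None, :]) @ member.T  # F(I_A & I_B)
    denom = f_self[:, None] + f_self[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * f_inter / np.where(denom > 0, denom, 1.0), 0.0)
    return _finish(sim, ids, SimilarityKind.entropy)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_similarity(matrix: SimilarityMatrix, path: str | Path, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.DataFrame(matrix.values, index=list(matrix.ids), columns=list(matrix.ids))
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_similarity(
    path: str | Path, kind: SimilarityKind | str, dialect: str = "csv"
) -> SimilarityMatrix:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ParseError(f"{path}: similarity file row/column ids differ")
    return SimilarityMatrix(
        values=df.to_numpy(dtype=np.float64),
        ids=tuple(str(i) for i in df.index),
        kind=SimilarityKind(kind),
    )
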