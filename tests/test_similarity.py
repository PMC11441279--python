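"""The four similarity kernels against hand values and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circdrug import (
    AssociationMatrix,
    CircRNARecord,
    DrugRecord,
    circrna_sequence_similarity,
    drug_structure_similarity,
    entropy_similarity,
    fingerprint_from_smiles,
    gip_similarity,
    read_similarity,
    write_similarity,
)
from circdrug.errors import ComputationError, DimensionError, RecordError
from circdrug.similarity import SimilarityKind

# ---------------------------------------------------------------------------
# independent naive-loop oracles
# ---------------------------------------------------------------------------


def tanimoto_oracle(a, b):
    dot = sum(x * y for x, y in zip(a, b))
    na, nb = sum(a), sum(b)
    return dot / (na + nb - dot) if na + nb - dot > 0 else 0.0


def ratio_oracle(a: str, b: str) -> float:
    """Edit distance with substitution cost 2, full DP table."""
    la, lb = len(a), len(b)
    D = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        D[i][0] = i
    for j in range(lb + 1):
        D[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = D[i - 1][j - 1] + (0 if a[i - 1] == b[j - 1] else 2)
            D[i][j] = min(D[i - 1][j] + 1, D[i][j - 1] + 1, sub)
    return (la + lb - D[la][lb]) / (la + lb)


def gip_oracle(A, axis):
    profiles = A.T if axis == "drug" else A
    n = profiles.shape[0]
    omega = 1.0 / (sum(float(p @ p) for p in profiles) / n)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = profiles[i] - profiles[j]
            K[i, j] = math.exp(-omega * float(d @ d))
    return K


def entropy_oracle(A, axis):
    mat = A if axis == "circrna" else A.T
    an = A.sum()
    p = (A.sum(axis=0) if axis == "circrna" else A.sum(axis=1)) / an
    sets = [set(np.nonzero(row)[0]) for row in mat]

    def F(S):
        return -sum(p[i] * math.log2(p[i]) for i in S if p[i] > 0)

    n = len(sets)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            denom = F(sets[i]) + F(sets[j])
            out[i, j] = 2 * F(sets[i] & sets[j]) / denom if denom > 0 else 0.0
    return out


def _random_assoc(seed, n=10, m=8, density=0.3):
    r = np.random.default_rng(seed)
    values = (r.random((n, m)) < density).astype(int)
    values[0, 0] = 1  # ensure non-degenerate
    return AssociationMatrix(
        values, tuple(f"c{i}" for i in range(n)), tuple(f"d{j}" for j in range(m))
    )


# ---------------------------------------------------------------------------
# Tanimoto / fingerprints
# ---------------------------------------------------------------------------


class TestDrugStructure:
    def test_hand_example(self):
        # ones at {1,2,3} vs {2,3,4,5}: 2/(3+4-2) = 0.4
        a = np.zeros(8, dtype=int)
        b = np.zeros(8, dtype=int)
        a[[1, 2, 3]] = 1
        b[[2, 3, 4, 5]] = 1
        sim = drug_structure_similarity(
            [DrugRecord("a", fingerprint=a), DrugRecord("b", fingerprint=b)]
        )
        assert sim.values[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_identity_and_disjoint_cases(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([0, 0, 1, 1])
        sim = drug_structure_similarity(
            [DrugRecord("a", fingerprint=a), DrugRecord("b", fingerprint=a.copy()),
             DrugRecord("c", fingerprint=b)]
        )
        assert sim.values[0, 1] == 1.0
        assert sim.values[0, 2] == 0.0

    def test_all_zero_pair_defined_as_zero(self):
        z = np.zeros(4, dtype=int)
        sim = drug_structure_similarity(
            [DrugRecord("a", fingerprint=z), DrugRecord("b", fingerprint=z.copy())]
        )
        assert sim.values[0, 1] == 0.0
        assert sim.values[0, 0] == 1.0  # diagonal forced

    def test_mixed_lengths_rejected(self):
        with pytest.raises(DimensionError):
            drug_structure_similarity(
                [DrugRecord("a", fingerprint=np.ones(4, dtype=int)),
                 DrugRecord("b", fingerprint=np.ones(5, dtype=int))]
            )

    def test_matches_oracle_on_random_fingerprints(self, rng):
        fps = (rng.random((10, 16)) < 0.4).astype(int)
        recs = [DrugRecord(f"d{i}", fingerprint=fp) for i, fp in enumerate(fps)]
        sim = drug_structure_similarity(recs)
        for i in range(10):
            for j in range(10):
                expected = 1.0 if i == j else tanimoto_oracle(fps[i], fps[j])
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-10)


class TestFingerprints:
    def test_deterministic_per_smiles(self):
        recs = fingerprint_from_smiles(
            [DrugRecord("a", smiles="CCO"), DrugRecord("b", smiles="CCO")], n_bits=512
        )
        np.testing.assert_array_equal(recs[0].fingerprint, recs[1].fingerprint)
        assert recs[0].fingerprint.size == 512

    def test_invalid_smiles_names_offender(self):
        with pytest.raises(RecordError, match="bad"):
            fingerprint_from_smiles([DrugRecord("bad", smiles="not_a_smiles")])

    def test_canonicalization_invariance(self):
        # two spellings of toluene; canonical form checked with the toolkit itself
        from rdkit import Chem

        s1, s2 = "Cc1ccccc1", "c1ccccc1C"
        assert Chem.CanonSmiles(s1) == Chem.CanonSmiles(s2)
        recs = fingerprint_from_smiles(
            [DrugRecord("a", smiles=s1), DrugRecord("b", smiles=s2)], n_bits=1024
        )
        np.testing.assert_array_equal(recs[0].fingerprint, recs[1].fingerprint)


# ---------------------------------------------------------------------------
# sequence similarity
# ---------------------------------------------------------------------------


class TestSequenceSimilarity:
    def test_hand_examples(self):
        recs = [CircRNARecord("a", "ACGT"), CircRNARecord("b", "ACGA")]
        sim = circrna_sequence_similarity(recs)
        assert sim.values[0, 1] == pytest.approx(0.75, abs=1e-12)  # (4+4-2)/8
        recs = [CircRNARecord("a", "A"), CircRNARecord("b", "G")]
        sim = circrna_sequence_similarity(recs)
        assert sim.values[0, 1] == 0.0  # (1+1-2)/2

    def test_identical_strings_give_one(self):
        recs = [CircRNARecord("a", "ACGTACGT"), CircRNARecord("b", "ACGTACGT")]
        assert circrna_sequence_similarity(recs).values[0, 1] == 1.0

    def test_ratio_matches_dp_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=rng.integers(5, 25))) for _ in range(10)]
        recs = [CircRNARecord(f"c{i}", s) for i, s in enumerate(seqs)]
        sim = circrna_sequence_similarity(recs)
        for i in range(10):
            for j in range(10):
                assert sim.values[i, j] == pytest.approx(
                    1.0 if i == j else ratio_oracle(seqs[i], seqs[j]), abs=1e-10
                )

    def test_unit_convention_matches_edlib(self, rng):
        edlib = pytest.importorskip("edlib")
        seqs = ["".join(rng.choice(list("ACGT"), size=rng.integers(5, 30))) for _ in range(8)]
        recs = [CircRNARecord(f"c{i}", s) for i, s in enumerate(seqs)]
        sim = circrna_sequence_similarity(recs, convention="unit")
        for i in range(8):
            for j in range(i + 1, 8):
                d = edlib.align(seqs[i], seqs[j])["editDistance"]
                expected = (len(seqs[i]) + len(seqs[j]) - d) / (len(seqs[i]) + len(seqs[j]))
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------


class TestGIP:
    def test_identity_two_by_two(self):
        A = AssociationMatrix(np.eye(2, dtype=int), ("c1", "c2"), ("d1", "d2"))
        sim = gip_similarity(A, axis="drug")
        # omega = 1/((1+1)/2) = 1, K12 = exp(-2)
        assert sim.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)
        assert sim.values[0, 0] == 1.0

    def test_identical_profiles_give_one(self):
        values = np.array([[1, 1], [1, 1], [0, 0]])
        A = AssociationMatrix(values, ("c1", "c2", "c3"), ("d1", "d2"))
        assert gip_similarity(A, axis="drug").values[0, 1] == pytest.approx(1.0)

    def test_all_zero_matrix_rejected(self):
        A = AssociationMatrix(np.zeros((3, 2), dtype=int), ("c1", "c2", "c3"), ("d1", "d2"))
        with pytest.raises(ComputationError):
            gip_similarity(A, axis="drug")

    @pytest.mark.parametrize("axis", ["drug", "circrna"])
    def test_matches_oracle(self, axis):
        A = _random_assoc(7)
        sim = gip_similarity(A, axis=axis)
        np.testing.assert_allclose(sim.values, gip_oracle(A.values, axis), atol=1e-10)

    def test_permutation_equivariance(self):
        A = _random_assoc(13)
        perm = np.random.default_rng(0).permutation(A.n_circ)
        A_perm = AssociationMatrix(
            A.values[perm], tuple(A.circ_ids[i] for i in perm), A.drug_ids
        )
        sim = gip_similarity(A, axis="circrna").values
        sim_perm = gip_similarity(A_perm, axis="circrna").values
        np.testing.assert_allclose(sim_perm, sim[np.ix_(perm, perm)], atol=1e-12)


# ---------------------------------------------------------------------------
# entropy similarity
# ---------------------------------------------------------------------------


class TestEntropySimilarity:
    def test_hand_example(self):
        # circ1 -> {d1, d2}, circ2 -> {d2}: AN=3, p=(1/3, 2/3),
        # F(I1)=0.9183, F(I2)=0.3900, F(inter)=0.3900, sim = 2*0.39/1.3083
        values = np.array([[1, 1], [0, 1]])
        A = AssociationMatrix(values, ("c1", "c2"), ("d1", "d2"))
        sim = entropy_similarity(A, axis="circrna")
        f1 = -(1 / 3) * math.log2(1 / 3) - (2 / 3) * math.log2(2 / 3)
        f2 = -(2 / 3) * math.log2(2 / 3)
        assert sim.values[0, 1] == pytest.approx(2 * f2 / (f1 + f2), abs=1e-10)
        assert sim.values[0, 1] == pytest.approx(0.5962, abs=1e-4)

    def test_disjoint_sets_give_zero(self):
        values = np.array([[1, 0], [0, 1]])
        A = AssociationMatrix(values, ("c1", "c2"), ("d1", "d2"))
        assert entropy_similarity(A, axis="circrna").values[0, 1] == 0.0

    def test_self_similarity_is_one(self):
        A = _random_assoc(3)
        assert (np.diag(entropy_similarity(A, axis="circrna").values) == 1.0).all()

    @pytest.mark.parametrize("axis", ["drug", "circrna"])
    def test_matches_oracle(self, axis):
        A = _random_assoc(21)
        sim = entropy_similarity(A, axis=axis)
        np.testing.assert_allclose(sim.values, entropy_oracle(A.values, axis), atol=1e-10)


# ---------------------------------------------------------------------------
# shared invariants and persistence
# ---------------------------------------------------------------------------


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_kernels_symmetric_in_unit_range(seed):
    A = _random_assoc(seed)
    for sim in (
        gip_similarity(A, axis="drug"),
        gip_similarity(A, axis="circrna"),
        entropy_similarity(A, axis="drug"),
        entropy_similarity(A, axis="circrna"),
    ):
        np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-12)
        assert sim.values.min() >= 0.0 and sim.values.max() <= 1.0


def test_similarity_round_trip_bit_exact(tmp_path, rng):
    A = _random_assoc(3)
    sim = gip_similarity(A, axis="drug")
    p = tmp_path / "sim.csv"
    write_similarity(sim, p)
    back = read_similarity(p, SimilarityKind.gip)
    assert back.ids == sim.ids
    np.testing.assert_array_equal(back.values, sim.values)
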