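import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfblup.gamma import GammaMatrix
from mfblup.genomic import GenotypeMatrix
from mfblup.pedigree import (
    Pedigree,
    PedigreeError,
    a_gamma_inverse,
    a_gamma_matrix,
    a_inverse,
    a_matrix,
    genotype_pedigree_conflicts,
    inbreeding,
    sort_and_validate,
    upg_design,
)

from conftest import random_pedigree


class TestSortAndValidate:
    def test_child_first_is_reordered(self):
        ped = sort_and_validate(Pedigree(["C", "A", "B"], ["A", 0, 0], ["B", 0, 0]))
        assert ped.ids.index("C") > ped.ids.index("A")
        assert ped.ids.index("C") > ped.ids.index("B")

    def test_cycle_raises_naming_an_individual(self):
        with pytest.raises(PedigreeError, match="cycle"):
            sort_and_validate(Pedigree(["A", "B"], ["B", "A"], [0, 0]))

    def test_phantom_parents_materialized(self):
        ped = sort_and_validate(Pedigree(["X"], ["S"], ["D"]))
        assert sorted(ped.phantoms) == ["D", "S"]
        assert ped.n == 3

    def test_duplicate_id_raises(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            Pedigree(["A", "A"], [0, 0], [0, 0])

    def test_empty_raises(self):
        with pytest.raises(PedigreeError, match="empty"):
            sort_and_validate(Pedigree([], [], []))


class TestAMatrix:
    def test_trio(self, trio):
        A = a_matrix(trio, subset=["A", "B", "C"])
        assert np.allclose(
            A.to_dense(), [[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]]
        )

    def test_full_sibs(self):
        ped = sort_and_validate(
            Pedigree(["A", "B", "D", "E"], [0, 0, "A", "A"], [0, 0, "B", "B"])
        )
        A = a_matrix(ped, subset=["D", "E"])
        assert A.to_dense()[0, 1] == 0.5
        assert A.to_dense()[0, 0] == 1.0  # F(D) = 0

    def test_parent_offspring_mating_inbreeding(self):
        # C = A x B, then F = C x A: F(F) = 0.25
        ped = sort_and_validate(
            Pedigree(["A", "B", "C", "F"], [0, 0, "A", "C"], [0, 0, "B", "A"])
        )
        A = a_matrix(ped)
        i = A.entity_ids.index("F")
        assert A.to_dense()[i, i] == pytest.approx(1.25)
        assert inbreeding(ped)["F"] == pytest.approx(0.25)

    def test_subset_matches_full(self):
        ped = random_pedigree(80, 15, seed=4)
        full = a_matrix(ped)
        sub_ids = ped.ids[::7]
        sub = a_matrix(ped, subset=sub_ids)
        idx = full.index_of(sub_ids)
        assert np.allclose(sub.to_dense(), full.to_dense()[np.ix_(idx, idx)])

    def test_unknown_subset_id(self, trio):
        with pytest.raises(PedigreeError, match="unknown"):
            a_matrix(trio, subset=["nope"])


class TestAInverse:
    def test_trio_known_inverse(self, trio):
        Ainv = a_inverse(trio).submatrix(["A", "B", "C"]).to_dense()
        assert np.allclose(Ainv, [[1.5, 0.5, -1], [0.5, 1.5, -1], [-1, -1, 2]])

    def test_founders_only_identity(self):
        ped = sort_and_validate(Pedigree(["A", "B", "C"], [0] * 3, [0] * 3))
        assert np.allclose(a_inverse(ped).to_dense(), np.eye(3))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dense_inverse_oracle_random_pedigree(self, seed):
        ped = random_pedigree(200, 30, seed=seed)
        A = a_matrix(ped).to_dense()
        Ainv = a_inverse(ped).to_dense()
        assert np.max(np.abs(Ainv @ A - np.eye(ped.n))) < 1e-8


class TestAGamma:
    def test_single_mf_two_founders(self):
        gamma = GammaMatrix(["g"], [[0.5]])
        ped = sort_and_validate(
            Pedigree(["A", "B"], [0, 0], [0, 0], ["g", "g"], ["g", "g"])
        )
        AG = a_gamma_matrix(ped, gamma, include_metafounders=False).to_dense()
        assert np.allclose(AG, [[1.25, 0.5], [0.5, 1.25]])

    @settings(max_examples=25, deadline=None)
    @given(
        gam=st.floats(0.0, 1.0),
        seed=st.integers(0, 50),
    )
    def test_single_mf_closed_form(self, gam, seed):
        """A_gamma = (1 - gamma/2) A + gamma 11' on the individual block."""
        ped = random_pedigree(40, 8, k_groups=1, seed=seed)
        gamma = GammaMatrix(["g1"], [[gam]])
        AG = a_gamma_matrix(ped, gamma, include_metafounders=False).to_dense()
        A = a_matrix(ped).to_dense()
        closed = (1.0 - gam / 2.0) * A + gam
        assert np.max(np.abs(AG - closed)) < 1e-10

    def test_zero_gamma_equals_a(self):
        ped = random_pedigree(50, 10, k_groups=3, seed=5)
        gamma = GammaMatrix(["g1", "g2", "g3"], np.zeros((3, 3)))
        AG = a_gamma_matrix(ped, gamma, include_metafounders=False).to_dense()
        assert np.allclose(AG, a_matrix(ped).to_dense())

    def test_two_mf_cross_founder_relationship(self):
        gamma = GammaMatrix(["g1", "g2"], [[0.5, 0.2], [0.2, 0.5]])
        ped = sort_and_validate(
            Pedigree(["A", "B"], [0, 0], [0, 0], ["g1", "g2"], ["g1", "g2"])
        )
        AG = a_gamma_matrix(ped, gamma, include_metafounders=False).to_dense()
        assert AG[0, 1] == pytest.approx(0.2)
        assert AG[0, 0] == pytest.approx(1.25)

    def test_diag_dominates_plain_a_for_nonnegative_gamma(self):
        ped = random_pedigree(100, 20, k_groups=2, seed=9)
        gamma = GammaMatrix(["g1", "g2"], [[0.6, 0.1], [0.1, 0.4]])
        AG = a_gamma_matrix(ped, gamma, include_metafounders=False)
        A = a_matrix(ped)
        assert np.all(AG.diagonal() - A.diagonal() >= -1e-12)

    def test_unlabeled_missing_parent_raises(self):
        ped = sort_and_validate(Pedigree(["A"], [0], [0]))
        gamma = GammaMatrix(["g"], [[0.5]])
        with pytest.raises(PedigreeError, match="no metafounder label"):
            a_gamma_matrix(ped, gamma)


class TestAGammaInverse:
    def test_single_founder_hand_inverse(self):
        gamma = GammaMatrix(["g"], [[0.5]])
        ped = sort_and_validate(Pedigree(["A"], [0], [0], ["g"], ["g"]))
        AGi = a_gamma_inverse(ped, gamma).to_dense()
        AG = np.array([[1.25, 0.5], [0.5, 0.5]])
        assert np.allclose(AGi, np.linalg.inv(AG))

    @pytest.mark.parametrize("seed", [0, 3])
    def test_dense_inverse_oracle(self, seed):
        ped = random_pedigree(300, 40, k_groups=3, seed=seed)
        gamma = GammaMatrix(
            ["g1", "g2", "g3"],
            [[0.5, 0.2, 0.1], [0.2, 0.6, 0.15], [0.1, 0.15, 0.4]],
        )
        AG = a_gamma_matrix(ped, gamma).to_dense()
        AGi = a_gamma_inverse(ped, gamma).to_dense()
        assert np.max(np.abs(AGi @ AG - np.eye(AG.shape[0]))) < 1e-8

    def test_gamma_to_zero_limit_recovers_a_inverse(self):
        ped = random_pedigree(60, 12, k_groups=2, seed=1)
        eps = 1e-8
        gamma = GammaMatrix(["g1", "g2"], eps * np.eye(2))
        AGi = a_gamma_inverse(ped, gamma).to_dense()[: ped.n, : ped.n]
        Ainv = a_inverse(ped).to_dense()
        assert np.max(np.abs(AGi - Ainv)) < 1e-4

    def test_singular_gamma_raises(self):
        ped = random_pedigree(20, 5, k_groups=2, seed=2)
        gamma = GammaMatrix(["g1", "g2"], [[0.4, 0.4], [0.4, 0.4]])
        with pytest.raises(ValueError, match="PSD repair"):
            a_gamma_inverse(ped, gamma)


class TestUpgDesign:
    def test_founder_indicator_and_child_mean(self):
        ped = sort_and_validate(
            Pedigree(
                ["A", "B", "C", "D"],
                [0, 0, "A", "C"],
                [0, 0, "B", "B"],
                ["g1", "g2", None, None],
                ["g1", "g2", None, None],
            )
        )
        Q = upg_design(ped)
        assert Q.loc["A"].tolist() == [1.0, 0.0]
        assert Q.loc["C"].tolist() == [0.5, 0.5]
        # grandchild of (g1 x g2) x g2: (0.25, 0.75)
        assert Q.loc["D"].tolist() == [0.25, 0.75]

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 100), k=st.integers(1, 4))
    def test_rows_sum_to_one(self, seed, k):
        ped = random_pedigree(60, 10, k_groups=k, seed=seed)
        Q = upg_design(ped)
        assert np.allclose(Q.sum(axis=1), 1.0, atol=0)


class TestGenotypeConflicts:
    def test_true_pair_rate_zero(self, mini_dataset):
        report = genotype_pedigree_conflicts(
            mini_dataset.pedigree, mini_dataset.genotypes
        )
        assert len(report) > 0
        assert (report["rate"] == 0).all()

    def test_unrelated_pair_rate_matches_binomial(self):
        rng = np.random.default_rng(0)
        m = 1000
        geno = GenotypeMatrix(
            ["X", "Y"],
            [f"m{j}" for j in range(m)],
            rng.binomial(2, 0.5, size=(2, m)).astype(float),
        )
        ped = sort_and_validate(Pedigree(["X", "Y"], [0, "X"], [0, 0]))
        report = genotype_pedigree_conflicts(ped, geno)
        # expected opposing-homozygote rate 2 * 0.25 * 0.25 = 0.125
        se = np.sqrt(0.125 * 0.875 / m)
        assert abs(report["rate"].iloc[0] - 0.125) < 3 * se
        assert report["flagged"].iloc[0]

    def test_no_shared_ids_raises(self, trio):
        geno = GenotypeMatrix(["Z"], ["m1"], [[1.0]])
        with pytest.raises(ValueError, match="no ids shared"):
            genotype_pedigree_conflicts(trio, geno)
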