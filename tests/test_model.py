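import numpy as np
import pandas as pd
import pytest

from mfblup.gamma import GammaMatrix
from mfblup.model import ModelSpec, build_mme, fit, solve_blup
from mfblup.pedigree import (
    a_gamma_inverse,
    a_inverse,
    a_matrix,
    upg_design,
)
from mfblup.relmat import RelationshipMatrix

from conftest import random_pedigree


def ph(rows):
    return pd.DataFrame(rows, columns=["id", "site", "family", "value"])


class TestBuildAndSolve:
    def test_single_record_matches_hand_system(self):
        """One record, one site, one unrelated individual, one family."""
        sa2, sf2, se2 = 0.2, 0.1, 0.7
        spec = ModelSpec("ABLUP", sa2, sf2, se2)
        k_inv = RelationshipMatrix(["x"], np.eye(1), "A_inv")
        data = ph([("x", "s1", "f1", 1.0)])
        sol = fit(data, spec, k_inv)
        lam_a, lam_f = se2 / sa2, se2 / sf2
        M = np.array(
            [[1, 1, 1], [1, 1 + lam_a, 1], [1, 1, 1 + lam_f]], dtype=float
        )
        b, a, f = np.linalg.solve(M, np.ones(3))
        assert sol.fixed_effects["s1"] == pytest.approx(b)
        assert sol.additive["x"] == pytest.approx(a)
        assert sol.family["f1"] == pytest.approx(f)

    def test_trio_matches_dense_oracle(self, trio):
        spec = ModelSpec("ABLUP", 0.3, 0.1, 0.6)
        k_inv = a_inverse(trio)
        data = ph(
            [
                ("A", "s1", "f1", 0.8),
                ("B", "s1", "f1", -0.2),
                ("C", "s2", "f2", 1.4),
            ]
        )
        system = build_mme(data, spec, k_inv)
        sol = solve_blup(system)
        dense = np.linalg.solve(system.coeff.toarray(), system.rhs)
        stacked = np.concatenate(
            [sol.fixed_effects, sol.additive.reindex(system.entity_ids), sol.family]
        )
        assert np.allclose(stacked, dense, atol=1e-10)

    def test_duplicated_records_leave_solutions_unchanged_in_pattern(self, trio):
        spec = ModelSpec("ABLUP", 0.3, 0.1, 0.6)
        k_inv = a_inverse(trio)
        data = ph([("C", "s1", "f1", 1.0), ("A", "s1", "f1", -1.0)])
        sol1 = fit(data, spec, k_inv)
        sol2 = fit(pd.concat([data, data], ignore_index=True), spec, k_inv)
        # doubling every record doubles all information equally: shrinkage
        # changes, but ranking and signs stay consistent
        assert np.sign(sol1.additive["C"]) == np.sign(sol2.additive["C"])
        # and permuting record order changes nothing at all
        sol3 = fit(data.iloc[::-1].reset_index(drop=True), spec, k_inv)
        pd.testing.assert_series_equal(sol1.additive, sol3.additive)

    def test_unknown_id_lists_offenders(self, trio):
        spec = ModelSpec("ABLUP", 0.3, 0.1, 0.6)
        with pytest.raises(ValueError, match="ghost"):
            fit(ph([("ghost", "s1", "f1", 0.0)]), spec, a_inverse(trio))

    def test_wrong_kind_for_variant(self, trio):
        A = a_matrix(trio)
        spec = ModelSpec("ABLUP", 0.3, 0.1, 0.6)
        with pytest.raises(ValueError, match="kind"):
            build_mme(ph([("A", "s", "f", 0.0)]), spec, A)

    def test_cg_agrees_with_direct(self, mini_dataset):
        ds = mini_dataset
        spec = ModelSpec("ABLUP", 0.17, 0.04, 0.80)
        k_inv = a_inverse(ds.pedigree)
        s1 = fit(ds.phenotypes, spec, k_inv, method="direct")
        s2 = fit(ds.phenotypes, spec, k_inv, method="cg")
        assert np.max(np.abs(s1.additive - s2.additive)) < 1e-6

    def test_per_site_residual_mode(self, trio):
        data = ph([("A", "s1", "f1", 1.0), ("B", "s2", "f1", 0.5)])
        spec = ModelSpec(
            "ABLUP", 0.3, 0.1, 0.6, residual_mode="per-site",
            site_sigma_e2={"s1": 0.5, "s2": 1.0},
        )
        sol = fit(data, spec, a_inverse(trio))
        assert np.isfinite(sol.additive).all()


class TestMetafounderVariants:
    def make(self, seed=3):
        ped = random_pedigree(80, 15, k_groups=2, seed=seed)
        gamma = GammaMatrix(["g1", "g2"], [[0.5, 0.2], [0.2, 0.4]])
        rng = np.random.default_rng(seed)
        recs = [
            (i, f"s{rng.integers(2) + 1}", f"f{rng.integers(8) + 1}",
             float(rng.normal()))
            for i in ped.ids[20:]
        ]
        return ped, gamma, ph(recs)

    def test_apply_k_with_k_equal_one_is_noop(self):
        ped, _, data = self.make()
        # diagonal-equal gamma with zero off-diagonals gives k = 1 - off/2 = 1
        gamma = GammaMatrix(["g1", "g2"], 0.4 * np.eye(2))
        k_inv = a_gamma_inverse(ped, gamma)
        s_k = fit(data, ModelSpec("ABLUP_MF", 0.2, 0.05, 0.75, apply_k=True),
                  k_inv, gamma=gamma)
        s_nok = fit(data, ModelSpec("ABLUP_MF", 0.2, 0.05, 0.75, apply_k=False),
                    k_inv, gamma=gamma)
        assert np.allclose(s_k.additive, s_nok.additive, atol=1e-12)

    def test_mf_solutions_reported_separately(self):
        ped, gamma, data = self.make()
        k_inv = a_gamma_inverse(ped, gamma)
        sol = fit(data, ModelSpec("ABLUP_MF", 0.2, 0.05, 0.75), k_inv, gamma=gamma)
        assert list(sol.metafounders.index) == ["g1", "g2"]
        assert len(sol.additive) == ped.n

    def test_gamma_to_zero_shrinks_mf_to_ablup(self):
        ped, _, data = self.make()
        eps = 1e-7
        gamma = GammaMatrix(["g1", "g2"], eps * np.eye(2))
        k_inv = a_gamma_inverse(ped, gamma)
        s_mf = fit(data, ModelSpec("ABLUP_MF", 0.2, 0.05, 0.75, apply_k=False),
                   k_inv, gamma=gamma)
        s_ab = fit(data, ModelSpec("ABLUP", 0.2, 0.05, 0.75), a_inverse(ped))
        assert np.max(np.abs(s_mf.metafounders)) < 1e-6
        assert np.max(np.abs(s_mf.additive - s_ab.additive)) < 1e-6


class TestUpgQuaasPollak:
    def explicit_covariate_solutions(self, data, ped, spec, q):
        """Independent oracle: groups as explicit unpenalized covariates."""
        ids = list(ped.ids)
        sites = sorted(data["site"].unique())
        fams = sorted(data["family"].unique())
        groups = list(q.columns)[:-1]  # same reference-level drop
        n = len(data)
        X = np.zeros((n, len(sites)))
        Zq = np.zeros((n, len(groups)))
        Z = np.zeros((n, len(ids)))
        Z2 = np.zeros((n, len(fams)))
        for r, rec in enumerate(data.itertuples(index=False)):
            X[r, sites.index(rec.site)] = 1
            Z[r, ids.index(rec.id)] = 1
            Zq[r] = q.loc[rec.id, groups].to_numpy()
            Z2[r, fams.index(rec.family)] = 1
        lam_a = spec.sigma_e2 / spec.sigma_a2
        lam_f = spec.sigma_e2 / spec.sigma_f2
        Ainv = np.linalg.inv(a_matrix(ped).to_dense())
        W = np.hstack([X, Zq, Z, Z2])
        M = W.T @ W
        o = len(sites) + len(groups)
        M[o : o + len(ids), o : o + len(ids)] += Ainv * lam_a
        M[o + len(ids) :, o + len(ids) :] += np.eye(len(fams)) * lam_f
        y = data["value"].to_numpy()
        theta = np.linalg.solve(M, W.T @ y)
        g = theta[len(sites) : o]
        u = theta[o : o + len(ids)]
        total = u + q[groups].to_numpy() @ g
        return pd.Series(total, index=ids), pd.Series(g, index=groups)

    def test_qp_equivalence(self):
        ped = random_pedigree(120, 20, k_groups=3, seed=6)
        rng = np.random.default_rng(1)
        data = ph(
            [
                (i, f"s{rng.integers(3) + 1}", f"f{rng.integers(10) + 1}",
                 float(rng.normal()))
                for i in ped.ids[30:]
            ]
        )
        spec = ModelSpec("ABLUP_UPG", 0.25, 0.06, 0.7)
        q = upg_design(ped)
        sol = fit(data, spec, a_inverse(ped), q=q)
        total_oracle, g_oracle = self.explicit_covariate_solutions(
            data, ped, spec, q
        )
        assert np.max(np.abs(sol.additive - total_oracle)) < 1e-8
        assert np.max(np.abs(sol.groups[g_oracle.index] - g_oracle)) < 1e-8
        assert sol.groups[list(q.columns)[-1]] == 0.0  # reference level

    def test_upg_needs_q(self, trio):
        spec = ModelSpec("ABLUP_UPG", 0.2, 0.1, 0.7)
        with pytest.raises(ValueError, match="q"):
            fit(ph([("A", "s", "f", 0.1)]), spec, a_inverse(trio))


class TestHblupReducesToAblup:
    def test_g_equal_a22_identical_solutions(self, mini_dataset):
        from mfblup.hmatrix import h_inverse

        ds = mini_dataset
        gids = list(ds.genotypes.individual_ids)
        a22 = a_matrix(ds.pedigree, subset=gids)
        G = RelationshipMatrix(gids, a22.to_dense(), "G_blend")
        ainv = a_inverse(ds.pedigree)
        hinv = h_inverse(ainv, a22, G, gids)
        spec_h = ModelSpec("HBLUP", 0.17, 0.04, 0.80)
        spec_a = ModelSpec("ABLUP", 0.17, 0.04, 0.80)
        s_h = fit(ds.phenotypes, spec_h, hinv)
        s_a = fit(ds.phenotypes, spec_a, ainv)
        assert np.max(np.abs(s_h.additive - s_a.additive)) < 1e-8


class TestModelSpecValidation:
    def test_bad_variant(self):
        with pytest.raises(ValueError, match="variant"):
            ModelSpec("XBLUP", 0.1, 0.1, 0.8)

    def test_nonpositive_variance(self):
        with pytest.raises(ValueError, match="sigma_f2"):
            ModelSpec("ABLUP", 0.1, 0.0, 0.8)
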