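"""Genomic relationship building blocks and the mixed-model solvers."""

import numpy as np
import pandas as pd
import pytest

import crossblup as cb
from crossblup.model import (
    MMEFactor,
    ModelSpec,
    assemble_H,
    build_B,
    build_G,
    center_genotypes,
    solve_mme,
    solve_snp_level,
)
from conftest import random_pedigree


def _random_instance(seed, n_founders=8, n_total=20, n_geno=9, n_snps=25,
                     n_records=14, J_kind=None, w=0.05):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, n_founders, n_total)
    g = np.unique(rng.choice(ped.labels, n_geno, replace=False))
    dosages = rng.integers(0, 3, size=(len(g), n_snps)).astype(float)
    recs = rng.choice(ped.labels, n_records, replace=False)
    spec = ModelSpec(
        y=rng.normal(100, 15, n_records),
        fixed_levels=rng.integers(0, 3, n_records),
        record_animals=recs,
        dams=rng.integers(0, 4, n_records),
        ped=ped,
        var_a=69.01, var_c=43.73, var_e=151.07,
        genotypes=(g, dosages), w=w,
    )
    if J_kind == "ONE":
        spec.J = cb.compute_J_direct(cb.partition(ped, g), None, ped=ped)
    return spec


class TestGenotypeCentring:
    def test_simple_column(self):
        Zc, p = center_genotypes(np.array([[0.0], [1.0], [2.0]]))
        assert p[0] == 0.5
        assert np.allclose(Zc[:, 0], [-1, 0, 1])

    def test_monomorphic_column_warns_and_centres_to_zero(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            Zc, p = center_genotypes(np.full((4, 1), 2.0))
        assert p[0] == 1.0 and np.allclose(Zc, 0.0)

    def test_centred_columns_have_zero_mean(self, rng):
        Zc, _ = center_genotypes(rng.integers(0, 3, size=(50, 30)).astype(float))
        assert np.abs(Zc.mean(axis=0)).max() < 1e-12


class TestScalingFactors:
    def test_b_value(self):
        # 2 sum p(1-p) = 10 with w = 5% gives 0.95 / 10
        p = np.array([0.5] * 20)  # 2*sum(0.25) = 10
        assert build_B(p, 0.05) == pytest.approx(0.095)

    def test_b_limits(self):
        p = np.array([0.5, 0.5, 0.5])
        assert build_B(p, 1.0) == 0.0
        assert build_B(p, 0.0) == pytest.approx(1 / 1.5)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_B(np.array([0.0, 1.0]), 0.05)


class TestGenomicRelationships:
    def test_w_one_returns_pedigree_block(self, rng):
        ped = random_pedigree(rng, 5, 12)
        sub = cb.partition(ped, ped.labels[:6])
        Zc, p = center_genotypes(rng.integers(0, 3, (6, 30)).astype(float))
        G = build_G(Zc, build_B(p, 1.0), 1.0, sub.A_gg)
        assert np.allclose(G, sub.A_gg)

    def test_identical_genotypes_identical_entries(self, rng):
        dos = rng.integers(0, 3, (4, 40)).astype(float)
        dos[1] = dos[0]
        Zc, p = center_genotypes(dos)
        G = build_G(Zc, build_B(p, 0.0), 0.0, np.eye(4))
        assert G[0, 0] == pytest.approx(G[1, 1])
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_hardy_weinberg_diagonal_mean(self, rng):
        # unrelated individuals, genotypes at known p, centred at true p:
        # E[diag(G)] = 1 - w + w * diag(A) with A = I
        n, m, w = 400, 4000, 0.05
        p = rng.uniform(0.1, 0.9, m)
        dos = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
        Zc = dos - 2 * p
        G = build_G(Zc, (1 - w) / (2 * np.sum(p * (1 - p))), w, np.eye(n))
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.05)

    def test_h_routes_agree(self, rng):
        ped = random_pedigree(rng, 5, 12)
        g = np.unique(rng.choice(ped.labels, 5, replace=False))
        sub = cb.partition(ped, g)
        Zc, p = center_genotypes(rng.integers(0, 3, (5, 30)).astype(float))
        G = build_G(Zc, build_B(p, 0.05), 0.05, sub.A_gg)
        H1 = assemble_H(sub, G, "blocks")
        H2 = assemble_H(sub, G, "inverse")
        assert np.abs(H1 - H2).max() <= 1e-6

    def test_h_identity_cases(self, rng):
        ped = random_pedigree(rng, 5, 12)
        g = np.unique(rng.choice(ped.labels, 5, replace=False))
        sub = cb.partition(ped, g)
        assert np.allclose(assemble_H(sub, sub.A_gg), cb.a_matrix(ped)[
            np.ix_(np.concatenate([sub.nongenotyped_idx, sub.genotyped_idx]),
                   np.concatenate([sub.nongenotyped_idx, sub.genotyped_idx]))])
        sub_all = cb.partition(ped, ped.labels)
        G = sub_all.A_gg * 1.1
        assert np.allclose(assemble_H(sub_all, G), G)


class TestSolveMME:
    def test_w_one_equals_pedigree_blup(self):
        spec = _random_instance(3, w=1.0)
        sol_ss = solve_mme(spec)
        spec_ped = ModelSpec(y=spec.y, fixed_levels=spec.fixed_levels,
                             record_animals=spec.record_animals, dams=spec.dams,
                             ped=spec.ped, var_a=spec.var_a, var_c=spec.var_c,
                             var_e=spec.var_e)
        sol_ped = solve_mme(spec_ped)
        assert np.abs(sol_ss.u - sol_ped.u).max() <= 1e-8

    def test_single_record_shrinkage_closed_form(self):
        # one founder, one record, known mean level: the MME reduce to a
        # 3x3 system solved here independently as the oracle
        ped = cb.validate_and_sort([(1, 0, 0)])
        y = np.array([10.0])
        var_a, var_c, var_e = 40.0, 20.0, 100.0
        spec = ModelSpec(y=y, fixed_levels=np.array([0]),
                         record_animals=np.array([1]), dams=np.array([0]),
                         ped=ped, var_a=var_a, var_c=var_c, var_e=var_e)
        sol = solve_mme(spec)
        lam_a, lam_c = var_e / var_a, var_e / var_c
        LHS = np.array([[1, 1, 1], [1, 1 + lam_a, 1], [1, 1, 1 + lam_c]])
        b, u, c = np.linalg.solve(LHS, np.array([y[0], y[0], y[0]]))
        assert sol.u[0] == pytest.approx(u, abs=1e-10)
        assert sol.fixed_effects.iloc[0] == pytest.approx(b, abs=1e-10)

    def test_full_genotyping_one_equals_none(self):
        # every phenotyped animal genotyped: single J confounded with mean
        spec = _random_instance(11, n_geno=20, n_total=20, n_records=15)
        g, dos = spec.genotypes
        spec.record_animals = g[:15]
        spec.J = cb.compute_J_direct(cb.partition(spec.ped, g), None, ped=spec.ped)
        with pytest.warns(UserWarning, match="confounded"):
            sol_one = solve_mme(spec)
        spec.J = None
        sol_none = solve_mme(spec)
        assert sol_one.j_nonestimable.all()
        assert np.abs(sol_one.gebv - sol_none.gebv).max() <= 1e-10

    def test_phenotype_shift_moves_only_fixed_effects(self):
        spec = _random_instance(5, J_kind="ONE")
        sol = solve_mme(spec)
        spec_shift = ModelSpec(y=spec.y + 50.0, fixed_levels=spec.fixed_levels,
                               record_animals=spec.record_animals, dams=spec.dams,
                               ped=spec.ped, var_a=spec.var_a, var_c=spec.var_c,
                               var_e=spec.var_e, J=spec.J,
                               genotypes=spec.genotypes, w=spec.w)
        sol_s = solve_mme(spec_shift)
        assert np.abs(sol_s.gebv - sol.gebv).max() <= 1e-7
        assert np.allclose(sol_s.fixed_effects.values,
                           sol.fixed_effects.values + 50.0, atol=1e-7)

    def test_gebv_of_genotyped_equals_u_minus_mu(self):
        spec = _random_instance(6, J_kind="ONE")
        sol = solve_mme(spec)
        g = spec.genotypes[0]
        gi = spec.ped.index_of(g)
        assert np.allclose(sol.gebv[gi], sol.u[gi] - sol.j_coefficients[0])

    def test_factorization_reuse_matches_fresh_solves(self):
        spec = _random_instance(8)
        J = cb.compute_J_direct(cb.partition(spec.ped, spec.genotypes[0]),
                                None, ped=spec.ped)
        fac = MMEFactor(spec)
        sol_b = fac.solve(J)
        spec.J = J
        sol_f = solve_mme(spec)
        assert np.abs(sol_b.gebv - sol_f.gebv).max() <= 1e-9


class TestSNPLevelRoute:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_h_route(self, seed):
        spec = _random_instance(seed, J_kind="ONE" if seed % 2 else None)
        s1 = solve_mme(spec)
        s2 = solve_snp_level(spec)
        assert np.abs(s1.u - s2.u).max() <= 1e-6
        assert np.abs(s1.gebv - s2.gebv).max() <= 1e-6

    def test_w_one_reduces_to_pedigree_blup(self):
        spec = _random_instance(4, w=1.0)
        s2 = solve_snp_level(spec)
        assert s2.snp_effects.size == 0
        spec_ped = ModelSpec(y=spec.y, fixed_levels=spec.fixed_levels,
                             record_animals=spec.record_animals, dams=spec.dams,
                             ped=spec.ped, var_a=spec.var_a, var_c=spec.var_c,
                             var_e=spec.var_e)
        assert np.abs(s2.u - solve_mme(spec_ped).u).max() <= 1e-6

    def test_requires_genotypes(self):
        spec = _random_instance(9)
        spec.genotypes = None
        with pytest.raises(ValueError, match="genotypes"):
            solve_snp_level(spec)


class TestEstimators:
    def _data(self, spec):
        return pd.DataFrame({"animal": spec.record_animals, "y": spec.y,
                             "fixed": spec.fixed_levels, "dam": spec.dams})

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = cb.SingleStepSNPBLUP(var_a=10.0, w=0.1)
        params = est.get_params()
        assert params["w"] == 0.1 and params["var_a"] == 10.0
        est2 = clone(est).set_params(w=0.2)
        assert est2.get_params()["w"] == 0.2

    def test_fit_predict_roundtrip(self):
        spec = _random_instance(12)
        est = cb.SingleStepSNPBLUP(var_a=spec.var_a, var_c=spec.var_c,
                                   var_e=spec.var_e, w=spec.w)
        est.fit(self._data(spec), spec.ped, spec.genotypes)
        assert est.gebv_.shape == (spec.ped.n,)
        some = spec.ped.labels[:5]
        assert np.allclose(est.predict(some),
                           pd.Series(est.gebv_, index=est.animal_labels_).loc[some])

    def test_pedigree_blup_estimator_matches_solver(self):
        spec = _random_instance(13)
        est = cb.PedigreeBLUP(var_a=spec.var_a, var_c=spec.var_c, var_e=spec.var_e)
        est.fit(self._data(spec), spec.ped)
        spec_p = ModelSpec(y=spec.y, fixed_levels=spec.fixed_levels,
                           record_animals=spec.record_animals, dams=spec.dams,
                           ped=spec.ped, var_a=spec.var_a, var_c=spec.var_c,
                           var_e=spec.var_e)
        assert np.allclose(est.u_, solve_mme(spec_p).u)

    def test_snp_level_estimator_exposes_effects(self):
        spec = _random_instance(14)
        est = cb.SNPLevelSingleStep(var_a=spec.var_a, var_c=spec.var_c,
                                    var_e=spec.var_e, w=spec.w)
        est.fit(self._data(spec), spec.ped, spec.genotypes)
        assert est.snp_effects_.shape == (spec.genotypes[1].shape[1],)

    def test_input_validation(self):
        spec = _random_instance(15)
        df = self._data(spec).drop(columns=["dam"])
        with pytest.raises(ValueError, match="dam"):
            cb.PedigreeBLUP().fit(df, spec.ped)
        df2 = self._data(spec)
        df2.loc[0, "y"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cb.PedigreeBLUP().fit(df2, spec.ped)
        with pytest.raises(AttributeError, match="not fitted"):
            cb.PedigreeBLUP().predict([1])
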