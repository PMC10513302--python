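import numpy as np
import pandas as pd
import pytest

import palmbreed.genome as gn
from palmbreed.evaluation import (
    RelationshipMatrix,
    VarianceComponents,
    build_A,
    build_G,
    components_from_model,
    expected_hybrid_ffb,
    fit_gblup,
    fit_progeny_test_blup,
    make_ebv_table,
)
from palmbreed.genome import Pedigree, Population, build_genome_map
from palmbreed.fixtures import tiny_pedigree
from _panels import simulated_three_generation_panel


class TestBuildA:
    def test_unrelated_founders_give_identity(self):
        ped = Pedigree.from_records([(1, 0, 0), (2, 0, 0)])
        A = build_A(ped)
        np.testing.assert_allclose(A.values, np.eye(2))

    def test_parent_offspring_relationship_is_half(self):
        ped = Pedigree.from_records([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        A = build_A(ped)
        assert A.loc(1, 3) == pytest.approx(0.5)
        assert A.loc(3, 3) == pytest.approx(1.0)

    def test_selfed_offspring_diagonal_is_one_and_a_half(self):
        ped = Pedigree.from_records([(1, 0, 0), (2, 1, 1)])
        A = build_A(ped)
        assert A.loc(2, 2) == pytest.approx(1.5)

    def test_full_sib_mating_relationships(self):
        A = build_A(tiny_pedigree())
        assert A.loc(5, 6) == pytest.approx(0.5)      # full sibs
        assert A.loc(8, 8) == pytest.approx(1.25)     # F = 0.25
        assert A.loc(9, 9) == pytest.approx(1.5)      # selfing, F = 0.5

    def test_diagonal_equals_one_plus_pedigree_inbreeding(self):
        # cross-module identity with the recursive kinship calculation
        from palmbreed.inbreeding import genealogical_inbreeding

        rng = np.random.default_rng(3)
        ped = Pedigree.from_records([(i, 0, 0) for i in range(1, 7)])
        pool = list(range(1, 7))
        for _ in range(40):  # 4 overlapping generations with selfing allowed
            m, f = rng.choice(pool[-12:], size=2)
            pool.append(ped.add_offspring(int(m), int(f)))
        A = build_A(ped)
        F = genealogical_inbreeding(ped)
        np.testing.assert_allclose(A.diagonal(), 1.0 + F.to_numpy(), atol=1e-10)

    def test_unordered_pedigree_rejected(self):
        ped = tiny_pedigree()
        ped._order.reverse()
        with pytest.raises(ValueError):
            build_A(ped)


class TestBuildG:
    def test_duplicate_genotypes_share_relationship(self, rng):
        dos = rng.integers(0, 3, size=(3, 200))
        dos[1] = dos[0]
        p = np.full(200, 0.5)
        G = build_G([1, 2, 3], dos, p)
        assert G.loc(1, 2) == pytest.approx(G.loc(1, 1))

    def test_individual_at_base_expectation_has_zero_row(self):
        p = np.full(100, 0.5)
        dos = np.vstack([np.ones(100), np.zeros(100)])
        G = build_G([1, 2], dos, p)
        assert G.loc(1, 1) == pytest.approx(0.0)
        assert G.loc(1, 2) == pytest.approx(0.0)

    def test_monomorphic_panel_is_an_error(self):
        with pytest.raises(ValueError):
            build_G([1, 2], np.zeros((2, 10)), np.zeros(10))

    def test_genomic_matches_pedigree_relationships(self):
        # 3-generation pedigree, >=2000 markers: cor(A_ij, G_ij) > 0.8
        ped, ids, dos, base_freqs = simulated_three_generation_panel()
        A = build_A(ped, ids=ids)
        G = build_G(ids, dos, base_freqs)
        iu = np.triu_indices(ids.size, k=1)
        r = np.corrcoef(A.values[iu], G.values[iu])[0, 1]
        assert r > 0.8
        # mean diagonal tracks 1 + F
        assert G.diagonal().mean() == pytest.approx(A.diagonal().mean(), abs=0.12)


def synthetic_progeny_test(seed, n_parents=40, noise_sd=0.0, n_offspring=2):
    """Additive-truth hybrid phenotypes from two unrelated parent sets."""
    rng = np.random.default_rng(seed)
    ids_a = np.arange(1, n_parents + 1)
    ids_b = np.arange(101, 101 + n_parents)
    tbv_a = rng.normal(0, 1, n_parents)
    tbv_b = rng.normal(0, 1, n_parents)
    perm = rng.permutation(n_parents)
    pairs = [(a, int(perm[a])) for a in range(n_parents)]  # both sides covered
    pairs += [
        (a, int(b))
        for a in range(n_parents)
        for b in rng.integers(0, n_parents, n_offspring - 1)
    ]
    rows = []
    for i, j in pairs:
        y = 0.5 * tbv_a[i] + 0.5 * tbv_b[j] + rng.normal(0, noise_sd)
        rows.append({"parent_a": ids_a[i], "parent_b": ids_b[j],
                     "bn_pheno": y, "bw_pheno": y})
    K_a = RelationshipMatrix(ids_a, np.eye(n_parents), "pedigree")
    K_b = RelationshipMatrix(ids_b, np.eye(n_parents), "pedigree")
    return pd.DataFrame(rows), K_a, K_b, tbv_a, tbv_b


class TestProgenyTestBlup:
    def test_noiseless_limit_recovers_truth(self):
        phen, K_a, K_b, tbv_a, tbv_b = synthetic_progeny_test(1, noise_sd=0.0)
        vc = {t: VarianceComponents(0.25, 0.25, 1e-4) for t in ("bn", "bw")}
        tab_a, tab_b, fits = fit_progeny_test_blup(phen, K_a, K_b, vc)
        assert np.corrcoef(tab_a["g_bn"], tbv_a)[0, 1] > 0.99
        assert np.corrcoef(tab_b["g_bn"], tbv_b)[0, 1] > 0.99
        assert fits["bn"].residual_norm < 1e-8

    def test_permuted_phenotypes_give_null_accuracy(self):
        rs = []
        for rep in range(5):
            phen, K_a, K_b, tbv_a, _ = synthetic_progeny_test(10 + rep, noise_sd=0.2)
            rng = np.random.default_rng(rep)
            phen["bn_pheno"] = rng.permutation(phen["bn_pheno"].to_numpy())
            vc = {t: VarianceComponents(0.25, 0.25, 0.5) for t in ("bn", "bw")}
            tab_a, _, _ = fit_progeny_test_blup(phen, K_a, K_b, vc)
            rs.append(np.corrcoef(tab_a["g_bn"], tbv_a)[0, 1])
        assert abs(np.mean(rs)) < 0.25

    def test_mixed_model_equations_satisfied(self):
        phen, K_a, K_b, _, _ = synthetic_progeny_test(2, noise_sd=0.5)
        vc = {t: VarianceComponents(0.25, 0.25, 0.5) for t in ("bn", "bw")}
        _, _, fits = fit_progeny_test_blup(phen, K_a, K_b, vc)
        for f in fits.values():
            assert f.residual_norm < 1e-8

    def test_progeny_test_accuracy_on_simulated_scheme(self, small_state, small_config):
        # pedigree BLUP from a hybrid progeny test reaches high accuracy
        from palmbreed.scheme import evaluate_candidates, run_progeny_test

        state = small_state.clone()
        rng = np.random.default_rng(50)
        state.training = run_progeny_test(state, small_config, rng)
        ebvs = evaluate_candidates(state, small_config, rng)
        lame = state.pops["LaMe"]
        tab = ebvs["LaMe"].set_index("individual_id").loc[lame.ids]
        truth = state.model.tbv(lame, "bn")
        acc = np.corrcoef(tab["g_bn"], truth)[0, 1]
        assert acc > 0.6


class TestGblup:
    def test_duplicated_candidate_genotypes_get_identical_gebvs(self):
        phen, K_a, K_b, _, _ = synthetic_progeny_test(3, noise_sd=0.3, n_parents=20)
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(22, 400)).astype(float)
        dos[21] = dos[20]
        ids_b = np.concatenate([K_b.ids, [990, 991]])
        dos[:20] = rng.integers(0, 3, size=(20, 400))
        G_b = build_G(ids_b, dos, np.full(400, 0.5))
        vc = {t: VarianceComponents(0.25, 0.25, 0.5) for t in ("bn", "bw")}
        _, tab_b, _ = fit_gblup(phen, K_a, G_b, vc)
        g = tab_b.set_index("individual_id")
        assert g.loc[990, "g_bn"] == pytest.approx(g.loc[991, "g_bn"], abs=1e-8)

    def test_infinite_residual_shrinks_to_training_mean(self):
        phen, K_a, K_b, _, _ = synthetic_progeny_test(4, noise_sd=0.3)
        vc = {t: VarianceComponents(0.25, 0.25, 1e9) for t in ("bn", "bw")}
        tab_a, _, fits = fit_progeny_test_blup(phen, K_a, K_b, vc)
        # all deviations shrink to ~0, so g collapses to mu_hat / 2
        assert tab_a["g_bn"].std() < 1e-3
        assert tab_a["g_bn"].mean() == pytest.approx(fits["bn"].mu_hat / 2, abs=1e-3)

    def test_untested_candidate_accuracy_below_progeny_test(self, small_state, small_config):
        # genomic prediction of unphenotyped candidates is less accurate
        # than the progeny test of their parents, on the matched simulation
        from dataclasses import replace

        import palmbreed.scheme as sc

        state = small_state.clone()
        cfg = replace(small_config, scheme="RRGS")
        rng = np.random.default_rng(60)
        state.training = sc.run_progeny_test(state, cfg, rng)
        state.training_parents = {
            "Deli": sorted(set(int(i) for i in state.training["parent_a"])),
            "LaMe": sorted(set(int(i) for i in state.training["parent_b"])),
        }
        ebvs = sc.evaluate_candidates(state, cfg, rng)
        lame = state.pops["LaMe"]
        tested_acc = np.corrcoef(
            ebvs["LaMe"].set_index("individual_id").loc[lame.ids, "g_bn"],
            state.model.tbv(lame, "bn"),
        )[0, 1]
        # next generation, no new progeny test: GEBVs through G only
        designs = sc.select_and_mate(state, cfg, "conventional", ebvs, rng)
        sc.advance_generation(state, cfg, designs, rng)
        ebvs2 = sc.evaluate_candidates(state, cfg, rng)
        lame2 = state.pops["LaMe"]
        untested_acc = np.corrcoef(
            ebvs2["LaMe"].set_index("individual_id").loc[lame2.ids, "g_bn"],
            state.model.tbv(lame2, "bn"),
        )[0, 1]
        assert untested_acc < tested_acc
        assert untested_acc > 0.2

    def test_accuracy_increases_with_training_size(self):
        # replicate-averaged monotone trend over nested training subsets
        sizes = (30, 90, 240)
        acc = {s: [] for s in sizes}
        for rep in range(3):
            phen, K_a, K_b, _, tbv_b = synthetic_progeny_test(
                70 + rep, n_parents=40, noise_sd=1.2, n_offspring=6
            )
            vc = {t: VarianceComponents(0.25, 0.25, 1.44) for t in ("bn", "bw")}
            for s in sizes:
                sub = phen.iloc[:s]
                tab_a, tab_b, _ = fit_progeny_test_blup(sub, K_a, K_b, vc)
                acc[s].append(np.corrcoef(tab_b["g_bn"], tbv_b)[0, 1])
        means = [np.mean(acc[s]) for s in sizes]
        assert means[-1] > means[0]


class TestExpectedHybridFfb:
    def test_all_zero_inputs_give_zero(self):
        assert expected_hybrid_ffb((0, 0), (0, 0), (0, 0), (0, 0)) == 0.0

    def test_direct_formula_evaluation(self):
        # Deli BN 4,4; La Me BN 6,6; Deli BW 2,2; La Me BW 3,3 -> (4+6)(2+3)
        val = expected_hybrid_ffb((4, 2), (4, 2), (6, 3), (6, 3))
        assert val == pytest.approx(50.0)

    def test_within_population_swap_invariance(self, rng):
        for _ in range(20):
            gdi, gdj, gli, glj = (tuple(rng.normal(5, 1, 2)) for _ in range(4))
            assert expected_hybrid_ffb(gdi, gdj, gli, glj) == pytest.approx(
                expected_hybrid_ffb(gdj, gdi, gli, glj)
            )
            assert expected_hybrid_ffb(gdi, gdj, gli, glj) == pytest.approx(
                expected_hybrid_ffb(gdi, gdj, glj, gli)
            )


class TestEbvTable:
    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError):
            make_ebv_table([1], [np.nan], [0.0], "x")

    def test_components_from_model_follow_quarter_rule(self, small_state):
        vc = components_from_model(small_state.model, "Deli", "LaMe")
        assert vc["bn"].gca_a == pytest.approx(small_state.model.var_a["Deli"][0] / 4)
        assert vc["bw"].gca_b == pytest.approx(small_state.model.var_a["LaMe"][1] / 4)
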