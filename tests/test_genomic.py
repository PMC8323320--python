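import numpy as np
import pandas as pd
import pytest

from beegs.breeding import sample_genotyped_sets
from beegs.config import generate_fixture
from beegs.genomic import (
    DegeneratePanelError,
    GenotypeMatrix,
    MMESpec,
    NonIdentifiableAdjustmentError,
    adjust_constants,
    adjust_grm,
    blend_grm,
    build_H_inverse,
    build_grm,
    merge_pseudofathers_grm,
    run_analysis,
    solve_mixed_model,
)
from beegs.relationship import build_numerator_A
from beegs.trait_model import MOD, TraitBase

from conftest import gls_oracle


class TestGrm:
    def test_single_locus_toy_panel(self):
        geno = generate_fixture("grm-toy")
        G = build_grm(geno)
        assert np.allclose(G, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])

    def test_duplicated_individual_rows_equal(self):
        rng = np.random.default_rng(0)
        M = rng.integers(0, 3, size=(6, 30)).astype(float)
        M[3] = M[0]
        G = build_grm(GenotypeMatrix(ids=[f"q{i}" for i in range(6)], M=M))
        assert np.allclose(G[0], G[3])
        assert G[0, 0] == pytest.approx(G[3, 3])

    def test_matches_naive_double_loop(self):
        # brute-force evaluation of the VanRaden quotient, element by element
        rng = np.random.default_rng(1)
        M = rng.integers(0, 3, size=(20, 100)).astype(float)
        geno = GenotypeMatrix(ids=[f"q{i}" for i in range(20)], M=M)
        G = build_grm(geno)
        p = geno.p
        denom = 2 * np.sum(p * (1 - p))
        naive = np.empty((20, 20))
        for i in range(20):
            for j in range(20):
                naive[i, j] = np.sum((M[i] - 2 * p) * (M[j] - 2 * p)) / denom
        assert np.abs(G - naive).max() < 1e-10

    def test_monomorphic_panel_rejected(self):
        M = np.full((4, 10), 2.0)
        with pytest.raises(DegeneratePanelError):
            build_grm(GenotypeMatrix(ids=list("abcd"), M=M))


class TestAdjustment:
    def test_identity_when_means_already_match(self):
        rng = np.random.default_rng(2)
        A_g = np.eye(5) + 0.1
        alpha, beta = adjust_constants(A_g, A_g)
        assert alpha == pytest.approx(0.0, abs=1e-12)
        assert beta == pytest.approx(1.0)

    def test_defining_property_of_means(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 40))
        G = X @ X.T / 40
        A_g = np.eye(8) * 1.02 + 0.05
        out = adjust_grm(G, A_g)
        n = 8
        assert np.trace(out) / n == pytest.approx(np.trace(A_g) / n, abs=1e-12)
        off = lambda m: (m.sum() - np.trace(m)) / (n * (n - 1))
        assert off(out) == pytest.approx(off(A_g), abs=1e-12)

    def test_three_by_three_hand_solution(self):
        G = np.array([[1.0, 0.2, 0.4], [0.2, 1.2, 0.0], [0.4, 0.0, 0.8]])
        A_g = np.array([[1.1, 0.3, 0.3], [0.3, 1.0, 0.2], [0.3, 0.2, 1.05]])
        # solve the 2x2 system by hand: mean diag, mean offdiag
        dG, dA = 1.0, 1.05
        oG, oA = 0.2, 8 / 30
        beta = (dA - oA) / (dG - oG)
        alpha = oA - beta * oG
        out = adjust_grm(G, A_g)
        assert np.allclose(out, alpha + beta * G)

    def test_flat_grm_not_identifiable(self):
        G = np.full((4, 4), 0.5)
        with pytest.raises(NonIdentifiableAdjustmentError):
            adjust_grm(G, np.eye(4))


class TestBlend:
    def test_weight_one_returns_adjusted(self):
        G = np.eye(3) * 1.5
        assert np.allclose(blend_grm(G, np.eye(3), 1.0), G)

    def test_equal_inputs_fixed_point(self):
        A_g = np.eye(4) + 0.2
        for w in (0.5, 0.95):
            assert np.allclose(blend_grm(A_g, A_g, w), A_g)

    def test_restores_full_rank(self):
        # duplicated genotypes make G singular; blending repairs it
        rng = np.random.default_rng(4)
        M = rng.integers(0, 3, size=(5, 50)).astype(float)
        M[4] = M[0]
        G = build_grm(GenotypeMatrix(ids=list("abcde"), M=M))
        A_g = np.eye(5) + 0.03
        G_w = blend_grm(adjust_grm(G, A_g), A_g, 0.95)
        assert np.linalg.eigvalsh(G_w).min() > 0


class TestMergePseudofathers:
    def test_identical_member_genotypes_collapse(self):
        rng = np.random.default_rng(8)
        row = np.array([0.0, 1, 2, 1, 0, 2, 1, 2, 0, 1])
        other = rng.integers(0, 3, size=10).astype(float)
        M = np.vstack([row, row, row, row, other])
        G = build_grm(GenotypeMatrix(ids=list("abcde"), M=M))
        merged = merge_pseudofathers_grm(G, [[4], [0, 1, 2, 3]])
        assert merged[1, 1] == pytest.approx(G[0, 0])
        assert merged[0, 1] == pytest.approx(G[4, 0])

    def test_singleton_groups_identity(self):
        rng = np.random.default_rng(5)
        G = rng.normal(size=(4, 4))
        G = G + G.T
        merged = merge_pseudofathers_grm(G, [[0], [1], [2], [3]])
        assert np.allclose(merged, G)

    def test_matches_direct_sum_evaluation(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(7, 30))
        G = X @ X.T / 30
        groups = [[0], [1], [2, 3, 4], [5, 6]]
        merged = merge_pseudofathers_grm(G, groups)
        # pseudo-father diagonal: full member-grid mean including diagonal
        g = groups[2]
        direct = sum(G[d, b] for d in g for b in g) / len(g) ** 2
        assert merged[2, 2] == pytest.approx(direct, abs=1e-12)
        direct_off = sum(G[d, 5] + G[d, 6] for d in g) / (len(g) * 2)
        assert merged[2, 3] == pytest.approx(direct_off, abs=1e-12)


class TestHInverse:
    def test_empty_genotyped_set_is_A_inverse(self):
        A = np.eye(4) + 0.1
        A_inv = np.linalg.inv(A)
        H_inv = build_H_inverse(
            A_inv, np.empty((0, 0)), np.empty((0, 0)), np.array([], dtype=int)
        )
        assert np.allclose(H_inv, A_inv)

    def test_blocks_cancel_when_G_equals_A(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 6))
        A = X @ X.T + 6 * np.eye(6)
        A_inv = np.linalg.inv(A)
        idx = np.array([1, 3, 4])
        A_g = A[np.ix_(idx, idx)]
        H_inv = build_H_inverse(
            A_inv, np.linalg.inv(A_g), np.linalg.inv(A_g), idx
        )
        assert np.allclose(H_inv, A_inv)

    def test_inverse_restricted_to_genotyped_block(self, small_history):
        # (H_inv)^-1 on the genotyped block reproduces G_w
        geno = sample_genotyped_sets(small_history, 0.3, seed=1)
        ebv, det = run_analysis(
            small_history, "ssGBLUP_BQ", MOD, genotyped=geno, return_details=True
        )
        H = np.linalg.inv(det["K_inv"])
        R = det["A"]
        idx = np.array([R.index[i] for i in det["genotyped_ids"]])
        assert np.abs(H[np.ix_(idx, idx)] - det["G_w"]).max() < 1e-8


class TestMixedModel:
    def test_matches_gls_oracle_pblup(self):
        history = generate_fixture("mme-small", seed=4)
        ebv, det = run_analysis(
            history, "PBLUP", MOD, return_details=True
        )
        K = np.linalg.inv(det["K_inv"])
        ids, a_hat, m_hat, fixed = gls_oracle(history, MOD, K)
        table = ebv.set_index("id")
        assert np.abs(table.loc[ids, "ebv_direct"].to_numpy() - a_hat).max() < 1e-8
        assert np.abs(table.loc[ids, "ebv_maternal"].to_numpy() - m_hat).max() < 1e-8

    def test_matches_gls_oracle_ssgblup(self):
        history = generate_fixture("mme-small", seed=4)
        geno = sample_genotyped_sets(
            history, 1.0, include_dpq=True, seed=0,
            bq_years=(2, 3), extra_years=(4,), dpq_deploy_years=(3, 4),
        )
        ebv, det = run_analysis(
            history, "ssGBLUP_DPQ+BQ", MOD, genotyped=geno, return_details=True
        )
        K = np.linalg.inv(det["K_inv"])
        ids, a_hat, m_hat, _ = gls_oracle(history, MOD, K)
        table = ebv.set_index("id")
        assert np.abs(table.loc[ids, "ebv_direct"].to_numpy() - a_hat).max() < 1e-8

    def test_constant_phenotypes_give_zero_ebv(self):
        history = generate_fixture("mme-small", seed=4)
        const = history.worker_groups.copy()
        const.loc[const.phenotype.notna(), "phenotype"] = 3.7
        history.worker_groups = const
        ebv = run_analysis(history, "PBLUP", MOD)
        assert np.abs(ebv[["ebv_direct", "ebv_maternal"]].to_numpy()).max() < 1e-8

    def test_maternal_ebv_shrink_with_maternal_variance(self):
        history = generate_fixture("mme-small", seed=4)
        norms = []
        for sm in (1.0, 0.3, 0.05):
            trait = TraitBase(2.0, sm, 0.0, 1.0)
            ebv = run_analysis(history, "PBLUP", trait)
            norms.append(np.abs(ebv.ebv_maternal).mean())
        assert norms[0] > norms[1] > norms[2]


class TestAnalysisStructure:
    def test_empty_genotype_set_equals_pblup(self, small_history):
        p = run_analysis(small_history, "PBLUP", MOD)
        s = run_analysis(small_history, "ssGBLUP_BQ", MOD, genotyped={"bq": []})
        assert np.allclose(
            p[["ebv_direct", "ebv_maternal"]], s[["ebv_direct", "ebv_maternal"]],
            atol=1e-10,
        )

    def test_merging_pseudofathers_leaves_other_ebv_unchanged(self, small_history):
        geno = sample_genotyped_sets(
            small_history, 0.5, include_dpq=True, seed=2
        )
        merged = run_analysis(
            small_history, "ssGBLUP_DPQ+BQ", MOD, genotyped=geno, merged=True
        ).set_index("id")
        split = run_analysis(
            small_history, "ssGBLUP_DPQ+BQ", MOD, genotyped=geno, merged=False
        ).set_index("id")
        common = [
            i for i in merged.index
            if i in split.index and merged.loc[i, "type"] != "pseudofather"
        ]
        diff = np.abs(
            merged.loc[common, ["ebv_direct", "ebv_maternal"]].to_numpy()
            - split.loc[common, ["ebv_direct", "ebv_maternal"]].to_numpy()
        )
        assert diff.max() < 1e-8

    def test_unphenotyped_worker_groups_do_not_affect_others(self):
        import copy

        history = generate_fixture("mme-small", seed=4)
        full = run_analysis(history, "PBLUP", MOD).set_index("id")
        last = history.config.years - 1
        pruned = copy.copy(history)
        wg = history.worker_groups
        pruned.worker_groups = wg.loc[wg.year != last].reset_index(drop=True)
        reduced = run_analysis(pruned, "PBLUP", MOD).set_index("id")
        diff = np.abs(
            full.loc[reduced.index, ["ebv_direct", "ebv_maternal"]].to_numpy()
            - reduced[["ebv_direct", "ebv_maternal"]].to_numpy()
        )
        assert diff.max() < 1e-8
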