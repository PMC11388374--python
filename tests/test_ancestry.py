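"""Admixture EM, block bootstrap, pooling and congruence checks."""

import numpy as np
import pandas as pd
import pytest

from kindred import (
    AdmixtureModel,
    admixture_loglik,
    congruence_correlation,
    emit_genotype_likelihoods,
    estimate_admixture,
    pool_components,
    simulate_pedigree_genotypes,
    simulate_reference_panel,
)
from kindred.ancestry import BootstrapResult, _em_step
from kindred.gl import GLMatrix, ReferencePanel
from kindred.simulate import PedigreeSpec


class TestLoglik:
    def test_uniform_gls_give_constant_s_log_third(self, two_pop_panel):
        S = two_pop_panel.gmap.n_sites
        gl = np.full((S, 3), 1 / 3)
        lls = [
            admixture_loglik(q, gl, two_pop_panel.freqs)
            for q in (np.array([1.0, 0.0]), np.array([0.3, 0.7]))
        ]
        assert np.allclose(lls, S * np.log(1 / 3), atol=1e-6)
        assert abs(lls[0] - lls[1]) < 1e-8

    def test_single_population_likelihood_ignores_q(self):
        panel = simulate_reference_panel(1, 500, 0.2, seed=3)
        rng = np.random.default_rng(4)
        gl = rng.dirichlet(np.ones(3), size=500)
        assert admixture_loglik(np.array([1.0]), gl, panel.freqs) == pytest.approx(
            admixture_loglik(np.array([1.0]), gl, panel.freqs)
        )

    def test_dimension_mismatch_rejected(self, two_pop_panel):
        with pytest.raises(ValueError):
            admixture_loglik(np.array([0.5, 0.5]), np.full((7, 3), 1 / 3),
                             two_pop_panel.freqs[:5])

    def test_off_simplex_rejected(self, two_pop_panel):
        S = two_pop_panel.gmap.n_sites
        with pytest.raises(ValueError):
            admixture_loglik(np.array([0.9, 0.9]), np.full((S, 3), 1 / 3),
                             two_pop_panel.freqs)

    def test_em_iterates_never_decrease_loglik(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            S, K = 300, 3
            freqs = np.clip(rng.random((S, K)), 1e-5, 1 - 1e-5)
            gl = rng.dirichlet(np.ones(3), size=S)
            q = rng.dirichlet(np.ones(K))
            lls = []
            for _ in range(50):
                q, ll = _em_step(q, gl, freqs)
                lls.append(ll)
            assert np.all(np.diff(lls) >= -1e-8)


class TestEstimate:
    def test_pure_ancestry_recovered(self, two_pop_panel):
        spec = PedigreeSpec(founders={"X": np.array([1.0, 0.0])})
        haps, _ = simulate_pedigree_genotypes(two_pop_panel, spec, seed=21)
        glm = emit_genotype_likelihoods(haps, two_pop_panel.gmap, 5.0, 0.005, seed=22)
        res = AdmixtureModel.from_matrix(glm, two_pop_panel, "X").fit(restarts=5, seed=23)
        assert res.params.iloc[0] >= 0.95
        assert res.converged

    def test_estimate_on_simplex_and_summary_prints(self, two_pop_panel):
        spec = PedigreeSpec(founders={"X": np.array([0.5, 0.5])})
        haps, _ = simulate_pedigree_genotypes(two_pop_panel, spec, seed=24)
        glm = emit_genotype_likelihoods(haps, two_pop_panel.gmap, 1.0, 0.005, seed=25)
        res = AdmixtureModel.from_matrix(glm, two_pop_panel, "X").fit(restarts=3, seed=26)
        q = res.params.to_numpy()
        assert np.all(q >= 0) and abs(q.sum() - 1) < 1e-9
        assert "ancestry" not in res.summary()  # a table, not prose
        assert "POP1" in res.summary()

    def test_admixed_truth_recovered_and_matches_grid_search(self):
        # recovery at scale
        panel = simulate_reference_panel(2, 100_000, 0.1, seed=31)
        spec = PedigreeSpec(founders={"X": np.array([0.7, 0.3])})
        haps, _ = simulate_pedigree_genotypes(panel, spec, seed=32)
        glm = emit_genotype_likelihoods(haps, panel.gmap, 1.0, 0.005, seed=33)
        res = AdmixtureModel.from_matrix(glm, panel, "X").fit(restarts=5, seed=34)
        assert np.all(np.abs(res.params.to_numpy() - [0.7, 0.3]) < 0.05)
        # EM optimum vs exhaustive simplex grid at 0.01 on a small instance
        idx = np.arange(2000)
        sub = glm.subset_sites(idx)
        panel_sub = ReferencePanel(list(panel.populations), sub.gmap, panel.freqs[idx])
        res_small = AdmixtureModel.from_matrix(sub, panel_sub, "X").fit(restarts=10, seed=35)
        gl, miss = sub.individual("X")
        grid = np.linspace(0, 1, 101)
        lls = [
            admixture_loglik(np.array([a, 1 - a]), gl[~miss], panel_sub.freqs[~miss])
            for a in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert abs(res_small.params.iloc[0] - best) < 0.02

    def test_no_informative_sites_rejected(self, two_pop_panel):
        S = two_pop_panel.gmap.n_sites
        with pytest.raises(ValueError, match="informative"):
            estimate_admixture(
                np.full((S, 3), 1 / 3), two_pop_panel.freqs,
                restarts=2, seed=1, missing=np.ones(S, dtype=bool),
            )


class TestBootstrap:
    @pytest.fixture(scope="class")
    def fitted(self, two_pop_panel):
        spec = PedigreeSpec(founders={"X": np.array([0.6, 0.4])})
        haps, _ = simulate_pedigree_genotypes(two_pop_panel, spec, seed=41)
        glm = emit_genotype_likelihoods(haps, two_pop_panel.gmap, 2.0, 0.005, seed=42)
        return AdmixtureModel.from_matrix(glm, two_pop_panel, "X").fit(restarts=5, seed=43)

    def test_replicates_on_simplex_and_reproducible(self, fitted):
        b1 = fitted.bootstrap(B=8, seed=44, restarts=2)
        b2 = fitted.bootstrap(B=8, seed=44, restarts=2)
        assert np.allclose(b1.replicates, b2.replicates)
        assert np.all(b1.replicates >= 0)
        assert np.allclose(b1.replicates.sum(axis=1), 1, atol=1e-9)

    def test_homogeneous_blocks_give_near_zero_sd(self):
        # identical strongly informative data in every block
        from kindred.genome import GeneticMap

        n_blocks, per = 12, 40
        chrom = np.repeat([f"chr{i}" for i in range(1, 4)], 4 * per)
        pos = np.tile(
            np.concatenate([b * 10_000_000 + np.arange(1, per + 1) * 1000 for b in range(4)]), 3
        )
        gmap = GeneticMap(chrom, pos, pos * 1e-6)
        block = np.linspace(0.05, 0.95, per)
        freqs = np.stack([np.tile(block, n_blocks), np.tile(block[::-1], n_blocks)], axis=1)
        panel = ReferencePanel(["A", "B"], gmap, freqs)
        rng = np.random.default_rng(45)
        gl_block = rng.dirichlet(np.ones(3) * 2, size=per)
        gl = np.tile(gl_block, (n_blocks, 1))
        res = AdmixtureModel(gl, panel).fit(restarts=4, seed=46)
        boot = res.bootstrap(B=10, seed=47, restarts=2)
        assert np.all(boot.sd < 1e-6)

    def test_pooling_two_confusable_components_narrows_interval(self):
        # panel in which populations B1 and B2 are nearly identical
        base = simulate_reference_panel(2, 6000, 0.1, seed=48)
        rng = np.random.default_rng(49)
        anc = base.freqs[:, 1]
        f_small = 0.002
        f3 = np.stack(
            [base.freqs[:, 0]]
            + [rng.beta(anc * (1 - f_small) / f_small, (1 - anc) * (1 - f_small) / f_small)
               for _ in range(2)],
            axis=1,
        )
        panel3 = ReferencePanel(["A", "B1", "B2"], base.gmap, f3)
        spec = PedigreeSpec(founders={"X": np.array([0.4, 0.3, 0.3])})
        haps, _ = simulate_pedigree_genotypes(panel3, spec, seed=50)
        glm = emit_genotype_likelihoods(haps, panel3.gmap, 1.0, 0.005, seed=51)
        res = AdmixtureModel.from_matrix(glm, panel3, "X").fit(restarts=5, seed=52)
        boot = res.bootstrap(B=16, seed=53, restarts=2)
        pooled_sd = boot.pool([("B1", "B2")]).loc["B1+B2", "sd"]
        assert pooled_sd < boot.sd["B1"]
        assert pooled_sd < boot.sd["B2"]

    def test_too_few_blocks_rejected(self):
        from kindred.genome import GeneticMap

        gmap = GeneticMap.regular(200, n_chrom=1)  # single chromosome
        panel = simulate_reference_panel(2, 200, 0.1, seed=40, gmap=gmap)
        spec = PedigreeSpec(founders={"X": np.array([0.6, 0.4])})
        haps, _ = simulate_pedigree_genotypes(panel, spec, seed=41)
        glm = emit_genotype_likelihoods(haps, gmap, 2.0, 0.005, seed=42)
        res = AdmixtureModel.from_matrix(glm, panel, "X").fit(restarts=2, seed=43)
        with pytest.raises(ValueError, match="block"):
            res.bootstrap(B=4, block_bp=10**12, seed=44)


class TestPooling:
    def _boot(self):
        reps = np.array([[0.5, 0.2, 0.3], [0.4, 0.35, 0.25], [0.45, 0.3, 0.25], [0.5, 0.25, 0.25]])
        return BootstrapResult(["A", "B", "C"], reps)

    def test_pooled_estimate_is_sum_of_members(self):
        boot = self._boot()
        pooled = boot.pool([("B", "C")])
        assert pooled.loc["B+C", "estimate"] == pytest.approx(
            (boot.replicates[:, 1] + boot.replicates[:, 2]).mean()
        )

    def test_pooling_everything_in_k2_gives_one_with_zero_sd(self):
        reps = np.array([[0.7, 0.3], [0.2, 0.8], [0.55, 0.45]])
        boot = BootstrapResult(["A", "B"], reps)
        pooled = boot.pool([("A", "B")])
        assert pooled.loc["A+B", "estimate"] == pytest.approx(1.0)
        assert pooled.loc["A+B", "sd"] == pytest.approx(0.0, abs=1e-12)

    def test_pooled_sd_subadditive(self):
        boot = self._boot()
        pooled = boot.pool([("A", "B")])
        assert pooled.loc["A+B", "sd"] <= boot.sd["A"] + boot.sd["B"] + 1e-12

    def test_unknown_population_rejected(self):
        with pytest.raises(KeyError, match="unknown population"):
            self._boot().pool([("A", "Z")])


class TestCongruence:
    def _frame(self, vals):
        return pd.DataFrame({"N": vals, "S": 1 - np.asarray(vals)},
                            index=[f"I{i}" for i in range(len(vals))])

    def test_identical_estimates_correlate_perfectly(self):
        a = self._frame([0.1, 0.5, 0.9, 0.3])
        assert congruence_correlation(a, a.copy(), "N") == pytest.approx(1.0)

    def test_complementary_component_correlates_negatively(self):
        a = self._frame([0.1, 0.5, 0.9, 0.3])
        assert congruence_correlation(a, a, ["S"]) == pytest.approx(1.0)
        b = a.copy()
        b["N"] = a["S"]
        assert congruence_correlation(a, b, "N") == pytest.approx(-1.0)

    def test_independent_estimates_uncorrelated(self):
        rng = np.random.default_rng(61)
        a = self._frame(rng.random(1000))
        b = self._frame(rng.random(1000))
        assert abs(congruence_correlation(a, b, "N")) < 0.1

    def test_zero_variance_and_small_n_rejected(self):
        a = self._frame([0.5, 0.5, 0.5, 0.5])
        b = self._frame([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="variance"):
            congruence_correlation(a, b, "N")
        with pytest.raises(ValueError, match="at least 3"):
            congruence_correlation(self._frame([0.1, 0.2]), self._frame([0.3, 0.4]), "N")
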