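import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import ornameta as om
from ornameta.model import (
    FitOptions,
    ModelError,
    ModelSpec,
    RandomComponent,
    _nll_and_grad,
    build_design,
)


def brute_reml_loglik(sigma2, y, X, G_list, M):
    """Dense REML criterion with explicit inverses (independent oracle)."""
    V = M.copy()
    for s2, G in zip(sigma2, G_list):
        V = V + s2 * G
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    k, p = X.shape
    return -0.5 * (
        (k - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + resid @ Vi @ resid
    )


def toy_arrays(toy_dataset):
    y = toy_dataset.table["r"].to_numpy()
    v = toy_dataset.table["v"].to_numpy()
    X = np.ones((len(y), 1))
    study = toy_dataset.table["study_id"].to_numpy()
    G = (study[:, None] == study[None, :]).astype(float)
    return y, v, X, G


class TestSamplingCov:
    def test_diagonal_without_rho(self):
        M = om.build_sampling_cov([0.01, 0.04], ["x1", "x2"], None)
        assert np.allclose(M, np.diag([0.01, 0.04]))

    def test_shared_experiment_off_diagonal(self):
        M = om.build_sampling_cov([0.01, 0.04], ["x1", "x1"], 0.5)
        assert M[0, 1] == pytest.approx(0.5 * np.sqrt(0.01 * 0.04))
        assert M[0, 1] == pytest.approx(0.01)

    def test_block_is_psd(self):
        M = om.build_sampling_cov([0.01, 0.04, 0.02], ["a", "a", "a"], 0.5)
        assert np.linalg.eigvalsh(M).min() >= 0

    def test_bad_rho(self):
        with pytest.raises(ModelError):
            om.build_sampling_cov([0.01], ["a"], 1.0)


class TestMarginalCov:
    def test_zero_variances_return_M(self):
        M = np.diag([0.01, 0.02])
        V = om.build_marginal_cov([0.0], [np.ones((2, 2))], M)
        assert np.allclose(V, M)

    def test_hand_assembly_identity_component(self):
        M = np.diag([0.01, 0.01])
        G = np.ones((2, 2))  # both effects share one group
        V = om.build_marginal_cov([0.02], [G], M)
        assert np.allclose(V, [[0.03, 0.02], [0.02, 0.03]])

    def test_phylogeny_cross_term(self):
        A = om.CorrMatrix(("A", "B"), np.array([[1.0, 0.5], [0.5, 1.0]]))
        from ornameta.model import _incidence_cov

        G = _incidence_cov(np.array(["A", "B"]), A)
        V = om.build_marginal_cov([0.04], [G], np.zeros((2, 2)))
        assert V[0, 1] == pytest.approx(0.02)


class TestRemlLoglik:
    def test_closed_form_two_effects(self):
        # k = 2, intercept-only, sigma2 = 0, v = (0.01, 0.01), y = (0.1, 0.3)
        y = np.array([0.1, 0.3])
        X = np.ones((2, 1))
        M = np.diag([0.01, 0.01])
        ll = om.reml_loglik([], y, X, [], M)
        # beta = 0.2; quad = 2; |V| = 1e-4; X'V^-1X = 200
        expected = -0.5 * (np.log(2 * np.pi) + np.log(1e-4) + np.log(200.0) + 2.0)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_location_equivariance(self, toy_dataset):
        y, v, X, G = toy_arrays(toy_dataset)
        M = np.diag(v)
        ll1 = om.reml_loglik([0.02], y, X, [G], M)
        ll2 = om.reml_loglik([0.02], y + 5.0, X, [G], M)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_matches_dense_explicit_inverse_oracle(self, toy_dataset):
        y, v, X, G = toy_arrays(toy_dataset)
        M = np.diag(v)
        for s2 in (0.0, 1e-4, 0.01, 0.3):
            ours = om.reml_loglik([s2], y, X, [G], M)
            brute = brute_reml_loglik([s2], y, X, [G], M)
            assert ours == pytest.approx(brute, abs=1e-8)

    def test_analytic_gradient_matches_finite_differences(self, toy_dataset):
        y, v, X, G = toy_arrays(toy_dataset)
        species = toy_dataset.table["species"].to_numpy()
        G2 = (species[:, None] == species[None, :]).astype(float)
        M = np.diag(v)
        s2 = np.array([0.03, 0.015])
        _, grad = _nll_and_grad(s2, y, X, [G, G2], M)
        h = 1e-6
        for u in range(2):
            e = np.zeros(2)
            e[u] = h
            fd = (
                -(om.reml_loglik(s2 + e, y, X, [G, G2], M)
                  - om.reml_loglik(s2 - e, y, X, [G, G2], M))
                / (2 * h)
            )
            assert grad[u] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFitMlma:
    def test_fixed_effect_closed_form_when_sigma2_zero(self, toy_dataset):
        spec = ModelSpec(random=om.standard_random_components()[1:])  # no phylo
        opts = FitOptions(fix_sigma2={"species": 0.0, "study": 0.0, "observation": 0.0})
        fit = om.fit_mlma(toy_dataset, spec, options=opts)
        y, v, _, _ = toy_arrays(toy_dataset)
        w = 1.0 / v
        assert fit.beta[0] == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-12)
        assert fit.se[0] == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)
        assert y.min() <= fit.beta[0] <= y.max()

    def test_reml_matches_grid_search(self, toy_dataset):
        """sigma2-hat agrees with an exhaustive grid over [0, 1], step 1e-4."""
        y, v, X, G = toy_arrays(toy_dataset)
        M = np.diag(v)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        lls = [brute_reml_loglik([g], y, X, [G], M) for g in grid]
        s2_grid = grid[int(np.argmax(lls))]
        spec = ModelSpec(random=[RandomComponent("study", "study_id")])
        fit = om.fit_mlma(toy_dataset, spec)
        assert abs(fit.sigma2["study"] - s2_grid) <= 1e-4

    def test_permutation_invariance(self, sim_small):
        dataset, _, tree = sim_small
        spec = ModelSpec(random=om.standard_random_components(), scale="z")
        fit1 = om.fit_mlma(dataset, spec, tree=tree)
        shuffled = dataset.with_table(
            dataset.table.sample(frac=1.0, random_state=5), "shuffled"
        )
        fit2 = om.fit_mlma(shuffled, spec, tree=tree)
        assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-6)
        for name in fit1.sigma2:
            assert fit1.sigma2[name] == pytest.approx(fit2.sigma2[name], abs=1e-6)

    def test_reparameterization_invariance(self, toy_dataset):
        random = [RandomComponent("study", "study_id")]
        with_int = om.fit_mlma(
            toy_dataset, ModelSpec(random=random, moderator="uninfected_present")
        )
        no_int = om.fit_mlma(
            toy_dataset,
            ModelSpec(random=random, moderator="uninfected_present", intercept=False),
        )
        # per-level means = intercept (+ contrast); identical restricted likelihood
        b0, contrast = with_int.beta
        means = dict(zip(no_int.beta_names, no_int.beta))
        assert means["uninfected_present[no]"] == pytest.approx(b0, abs=1e-7)
        assert means["uninfected_present[yes]"] == pytest.approx(
            b0 + contrast, abs=1e-7
        )
        assert with_int.ll_reml == pytest.approx(no_int.ll_reml, abs=1e-7)

    def test_infinitely_imprecise_effect_changes_nothing(self, toy_dataset):
        spec = ModelSpec(random=[RandomComponent("study", "study_id")])
        fit1 = om.fit_mlma(toy_dataset, spec)
        extra = toy_dataset.table.iloc[[0]].assign(
            effect_id="e999", v=1e12, r=0.9, study_id="s99", experiment_id="x99"
        )
        bigger = toy_dataset.with_table(
            pd.concat([toy_dataset.table, extra], ignore_index=True), "plus inf-v"
        )
        fit2 = om.fit_mlma(bigger, spec)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0], abs=1e-8)
        assert fit2.sigma2["study"] == pytest.approx(fit1.sigma2["study"], abs=1e-6)

    def test_rank_deficient_design_rejected(self, toy_dataset):
        t = toy_dataset.table.copy()
        t["constant_mod"] = "only_level"
        ds = om.Dataset(t, [])
        with pytest.raises(ModelError):
            om.fit_mlma(
                ds,
                ModelSpec(
                    random=[RandomComponent("study", "study_id")],
                    moderator="constant_mod",
                ),
            )

    def test_missing_species_in_tree(self, toy_dataset):
        tree = om.grafen_transform(om.read_newick("((A,B),C);"))  # lacks D
        spec = ModelSpec(random=om.standard_random_components())
        with pytest.raises(ModelError, match="D"):
            om.fit_mlma(toy_dataset, spec, tree=tree)


class TestQm:
    def test_single_coefficient_equals_squared_z(self, toy_dataset):
        fit = om.fit_mlma(
            toy_dataset,
            ModelSpec(
                random=[RandomComponent("study", "study_id")],
                moderator="uninfected_present",
            ),
        )
        stat, df, p = om.qm_test(fit)
        z = fit.beta[1] / fit.se[1]
        assert df == 1
        assert stat == pytest.approx(z**2, rel=1e-10)
        assert p == pytest.approx(fit.p_values[1], rel=1e-10)

    def test_zero_coefficients_give_zero_statistic(self):
        beta = np.array([0.1, 0.0, 0.0])
        cov = np.diag([0.01, 0.02, 0.03])
        from ornameta.model import _qm_from

        stat, df, p = _qm_from(beta, cov, [1, 2])
        assert stat == 0.0 and p == 1.0

    def test_label_relabeling_invariance(self, toy_dataset):
        random = [RandomComponent("study", "study_id")]
        fit1 = om.fit_mlma(
            toy_dataset, ModelSpec(random=random, moderator="uninfected_present")
        )
        t = toy_dataset.table.copy()
        t["renamed"] = t["uninfected_present"].map({"yes": "alpha", "no": "beta"})
        fit2 = om.fit_mlma(
            om.Dataset(t, []), ModelSpec(random=random, moderator="renamed")
        )
        assert fit1.qm[0] == pytest.approx(fit2.qm[0], abs=1e-8)


class TestDesign:
    def test_interaction_indices_cover_products(self, sim_small):
        dataset, _, _ = sim_small
        spec = ModelSpec(interaction=("dynamism_binary", "uninfected_present"))
        X, names, tested = build_design(dataset.table, spec)
        assert names[0] == "intercept"
        assert all(":" in names[i] for i in tested)
        assert X.shape[1] == 4  # 2x2 cross: intercept + 2 mains + 1 interaction


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
class TestMetaforOracle:
    def test_four_component_fit_matches_rma_mv(self, tmp_path):
        """Independent cross-check of the REML engine against metafor."""
        params = om.SimParams(
            n_species=8, studies_per_species=1.5, effects_per_study=2.5, seed=42
        )
        dataset, truth = om.simulate_dataset(params)
        tree = om.read_newick(truth.tree_newick)
        fit = om.fit_mlma(
            dataset, ModelSpec(random=om.standard_random_components()), tree=tree
        )

        dataset.table.to_csv(tmp_path / "d.csv", index=False)
        om.brownian_correlation(tree).to_csv(tmp_path / "A.csv")
        rcode = f"""
        suppressMessages(library(metafor))
        d <- read.csv("{tmp_path}/d.csv")
        A <- as.matrix(read.csv("{tmp_path}/A.csv", row.names=1))
        colnames(A) <- rownames(A)
        d$phylo <- d$species
        res <- rma.mv(r, v,
            random = list(~1|phylo, ~1|species, ~1|study_id, ~1|effect_id),
            R = list(phylo=A), data=d, method="REML")
        cat(jsonlite::toJSON(list(beta=as.numeric(res$beta), se=res$se,
            sigma2=res$sigma2, ll=logLik(res)[1]), digits=12))
        """
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        assert fit.beta[0] == pytest.approx(ref["beta"][0], abs=1e-5)
        assert fit.se[0] == pytest.approx(ref["se"][0], abs=1e-5)
        ours = [
            fit.sigma2[c] for c in ("phylogeny", "species", "study", "observation")
        ]
        assert np.allclose(ours, ref["sigma2"], atol=1e-4)
        # metafor's REML constant differs by +0.5 log|X'X|
        offset = 0.5 * np.log(fit.k)
        assert fit.ll_reml + offset == pytest.approx(ref["ll"][0], abs=1e-5)
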