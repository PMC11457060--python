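"""Reaction-norm Gibbs sampler: design algebra, conjugate oracle,
exchangeability and prediction contracts."""

import numpy as np
import pandas as pd
import pytest

import strigagp as sg
from strigagp import DimensionError, DomainError, Kernel, build_design, fit_gibbs
from strigagp.reaction_norm import interaction_kernel, predict_gebv, predicted_cells


def design_from_arrays(y_by_env, ids, kernel):
    blues = pd.DataFrame(y_by_env, index=ids)
    return build_design(blues, kernel)


class TestDesign:
    def test_identity_grm_gives_blockdiagonal_identity_interaction(self):
        ids = ["A", "B"]
        k = Kernel(np.eye(2), ids)
        d = design_from_arrays({"E1": [1.0, 2.0], "E2": [3.0, 4.0]}, ids, k)
        k_int = interaction_kernel(d)
        expected = np.zeros((4, 4))
        expected[:2, :2] = np.eye(2)
        expected[2:, 2:] = np.eye(2)
        np.testing.assert_allclose(k_int, expected)

    def test_environment_incidence_structure(self):
        ids = ["A", "B", "C"]
        k = Kernel(np.full((3, 3), 0.5) + 0.5 * np.eye(3), ids)
        d = design_from_arrays(
            {"E1": [1.0, 2.0, 3.0], "E2": [1.0, 2.0, 3.0]}, ids, k
        )
        k_int = interaction_kernel(d)
        same_env = d.cell_env[:, None] == d.cell_env[None, :]
        assert (k_int[~same_env] == 0).all()
        assert (k_int[same_env] != 0).all()

    def test_masking_keeps_line_in_design(self):
        ids = ["A", "B"]
        k = Kernel(np.eye(2), ids)
        blues = pd.DataFrame({"E1": [1.0, 2.0], "E2": [3.0, 4.0]}, index=ids)
        d = build_design(blues, k, masked_cells=[("A", "E1")])
        assert d.mask.sum() == 1
        assert d.n_cells == 4
        assert "A" in d.line_ids

    def test_phenotyped_line_missing_from_grm_is_named(self):
        k = Kernel(np.eye(1), ["A"])
        blues = pd.DataFrame({"E1": [1.0, 2.0]}, index=["A", "Z"])
        with pytest.raises(DimensionError, match="Z"):
            build_design(blues, k)

    def test_masked_cell_without_phenotype_rejected(self):
        k = Kernel(np.eye(2), ["A", "B"])
        blues = pd.DataFrame({"E1": [1.0, np.nan]}, index=["A", "B"])
        with pytest.raises(DomainError):
            build_design(blues, k, masked_cells=[("B", "E1")])


class TestGibbs:
    def test_frozen_variances_match_closed_form_gblup(self, toy_kernel):
        """With variances pinned and no interaction, the posterior mean
        of g equals the single-kernel mixed-model-equation solution."""
        kernel, rng = toy_kernel
        n = kernel.n
        y = rng.standard_normal(n) * 2
        blues = pd.DataFrame({"E1": y}, index=kernel.ids)
        d = build_design(blues, kernel)
        s2g, s2e = 1.5, 0.8
        samples = fit_gibbs(
            d, iterations=40_000, burn_in=5_000, thin=5, seed=3,
            include_interaction=False, include_intercept=False,
            update_variances=False,
            fixed_variances={"sigma2_g": s2g, "sigma2_e": s2e, "sigma2_E": 1e-12},
        )
        ghat = samples.g.mean(axis=0)
        closed = np.linalg.solve(
            np.eye(n) / s2e + np.linalg.inv(kernel.values) / s2g, y / s2e
        )
        # conservative MC error: independent-draw SE inflated for autocorrelation
        mc_se = samples.g.std(axis=0) / np.sqrt(samples.n_retained / 10)
        assert (np.abs(ghat - closed) <= 3 * mc_se).all()

    def test_zero_response_gives_zero_effects(self, toy_kernel):
        kernel, _ = toy_kernel
        blues = pd.DataFrame(
            {"E1": np.zeros(kernel.n), "E2": np.zeros(kernel.n)}, index=kernel.ids
        )
        d = build_design(blues, kernel)
        samples = fit_gibbs(d, iterations=3000, burn_in=1000, thin=5, seed=0)
        assert np.abs(samples.g.mean(axis=0)).max() < 0.05
        assert np.abs(samples.beta_E.mean(axis=0)).max() < 0.05

    def test_seeded_chains_are_identical(self, toy_kernel):
        kernel, rng = toy_kernel
        y = rng.standard_normal(kernel.n)
        blues = pd.DataFrame({"E1": y}, index=kernel.ids)
        d = build_design(blues, kernel)
        a = fit_gibbs(d, iterations=500, burn_in=100, thin=4, seed=7)
        b = fit_gibbs(d, iterations=500, burn_in=100, thin=4, seed=7)
        np.testing.assert_array_equal(a.g, b.g)
        np.testing.assert_array_equal(a.sigma2_e, b.sigma2_e)

    def test_retained_draw_count(self, toy_kernel):
        kernel, rng = toy_kernel
        blues = pd.DataFrame({"E1": rng.standard_normal(kernel.n)}, index=kernel.ids)
        d = build_design(blues, kernel)
        samples = fit_gibbs(d, iterations=1000, burn_in=400, thin=10, seed=1)
        assert samples.n_retained == 60
        uneven = fit_gibbs(d, iterations=1005, burn_in=400, thin=10, seed=1)
        assert uneven.n_retained == 60  # floor when not divisible

    def test_iterations_must_exceed_burnin(self, toy_kernel):
        kernel, rng = toy_kernel
        blues = pd.DataFrame({"E1": np.ones(kernel.n)}, index=kernel.ids)
        d = build_design(blues, kernel)
        with pytest.raises(DomainError):
            fit_gibbs(d, iterations=100, burn_in=100)

    def test_non_psd_kernel_rejected(self):
        values = np.eye(3)
        values[0, 0] = -1.0
        k = Kernel(values, ["A", "B", "C"])
        blues = pd.DataFrame({"E1": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
        d = build_design(blues, k)
        with pytest.raises(DomainError, match="positive semidefinite"):
            fit_gibbs(d, iterations=20, burn_in=10)


class TestPrediction:
    def test_unphenotyped_clone_gets_matching_gebv(self):
        rng = np.random.default_rng(12)
        values = (rng.random((30, 60)) < 0.4).astype(float)
        values = np.vstack([values, values[0]])  # clone of line 0, unphenotyped
        ids = [f"L{i}" for i in range(31)]
        markers = sg.MarkerMatrix(values, ids)
        grm = sg.compute_grm(sg.qc_markers(markers, maf_threshold=0.01))
        y = rng.standard_normal(30) * 2 + 5
        blues = pd.DataFrame({"E1": np.append(y, np.nan)}, index=ids)
        d = build_design(blues, grm)
        samples = fit_gibbs(d, iterations=6000, burn_in=2000, thin=4, seed=4)
        gebv = predict_gebv(samples, d)
        assert gebv.loc["L30", "set"] == "TST"
        assert gebv.loc["L0", "gebv"] == pytest.approx(
            gebv.loc["L30", "gebv"], abs=0.3
        )

    def test_identity_grm_shrinks_unphenotyped_to_population_mean(self):
        rng = np.random.default_rng(13)
        n = 25
        ids = [f"L{i}" for i in range(n)]
        k = Kernel(np.eye(n), ids)
        y = np.append(rng.standard_normal(n - 5) * 3 + 10, [np.nan] * 5)
        blues = pd.DataFrame({"E1": y}, index=ids)
        d = build_design(blues, k)
        samples = fit_gibbs(d, iterations=6000, burn_in=2000, thin=4, seed=5)
        gebv = predict_gebv(samples, d)
        tst = gebv[gebv["set"] == "TST"]
        baseline = samples.mu.mean() + samples.beta_E.mean()
        assert np.abs(tst["gebv"] - baseline).max() < 0.35

    def test_line_order_permutation_invariance(self, toy_kernel):
        kernel, rng = toy_kernel
        y = rng.standard_normal(kernel.n) * 2
        blues = pd.DataFrame({"E1": y, "E2": y + rng.standard_normal(kernel.n)},
                             index=kernel.ids)
        d = build_design(blues, kernel)
        s1 = fit_gibbs(d, iterations=8000, burn_in=2000, thin=4, seed=6)
        g1 = predict_gebv(s1, d)

        perm = rng.permutation(kernel.n)
        ids_p = [kernel.ids[i] for i in perm]
        kernel_p = Kernel(kernel.values[np.ix_(perm, perm)], ids_p)
        blues_p = blues.loc[ids_p]
        d_p = build_design(blues_p, kernel_p)
        s2 = fit_gibbs(d_p, iterations=8000, burn_in=2000, thin=4, seed=6)
        g2 = predict_gebv(s2, d_p)
        # same posterior up to Monte-Carlo error, line-by-line
        diff = (g1["gebv"] - g2["gebv"].reindex(g1.index)).abs()
        assert diff.max() < 0.2

    def test_all_lines_receive_values(self, cell_level_dataset):
        _, cells, grm, _ = cell_level_dataset(seed=0, n_lines=40, n_markers=60)
        half = cells.iloc[:20]  # phenotype only half the panel
        d = build_design(half, grm)
        samples = fit_gibbs(d, iterations=1500, burn_in=500, thin=5, seed=2)
        gebv = predict_gebv(samples, d)
        assert len(gebv) == grm.n
        assert set(gebv["set"]) == {"TRN", "TST"}
        assert gebv["gebv"].notna().all()


def test_masked_cells_do_not_inform_the_fit(toy_kernel):
    """Masking a cell must give the same posterior as dropping it."""
    kernel, rng = toy_kernel
    y1 = rng.standard_normal(kernel.n)
    y2 = rng.standard_normal(kernel.n)
    blues = pd.DataFrame({"E1": y1, "E2": y2}, index=kernel.ids)
    masked = [(kernel.ids[0], "E2"), (kernel.ids[3], "E2")]
    d_mask = build_design(blues, kernel, masked_cells=masked)
    dropped = blues.copy()
    for ln, env in masked:
        dropped.loc[ln, env] = np.nan
    d_drop = build_design(dropped, kernel)
    s_mask = fit_gibbs(d_mask, iterations=4000, burn_in=1000, thin=4, seed=9)
    s_drop = fit_gibbs(d_drop, iterations=4000, burn_in=1000, thin=4, seed=9)
    np.testing.assert_allclose(
        s_mask.g.mean(axis=0), s_drop.g.mean(axis=0), atol=0.15
    )
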