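"""Trial mixed models: heritability, BLUE/BLUP behaviour, recovery."""

import numpy as np
import pandas as pd
import pytest

import strigagp as sg
from strigagp import (
    DomainError,
    VarianceComponents,
    fit_across_sites,
    fit_single_site,
    heritability_across,
    heritability_single,
    trait_correlations,
)


class TestHeritability:
    @pytest.mark.parametrize(
        "s2g, s2e, r, expected",
        [
            (16.75, 63.51, 2, 0.35),   # emerged parasites, 8 WAP, Kibos
            (0.45, 1.47, 2, 0.38),     # grain yield, Kibos
        ],
    )
    def test_single_site_reference_values(self, s2g, s2e, r, expected):
        vc = VarianceComponents(sigma2_G=s2g, sigma2_error=s2e, n_replicates=r)
        assert round(heritability_single(vc), 2) == expected

    @pytest.mark.parametrize(
        "s2g, s2ge, s2e, expected",
        [
            (181.61, 32.99, 520.38, 0.65),   # emerged parasites, 12 WAP
            (0.40, 0.22, 1.61, 0.54),        # grain yield
        ],
    )
    def test_across_site_reference_values(self, s2g, s2ge, s2e, expected):
        vc = VarianceComponents(
            sigma2_G=s2g, sigma2_GE=s2ge, sigma2_error=s2e,
            n_environments=3, n_replicates=2,
        )
        assert round(heritability_across(vc), 2) == expected

    def test_limits(self):
        noiseless = VarianceComponents(sigma2_G=5.0, sigma2_error=0.0)
        assert heritability_single(noiseless) == 1.0
        assert heritability_across(
            VarianceComponents(sigma2_G=5.0, sigma2_error=0.0, sigma2_GE=0.0)
        ) == 1.0
        empty = VarianceComponents(sigma2_G=0.0, sigma2_error=0.0)
        assert heritability_single(empty) == 0.0

    def test_monotone_in_components(self):
        h = [
            heritability_single(
                VarianceComponents(sigma2_G=s2g, sigma2_error=50.0, n_replicates=2)
            )
            for s2g in (1.0, 10.0, 100.0)
        ]
        assert h == sorted(h) and all(0 <= x <= 1 for x in h)
        h_e = [
            heritability_single(
                VarianceComponents(sigma2_G=20.0, sigma2_error=s2e, n_replicates=2)
            )
            for s2e in (1.0, 10.0, 100.0)
        ]
        assert h_e == sorted(h_e, reverse=True)


def _one_site_frame(n_entries=40, n_rep=2, s2g=60.0, s2e=25.0, seed=0,
                    block_size=8):
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_entries) * np.sqrt(s2g)
    rows = []
    for rep in range(n_rep):
        order = rng.permutation(n_entries)
        for pos, idx in enumerate(order):
            rows.append(
                dict(location="E1", replicate=f"R{rep}",
                     block=f"B{pos // block_size}", entry=f"G{idx:03d}",
                     tester="T1",
                     Y=5 + g[idx] + rng.standard_normal() * np.sqrt(s2e))
            )
    return pd.DataFrame(rows), g


class TestSingleSite:
    def test_blue_equals_entry_mean_on_orthogonal_design(self):
        # complete blocks (one block per replicate): the design is
        # orthogonal and GLS collapses to OLS whatever the components
        df, _ = _one_site_frame(seed=1, block_size=40)
        out = fit_single_site(df, "Y")
        raw = df.groupby("entry")["Y"].mean().sort_index()
        np.testing.assert_allclose(out.blues.to_numpy(), raw.to_numpy(), atol=1e-6)

    def test_all_equal_observations_hit_boundary(self):
        df, _ = _one_site_frame(seed=2)
        df["Y"] = 4.2
        out = fit_single_site(df, "Y")
        assert out.varcomps.sigma2_G == 0.0
        assert out.varcomps.sigma2_error == 0.0
        np.testing.assert_allclose(out.blues.to_numpy(), 4.2, atol=1e-8)

    def test_blups_shrink_relative_to_blues(self):
        df, _ = _one_site_frame(s2g=20.0, s2e=80.0, seed=3)
        out = fit_single_site(df, "Y")
        assert out.blups.var() <= out.blues.var() + 1e-9

    def test_single_replicate_rejected(self):
        df, _ = _one_site_frame(n_rep=1)
        with pytest.raises(DomainError):
            fit_single_site(df, "Y")

    def test_unknown_trait_rejected(self):
        df, _ = _one_site_frame()
        with pytest.raises(DomainError):
            fit_single_site(df, "nope")

    def test_variance_recovery_over_replicated_simulations(self):
        """Mean REML genotypic variance over repeated trials within 10%
        of the generating value (scaled-down replicate count)."""
        est = []
        for seed in range(20):
            c = sg.SimulationConfig(
                n_lines=200, n_markers=50, n_testers=1, block_size=8,
                n_environments=1, n_replicates=2, var_genetic=80.0,
                var_gxe=0.0, var_env=0.0, var_replicate=4.0, var_block=4.0,
                var_error=320.0, seed=seed,
            )
            m = sg.simulate_markers(c)
            plots, _ = sg.simulate_trial(c, m)
            out = fit_single_site(plots, "Y", genotype_effect="random")
            est.append(out.varcomps.sigma2_G)
        assert np.mean(est) == pytest.approx(80.0, rel=0.10)


class TestAcrossSites:
    def test_interaction_component_recovery(self, small_trial):
        _, _, plots, _ = small_trial
        out = fit_across_sites(plots, "Y")
        vc = out.varcomps
        # generous single-dataset bands: n=60 lines is deliberately small
        assert vc.sigma2_G == pytest.approx(80.0, rel=0.5)
        assert vc.sigma2_error == pytest.approx(160.0, rel=0.35)
        assert 0.0 <= vc.sigma2_GE < 100.0
        assert 0.0 < out.heritability <= 1.0

    def test_null_interaction_estimated_small(self):
        ratios = []
        for seed in range(6):
            c = sg.SimulationConfig(
                n_lines=80, n_markers=60, n_testers=1, block_size=8,
                var_genetic=80.0, var_gxe=0.0, var_error=160.0,
                var_env=30.0, var_replicate=4.0, var_block=4.0, seed=seed,
            )
            m = sg.simulate_markers(c)
            plots, _ = sg.simulate_trial(c, m)
            vc = fit_across_sites(plots, "Y", genotype_effect="random").varcomps
            ratios.append(vc.sigma2_GE / max(vc.sigma2_G, 1e-9))
        assert np.median(ratios) < 0.10

    def test_requires_two_environments(self):
        c = sg.SimulationConfig(n_lines=20, n_markers=30, n_testers=1,
                                block_size=4, n_environments=1, seed=0)
        m = sg.simulate_markers(c)
        plots, _ = sg.simulate_trial(c, m)
        with pytest.raises(DomainError):
            fit_across_sites(plots, "Y")

    def test_blues_by_environment_shape(self, small_trial):
        _, _, plots, _ = small_trial
        blues = sg.blues_by_environment(plots, "Y")
        assert blues.shape == (60, 3)
        assert not blues.isna().any().any()


class TestTraitCorrelations:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        corr = trait_correlations(df)
        for i in "abc":
            for j in "abc":
                x, y = df[i].to_numpy(), df[j].to_numpy()
                manual = (
                    np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                )
                assert corr.loc[i, j] == pytest.approx(manual, abs=1e-12)

    def test_self_and_negation(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(15)
        df = pd.DataFrame({"t": x, "neg": -x})
        corr = trait_correlations(df)
        assert corr.loc["t", "t"] == 1.0
        assert corr.loc["t", "neg"] == pytest.approx(-1.0)

    def test_constant_trait_flagged_not_zero(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            corr = trait_correlations(df)
        assert np.isnan(corr.loc["t", "const"])
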