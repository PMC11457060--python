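"""Synthetic marker panels and multi-location testcross trials.

The generator reproduces the statistical structure the downstream
analysis assumes: doubled-haploid (DH) lines carry dominant presence/
absence markers; each line is crossed to a small number of testers and
the testcrosses are grown in resolvable incomplete-block (alpha-lattice)
trials at several locations with two replicates.  A plot phenotype is

    y = mu + E_j + R_k(E_j) + B_l(R_k) + tester + g_i + (gxE)_ij + eps

with the line main value ``g_i`` a linear combination of causal-marker
genotypes scaled so its realised variance equals ``var_genetic``
exactly, and the line-by-environment deviation built from fresh
env-specific marker effects scaled to ``var_gxe`` per environment.
Marker-driven interaction keeps the simulated G x E inside the span of
the genomic relationship matrix, which is what the reaction-norm model
assumes; deviations are independent across environments.

Default variance components mirror a moderately heritable emerged-
parasite count in a three-location trial; the count trait mapping
``round(max(0, latent))`` keeps count-like traits nonnegative integers
while staying near-gaussian.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DimensionError
from .markers import MarkerMatrix, standardize_markers

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_markers",
    "simulate_trial",
    "simulate_striga_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a marker panel plus field trial.

    Defaults describe the reference scenario: 116 DH lines crossed to
    2 testers, evaluated at 3 locations x 2 replicates in blocks of 4,
    genotyped at 8,439 dominant markers, with variance components of a
    mid-heritability emerged-parasite count (genetic 80, GxE 23,
    plot error 323).  ``n_qtl`` defaults to a fully polygenic
    architecture (every marker causal, many genes of small effect).
    """

    n_lines: int = 116
    n_markers: int = 8439
    maf_range: tuple = (0.05, 0.5)
    n_environments: int = 3
    n_replicates: int = 2
    block_size: int = 4
    n_testers: int = 2
    var_genetic: float = 80.0
    var_gxe: float = 23.0
    var_env: float = 40.0
    var_replicate: float = 8.0
    var_block: float = 8.0
    var_error: float = 323.0
    n_qtl: int | None = None
    trait_kind: str = "gaussian"
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("var_genetic", "var_gxe", "var_env", "var_replicate",
                     "var_block", "var_error"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in ("n_lines", "n_markers", "n_environments",
                     "n_replicates", "block_size", "n_testers"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_qtl is not None and not (1 <= self.n_qtl <= self.n_markers):
            raise ConfigurationError("n_qtl must be in [1, n_markers]")
        if self.trait_kind not in ("gaussian", "count"):
            raise ConfigurationError("trait_kind must be 'gaussian' or 'count'")
        entries_per_rep = self.n_lines * self.n_testers
        if entries_per_rep % self.block_size != 0:
            raise ConfigurationError(
                f"block_size {self.block_size} does not divide the "
                f"{entries_per_rep} entries per replicate"
            )

    @property
    def effective_n_qtl(self) -> int:
        return self.n_markers if self.n_qtl is None else self.n_qtl


@dataclass
class SyntheticTruth:
    """Ground-truth effects behind one simulated trial."""

    line_main: pd.Series
    interaction: pd.DataFrame  # lines x environments
    environment_effects: pd.Series
    marker_effects: pd.Series  # causal markers only
    tester_offsets: pd.Series
    intercept: float


def simulate_markers(config: SimulationConfig) -> MarkerMatrix:
    """Dominant {0,1} marker panel with a controlled frequency spectrum.

    Each marker's presence frequency is drawn uniformly from
    ``maf_range`` (or, with probability 1/2, its complement), and the
    exact count ``round(f * n_lines)`` of carriers is placed by
    permutation so the realised frequency matches the drawn one as
    closely as the panel size allows.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_lines, config.n_markers
    f = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    flip = rng.random(p) < 0.5
    f = np.where(flip, 1.0 - f, f)
    counts = np.clip(np.rint(f * n).astype(int), 1, max(n - 1, 1))
    values = np.zeros((n, p))
    for j in range(p):
        carriers = rng.permutation(n)[: counts[j]]
        values[carriers, j] = 1.0
    return MarkerMatrix(
        values,
        [f"DH{i:04d}" for i in range(n)],
        [f"TAG{j:05d}" for j in range(p)],
    )


def _scaled(x: np.ndarray, target_var: float, idx: np.ndarray) -> tuple:
    """Rescale x so that the population variance of x[idx] is target_var."""
    v = float(np.var(x[idx]))
    if target_var == 0 or v == 0:
        return np.zeros_like(x), 0.0
    factor = np.sqrt(target_var / v)
    return x * factor, factor


def _build_design(config: SimulationConfig, rng: np.random.Generator,
                  lines: list, testers: list) -> pd.DataFrame:
    """Alpha-lattice field book: every line x tester once per replicate,
    blocks of ``block_size`` partitioning each replicate."""
    envs = [f"E{j + 1}" for j in range(config.n_environments)]
    entries = [(ln, t) for ln in lines for t in testers]
    rows = []
    for env in envs:
        for rep in range(1, config.n_replicates + 1):
            order = rng.permutation(len(entries))
            for plot, k in enumerate(order):
                ln, t = entries[k]
                rows.append(
                    (env, f"R{rep}", f"B{plot // config.block_size + 1:02d}", ln, t)
                )
    return pd.DataFrame(
        rows, columns=["location", "replicate", "block", "entry", "tester"]
    )


def simulate_trial(
    config: SimulationConfig,
    markers: MarkerMatrix,
    phenotyped_lines: list | None = None,
    trait_name: str = "Y",
    rng: np.random.Generator | None = None,
    design: pd.DataFrame | None = None,
):
    """Simulate one trait over a multi-location trial.

    Returns ``(plots, truth)`` where ``plots`` is a plot-level table
    with columns location, replicate, block, entry, tester and the
    trait, and ``truth`` carries every generative effect.  Truth values
    are produced for *all* marker lines, phenotypes only for
    ``phenotyped_lines`` (default: all).
    """
    if phenotyped_lines is None:
        phenotyped_lines = list(markers.line_ids)
    phenotyped_lines = [str(x) for x in phenotyped_lines]
    missing = set(phenotyped_lines) - set(markers.line_ids)
    if missing:
        raise DimensionError(f"phenotyped lines absent from markers: {sorted(missing)[:5]}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    s = standardize_markers(markers)
    n_all = markers.n_lines
    phen_idx = np.asarray(
        [markers.line_ids.index(x) for x in phenotyped_lines], dtype=int
    )
    envs = [f"E{j + 1}" for j in range(config.n_environments)]
    testers = [f"T{k + 1}" for k in range(config.n_testers)]

    # line main genetic values: causal marker effects, exactly scaled
    causal = np.sort(rng.choice(config.n_markers, config.effective_n_qtl, replace=False))
    alpha = rng.standard_normal(len(causal))
    g_raw = s[:, causal] @ alpha
    g, g_factor = _scaled(g_raw, config.var_genetic, phen_idx)
    marker_effects = pd.Series(
        alpha * g_factor, index=[markers.marker_ids[j] for j in causal]
    )

    # G x E: fresh effects per environment on the same causal markers
    u = np.zeros((n_all, config.n_environments))
    for e in range(config.n_environments):
        beta_e = rng.standard_normal(len(causal))
        u[:, e], _ = _scaled(s[:, causal] @ beta_e, config.var_gxe, phen_idx)

    env_eff = rng.standard_normal(config.n_environments) * np.sqrt(config.var_env)
    if config.n_testers == 1:
        tester_off = np.zeros(1)
    else:
        tester_off = (
            np.linspace(-1.0, 1.0, config.n_testers)
            * 0.25
            * np.sqrt(config.var_genetic)
        )

    if design is None:
        design = _build_design(config, rng, phenotyped_lines, testers)
    plots = design.copy()

    rep_keys = plots[["location", "replicate"]].drop_duplicates()
    rep_eff = {
        tuple(k): rng.standard_normal() * np.sqrt(config.var_replicate)
        for k in rep_keys.itertuples(index=False)
    }
    block_keys = plots[["location", "replicate", "block"]].drop_duplicates()
    block_eff = {
        tuple(k): rng.standard_normal() * np.sqrt(config.var_block)
        for k in block_keys.itertuples(index=False)
    }

    line_pos = {ln: markers.line_ids.index(ln) for ln in phenotyped_lines}
    env_pos = {e: j for j, e in enumerate(envs)}
    tester_pos = {t: k for k, t in enumerate(testers)}

    li = plots["entry"].map(line_pos).to_numpy()
    ei = plots["location"].map(env_pos).to_numpy()
    ti = plots["tester"].map(tester_pos).to_numpy()
    latent = (
        config.intercept
        + env_eff[ei]
        + np.array([rep_eff[(r.location, r.replicate)] for r in plots.itertuples()])
        + np.array(
            [block_eff[(r.location, r.replicate, r.block)] for r in plots.itertuples()]
        )
        + tester_off[ti]
        + g[li]
        + u[li, ei]
        + rng.standard_normal(len(plots)) * np.sqrt(config.var_error)
    )
    if config.trait_kind == "count":
        latent = np.rint(np.maximum(0.0, latent))
    plots[trait_name] = latent

    truth = SyntheticTruth(
        line_main=pd.Series(g, index=markers.line_ids),
        interaction=pd.DataFrame(u, index=markers.line_ids, columns=envs),
        environment_effects=pd.Series(env_eff, index=envs),
        marker_effects=marker_effects,
        tester_offsets=pd.Series(tester_off, index=testers),
        intercept=config.intercept,
    )
    return plots, truth


#: Per-trait generative settings for the composite data set:
#: (trait kind, intercept, var_genetic, var_gxe, var_error).
STRIGA_TRAIT_SETTINGS = {
    "STR8WAP": ("count", 8.0, 9.24, 9.94, 72.39),
    "STR10WAP": ("count", 27.0, 80.02, 22.65, 322.99),
    "STR12WAP": ("count", 39.0, 181.61, 32.99, 520.38),
    "SDR1": ("rating", 2.1, 0.12, 0.05, 0.57),
    "SDR2": ("rating", 2.6, 0.13, 0.06, 0.68),
    "GY": ("gaussian", 4.5, 0.40, 0.22, 1.61),
}


def simulate_striga_dataset(
    config: SimulationConfig, phenotyped_lines: list | None = None
):
    """Full synthetic analogue of a *Striga* screening trial.

    Generates one marker panel and one shared field layout, then one
    trait per entry of :data:`STRIGA_TRAIT_SETTINGS` (emerged-parasite
    counts at 8/10/12 WAP, two damage ratings, grain yield re-expressed
    as plot ear weight at 12.5 % moisture).  Traits are generated
    independently; cross-trait genetic correlations are not emulated.

    Returns ``(markers, phenotypes, truths)`` with ``truths`` a dict
    trait -> :class:`SyntheticTruth`.
    """
    markers = simulate_markers(config)
    rng = np.random.default_rng(config.seed + 1)
    if phenotyped_lines is None:
        phenotyped_lines = list(markers.line_ids)
    testers = [f"T{k + 1}" for k in range(config.n_testers)]
    design = _build_design(config, rng, [str(x) for x in phenotyped_lines], testers)

    phenotypes = design.copy()
    truths = {}
    for trait, (kind, mu, vg, vgxe, verr) in STRIGA_TRAIT_SETTINGS.items():
        sub = dataclasses.replace(
            config,
            trait_kind="count" if kind == "count" else "gaussian",
            intercept=mu,
            var_genetic=vg,
            var_gxe=vgxe,
            var_error=verr,
        )
        plots, truth = simulate_trial(
            sub, markers, phenotyped_lines, trait_name=trait, rng=rng, design=design
        )
        values = plots[trait].to_numpy()
        if kind == "rating":
            values = np.clip(np.rint(values), 1, 9)
        phenotypes[trait] = values
        truths[trait] = truth

    # grain yield back to plot ear weight (kg) at target moisture
    if "GY" in phenotypes.columns:
        phenotypes["EarWeight"] = np.maximum(
            0.0, phenotypes.pop("GY") * 3.0 / 0.8 / 10.0
        )
        phenotypes["Moisture"] = 12.5
    return markers, phenotypes, truths
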