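"""Bayesian reaction-norm model for genomic prediction with G x E.

The stacked line-by-environment response (typically per-environment
BLUEs) is modelled as

    y = mu + Z_E beta_E + Z_g g + u + e

with beta_E ~ N(0, s2_E I) the dummy-environment effects,
g ~ N(0, s2_g G) the genomic line main effects (G a genomic
relationship matrix over *all* lines, phenotyped or not), the
interaction u ~ N(0, s2_gxE (Z_g G Z_g') # (Z_E Z_E')) with # the
element-wise (Hadamard) product, and e ~ N(0, s2_e I).  Because the
environment incidence kernel Z_E Z_E' is 1 only for observations that
share an environment, the interaction kernel is block diagonal by
environment, each block a submatrix of G.

Fitting is by Gibbs sampling.  Each Gaussian effect block is sampled
through the eigendecomposition of its kernel: writing the effect as
Phi delta with Phi = V sqrt(Lambda) and delta iid N(0, s2), the full
conditional of delta is Gaussian with posterior precision
Phi'Phi/s2_e + I/s2 — diagonal whenever the design is balanced and
unmasked, a small Cholesky solve otherwise.  Variances carry scaled
inverse chi-square priors with conjugate full conditionals; the default
prior is weakly informative (1 prior degree of freedom, scale matched
to a share of the sample phenotypic variance) so that the likelihood
dominates variance inference whenever the data carry information —
with few environments the interaction variance is only weakly
identified and posterior means of it are prior-sensitive under
stronger priors.

Unphenotyped lines ride inside G during sampling, so their breeding
values are drawn from the joint full conditional rather than kriged
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, DomainError
from .markers import Kernel

__all__ = [
    "ReactionNormDesign",
    "PosteriorSamples",
    "build_design",
    "interaction_kernel",
    "fit_gibbs",
    "predict_gebv",
    "predicted_cells",
]


@dataclass
class ReactionNormDesign:
    """Stacked cell-level design for the reaction-norm model.

    One row per phenotyped (line, environment) cell, environment-major.
    ``mask`` flags cells excluded from the likelihood (their y is kept
    for later accuracy computation); ``line_ids`` covers every line in
    the relationship matrix, phenotyped or not.
    """

    y: np.ndarray
    cell_line: np.ndarray  # index into line_ids, per cell
    cell_env: np.ndarray   # index into env_ids, per cell
    mask: np.ndarray       # bool, True = held out
    line_ids: list
    env_ids: list
    grm: Kernel

    @property
    def n_cells(self) -> int:
        return len(self.y)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    def cell_index(self) -> dict:
        """(line_id, env_id) -> cell position."""
        return {
            (self.line_ids[li], self.env_ids[ei]): k
            for k, (li, ei) in enumerate(zip(self.cell_line, self.cell_env))
        }


def build_design(
    blues: pd.DataFrame, grm: Kernel, masked_cells=()
) -> ReactionNormDesign:
    """Assemble the stacked design from a line x environment BLUE table.

    ``blues``: index = line ids, columns = environment ids, NaN = line
    not phenotyped in that environment (no cell).  ``masked_cells`` is
    an iterable of (line, environment) pairs to hold out of the
    likelihood while keeping them in the design for prediction.
    """
    grm_pos = {x: i for i, x in enumerate(grm.ids)}
    absent = [str(ln) for ln in blues.index if str(ln) not in grm_pos]
    if absent:
        raise DimensionError(
            f"phenotyped lines absent from the relationship matrix: {absent[:10]}"
        )
    env_ids = [str(c) for c in blues.columns]
    env_pos = {e: j for j, e in enumerate(env_ids)}
    masked = {(str(a), str(b)) for a, b in masked_cells}

    y, cl, ce, mk = [], [], [], []
    for env in env_ids:
        col = blues[env if env in blues.columns else blues.columns[env_pos[env]]]
        for ln, val in col.items():
            ln = str(ln)
            if pd.isna(val):
                continue
            y.append(float(val))
            cl.append(grm_pos[ln])
            ce.append(env_pos[env])
            mk.append((ln, env) in masked)
    cells = {(a, b) for a, b in zip(cl, ce)}
    unknown = masked - {
        (grm.ids[a], env_ids[b]) for a, b in cells
    }
    if unknown:
        raise DomainError(f"masked cells without a phenotype: {sorted(unknown)[:5]}")
    return ReactionNormDesign(
        np.asarray(y, dtype=float),
        np.asarray(cl, dtype=int),
        np.asarray(ce, dtype=int),
        np.asarray(mk, dtype=bool),
        list(grm.ids),
        env_ids,
        grm,
    )


def interaction_kernel(design: ReactionNormDesign) -> np.ndarray:
    """K_int = (Z_g G Z_g') # (Z_E Z_E') over all cells (dense; for
    inspection and small-problem verification)."""
    gg = design.grm.values[np.ix_(design.cell_line, design.cell_line)]
    same_env = design.cell_env[:, None] == design.cell_env[None, :]
    return gg * same_env


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in Gibbs draws."""

    mu: np.ndarray          # (d,)
    beta_E: np.ndarray      # (d, n_envs)
    g: np.ndarray           # (d, n_lines) -- every line in G
    u: np.ndarray           # (d, n_cells) -- includes masked cells
    sigma2_E: np.ndarray
    sigma2_g: np.ndarray
    sigma2_gxE: np.ndarray
    sigma2_e: np.ndarray
    line_ids: list = field(default_factory=list)
    env_ids: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.mu)


def _eig_basis(K: np.ndarray, tol: float) -> np.ndarray:
    lam, vec = np.linalg.eigh(K)
    lo = -tol * max(lam[-1], 1.0)
    if lam[0] < lo:
        raise DomainError(
            f"kernel is not positive semidefinite (min eigenvalue {lam[0]:.3e})"
        )
    keep = lam > tol * max(lam[-1], 1.0)
    return vec[:, keep] * np.sqrt(lam[keep])


def _sample_block(rng, W, WtW, Wtr, s2_eff, s2_e, diag):
    """Draw delta from N(C^-1 Wtr/s2_e, C^-1), C = WtW/s2_e + I/s2_eff."""
    r = WtW.shape[0]
    if diag:
        d = np.diag(WtW) / s2_e + 1.0 / s2_eff
        mean = (Wtr / s2_e) / d
        return mean + rng.standard_normal(r) / np.sqrt(d)
    C = WtW / s2_e + np.eye(r) / s2_eff
    L = np.linalg.cholesky(C)
    mean = np.linalg.solve(C, Wtr / s2_e)
    z = rng.standard_normal(r)
    return mean + np.linalg.solve(L.T, z)


def _is_diag(A: np.ndarray) -> bool:
    off = A - np.diag(np.diag(A))
    return float(np.abs(off).max(initial=0.0)) < 1e-10 * max(
        float(np.abs(np.diag(A)).max(initial=1.0)), 1.0
    )


def fit_gibbs(
    design: ReactionNormDesign,
    iterations: int = 30_000,
    burn_in: int = 15_000,
    thin: int = 10,
    seed: int | None = None,
    include_interaction: bool = True,
    include_intercept: bool = True,
    update_variances: bool = True,
    fixed_variances: dict | None = None,
    prior_df: float = 1.0,
    r2_error: float = 0.5,
    eig_tol: float = 1e-8,
) -> PosteriorSamples:
    """Gibbs-sample the reaction-norm model.

    The default schedule retains (iterations - burn_in) / thin draws.
    ``fixed_variances`` (keys among sigma2_E, sigma2_g, sigma2_gxE,
    sigma2_e) pins components, e.g. for conjugate closed-form checks
    with ``update_variances=False``.
    """
    if iterations <= burn_in:
        raise DomainError("iterations must exceed burn_in")
    rng = np.random.default_rng(seed)
    obs = ~design.mask
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise DomainError("no observed cells in the likelihood")
    y_obs = design.y[obs]
    vy = float(np.var(y_obs)) or 1.0

    # genomic main-effect basis over all lines
    phi_g = _eig_basis(design.grm.values, eig_tol)
    r_g = phi_g.shape[1]
    Wg = phi_g[design.cell_line[obs]]
    WtWg = Wg.T @ Wg
    diag_g = _is_diag(WtWg)

    # interaction basis, block diagonal by environment
    env_blocks = []
    if include_interaction:
        eig_cache = {}
        for e in range(design.n_envs):
            cells_e = np.nonzero(design.cell_env == e)[0]
            if len(cells_e) == 0:
                env_blocks.append(None)
                continue
            lines_e = design.cell_line[cells_e]
            key = tuple(lines_e)
            if key not in eig_cache:
                eig_cache[key] = _eig_basis(
                    design.grm.values[np.ix_(lines_e, lines_e)], eig_tol
                )
            phi_e = eig_cache[key]
            local_obs = obs[cells_e]
            We = phi_e[local_obs]
            WtWe = We.T @ We
            env_blocks.append(
                dict(
                    cells=cells_e,
                    phi=phi_e,
                    W=We,
                    WtW=WtWe,
                    diag=_is_diag(WtWe),
                    local_obs=local_obs,
                    delta=np.zeros(phi_e.shape[1]),
                )
            )

    # priors: scaled-inverse-chi-square, mode at a share of var(y)
    nu0 = prior_df
    n_eff_blocks = 3 if include_interaction else 2
    mode_e = r2_error * vy
    mode_rest = (1.0 - r2_error) * vy / n_eff_blocks
    s0 = {
        "sigma2_e": mode_e * (nu0 + 2) / nu0,
        "sigma2_E": mode_rest * (nu0 + 2) / nu0,
        "sigma2_g": mode_rest * (nu0 + 2) / nu0,
        "sigma2_gxE": mode_rest * (nu0 + 2) / nu0,
    }
    sigma2 = {
        "sigma2_e": mode_e,
        "sigma2_E": mode_rest,
        "sigma2_g": mode_rest,
        "sigma2_gxE": mode_rest,
    }
    if fixed_variances:
        sigma2.update(fixed_variances)

    env_of_obs = design.cell_env[obs]
    env_counts = np.bincount(env_of_obs, minlength=design.n_envs).astype(float)

    mu = float(np.mean(y_obs)) if include_intercept else 0.0
    beta = np.zeros(design.n_envs)
    delta_g = np.zeros(r_g)
    u_obs = np.zeros(n_obs)
    resid = y_obs - mu

    n_keep = (iterations - burn_in) // thin
    out = {
        "mu": np.empty(n_keep),
        "beta_E": np.empty((n_keep, design.n_envs)),
        "g": np.empty((n_keep, design.n_lines)),
        "u": np.zeros((n_keep, design.n_cells)),
        "sigma2_E": np.empty(n_keep),
        "sigma2_g": np.empty(n_keep),
        "sigma2_gxE": np.empty(n_keep),
        "sigma2_e": np.empty(n_keep),
    }
    kept = 0

    for it in range(1, iterations + 1):
        s2e = sigma2["sigma2_e"]

        # intercept (flat prior)
        if include_intercept:
            resid += mu
            mu = float(np.mean(resid)) + rng.standard_normal() * np.sqrt(s2e / n_obs)
            resid -= mu

        # environment effects
        sums = np.bincount(env_of_obs, weights=resid + beta[env_of_obs],
                           minlength=design.n_envs)
        prec = env_counts / s2e + 1.0 / sigma2["sigma2_E"]
        means = (sums / s2e) / prec
        beta_new = means + rng.standard_normal(design.n_envs) / np.sqrt(prec)
        resid += beta[env_of_obs] - beta_new[env_of_obs]
        beta = beta_new

        # genomic main effects
        r_full = resid + Wg @ delta_g
        delta_g = _sample_block(
            rng, Wg, WtWg, Wg.T @ r_full, sigma2["sigma2_g"], s2e, diag_g
        )
        resid = r_full - Wg @ delta_g

        # interaction, one block per environment
        if include_interaction:
            for blk in env_blocks:
                if blk is None or blk["W"].shape[0] == 0:
                    if blk is not None:
                        blk["delta"] = rng.standard_normal(
                            blk["phi"].shape[1]
                        ) * np.sqrt(sigma2["sigma2_gxE"])
                    continue
                sel = env_of_obs == design.cell_env[blk["cells"][0]]
                r_blk = resid[sel] + blk["W"] @ blk["delta"]
                blk["delta"] = _sample_block(
                    rng, blk["W"], blk["WtW"], blk["W"].T @ r_blk,
                    sigma2["sigma2_gxE"], s2e, blk["diag"],
                )
                resid[sel] = r_blk - blk["W"] @ blk["delta"]

        # variance components
        if update_variances:
            def draw(ss, q, key):
                scale = nu0 * s0[key] + ss
                return scale / rng.chisquare(nu0 + q)

            sigma2["sigma2_e"] = draw(float(resid @ resid), n_obs, "sigma2_e")
            sigma2["sigma2_E"] = draw(float(beta @ beta), design.n_envs, "sigma2_E")
            sigma2["sigma2_g"] = draw(float(delta_g @ delta_g), r_g, "sigma2_g")
            if include_interaction:
                ss_u = sum(
                    float(b["delta"] @ b["delta"])
                    for b in env_blocks if b is not None
                )
                q_u = sum(
                    len(b["delta"]) for b in env_blocks if b is not None
                )
                sigma2["sigma2_gxE"] = draw(ss_u, q_u, "sigma2_gxE")
            for key, v in sigma2.items():
                if not np.isfinite(v) or v > 1e12 * vy:
                    raise RuntimeError(
                        f"divergent variance {key}={v:.3e} at iteration {it}"
                    )
            if fixed_variances:
                sigma2.update(fixed_variances)

        if it > burn_in and (it - burn_in) % thin == 0:
            out["mu"][kept] = mu
            out["beta_E"][kept] = beta
            out["g"][kept] = phi_g @ delta_g
            if include_interaction:
                for blk in env_blocks:
                    if blk is not None:
                        out["u"][kept, blk["cells"]] = blk["phi"] @ blk["delta"]
            out["sigma2_E"][kept] = sigma2["sigma2_E"]
            out["sigma2_g"][kept] = sigma2["sigma2_g"]
            out["sigma2_gxE"][kept] = (
                sigma2["sigma2_gxE"] if include_interaction else 0.0
            )
            out["sigma2_e"][kept] = sigma2["sigma2_e"]
            kept += 1

    return PosteriorSamples(
        out["mu"], out["beta_E"], out["g"], out["u"],
        out["sigma2_E"], out["sigma2_g"], out["sigma2_gxE"], out["sigma2_e"],
        list(design.line_ids), list(design.env_ids),
    )


def predicted_cells(samples: PosteriorSamples, design: ReactionNormDesign) -> np.ndarray:
    """Posterior-mean model value mu + beta_e + g + u for every cell."""
    mu = samples.mu.mean()
    beta = samples.beta_E.mean(axis=0)
    g = samples.g.mean(axis=0)
    u = samples.u.mean(axis=0)
    return mu + beta[design.cell_env] + g[design.cell_line] + u


def predict_gebv(samples: PosteriorSamples, design: ReactionNormDesign) -> pd.DataFrame:
    """Genomic estimated breeding values for every line in G.

    Per-environment value: mu + beta_e + g_i (+ the cell's interaction
    mean where the line has a cell in that environment).  The
    across-environment GEBV averages the per-environment values.
    Lines with at least one unmasked cell are labelled TRN, the rest
    TST.
    """
    if samples.n_retained == 0:
        raise DomainError("no retained draws")
    mu = samples.mu.mean()
    beta = samples.beta_E.mean(axis=0)
    g = samples.g.mean(axis=0)
    u = samples.u.mean(axis=0)

    n_lines, n_envs = design.n_lines, design.n_envs
    per_env = np.tile(mu + beta, (n_lines, 1)) + g[:, None]
    for k, (li, ei) in enumerate(zip(design.cell_line, design.cell_env)):
        per_env[li, ei] += u[k]

    observed_lines = set(design.cell_line[~design.mask].tolist())
    out = pd.DataFrame(
        per_env, index=design.line_ids,
        columns=[f"gebv_{e}" for e in design.env_ids],
    )
    out.insert(0, "gebv", per_env.mean(axis=1))
    out.insert(
        0, "set",
        ["TRN" if i in observed_lines else "TST" for i in range(n_lines)],
    )
    return out
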