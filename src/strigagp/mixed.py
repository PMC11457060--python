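"""Trial mixed models: BLUEs, BLUPs, variance components, heritability.

Single-site model for an alpha-lattice trial:

    y_ijk = mu + G_i + R_j + B_k(R_j) + eps_ijk

Across-site model (environment = location, fixed; everything else
except the intercept random):

    y_ijkl = mu + G_i + E_j + R_k(E_j) + B_l(ER)_jk + GE_ij + eps_ijkl

The tester enters both models as an additional fixed effect, and the
per-line value reported is the line effect averaged over testers.
BLUEs come from the genotype-fixed fit (GLS at the REML components),
BLUPs from the genotype-random fit (mixed-model equations).

Broad-sense heritability on an entry-mean basis:

    single site:   H2 = s2_G / (s2_G + s2_e / R)
    across sites:  H2 = s2_G / (s2_G + s2_GE / E + s2_e / (E R))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .reml import RandomTerm, em_reml

__all__ = [
    "VarianceComponents",
    "TraitSummary",
    "fit_single_site",
    "fit_across_sites",
    "blues_by_environment",
    "heritability_single",
    "heritability_across",
    "trait_correlations",
]


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_error: float
    sigma2_rep: float = 0.0
    sigma2_block: float = 0.0
    sigma2_GE: float | None = None
    n_environments: int = 1
    n_replicates: int = 2


@dataclass
class TraitSummary:
    trait: str
    blues: pd.Series | None
    blups: pd.Series | None
    varcomps: VarianceComponents
    heritability: float
    lsd05: float | None = None


def _dummies(values, drop_first: bool):
    cat = pd.Categorical(values)
    d = pd.get_dummies(cat, drop_first=drop_first, dtype=float)
    return d.to_numpy(), [str(c) for c in d.columns], [str(c) for c in cat.categories]


def _check_records(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    required = {"location", "replicate", "block", "entry", "tester"}
    missing = required - set(records.columns)
    if missing:
        raise DomainError(f"missing design columns: {sorted(missing)}")
    if trait not in records.columns:
        raise DomainError(f"unknown trait column {trait!r}")
    df = records.dropna(subset=[trait]).copy()
    for c in ("location", "replicate", "block", "entry", "tester"):
        df[c] = df[c].astype(str)
    return df


def _tester_mean(beta, names, prefix="tester:"):
    """Mean fixed effect over tester levels under treatment coding
    (reference level contributes 0)."""
    effs = [beta[i] for i, nm in enumerate(names) if nm.startswith(prefix)]
    n_lev = len(effs) + 1
    return float(sum(effs)) / n_lev if effs else 0.0


def _fixed_design(df, factors):
    """Intercept + treatment-coded dummies for each (name, values) factor."""
    cols = [np.ones((len(df), 1))]
    names = ["intercept"]
    levels = {}
    for name, values in factors:
        d, lab, cats = _dummies(values, drop_first=True)
        cols.append(d)
        names += [f"{name}:{c}" for c in lab]
        levels[name] = cats
    return np.hstack(cols), names, levels


def fit_single_site(
    records: pd.DataFrame,
    trait: str,
    genotype_effect: str = "both",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> TraitSummary:
    """Fit the single-environment model for one trait.

    ``records`` must contain exactly one location.  Returns BLUEs
    (genotype fixed), BLUPs and variance components (genotype random),
    and the single-site heritability.
    """
    df = _check_records(records, trait)
    if df["location"].nunique() != 1:
        raise DomainError("single-site fit expects exactly one location")
    n_rep = df["replicate"].nunique()
    if n_rep < 2:
        raise DomainError("need >= 2 replicates to separate error variance")
    y = df[trait].to_numpy(dtype=float)
    rep_f = df["replicate"]
    block_f = df["replicate"] + "/" + df["block"]

    blues = blups = None
    vc = None

    if genotype_effect in ("random", "both"):
        X, names, _ = _fixed_design(df, [("tester", df["tester"])])
        Zg, g_lab, _ = _dummies(df["entry"], drop_first=False)
        Zr, _, _ = _dummies(rep_f, drop_first=False)
        Zb, _, _ = _dummies(block_f, drop_first=False)
        res = em_reml(
            y, X,
            [RandomTerm("entry", Zg), RandomTerm("rep", Zr), RandomTerm("block", Zb)],
            tol=tol, max_iter=max_iter,
        )
        vc = VarianceComponents(
            sigma2_G=res.sigma2["entry"],
            sigma2_error=res.sigma2["error"],
            sigma2_rep=res.sigma2["rep"],
            sigma2_block=res.sigma2["block"],
            n_environments=1,
            n_replicates=n_rep,
        )
        base = res.beta[0] + _tester_mean(res.beta, names)
        blups = pd.Series(res.u["entry"] + base, index=g_lab).sort_index()

    if genotype_effect in ("fixed", "both"):
        X, names, levels = _fixed_design(
            df, [("entry", df["entry"]), ("tester", df["tester"])]
        )
        Zr, _, _ = _dummies(rep_f, drop_first=False)
        Zb, _, _ = _dummies(block_f, drop_first=False)
        res_f = em_reml(
            y, X, [RandomTerm("rep", Zr), RandomTerm("block", Zb)],
            tol=tol, max_iter=max_iter,
        )
        base = res_f.beta[0] + _tester_mean(res_f.beta, names)
        entry_levels = levels["entry"]
        eff = {lv: 0.0 for lv in entry_levels}
        for i, nm in enumerate(names):
            if nm.startswith("entry:"):
                eff[nm[len("entry:"):]] = res_f.beta[i]
        blues = pd.Series({lv: base + e for lv, e in eff.items()}).sort_index()
        if vc is None:
            vc = VarianceComponents(
                sigma2_G=float("nan"),
                sigma2_error=res_f.sigma2["error"],
                sigma2_rep=res_f.sigma2["rep"],
                sigma2_block=res_f.sigma2["block"],
                n_environments=1,
                n_replicates=n_rep,
            )

    h2 = heritability_single(vc) if np.isfinite(vc.sigma2_G) else float("nan")
    dof = len(y) - df["entry"].nunique() - df["tester"].nunique()
    lsd = None
    if dof > 0 and vc.sigma2_error > 0:
        lsd = float(
            stats.t.ppf(0.975, dof) * np.sqrt(2 * vc.sigma2_error / n_rep)
        )
    return TraitSummary(trait, blues, blups, vc, h2, lsd)


def fit_across_sites(
    records: pd.DataFrame,
    trait: str,
    genotype_effect: str = "both",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> TraitSummary:
    """Fit the combined multi-location model for one trait.

    Environment (location) is fixed; genotype, GxE, replicate within
    environment and block within replicate are random.  For BLUEs the
    genotype switches to fixed and is averaged over environments and
    testers.
    """
    df = _check_records(records, trait)
    n_env = df["location"].nunique()
    if n_env < 2:
        raise DomainError("across-site fit expects >= 2 locations")
    n_rep = df.groupby("location")["replicate"].nunique().max()
    all_entries = set(records["entry"].astype(str))
    orphans = sorted(all_entries - set(df["entry"]))
    if orphans:
        warnings.warn(
            f"excluding entries with no observed environment: {orphans[:10]}"
        )
    y = df[trait].to_numpy(dtype=float)
    rep_f = df["location"] + "/" + df["replicate"]
    block_f = rep_f + "/" + df["block"]
    ge_f = df["entry"] + "@" + df["location"]

    blues = blups = None
    vc = None

    if genotype_effect in ("random", "both"):
        X, names, _ = _fixed_design(
            df, [("location", df["location"]), ("tester", df["tester"])]
        )
        Zg, g_lab, _ = _dummies(df["entry"], drop_first=False)
        Zge, _, _ = _dummies(ge_f, drop_first=False)
        Zr, _, _ = _dummies(rep_f, drop_first=False)
        Zb, _, _ = _dummies(block_f, drop_first=False)
        res = em_reml(
            y, X,
            [
                RandomTerm("entry", Zg),
                RandomTerm("gxe", Zge),
                RandomTerm("rep", Zr),
                RandomTerm("block", Zb),
            ],
            tol=tol, max_iter=max_iter,
        )
        vc = VarianceComponents(
            sigma2_G=res.sigma2["entry"],
            sigma2_error=res.sigma2["error"],
            sigma2_rep=res.sigma2["rep"],
            sigma2_block=res.sigma2["block"],
            sigma2_GE=res.sigma2["gxe"],
            n_environments=n_env,
            n_replicates=int(n_rep),
        )
        env_mean = _tester_mean(res.beta, names, prefix="location:")
        base = res.beta[0] + env_mean + _tester_mean(res.beta, names)
        blups = pd.Series(res.u["entry"] + base, index=g_lab).sort_index()

    if genotype_effect in ("fixed", "both"):
        X, names, levels = _fixed_design(
            df,
            [
                ("entry", df["entry"]),
                ("location", df["location"]),
                ("tester", df["tester"]),
            ],
        )
        Zge, _, _ = _dummies(ge_f, drop_first=False)
        Zr, _, _ = _dummies(rep_f, drop_first=False)
        Zb, _, _ = _dummies(block_f, drop_first=False)
        res_f = em_reml(
            y, X,
            [RandomTerm("gxe", Zge), RandomTerm("rep", Zr), RandomTerm("block", Zb)],
            tol=tol, max_iter=max_iter,
        )
        env_mean = _tester_mean(res_f.beta, names, prefix="location:")
        base = res_f.beta[0] + env_mean + _tester_mean(res_f.beta, names)
        eff = {lv: 0.0 for lv in levels["entry"]}
        for i, nm in enumerate(names):
            if nm.startswith("entry:"):
                eff[nm[len("entry:"):]] = res_f.beta[i]
        blues = pd.Series({lv: base + e for lv, e in eff.items()}).sort_index()
        if vc is None:
            vc = VarianceComponents(
                sigma2_G=float("nan"),
                sigma2_error=res_f.sigma2["error"],
                sigma2_rep=res_f.sigma2["rep"],
                sigma2_block=res_f.sigma2["block"],
                sigma2_GE=res_f.sigma2["gxe"],
                n_environments=n_env,
                n_replicates=int(n_rep),
            )

    h2 = heritability_across(vc) if np.isfinite(vc.sigma2_G) else float("nan")
    dof = len(y) - df["entry"].nunique() - n_env - df["tester"].nunique()
    lsd = None
    if dof > 0 and vc.sigma2_error > 0:
        lsd = float(
            stats.t.ppf(0.975, dof)
            * np.sqrt(2 * vc.sigma2_error / (n_rep * n_env))
        )
    return TraitSummary(trait, blues, blups, vc, h2, lsd)


def blues_by_environment(
    records: pd.DataFrame, trait: str, tol: float = 1e-8, max_iter: int = 200
) -> pd.DataFrame:
    """Per-environment single-site BLUEs, one row per line, one column
    per environment — the stacked response of the reaction-norm model."""
    df = _check_records(records, trait)
    out = {}
    for env, sub in df.groupby("location"):
        summary = fit_single_site(sub, trait, genotype_effect="fixed",
                                  tol=tol, max_iter=max_iter)
        out[env] = summary.blues
    return pd.DataFrame(out).sort_index()


def heritability_single(vc: VarianceComponents) -> float:
    """H2 = s2_G / (s2_G + s2_e / R); defined as 0 when everything is 0."""
    if vc.n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    denom = vc.sigma2_G + vc.sigma2_error / vc.n_replicates
    return float(vc.sigma2_G / denom) if denom > 0 else 0.0


def heritability_across(vc: VarianceComponents) -> float:
    """H2 = s2_G / (s2_G + s2_GE / E + s2_e / (E R))."""
    if vc.n_environments < 1 or vc.n_replicates < 1:
        raise DomainError("environment and replicate counts must be >= 1")
    s2ge = vc.sigma2_GE or 0.0
    denom = (
        vc.sigma2_G
        + s2ge / vc.n_environments
        + vc.sigma2_error / (vc.n_environments * vc.n_replicates)
    )
    return float(vc.sigma2_G / denom) if denom > 0 else 0.0


def trait_correlations(blups: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between per-entry trait values (e.g. BLUPs).

    Constant traits yield NaN correlations and a warning, never a
    silent 0.
    """
    if len(blups) < 3:
        raise DomainError("need >= 3 entries for a correlation")
    constant = [c for c in blups.columns if blups[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"constant traits have undefined correlations: {constant}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = blups.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, [1.0 if c not in constant else np.nan
                                   for c in corr.columns])
    return corr
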