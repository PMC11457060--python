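"""Sparse-testing cross-validation schemes CV0, CV1 and CV2.

* **CV0** — leave one environment out entirely: the model is trained on
  the other environments and predicts every line in the held-out one
  (one fold per environment).
* **CV1** — untested lines: a random 20 % of the lines have *all* their
  environments masked; their predictions rely purely on genomic
  relationships.
* **CV2** — sparse testing: random line-by-environment cells are
  masked, but every line keeps at least one observed environment, so
  predictions can borrow both relatives and the line's own performance
  elsewhere.

Accuracy is the raw Pearson correlation between observed and predicted
values on masked cells, computed per fold and per environment and then
averaged over folds; the across-environment figure is a pair-count
weighted mean of the per-environment accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .markers import Kernel
from .reaction_norm import build_design, fit_gibbs, predicted_cells

__all__ = [
    "CVPartition",
    "AccuracyResult",
    "make_partitions",
    "run_cv",
    "weighted_across_r",
    "gibbs_fitter",
]

SCHEMES = ("CV0", "CV1", "CV2")


@dataclass(frozen=True)
class CVPartition:
    scheme: str
    fold_index: int
    masked_cells: frozenset  # of (line, environment)
    seed: int


@dataclass
class AccuracyResult:
    scheme: str
    trait: str
    per_environment: dict      # env -> mean fold-level r
    across: float              # pair-count weighted mean
    n_folds: int
    fold_results: list = field(default_factory=list)  # per fold: env -> (r, n)


def make_partitions(
    scheme: str,
    lines,
    environments,
    n_folds: int = 50,
    test_fraction: float = 0.2,
    seed: int | None = None,
    cells=None,
) -> list:
    """Generate masking partitions for one CV scheme.

    ``cells`` restricts the candidate (line, environment) pairs to
    those actually phenotyped; by default every line x environment
    combination is a cell.  CV0 ignores ``n_folds`` (one fold per
    environment).
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    lines = [str(x) for x in lines]
    environments = [str(x) for x in environments]
    if not (0 < test_fraction < 1):
        raise ConfigurationError("test_fraction must be in (0, 1)")
    if scheme in ("CV0", "CV2") and len(environments) < 2:
        raise ConfigurationError(f"{scheme} needs >= 2 environments")
    if cells is None:
        cells = [(ln, env) for ln in lines for env in environments]
    cells = [(str(a), str(b)) for a, b in cells]
    rng = np.random.default_rng(seed)
    base_seed = seed if seed is not None else 0

    if scheme == "CV0":
        return [
            CVPartition(
                "CV0", k,
                frozenset(c for c in cells if c[1] == env),
                base_seed,
            )
            for k, env in enumerate(environments)
        ]

    partitions = []
    if scheme == "CV1":
        n_test = int(np.floor(test_fraction * len(lines)))
        if n_test == 0:
            raise ConfigurationError("test_fraction leaves no test lines")
        for k in range(n_folds):
            test_lines = set(rng.choice(lines, size=n_test, replace=False))
            masked = frozenset(c for c in cells if c[0] in test_lines)
            partitions.append(CVPartition("CV1", k, masked, base_seed))
        return partitions

    # CV2: mask cells, keep >= 1 observed environment per line
    cells_by_line = {}
    for c in cells:
        cells_by_line.setdefault(c[0], []).append(c)
    n_mask = int(np.floor(test_fraction * len(cells)))
    max_maskable = len(cells) - len(cells_by_line)
    if n_mask > max_maskable:
        raise ConfigurationError(
            "test_fraction too large: every line must keep one observed environment"
        )
    for k in range(n_folds):
        idx = rng.choice(len(cells), size=n_mask, replace=False)
        masked = {cells[i] for i in idx}
        # repair lines left with no observed environment
        for ln, own in cells_by_line.items():
            guard = 0
            while all(c in masked for c in own):
                freed = own[rng.integers(len(own))]
                masked.discard(freed)
                candidates = [c for c in cells if c not in masked
                              and not all(
                                  x in masked or x == c
                                  for x in cells_by_line[c[0]]
                              )]
                masked.add(candidates[rng.integers(len(candidates))])
                guard += 1
                if guard > 100:
                    raise ConfigurationError("cannot satisfy CV2 constraint")
        partitions.append(CVPartition("CV2", k, frozenset(masked), base_seed))
    return partitions


def weighted_across_r(per_environment: dict) -> float:
    """Pair-count weighted mean of per-environment accuracies.

    ``per_environment``: env -> (r, n_pairs); environments with
    undefined r (NaN) are excluded.  Raises if nothing is defined.
    """
    items = [(r, n) for r, n in per_environment.values()
             if np.isfinite(r) and n > 0]
    if not items:
        raise DomainError("no environment has a defined accuracy")
    total = sum(n for _, n in items)
    return float(sum(r * n for r, n in items) / total)


def gibbs_fitter(design, seed, **sampler):
    """Default fold fitter: Gibbs fit + posterior-mean cell predictions."""
    samples = fit_gibbs(design, seed=seed, **sampler)
    return predicted_cells(samples, design)


def run_cv(
    blues: pd.DataFrame,
    grm: Kernel,
    scheme: str,
    n_folds: int = 50,
    test_fraction: float = 0.2,
    seed: int | None = None,
    sampler: dict | None = None,
    fitter=None,
    trait: str = "",
    min_pairs: int = 3,
) -> AccuracyResult:
    """Run one CV scheme over a line x environment BLUE table.

    Per fold: mask the partition's cells, refit the reaction-norm
    model, predict the masked cells, and correlate observed with
    predicted per environment.  Fold-level correlations are averaged
    over folds; the across figure weights environments by their total
    number of masked pairs.
    """
    sampler = dict(sampler or {})
    fitter = fitter or gibbs_fitter
    lines = [str(x) for x in blues.index]
    envs = [str(c) for c in blues.columns]
    cells = [
        (str(ln), str(env))
        for env in blues.columns
        for ln, v in blues[env].items()
        if pd.notna(v)
    ]
    partitions = make_partitions(
        scheme, lines, envs, n_folds=n_folds,
        test_fraction=test_fraction, seed=seed, cells=cells,
    )

    fold_results = []
    for part in partitions:
        design = build_design(blues, grm, masked_cells=part.masked_cells)
        fold_seed = None if seed is None else seed + 1000 * (part.fold_index + 1)
        pred = fitter(design, fold_seed, **sampler)
        env_r = {}
        for e, env in enumerate(envs):
            sel = design.mask & (design.cell_env == e)
            n = int(sel.sum())
            if n < min_pairs:
                if n > 0:
                    warnings.warn(
                        f"{scheme} fold {part.fold_index}: only {n} masked "
                        f"pairs in {env}; skipped"
                    )
                continue
            obs_v = design.y[sel]
            pred_v = pred[sel]
            if np.std(obs_v) == 0 or np.std(pred_v) == 0:
                env_r[env] = (float("nan"), n)
                continue
            env_r[env] = (float(np.corrcoef(obs_v, pred_v)[0, 1]), n)
        fold_results.append(env_r)

    per_env = {}
    for env in envs:
        rs = [fr[env][0] for fr in fold_results
              if env in fr and np.isfinite(fr[env][0])]
        if rs:
            per_env[env] = float(np.mean(rs))
    totals = {
        env: (
            per_env[env],
            sum(fr[env][1] for fr in fold_results if env in fr),
        )
        for env in per_env
    }
    across = weighted_across_r(totals) if totals else float("nan")
    return AccuracyResult(scheme, trait, per_env, across, len(partitions), fold_results)
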