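"""EM-REML for variance components in Gaussian linear mixed models.

The models fitted here have the form

    y = X b + sum_i Z_i u_i + e,   u_i ~ N(0, s2_i I),  e ~ N(0, s2_e I)

with dense design matrices.  Variance components are estimated by
EM-REML on Henderson's mixed-model equations (MME): each iteration
solves the MME at the current components and updates

    s2_i <- (u_i' u_i + s2_e * tr(C_ii)) / q_i
    s2_e <- (y'y - b' X'y - u' Z'y) / (n - rank(X))

where C_ii is the u_i block of the inverse MME coefficient matrix.
EM steps never decrease the restricted likelihood and keep every
component nonnegative; components collapsing to the boundary are held
at a small floor.  Convergence: relative change of every component
below ``tol`` or ``max_iter`` iterations, whichever first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import DimensionError, DomainError

__all__ = ["RandomTerm", "REMLResult", "em_reml", "reml_loglik"]


@dataclass
class RandomTerm:
    """A named iid random-effect block with incidence matrix Z (n x q)."""

    name: str
    Z: np.ndarray

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise DimensionError("Z must be 2-d")

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class REMLResult:
    sigma2: dict                  # term name -> variance, plus "error"
    beta: np.ndarray              # GLS fixed-effect estimates at the REML fit
    u: dict                       # term name -> BLUP vector
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)  # per-iteration components
    dof_error: int = 0


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    terms: list,
    tol: float = 1e-8,
    max_iter: int = 200,
    init: dict | None = None,
) -> REMLResult:
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n = len(y)
    if X.shape[0] != n or any(t.Z.shape[0] != n for t in terms):
        raise DimensionError("design matrices must have one row per observation")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise DomainError("fixed-effect design X is rank deficient")
    if n <= p:
        raise DomainError("no residual degrees of freedom (n <= rank(X))")

    vary = float(np.var(y))
    if vary <= 1e-13 * max(1.0, float(np.mean(y)) ** 2):
        vary = 0.0
    if vary == 0:
        # degenerate: constant response, everything at the boundary
        zero = {t.name: 0.0 for t in terms}
        zero["error"] = 0.0
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return REMLResult(zero, beta, {t.name: np.zeros(t.q) for t in terms},
                          0, True, [], n - p)

    floor = 1e-8 * vary
    k = len(terms)
    sigma2 = {t.name: max(vary / (k + 1), floor) for t in terms}
    sigma2["error"] = max(vary / (k + 1), floor)
    if init:
        for name, v in init.items():
            sigma2[name] = max(float(v), floor)

    Z = np.hstack([t.Z for t in terms]) if terms else np.zeros((n, 0))
    q_tot = Z.shape[1]
    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    slices, start = {}, p
    for t in terms:
        slices[t.name] = slice(start, start + t.q)
        start += t.q

    history = []
    converged = False
    sol = np.zeros(p + q_tot)
    for it in range(1, max_iter + 1):
        A = WtW.copy()
        for t in terms:
            sl = slices[t.name]
            lam = sigma2["error"] / sigma2[t.name]
            A[sl, sl] += np.eye(t.q) * lam
        try:
            cho = linalg.cho_factor(A, lower=True, check_finite=False)
            sol = linalg.cho_solve(cho, Wty, check_finite=False)
            Ainv = linalg.cho_solve(cho, np.eye(p + q_tot), check_finite=False)
        except np.linalg.LinAlgError:
            # near-singular MME (components pinned at the boundary)
            Ainv = np.linalg.pinv(A, hermitian=True)
            sol = Ainv @ Wty

        s2e_new = (yty - float(sol @ Wty)) / (n - p)
        s2e_new = max(s2e_new, floor)
        new = {}
        for t in terms:
            sl = slices[t.name]
            u_t = sol[sl]
            tr = float(np.trace(Ainv[sl, sl]))
            new[t.name] = max((float(u_t @ u_t) + sigma2["error"] * tr) / t.q, floor)
        new["error"] = s2e_new

        rel = max(
            abs(new[name] - sigma2[name]) / max(sigma2[name], floor)
            for name in new
        )
        sigma2 = new
        history.append(dict(sigma2))
        if rel < tol:
            converged = True
            break

    beta = sol[:p]
    u = {t.name: sol[slices[t.name]] for t in terms}
    # zero-out components that sit at the floor (boundary estimates)
    for name in list(sigma2):
        if sigma2[name] <= floor * 1.01 and name != "error":
            sigma2[name] = 0.0
    return REMLResult(sigma2, beta, u, len(history), converged, history, n - p)


def reml_loglik(y, X, terms, sigma2) -> float:
    """Restricted log-likelihood at given components (direct dense form).

    -2 ln L_R = ln|V| + ln|X'V^-1 X| + y'Py  (constants dropped).
    Intended for verification on small problems.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n = len(y)
    V = np.eye(n) * sigma2["error"]
    for t in terms:
        V += sigma2[t.name] * (t.Z @ t.Z.T)
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    XtVinvX = XtVinv @ X
    beta = np.linalg.solve(XtVinvX, XtVinv @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVinvX)
    return -0.5 * (ld_v + ld_x + float(r @ Vinv @ r))
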