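"""Crucial-wavenumber screening.

Two selectors share this module: stepwise discriminant analysis (SWDA) for
the classification task — forward entry with backward removal driven by
Wilks' lambda partial F statistics — and competitive adaptive reweighted
sampling (CARS) for the quantification task — Monte-Carlo PLS-coefficient
weighting under an exponentially decreasing retention schedule, with the
subset chosen by cross-validated RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .errors import EmptySelectionError


@dataclass
class SelectionResult:
    """Selected variable indices (ascending) plus the per-step audit trace."""

    method: str
    selected: np.ndarray
    trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# PLS primitive
# ---------------------------------------------------------------------------

def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, float]:
    """PLS1 regression coefficients (coef, intercept) for centered X, y.

    NIPALS via scikit-learn; deterministic.  ``n_components`` must not
    exceed min(n - 1, p).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components={n_components} invalid for shape {X.shape}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    coef = pls.coef_.ravel()
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return coef, intercept


def _pls_cv_rmse(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    cv_folds: int,
    seed: int,
) -> tuple[float, int]:
    """Minimum K-fold RMSECV over 1..max_components PLS components.

    One PLS fit per fold at the maximum component count; the k-component
    coefficient vector is recovered by truncating the rotation/loading
    expansion, so all component counts share the folds' fits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    kmax = min(max_components, n - 1 - int(np.ceil(n / cv_folds)), p)
    kmax = max(kmax, 1)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    sse = np.zeros(kmax)
    for tr, te in kf.split(X):
        k_fit = min(kmax, len(tr) - 1, p)
        pls = PLSRegression(n_components=k_fit, scale=False)
        pls.fit(X[tr], y[tr])
        Xc = X[te] - X[tr].mean(axis=0)
        for k in range(1, k_fit + 1):
            coef_k = pls.x_rotations_[:, :k] @ pls.y_loadings_[:, :k].T
            pred = y[tr].mean() + Xc @ coef_k.ravel()
            sse[k - 1] += np.sum((y[te] - pred) ** 2)
        if k_fit < kmax:
            sse[k_fit:] += sse[k_fit - 1]
    rmse = np.sqrt(sse / n)
    best = int(np.argmin(rmse))
    return float(rmse[best]), best + 1


# ---------------------------------------------------------------------------
# SWDA
# ---------------------------------------------------------------------------

def swda_select(
    X: np.ndarray,
    labels: np.ndarray,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_vars: int | None = None,
) -> SelectionResult:
    """Stepwise discriminant analysis minimizing Wilks' lambda.

    At each step the variable with the largest partial F enters if
    F >= ``f_enter``; afterwards any included variable whose partial F drops
    below ``f_remove`` is removed.  Stops when no entry qualifies or
    ``max_vars`` is reached.  Constant or collinear variables are skipped.
    """
    if f_enter <= f_remove:
        raise ValueError("f_enter must exceed f_remove (prevents cycling)")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    classes = np.unique(labels)
    g = classes.size
    if g < 2:
        raise ValueError("SWDA needs at least 2 classes")
    if n <= g:
        raise ValueError("SWDA needs more samples than classes")
    if max_vars is None:
        max_vars = min(n - g - 1, p)

    # within- and total-scatter residual matrices; scatter rows are computed
    # lazily (Xw.T @ Xw would be p x p)
    Xt = X - X.mean(axis=0)
    Xw = X.copy()
    for c in classes:
        m = labels == c
        Xw[m] -= X[m].mean(axis=0)
    diag_w = np.einsum("ij,ij->j", Xw, Xw)
    diag_t = np.einsum("ij,ij->j", Xt, Xt)
    usable = diag_t > 1e-12 * max(diag_t.max(), 1.0)

    selected: list[int] = []
    rows_w: list[np.ndarray] = []  # within-scatter rows of the selected vars
    rows_t: list[np.ndarray] = []
    lam = 1.0
    trace: list[dict] = []

    def conditional(diag: np.ndarray, rows: list[np.ndarray]) -> np.ndarray:
        """diag of the Schur complement: var_vv - var_vS var_SS^-1 var_Sv."""
        if not selected:
            return diag.copy()
        R = np.vstack(rows)  # |S| x p
        A = np.linalg.solve(R[:, selected], R)
        return diag - np.einsum("sj,sj->j", R, A)

    while len(selected) < max_vars:
        w_cond = conditional(diag_w, rows_w)
        t_cond = conditional(diag_t, rows_t)
        m = len(selected)
        cand = usable.copy()
        cand[selected] = False
        # collinear with the selected set, or numerically negative
        cand &= t_cond > 1e-10 * np.maximum(diag_t, 1e-300)
        cand &= w_cond > 1e-12 * np.maximum(diag_w, 1e-300)
        if not np.any(cand):
            break
        ratio = np.where(cand, t_cond / np.maximum(w_cond, 1e-300), 0.0)
        F = (n - g - m) / (g - 1) * (ratio - 1.0)
        F[~cand] = -np.inf
        v = int(np.argmax(F))  # argmax returns the lowest index on ties
        if F[v] < f_enter or not np.isfinite(F[v]):
            break
        lam *= w_cond[v] / t_cond[v]
        selected.append(v)
        rows_w.append(Xw[:, v] @ Xw)
        rows_t.append(Xt[:, v] @ Xt)
        trace.append({"action": "enter", "variable": v, "wilks_lambda": lam, "F": float(F[v])})

        # backward removal sweep
        while len(selected) > 1:
            Ws = np.vstack(rows_w)[:, selected]
            Ts = np.vstack(rows_t)[:, selected]
            w_part = 1.0 / np.diag(np.linalg.inv(Ws))
            t_part = 1.0 / np.diag(np.linalg.inv(Ts))
            m = len(selected)
            Frem = (n - g - m + 1) / (g - 1) * (t_part / w_part - 1.0)
            worst = int(np.argmin(Frem))
            if Frem[worst] >= f_remove:
                break
            lam /= w_part[worst] / t_part[worst]
            v_out = selected.pop(worst)
            rows_w.pop(worst)
            rows_t.pop(worst)
            trace.append(
                {"action": "remove", "variable": v_out, "wilks_lambda": lam,
                 "F": float(Frem[worst])}
            )

    if not selected:
        raise EmptySelectionError("SWDA: no variable met the F-to-enter threshold")
    return SelectionResult(method="swda", selected=np.array(sorted(selected)), trace=trace)


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    cv_folds: int = 5,
    max_pls_components: int = 10,
    sample_ratio: float = 0.8,
    rng: np.random.Generator | int | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling on training data.

    Per run i: fit PLS on a random ``sample_ratio`` subset of the samples,
    weight each retained variable by its absolute PLS coefficient, enforce
    the exponentially decreasing retention ratio r_i = a*exp(-k*i) (r_1
    keeps all p variables, r_{n_runs} keeps 2), then adaptive reweighted
    sampling (a weighted draw with replacement) fixes the retained set.
    Each run's subset is scored by ``cv_folds``-fold cross-validated RMSE
    with the component count chosen by that same CV (capped at
    ``max_pls_components``); the subset with minimal RMSECV wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 variables")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))

    # retention schedule: r_1 * p = p, r_N * p = 2
    N = n_runs
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)

    retained = np.arange(p)
    n_mc = max(2, int(round(sample_ratio * n)))
    trace: list[dict] = []
    best = {"rmsecv": np.inf, "subset": None}
    for i in range(1, N + 1):
        rows = rng.choice(n, size=n_mc, replace=False)
        ncomp = min(max_pls_components, n_mc - 1, retained.size)
        coef, _ = pls_fit(X[np.ix_(rows, retained)], y[rows], ncomp)
        w = np.abs(coef)
        n_keep = int(round(a * np.exp(-k * i) * p))
        n_keep = int(np.clip(n_keep, 2, retained.size))
        # enforced selection: top-|coef| variables survive
        order = np.argsort(-w, kind="stable")
        retained = retained[order[:n_keep]]
        w = w[order[:n_keep]]
        # adaptive reweighted sampling: weighted draw with replacement
        if w.sum() <= 0:
            raise EmptySelectionError("CARS: all PLS weights vanished")
        draw = rng.choice(retained.size, size=n_keep, replace=True, p=w / w.sum())
        sampled = np.unique(retained[draw])
        # degenerate ARS draw (< 2 distinct) falls back to the enforced set
        retained = sampled if sampled.size >= 2 else retained
        cv_seed = int(rng.integers(2**31 - 1))
        rmsecv, ncomp_cv = _pls_cv_rmse(
            X[:, retained], y, max_pls_components, cv_folds, cv_seed
        )
        trace.append(
            {"run": i, "n_retained": int(retained.size), "rmsecv": rmsecv,
             "n_components": ncomp_cv}
        )
        if rmsecv < best["rmsecv"]:
            best = {"rmsecv": rmsecv, "subset": retained.copy()}

    if best["subset"] is None or best["subset"].size < 2:
        raise EmptySelectionError("CARS: fewer than 2 variables survived")
    return SelectionResult(method="cars", selected=np.sort(best["subset"]), trace=trace)
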