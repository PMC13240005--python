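"""Redundancy analysis (RDA) with permutation inference, from first principles.

RDA is the constrained form of principal component analysis: the response
matrix Y (here, the demographic matrix — N0, z, N2..N10 per generation) is
regressed on the constraint matrix X (selected environmental parameters), and
the fitted values are decomposed by SVD.  The canonical eigenvalues partition
the part of Y's total variance (inertia) that X explains; the residual matrix
supplies the unconstrained axes.

Significance is assessed by permutation:

* whole model — pseudo-F with rows of Y permuted uniformly;
* individual canonical axes — forward (sequential) tests, axis k assessed
  with the preceding axes as conditioning covariates, permuting residuals;
* individual constraints — marginal tests, each column against the model
  containing all the others, permuting residuals of the reduced model.

All permutation p-values use the add-one rule p = (1 + #{F* >= F}) / (1 + n)
so that a permutation test can never report exactly zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

__all__ = [
    "RDAResult",
    "fit_rda",
    "permutation_test_model",
    "permutation_test_axes",
    "permutation_test_terms",
]

_EIG_TOL = 1e-10


def _center_scale(A: np.ndarray, scale: bool) -> np.ndarray:
    out = A - A.mean(axis=0)
    if scale:
        sd = out.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        out = out / sd
    return out


def _independent_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedy drop of linearly dependent columns (left-to-right)."""
    kept_idx: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        cols = kept_idx + [j]
        rank = np.linalg.matrix_rank(X[:, cols], tol=1e-9)
        if rank == len(cols):
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropping linearly dependent constraint(s): {dropped}", stacklevel=3)
    return X[:, kept_idx], [names[j] for j in kept_idx], dropped


@dataclass
class RDAResult:
    """Canonical decomposition of Y constrained by X."""

    eigenvalues: np.ndarray  #: constrained, variance scale (s^2 / (n - 1))
    residual_eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    proportion_total: np.ndarray  #: % of total inertia per canonical axis
    proportion_constrained: np.ndarray  #: % of constrained inertia per axis
    site_scores: pd.DataFrame  #: linear-combination (fitted) site scores
    response_loadings: pd.DataFrame  #: response-variable loadings (V)
    biplot_scores: pd.DataFrame  #: correlations of constraints with axes
    scale_response: bool
    dropped_constraints: tuple[str, ...]
    rank: int
    p_model: float | None = None
    p_axes: np.ndarray | None = None
    p_terms: pd.Series | None = None
    n_perm: int | None = None
    seed: int | None = None
    pseudo_f: float | None = None
    axis_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.axis_names = tuple(self.site_scores.columns)

    def to_dict(self) -> dict:
        d = {
            "eigenvalues": self.eigenvalues.tolist(),
            "residual_eigenvalues": self.residual_eigenvalues.tolist(),
            "total_inertia": self.total_inertia,
            "constrained_inertia": self.constrained_inertia,
            "proportion_total_pct": self.proportion_total.tolist(),
            "proportion_constrained_pct": self.proportion_constrained.tolist(),
            "scale_response": self.scale_response,
            "dropped_constraints": list(self.dropped_constraints),
            "rank": self.rank,
            "pseudo_f": self.pseudo_f,
            "p_model": self.p_model,
            "p_axes": None if self.p_axes is None else list(self.p_axes),
            "p_terms": None if self.p_terms is None else self.p_terms.to_dict(),
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        return d


def _sorted_by_label(Y: pd.DataFrame, X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    # permutation tests canonicalize row order so p-values depend on labels,
    # not on the order rows arrived in
    order = np.argsort([str(i) for i in Y.index])
    return Y.iloc[order], X.iloc[order]


def _prepare(
    Y: pd.DataFrame, X: pd.DataFrame, scale_response: bool
) -> tuple[np.ndarray, np.ndarray, list[str], list[str], list[str]]:
    if list(Y.index) != list(X.index):
        raise ValueError("Y and X must share the same row labels in the same order")
    Yc = _center_scale(Y.to_numpy(dtype=float), scale_response)
    Xs = _center_scale(X.to_numpy(dtype=float), True)
    Xk, kept, dropped = _independent_columns(Xs, [str(c) for c in X.columns])
    n, q = Xk.shape
    if n <= q:
        raise ValueError(f"n = {n} rows cannot support {q} constraints")
    return Yc, Xk, kept, dropped, [str(c) for c in Y.columns]


def _require_residual_df(n: int, q: int) -> None:
    if n <= q + 1:
        raise ValueError(
            f"permutation pseudo-F needs residual degrees of freedom: "
            f"n = {n} rows, {q} constraints"
        )


def fit_rda(
    Y: pd.DataFrame, X: pd.DataFrame, scale_response: bool = False
) -> RDAResult:
    """Fit the redundancy analysis of ``Y`` constrained by ``X``.

    Y columns are centered (and scaled to unit variance if
    ``scale_response``); X columns are centered and standardized, with
    linearly dependent columns dropped.  Eigenvalues are on the variance scale
    (squared singular values of the fitted matrix divided by n - 1), so the
    constrained plus residual eigenvalues add up to the total inertia — the
    sum of Y's column variances.
    """
    Yc, Xk, kept, dropped, ycols = _prepare(Y, X, scale_response)
    n, q = Xk.shape
    labels = [str(i) for i in Y.index]

    B, *_ = np.linalg.lstsq(Xk, Yc, rcond=None)
    Yhat = Xk @ B
    resid = Yc - Yhat

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    k = min(q, Yc.shape[1])
    eig = (s**2) / (n - 1)
    keep = eig > _EIG_TOL * max(eig[0], 1.0) if len(eig) else np.array([], bool)
    k = min(k, int(keep.sum()))
    eig = eig[:k]
    U, s, Vt = U[:, :k], s[:k], Vt[:k]

    Ur, sr, Vtr = np.linalg.svd(resid, full_matrices=False)
    eig_r = (sr**2) / (n - 1)
    eig_r = eig_r[eig_r > _EIG_TOL * max(eig_r[0] if len(eig_r) else 1.0, 1.0)]

    total = float(np.sum(Yc**2) / (n - 1))
    constrained = float(eig.sum())
    axes = [f"RDA{i + 1}" for i in range(k)]

    site = pd.DataFrame(U * s, index=labels, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=ycols, columns=axes)
    # biplot scores: correlation of each standardized constraint with each axis
    bip = np.zeros((q, k))
    site_v = site.to_numpy()
    for j in range(q):
        for a in range(k):
            sv = site_v[:, a]
            denom = np.std(Xk[:, j]) * np.std(sv)
            bip[j, a] = 0.0 if denom == 0 else float(
                np.mean((Xk[:, j] - Xk[:, j].mean()) * (sv - sv.mean())) / denom
            )
    biplot = pd.DataFrame(bip, index=kept, columns=axes)

    return RDAResult(
        eigenvalues=eig,
        residual_eigenvalues=eig_r,
        total_inertia=total,
        constrained_inertia=constrained,
        proportion_total=100.0 * eig / total,
        proportion_constrained=100.0 * eig / constrained if constrained > 0 else eig * 0.0,
        site_scores=site,
        response_loadings=loadings,
        biplot_scores=biplot,
        scale_response=scale_response,
        dropped_constraints=tuple(dropped),
        rank=q,
    )


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _pseudo_f(ssc: float, ssr: float, q: int, n: int) -> float:
    return (ssc / q) / (ssr / (n - q - 1))


def permutation_test_model(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    scale_response: bool = False,
) -> tuple[float, float, int, bool]:
    """Whole-model permutation test.

    Pseudo-F = (constrained inertia / q) / (residual inertia / (n - q - 1));
    the null distribution permutes the rows of Y.  When n! does not exceed
    the requested number of permutations the test switches to exact
    enumeration over all n! row orders (the p-value is then the exact
    proportion of orders with F* >= F, identity included).

    Returns ``(p_value, F_observed, permutations_used, exact)``.
    """
    Y, X = _sorted_by_label(Y, X)
    Yc, Xk, *_ = _prepare(Y, X, scale_response)
    n, q = Xk.shape
    _require_residual_df(n, q)
    H = _hat(Xk)
    sst = float(np.sum(Yc**2))
    ssc = float(np.sum((H @ Yc) ** 2))
    f_obs = _pseudo_f(ssc, sst - ssc, q, n)

    exact = math.factorial(n) <= n_perm
    if exact:
        count = 0
        total = 0
        for perm in iter_permutations(range(n)):
            Yp = Yc[list(perm)]
            ssc_p = float(np.sum((H @ Yp) ** 2))
            if _pseudo_f(ssc_p, sst - ssc_p, q, n) >= f_obs - 1e-12:
                count += 1
            total += 1
        return count / total, f_obs, total, True

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Yp = Yc[rng.permutation(n)]
        ssc_p = float(np.sum((H @ Yp) ** 2))
        if _pseudo_f(ssc_p, sst - ssc_p, q, n) >= f_obs:
            count += 1
    return (1 + count) / (1 + n_perm), f_obs, n_perm, False


def _residualize(A: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    if Z is None or Z.shape[1] == 0:
        return A - A.mean(axis=0)
    HZ = _hat(Z)
    return A - HZ @ A


def permutation_test_axes(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    scale_response: bool = False,
) -> np.ndarray:
    """Forward (sequential) permutation tests of the canonical axes.

    Axis k is tested conditioned on axes 1..k-1: Y and X are residualized on
    the preceding axes' site scores, the partial RDA's first eigenvalue gives
    the numerator, the full model's residual mean square the denominator, and
    rows of the residualized Y are permuted.  Raw (non-monotonized) p-values
    are returned in axis order.
    """
    Y, X = _sorted_by_label(Y, X)
    result = fit_rda(Y, X, scale_response=scale_response)
    Yc, Xk, *_ = _prepare(Y, X, scale_response)
    n, q = Xk.shape
    _require_residual_df(n, q)
    scores = result.site_scores.to_numpy()
    k_axes = scores.shape[1]
    ms_resid = (result.total_inertia - result.constrained_inertia) * (n - 1) / (n - q - 1)
    rng = np.random.default_rng(seed)

    def first_eig(Ym: np.ndarray, Xm: np.ndarray) -> float:
        H = _hat(Xm)
        s = np.linalg.svd(H @ Ym, compute_uv=False)
        return float(s[0] ** 2 / (n - 1)) if len(s) else 0.0

    pvals = np.empty(k_axes)
    for k in range(k_axes):
        Z = scores[:, :k] if k else None
        Yr = _residualize(Yc, Z)
        Xr = _residualize(Xk, Z)
        lam_obs = first_eig(Yr, Xr)
        f_obs = lam_obs / ms_resid * (n - 1)
        count = 0
        for _ in range(n_perm):
            Yp = Yr[rng.permutation(n)]
            lam_p = first_eig(Yp, Xr)
            if lam_p / ms_resid * (n - 1) >= f_obs:
                count += 1
        pvals[k] = (1 + count) / (1 + n_perm)
    return pvals


def permutation_test_terms(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    scale_response: bool = False,
) -> pd.Series:
    """Marginal permutation tests of individual constraints.

    Each column is tested against the model containing all the other columns:
    F_j = (SS_full - SS_reduced) / (SS_resid_full / (n - q - 1)), with the
    null built by permuting the residuals of the reduced model (fitted values
    kept fixed).  A constraint collinear with the others contributes nothing
    uniquely and its p approaches 1.
    """
    Y, X = _sorted_by_label(Y, X)
    Yc, Xk, kept, *_ = _prepare(Y, X, scale_response)
    n, q = Xk.shape
    _require_residual_df(n, q)
    H_full = _hat(Xk)
    ss_full = float(np.sum((H_full @ Yc) ** 2))
    sst = float(np.sum(Yc**2))
    ms_resid = (sst - ss_full) / (n - q - 1)
    rng = np.random.default_rng(seed)

    pvals = {}
    for j, name in enumerate(kept):
        others = [i for i in range(q) if i != j]
        X_red = Xk[:, others]
        H_red = _hat(X_red) if others else np.zeros((n, n))
        fitted_red = H_red @ Yc
        resid_red = Yc - fitted_red
        ss_red = float(np.sum(fitted_red**2))
        f_obs = (ss_full - ss_red) / ms_resid

        count = 0
        for _ in range(n_perm):
            Ystar = fitted_red + resid_red[rng.permutation(n)]
            ss_full_p = float(np.sum((H_full @ Ystar) ** 2))
            ss_red_p = float(np.sum((H_red @ Ystar) ** 2))
            sst_p = float(np.sum((Ystar - Ystar.mean(axis=0)) ** 2))
            ms_p = (sst_p - ss_full_p) / (n - q - 1)
            if (ss_full_p - ss_red_p) / ms_p >= f_obs:
                count += 1
        pvals[name] = (1 + count) / (1 + n_perm)
    return pd.Series(pvals, name="p_marginal")
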