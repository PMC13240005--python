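"""Exhaustive BIO-ENV subset selection.

The BIO-ENV procedure searches for the subset of environmental variables whose
between-sample (here, between-generation) Euclidean distance matrix best
matches a fixed biotic distance matrix, match quality being the Mantel
correlation — the correlation of the two matrices' vectorized strict lower
triangles.  With p variables the search is exhaustive over all 2^p - 1
non-empty subsets (16,777,215 at p = 24).

The engine exploits the additivity of squared Euclidean distances,

    d_S^2 = sum_{j in S} d_j^2,

over per-column squared-difference pair vectors: subsets are partitioned into
a low and a high half of the column index range, partial sums over each half
are tabulated once by dynamic programming, and every subset's distance vector
is then a single vectorized addition of a low row and a high row.  The full
p = 24 enumeration runs in minutes on one CPU.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "BioEnvResult",
    "euclidean_distances",
    "mantel_r",
    "exhaustive_bioenv",
]


def euclidean_distances(
    table: pd.DataFrame, standardize: bool = True
) -> DistanceMatrix:
    """Pairwise Euclidean distances between the rows of ``table``.

    With ``standardize`` (the convention for environmental variables, whose
    units are incommensurable) each column is centered and scaled to unit
    standard deviation first; zero-variance columns are dropped with a warning
    since they carry no distance information and cannot be scaled.
    """
    if table.isna().any().any():
        raise ValueError("table contains missing cells")
    values = table.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = list(table.columns[~keep])
            warnings.warn(f"dropping zero-variance column(s): {dropped}", stacklevel=2)
            values = values[:, keep]
        values = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    condensed = pdist(values, metric="euclidean")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


def mantel_r(
    d1: DistanceMatrix, d2: DistanceMatrix, method: str = "pearson"
) -> float:
    """Mantel correlation: Pearson or Spearman correlation of the two
    matrices' strict lower triangles.

    Returns NaN (with a warning) if either triangle has zero variance, e.g.
    against a constant matrix.  No permutation test is attached — within
    BIO-ENV the statistic is a match criterion, not a hypothesis test.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices have different ids or orderings")
    if d1.shape[0] < 4:
        raise ValueError("need at least 4 objects for a meaningful Mantel correlation")
    v1 = d1.condensed_form()
    v2 = d2.condensed_form()
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        warnings.warn("zero variance in a distance triangle; Mantel r undefined", stacklevel=2)
        return float("nan")
    if method == "pearson":
        r = stats.pearsonr(v1, v2).statistic
    elif method == "spearman":
        r = stats.spearmanr(v1, v2).statistic
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r)


@dataclass
class BioEnvResult:
    """Outcome of an exhaustive BIO-ENV search."""

    best_subset: tuple[str, ...]
    best_r: float
    per_size: pd.DataFrame  #: columns size, subset (comma-joined), r
    total_subsets: int
    method: str
    standardize_env: bool
    standardize_biotic: bool
    dropped_columns: tuple[str, ...]
    tie_break: str = "smaller subset, then lexicographic column order"

    def to_dict(self) -> dict:
        return {
            "best_subset": list(self.best_subset),
            "best_r": self.best_r,
            "per_size": self.per_size.to_dict(orient="records"),
            "total_subsets": self.total_subsets,
            "method": self.method,
            "standardize_env": self.standardize_env,
            "standardize_biotic": self.standardize_biotic,
            "dropped_columns": list(self.dropped_columns),
            "tie_break": self.tie_break,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _mask_columns(mask: int, names: list[str]) -> tuple[str, ...]:
    return tuple(names[j] for j in range(len(names)) if mask >> j & 1)


def _lex_less(mask_a: int, mask_b: int) -> bool:
    """True if mask_a's sorted column-index tuple precedes mask_b's."""
    a = tuple(j for j in range(mask_a.bit_length()) if mask_a >> j & 1)
    b = tuple(j for j in range(mask_b.bit_length()) if mask_b >> j & 1)
    return a < b


def _partial_sums(M: np.ndarray) -> np.ndarray:
    """Table of condensed squared-distance sums for every subset mask of the
    rows of ``M`` (p x m): entry [mask] = sum of M[j] over set bits j."""
    p, m = M.shape
    table = np.zeros((1 << p, m))
    for mask in range(1, 1 << p):
        lsb = (mask & -mask).bit_length() - 1
        table[mask] = table[mask & (mask - 1)] + M[lsb]
    return table


def exhaustive_bioenv(
    biotic: DistanceMatrix,
    env: pd.DataFrame,
    method: str = "pearson",
    standardize_env: bool = True,
    max_p_guard: int = 24,
    allow_large: bool = False,
    standardize_biotic: bool = False,
) -> BioEnvResult:
    """Evaluate every non-empty column subset of ``env`` against ``biotic``.

    Parameters
    ----------
    biotic
        Fixed biotic (demographic) distance matrix; its ids must match
        ``env.index`` as strings, in order.  ``standardize_biotic`` is recorded
        for provenance only — the caller builds ``biotic`` and chooses there.
    env
        Environmental feature matrix, one row per object.
    method
        "pearson" (default) or "spearman" Mantel correlation.
    max_p_guard, allow_large
        Runtime guard: more than ``max_p_guard`` columns is refused unless
        ``allow_large`` is set (2^p subsets grow quickly).

    Ties on the correlation are broken toward the smaller subset, then toward
    the lexicographically earlier column combination.
    """
    ids = [str(i) for i in env.index]
    if list(biotic.ids) != ids:
        raise ValueError(
            f"env rows do not match biotic labels: {list(biotic.ids)[:4]}... vs {ids[:4]}..."
        )
    if env.isna().any().any():
        raise ValueError("env matrix contains missing cells")

    values = env.to_numpy(dtype=float)
    names = [str(c) for c in env.columns]
    dropped: tuple[str, ...] = ()
    if standardize_env:
        sd = values.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = tuple(n for n, k in zip(names, keep) if not k)
            warnings.warn(f"dropping zero-variance column(s): {list(dropped)}", stacklevel=2)
            values = values[:, keep]
            names = [n for n, k in zip(names, keep) if k]
        values = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    p = values.shape[1]
    if p == 0:
        raise ValueError("no usable environmental columns")
    if p > max_p_guard and not allow_large:
        raise ValueError(
            f"{p} columns exceed the guard ({max_p_guard}): 2^{p} subsets; "
            "pass allow_large=True to proceed"
        )

    n = values.shape[0]
    m = n * (n - 1) // 2
    # per-column condensed squared-difference pair vectors
    M = np.stack([pdist(values[:, [j]], metric="sqeuclidean") for j in range(p)])

    y = biotic.condensed_form().astype(float)
    if method == "spearman":
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    yc = y - y.mean()
    yss = float(yc @ yc)
    if yss == 0:
        raise ValueError("biotic distance triangle has zero variance")

    p_low = (p + 1) // 2
    p_high = p - p_low
    S_low = _partial_sums(M[:p_low])
    S_high = _partial_sums(M[p_low:]) if p_high else np.zeros((1, m))
    rowsum_low = S_low.sum(axis=1)
    rowsum_high = S_high.sum(axis=1)
    pc_low = np.array([bin(mask).count("1") for mask in range(S_low.shape[0])])
    # static row-index groups of the low table by popcount
    groups = [np.nonzero(pc_low == c)[0] for c in range(p_low + 1)]

    best_r = np.full(p + 1, -np.inf)
    best_mask = np.zeros(p + 1, dtype=np.int64)

    spearman = method == "spearman"
    for h in range(S_high.shape[0]):
        ph = bin(h).count("1")
        d2 = S_low + S_high[h]
        d = np.sqrt(d2)
        if spearman:
            d = stats.rankdata(d, axis=1)
            sumd2 = (d * d).sum(axis=1)
        else:
            sumd2 = rowsum_low + rowsum_high[h]
        sd = d.sum(axis=1)
        var_term = sumd2 - sd * sd / m
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (d @ yc) / np.sqrt(var_term * yss)
        r[var_term <= 1e-12] = np.nan

        for c, rows in enumerate(groups):
            s = c + ph
            if s == 0:
                continue
            r_sub = r[rows]
            finite = np.isfinite(r_sub)
            if not finite.any():
                continue
            rmax = np.nanmax(r_sub)
            if rmax < best_r[s]:
                continue
            tied_rows = rows[np.nonzero(r_sub == rmax)[0]]
            cand = min(
                (int(low) | (h << p_low) for low in tied_rows),
                key=lambda mk: tuple(j for j in range(p) if mk >> j & 1),
            )
            if rmax > best_r[s] or (
                rmax == best_r[s] and _lex_less(cand, int(best_mask[s]))
            ):
                best_r[s] = rmax
                best_mask[s] = cand

    per_size_rows = []
    for s in range(1, p + 1):
        if not np.isfinite(best_r[s]):
            continue
        per_size_rows.append(
            {
                "size": s,
                "subset": ", ".join(_mask_columns(int(best_mask[s]), names)),
                "r": float(best_r[s]),
            }
        )
    per_size = pd.DataFrame(per_size_rows, columns=["size", "subset", "r"])

    # overall winner: scan sizes ascending so that near-exact correlation ties
    # (within 1e-12, e.g. proportional columns) resolve to the smaller subset
    overall, overall_r = 0, -np.inf
    for s in range(1, p + 1):
        if np.isfinite(best_r[s]) and best_r[s] > overall_r + 1e-12:
            overall, overall_r = s, best_r[s]
    if overall == 0:
        raise ValueError("Mantel correlation undefined for every subset")
    result = BioEnvResult(
        best_subset=_mask_columns(int(best_mask[overall]), names),
        best_r=float(best_r[overall]),
        per_size=per_size,
        total_subsets=(1 << p) - 1,
        method=method,
        standardize_env=standardize_env,
        standardize_biotic=standardize_biotic,
        dropped_columns=dropped,
    )
    return result


def naive_bioenv(
    biotic: DistanceMatrix,
    env: pd.DataFrame,
    method: str = "pearson",
    standardize_env: bool = True,
) -> tuple[tuple[str, ...], float]:
    """Reference implementation: rebuild each subset's distance matrix from
    scratch.  Exponential in the column count — use only for small p."""
    names = [str(c) for c in env.columns]
    best = (-np.inf, ())
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            d = euclidean_distances(env[list(subset)], standardize=standardize_env)
            r = mantel_r(biotic, d, method=method)
            if np.isfinite(r) and r > best[0]:
                best = (r, subset)
    return best[1], best[0]
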