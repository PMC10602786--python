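"""The five pairwise association measures behind the ensemble network.

Four similarity measures — Bray–Curtis dissimilarity, Pearson and Spearman
correlation, mutual information on equal-frequency bins — plus a
regression score from a generalized boosted linear model (GBLM,
componentwise L2-boosting).  All five accept relative-abundance vectors;
undefined cases (zero variance, both-zero vectors) are signalled with
``nan`` so the ensemble can drop a pair from one measure's evidence
without losing the pair altogether.

The private ``_boost_path`` routine is vectorised over arbitrary leading
batch dimensions; the permutation-null machinery relies on this to refit
boosting under hundreds of renormalised permutations at once.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .core_io import AbundanceTable

__all__ = [
    "MEASURES",
    "bray_curtis",
    "pearson",
    "spearman",
    "mutual_information",
    "default_mi_bins",
    "gblm_scores",
    "score_matrix",
]

MEASURES = ("bray_curtis", "pearson", "spearman", "mi", "gblm")


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity, ``1 - 2 sum(min) / (sum x + sum y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 2")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires non-negative vectors")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; ``nan`` when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(np.clip(stats.pearsonr(x, y).statistic, -1.0, 1.0))


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Rank correlation: Pearson on mid-ranks (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan
    return float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))


def default_mi_bins(n: int) -> int:
    """Default bin count: floor(sqrt(n)), capped at 8, floor 2."""
    return max(2, min(8, int(math.isqrt(n))))


def _mi_bin_labels(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin labels via mid-ranks.

    Tied values share an average rank and therefore a bin, so a constant
    vector occupies a single bin and MI against it is exactly zero.
    """
    r = stats.rankdata(x, axis=-1)
    n = x.shape[-1]
    return np.clip(((r - 0.5) * bins / n).astype(np.int64), 0, bins - 1)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """MI in nats between equal-frequency discretisations of x and y.

    ``MI = sum p(a,b) log[p(a,b) / (p(a) p(b))]`` over the bins x bins
    contingency table.  Non-negative; 0 when the table factorises (in
    particular for any constant vector).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if bins is None:
        bins = default_mi_bins(n)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if n < bins:
        raise ValueError("need at least `bins` observations")
    la = _mi_bin_labels(x, bins)
    lb = _mi_bin_labels(y, bins)
    joint = np.bincount(la * bins + lb, minlength=bins * bins).reshape(bins, bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log(joint[mask] / np.outer(px, py)[mask])))
    return max(mi, 0.0)


def mi_matrix(V: np.ndarray, bins: int) -> np.ndarray:
    """All-pairs MI matrix (nats) for a samples x taxa matrix."""
    n, p = V.shape
    labels = _mi_bin_labels(V.T, bins)  # (p, n)
    M = np.empty((p, p))
    for i in range(p):
        joint = np.zeros((p, bins * bins), dtype=np.int64)
        flat = labels[i][None, :] * bins + labels  # (p, n)
        np.add.at(joint, (np.repeat(np.arange(p), n), flat.ravel()), 1)
        J = joint.reshape(p, bins, bins) / n
        px = J.sum(axis=2)
        py = J.sum(axis=1)
        outer = px[:, :, None] * py[:, None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(J > 0, J * np.log(J / outer), 0.0)
        M[i] = np.maximum(terms.sum(axis=(1, 2)), 0.0)
    return (M + M.T) / 2.0


# ---------------------------------------------------------------------------
# GBLM: componentwise L2-boosted linear regression
# ---------------------------------------------------------------------------

def _standardize(a: np.ndarray, axis: int = -2) -> np.ndarray:
    """Z-score along ``axis``; constant slices become all-zero columns."""
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a - mu) / sd
    return np.where(sd > 0, z, 0.0)


def _boost_path(
    X: np.ndarray,
    y: np.ndarray,
    shrinkage: float,
    iterations: int,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Componentwise L2 boosting of standardized y on standardized X.

    Shapes: ``X`` is ``(..., n, p)``, ``y`` is ``(..., n)``; the result is
    ``(..., p)`` coefficients on the standardized scale, vectorised over
    any leading batch dimensions.  Each iteration picks, per batch
    element, the predictor most correlated with the current residual and
    moves its coefficient by ``shrinkage`` times the univariate
    least-squares fit.  ``exclude`` is a boolean ``(..., p)`` mask of
    predictors barred from selection (used to drop the target itself when
    all taxa are fit jointly).
    """
    Xs = _standardize(np.asarray(X, dtype=float))
    ys = _standardize(np.asarray(y, dtype=float), axis=-1)
    n = Xs.shape[-2]
    batch = np.broadcast_shapes(Xs.shape[:-2], ys.shape[:-1])
    Xs = np.broadcast_to(Xs, batch + Xs.shape[-2:]).copy()
    ys = np.broadcast_to(ys, batch + (n,)).copy()
    p = Xs.shape[-1]
    coef = np.zeros(batch + (p,))
    resid = ys.copy()
    flatX = Xs.reshape(-1, n, p)
    flatR = resid.reshape(-1, n)
    flatC = coef.reshape(-1, p)
    if exclude is not None:
        excl = np.broadcast_to(exclude, batch + (p,)).reshape(-1, p)
    else:
        excl = None
    b = flatX.shape[0]
    rows = np.arange(b)
    for _ in range(iterations):
        # univariate LS slope of residual on each standardized predictor
        corr = np.einsum("bnp,bn->bp", flatX, flatR) / n
        if excl is not None:
            corr = np.where(excl, 0.0, corr)
        j = np.argmax(np.abs(corr), axis=1)
        step = shrinkage * corr[rows, j]
        flatC[rows, j] += step
        flatR -= step[:, None] * flatX[rows, :, j]
    return coef


def gblm_scores(
    table: AbundanceTable,
    target: str,
    shrinkage: float = 0.1,
    iterations: int = 500,
) -> dict[str, float]:
    """Boosted-linear-model coefficients of every other taxon on ``target``.

    Returns sparse signed coefficients (many exactly 0) on the
    standardized scale.  The symmetric pairwise GBLM score used by the
    ensemble is the mean of ``coef(j -> i)`` and ``coef(i -> j)``.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if target not in table.taxon_ids:
        raise ValueError(f"unknown target taxon {target!r}")
    others = [t for t in table.taxon_ids if t != target]
    if len(others) < 2:
        raise ValueError("need at least 2 predictor taxa")
    X = table.values[:, [table.taxon_ids.index(t) for t in others]]
    y = table.taxon_vector(target)
    coefs = _boost_path(X, y, shrinkage=shrinkage, iterations=iterations)
    return dict(zip(others, map(float, coefs)))


def gblm_coefficient_matrix(
    values: np.ndarray,
    shrinkage: float = 0.1,
    iterations: int = 100,
) -> np.ndarray:
    """Directed coefficient matrix C with ``C[t, j] = coef(j -> target t)``.

    ``values`` is ``(..., n, p)``; the result is ``(..., p, p)`` with a
    zero diagonal.  Batched over leading dimensions: one call refits all
    targets under every permutation simultaneously.
    """
    values = np.asarray(values, dtype=float)
    p = values.shape[-1]
    Y = np.swapaxes(values, -1, -2)  # (..., p targets, n)
    X = values[..., None, :, :]      # broadcast targets
    exclude = np.eye(p, dtype=bool)
    C = _boost_path(X, Y, shrinkage=shrinkage, iterations=iterations, exclude=exclude)
    return C


def score_matrix(
    table: AbundanceTable,
    measure: str,
    mi_bins: int | None = None,
    gblm_shrinkage: float = 0.1,
    gblm_iterations: int = 100,
) -> np.ndarray:
    """Symmetric taxa x taxa score matrix for one measure.

    The diagonal holds each measure's self-value (0 for Bray–Curtis,
    1 for Pearson/Spearman/GBLM, ``MI(x, x)`` for MI).  Pairs undefined
    under the measure are ``nan``.
    """
    if table.mode != "relative":
        raise ValueError("score_matrix requires a relative-mode table")
    V = table.values
    n, p = V.shape
    if measure == "bray_curtis":
        mins = np.minimum(V.T[:, None, :], V.T[None, :, :]).sum(axis=2)
        sums = V.sum(axis=0)
        denom = sums[:, None] + sums[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            M = 1.0 - 2.0 * mins / denom
        M[denom == 0] = np.nan
        np.fill_diagonal(M, np.where(sums > 0, 0.0, np.nan))
        return M
    if measure in ("pearson", "spearman"):
        Z = stats.rankdata(V, axis=0) if measure == "spearman" else V
        sd = np.where(np.ptp(Z, axis=0) == 0, 0.0, Z.std(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.clip(np.corrcoef(Z, rowvar=False), -1.0, 1.0)
        M[sd == 0, :] = np.nan
        M[:, sd == 0] = np.nan
        np.fill_diagonal(M, np.where(sd > 0, 1.0, np.nan))
        return M
    if measure == "mi":
        bins = mi_bins if mi_bins is not None else default_mi_bins(n)
        return mi_matrix(V, bins)
    if measure == "gblm":
        C = gblm_coefficient_matrix(V, shrinkage=gblm_shrinkage, iterations=gblm_iterations)
        M = (C + C.T) / 2.0
        np.fill_diagonal(M, 1.0)
        return M
    raise ValueError(f"unknown measure {measure!r}")
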