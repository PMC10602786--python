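"""Significance, merging and signed-network construction for the ensemble.

Relative abundances are compositional: closing each sample to sum one
induces spurious negative correlation between otherwise independent taxa.
The null model here preserves that constraint (a ReBoot-style scheme):
one taxon's values are permuted across samples, every sample is re-closed
to sum one, and the measure is recomputed — so the null distribution
carries the same compositional bias as the observed score.  A bootstrap
over samples stabilises the observed statistic, and the empirical
two-sided p-value compares the bootstrap mean against the permutation
null with an add-one correction:

    p = (1 + #{ |null_k - null_mean| >= |boot_mean - null_mean| }) / (P + 1)

Per-measure p-values are merged with Brown's method, whose scale and
degrees of freedom are estimated from the empirical covariance of
``-2 log p`` across the shared permutation draws, then BH-corrected
within one generation's family of pairs.  Edge signs come from a
majority vote of the directional measures; MI abstains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceTable, ConsortiumNetwork, PipelineConfig
from .measures import (
    _mi_bin_labels,
    default_mi_bins,
    gblm_coefficient_matrix,
    mi_matrix,
    score_matrix,
)

__all__ = [
    "AssociationResult",
    "association_scan",
    "reboot_pvalue",
    "merge_pvalues",
    "assign_sign",
    "build_network",
    "infer_network",
]

SIGNED_MEASURES = ("pearson", "spearman", "gblm")


@dataclass
class AssociationResult:
    """Evidence for one unordered taxon pair."""

    taxon_a: str
    taxon_b: str
    scores: dict[str, float] = field(default_factory=dict)
    null_mean: dict[str, float] = field(default_factory=dict)
    null_sd: dict[str, float] = field(default_factory=dict)
    boot_mean: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    merged_p: float = math.nan
    qvalue: float = math.nan
    sign: str = "conflict"
    weight: float = math.nan


# ---------------------------------------------------------------------------
# batched measure kernels: A is (P, n), B is (P, n, p) of re-closed columns
# ---------------------------------------------------------------------------

def _batched_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A0 = A - A.mean(axis=1, keepdims=True)
    B0 = B - B.mean(axis=1, keepdims=True)
    num = np.einsum("pn,pnj->pj", A0, B0)
    na = np.sqrt(np.einsum("pn,pn->p", A0, A0))
    nb = np.sqrt(np.einsum("pnj,pnj->pj", B0, B0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (na[:, None] * nb)
    r = np.clip(r, -1.0, 1.0)
    # exactly constant vectors leave O(eps) residue after centring; detect
    # them by range, not by the centred norm
    bad_a = (na == 0) | (np.ptp(A, axis=1) == 0)
    bad_b = (nb == 0) | (np.ptp(B, axis=1) == 0)
    r[np.broadcast_to(bad_a[:, None], r.shape)] = np.nan
    r[bad_b] = np.nan
    return r


def _batched_spearman(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    rA = stats.rankdata(A, axis=1)
    rB = stats.rankdata(B, axis=1)
    return _batched_pearson(rA, rB)


def _batched_bray_curtis(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    mins = np.minimum(A[:, :, None], B).sum(axis=1)
    denom = A.sum(axis=1)[:, None] + B.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - 2.0 * mins / denom
    d[denom == 0] = np.nan
    return d


def _batched_mi(A: np.ndarray, B: np.ndarray, bins: int) -> np.ndarray:
    P, n = A.shape
    p = B.shape[2]
    la = _mi_bin_labels(A, bins)                       # (P, n)
    lb = _mi_bin_labels(np.swapaxes(B, 1, 2), bins)    # (P, p, n)
    joint_idx = la[:, None, :] * bins + lb             # (P, p, n)
    base = (np.arange(P)[:, None] * p + np.arange(p)[None, :]) * bins * bins
    flat = (base[:, :, None] + joint_idx).ravel()
    counts = np.bincount(flat, minlength=P * p * bins * bins)
    J = counts.reshape(P, p, bins, bins) / n
    px = J.sum(axis=3)
    py = J.sum(axis=2)
    outer = px[..., :, None] * py[..., None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(J > 0, J * np.log(J / outer), 0.0)
    return np.maximum(terms.sum(axis=(2, 3)), 0.0)


def _quiet_nanmean(a: np.ndarray) -> np.ndarray:
    """nanmean over axis 0; all-nan slices yield nan without a warning."""
    valid = np.isfinite(a)
    count = valid.sum(axis=0)
    total = np.where(valid, a, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / count, np.nan)


# ---------------------------------------------------------------------------
# permutation null and bootstrap
# ---------------------------------------------------------------------------

def _null_scores_for_taxon(
    rel: np.ndarray,
    i: int,
    measures: tuple[str, ...],
    P: int,
    rng: np.random.Generator,
    bins: int,
    gblm_shrinkage: float,
    gblm_iterations: int,
) -> dict[str, np.ndarray]:
    """Null score draws for all pairs (i, j): permute taxon i, re-close.

    Returns, per measure, an array of shape (P, p) whose column j is the
    null distribution of the (i, j) score.
    """
    n, p = rel.shape
    perm = np.array([rng.permutation(n) for _ in range(P)])
    Pi = rel[perm, i]                                  # (P, n)
    D = 1.0 - rel[None, :, i] + Pi                     # re-closure denominator
    A = Pi / D                                         # re-closed permuted taxon i
    B = rel[None, :, :] / D[:, :, None]                # other columns, re-closed
    B[:, :, i] = A
    out: dict[str, np.ndarray] = {}
    for m in measures:
        if m == "pearson":
            out[m] = _batched_pearson(A, B)
        elif m == "spearman":
            out[m] = _batched_spearman(A, B)
        elif m == "bray_curtis":
            out[m] = _batched_bray_curtis(A, B)
        elif m == "mi":
            out[m] = _batched_mi(A, B, bins)
        elif m == "gblm":
            C = gblm_coefficient_matrix(B, shrinkage=gblm_shrinkage,
                                        iterations=gblm_iterations)
            out[m] = (C[:, i, :] + C[:, :, i]) / 2.0   # symmetrized, (P, p)
        else:
            raise ValueError(f"unknown measure {m!r}")
    return out


def _bootstrap_matrices(
    rel: np.ndarray,
    measures: tuple[str, ...],
    Bn: int,
    rng: np.random.Generator,
    bins: int,
    gblm_shrinkage: float,
    gblm_iterations: int,
) -> dict[str, np.ndarray]:
    """Mean score matrix over ``Bn`` bootstrap resamples of samples."""
    n, p = rel.shape
    idx = rng.integers(0, n, size=(Bn, n))
    V = rel[idx]                                       # (Bn, n, p)
    out: dict[str, np.ndarray] = {}
    for m in measures:
        if m in ("pearson", "spearman"):
            Z = stats.rankdata(V, axis=1) if m == "spearman" else V
            Z0 = Z - Z.mean(axis=1, keepdims=True)
            cov = np.einsum("bnp,bnq->bpq", Z0, Z0)
            sd = np.sqrt(np.einsum("bnp,bnp->bp", Z0, Z0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = cov / (sd[:, :, None] * sd[:, None, :])
            r = np.clip(r, -1.0, 1.0)
            bad = (sd == 0) | (np.ptp(Z, axis=1) == 0)
            r[np.broadcast_to(bad[:, :, None], r.shape)] = np.nan
            r[np.broadcast_to(bad[:, None, :], r.shape)] = np.nan
            out[m] = _quiet_nanmean(r)
        elif m == "bray_curtis":
            mins = np.minimum(V[:, :, :, None], V[:, :, None, :]).sum(axis=1)
            sums = V.sum(axis=1)
            denom = sums[:, :, None] + sums[:, None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                d = 1.0 - 2.0 * mins / denom
            d[denom == 0] = np.nan
            out[m] = _quiet_nanmean(d)
        elif m == "mi":
            acc = np.zeros((p, p))
            for b in range(Bn):
                acc += mi_matrix(V[b], bins)
            out[m] = acc / Bn
        elif m == "gblm":
            C = gblm_coefficient_matrix(V, shrinkage=gblm_shrinkage,
                                        iterations=gblm_iterations)
            out[m] = (C + np.swapaxes(C, 1, 2)).mean(axis=0) / 2.0
        else:
            raise ValueError(f"unknown measure {m!r}")
    return out


def _empirical_p(null: np.ndarray, stat: float) -> float:
    """Two-sided add-one empirical p of ``stat`` against centred null draws."""
    finite = null[np.isfinite(null)]
    if finite.size == 0 or not np.isfinite(stat):
        return math.nan
    mean = finite.mean()
    dev = np.abs(finite - mean)
    return float((1 + np.sum(dev >= abs(stat - mean))) / (finite.size + 1))


def _pseudo_pvalues(null: np.ndarray) -> np.ndarray:
    """Empirical two-sided p of each null draw within the null (for Brown)."""
    mean = np.nanmean(null)
    dev = np.abs(null - mean)
    order = stats.rankdata(dev, method="min", nan_policy="omit")
    P = np.sum(np.isfinite(dev))
    with np.errstate(invalid="ignore"):
        p = (P - order + 1) / (P + 1)
    return p


def merge_pvalues(pvals: dict[str, float], null_scores: dict[str, np.ndarray]) -> float:
    """Brown's method on dependent per-measure p-values.

    The Fisher statistic ``-2 sum log p`` is referred to a scaled
    chi-square whose scale and df follow from the empirical covariance of
    ``-2 log p`` across the measures' shared permutation draws; falls
    back to plain Fisher (independence) when the covariance cannot be
    estimated.
    """
    valid = [m for m, pv in pvals.items() if np.isfinite(pv)]
    if not valid:
        return math.nan
    if len(valid) == 1:
        return float(pvals[valid[0]])
    T = -2.0 * sum(math.log(max(pvals[m], 1e-300)) for m in valid)
    k = len(valid)
    mean_T = 2.0 * k
    X = []
    for m in valid:
        draws = null_scores.get(m)
        if draws is None or np.sum(np.isfinite(draws)) < 10:
            X = []
            break
        X.append(-2.0 * np.log(np.clip(_pseudo_pvalues(draws), 1e-300, 1.0)))
    if X:
        lengths = {len(x) for x in X}
        if len(lengths) == 1:
            C = np.cov(np.vstack(X))
            var_T = 4.0 * k + 2.0 * np.sum(np.triu(C, 1))
        else:
            var_T = math.nan
    else:
        var_T = math.nan
    if not np.isfinite(var_T) or var_T <= 0:
        return float(stats.chi2.sf(T, 2 * k))  # Fisher fallback
    c = var_T / (2.0 * mean_T)
    df = 2.0 * mean_T**2 / var_T
    return float(stats.chi2.sf(T / c, df))


def assign_sign(scores: dict[str, float], null_means: dict[str, float]) -> str:
    """Majority vote over directional measures; MI abstains.

    Pearson, Spearman and GBLM vote their coefficient sign; Bray–Curtis
    votes positive when the observed dissimilarity is *below* its null
    mean (more shared abundance than closure alone explains).  An exact
    tie, or no vote at all, yields ``conflict``.
    """
    votes = 0.0
    n_votes = 0
    for m in SIGNED_MEASURES:
        v = scores.get(m)
        if v is not None and np.isfinite(v) and v != 0:
            votes += np.sign(v)
            n_votes += 1
    bc = scores.get("bray_curtis")
    bc_null = null_means.get("bray_curtis")
    if (
        bc is not None and bc_null is not None
        and np.isfinite(bc) and np.isfinite(bc_null) and bc != bc_null
    ):
        votes += np.sign(bc_null - bc)
        n_votes += 1
    if n_votes == 0 or votes == 0:
        return "conflict"
    return "+" if votes > 0 else "-"


def association_scan(
    table: AbundanceTable,
    config: PipelineConfig | None = None,
) -> list[AssociationResult]:
    """Score, test and sign every unordered taxon pair of one table.

    The table is closed to relative mode if needed.  The permutation null
    for pair (i, j) with i < j permutes taxon i's values and re-closes
    every sample.  BH correction is applied over all pairs of this table
    (one family); callers wanting per-generation families pass
    per-generation tables.
    """
    config = config or PipelineConfig()
    if table.mode != "relative":
        table = table.to_relative()
    rel = table.values
    n, p = rel.shape
    bins = config.mi_bins if config.mi_bins is not None else default_mi_bins(n)
    measures = tuple(config.measures)
    rng = np.random.default_rng(config.seed)

    observed = {
        m: score_matrix(table, m, mi_bins=bins,
                        gblm_shrinkage=config.gblm_shrinkage,
                        gblm_iterations=config.gblm_iterations)
        for m in measures
    }
    if config.use_bootstrap:
        boot = _bootstrap_matrices(rel, measures, config.bootstraps, rng, bins,
                                   config.gblm_shrinkage, config.gblm_iterations)
    else:
        boot = observed

    results: list[AssociationResult] = []
    for i in range(p - 1):
        nulls_i = _null_scores_for_taxon(
            rel, i, measures, config.permutations, rng, bins,
            config.gblm_shrinkage, config.gblm_iterations,
        )
        for j in range(i + 1, p):
            res = AssociationResult(taxon_a=table.taxon_ids[i], taxon_b=table.taxon_ids[j])
            pair_nulls: dict[str, np.ndarray] = {}
            for m in measures:
                draws = nulls_i[m][:, j]
                obs = float(observed[m][i, j])
                bm = float(boot[m][i, j])
                finite = draws[np.isfinite(draws)]
                res.scores[m] = obs
                res.boot_mean[m] = bm
                res.null_mean[m] = float(finite.mean()) if finite.size else math.nan
                res.null_sd[m] = float(finite.std()) if finite.size else math.nan
                res.pvalues[m] = _empirical_p(draws, bm)
                pair_nulls[m] = draws
            res.merged_p = merge_pvalues(res.pvalues, pair_nulls)
            res.sign = assign_sign(res.scores, res.null_mean)
            res.weight = _edge_weight(res)
            results.append(res)

    _apply_bh(results)
    return results


def _edge_weight(res: AssociationResult) -> float:
    """Mean standardized effect over measures supporting the final sign."""
    if res.sign == "conflict":
        return math.nan
    effects = []
    for m, obs in res.scores.items():
        mu, sd = res.null_mean.get(m, math.nan), res.null_sd.get(m, math.nan)
        if not (np.isfinite(obs) and np.isfinite(mu) and np.isfinite(sd)) or sd == 0:
            continue
        if m == "mi":
            continue  # unsigned, abstains from support
        if m == "bray_curtis":
            vote = np.sign(mu - obs)
        else:
            vote = np.sign(obs)
        if (vote > 0) == (res.sign == "+") and vote != 0:
            effects.append(abs(obs - mu) / sd)
    return float(np.mean(effects)) if effects else math.nan


def _apply_bh(results: list[AssociationResult]) -> None:
    tested = [r for r in results if np.isfinite(r.merged_p)]
    if not tested:
        return
    _, q, _, _ = multipletests([r.merged_p for r in tested], method="fdr_bh")
    for r, qv in zip(tested, q):
        r.qvalue = float(qv)


def reboot_pvalue(
    table: AbundanceTable,
    pair: tuple[str, str],
    measure: str,
    P: int = 200,
    B: int = 100,
    seed: int = 0,
) -> tuple[float, float, float, tuple[float, float]]:
    """Single-pair ReBoot test.

    Returns ``(p, null_mean, null_sd, bootstrap 95% CI)``.  The first
    taxon of ``pair`` is the permuted one.
    """
    if P < 100 or B < 100:
        raise ValueError("P and B must each be >= 100")
    if table.mode != "relative":
        table = table.to_relative()
    rel = table.values
    n = rel.shape[0]
    i = table.taxon_ids.index(pair[0])
    j = table.taxon_ids.index(pair[1])
    bins = default_mi_bins(n)
    rng = np.random.default_rng(seed)
    nulls = _null_scores_for_taxon(rel, i, (measure,), P, rng, bins, 0.1, 100)[measure][:, j]
    obs_mat = score_matrix(table, measure, mi_bins=bins)
    boot = _bootstrap_matrices(rel, (measure,), B, rng, bins, 0.1, 100)[measure]
    boot_mean = float(boot[i, j])
    finite = nulls[np.isfinite(nulls)]
    if finite.size == 0 or not np.isfinite(obs_mat[i, j]):
        return math.nan, math.nan, math.nan, (math.nan, math.nan)
    idx = rng.integers(0, n, size=(B, n))
    # per-resample scores for the CI (pairwise only, cheap)
    per = _pair_boot_scores(rel[:, i], rel[:, j], idx, measure, bins)
    lo, hi = np.nanpercentile(per, [2.5, 97.5])
    p = _empirical_p(nulls, boot_mean)
    return p, float(finite.mean()), float(finite.std()), (float(lo), float(hi))


def _pair_boot_scores(x, y, idx, measure, bins):
    A = x[idx]
    B = y[idx][:, :, None]
    if measure == "pearson":
        return _batched_pearson(A, B)[:, 0]
    if measure == "spearman":
        return _batched_spearman(A, B)[:, 0]
    if measure == "bray_curtis":
        return _batched_bray_curtis(A, B)[:, 0]
    if measure == "mi":
        return _batched_mi(A, B, bins)[:, 0]
    raise ValueError(f"single-pair bootstrap CI not defined for {measure!r}")


def build_network(
    results: list[AssociationResult],
    q_threshold: float = 0.05,
    nodes: list[str] | None = None,
) -> ConsortiumNetwork:
    """Signed network of pairs with ``q <= threshold`` and a coherent sign.

    Every taxon named in ``nodes`` (or appearing in any tested pair) is
    kept as a node, so taxa with no significant partner remain visible as
    isolated, zero-centrality nodes.
    """
    if nodes is None:
        seen: dict[str, None] = {}
        for r in results:
            seen.setdefault(r.taxon_a)
            seen.setdefault(r.taxon_b)
        nodes = list(seen)
    edges = []
    for r in results:
        if not np.isfinite(r.qvalue) or r.qvalue > q_threshold:
            continue
        if r.sign == "conflict" or not np.isfinite(r.weight) or r.weight <= 0:
            continue
        edges.append((r.taxon_a, r.taxon_b, r.sign, r.weight, r.qvalue))
    return ConsortiumNetwork.from_edges(nodes, edges)


def infer_network(
    table: AbundanceTable,
    config: PipelineConfig | None = None,
    generation: str | None = None,
) -> tuple[ConsortiumNetwork, list[AssociationResult]]:
    """Scan one table (optionally one generation) and build its network."""
    config = config or PipelineConfig()
    if generation is not None:
        table = table.select_generation(generation)
    if table.mode != "relative":
        table = table.to_relative()
    results = association_scan(table, config)
    net = build_network(results, config.q_threshold, nodes=table.taxon_ids)
    return net, results
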