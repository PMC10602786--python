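"""Taxon-to-degradation-function association and community summaries.

For each genus, the same five measures used for taxon-taxon edges
(Bray–Curtis, Pearson, Spearman, MI, GBLM) are computed between the
genus's relative-abundance vector and the degradation-efficiency vector
of one oil fraction, each standardized against its own permutation null
(efficiencies shuffled across samples) into a signed z.  The *combined
coefficient* is the sum of the five signed z's — unbounded, typically
O(10) for strong associations — with MI's unsigned z given Spearman's
direction and Bray–Curtis's z flipped so that "more similar than the
null" counts as positive.  Its p-value comes from the permutation
distribution of the combined statistic itself; BH runs over taxa within
one fraction.

Also here: small-sample rank tests (exact enumeration at the study's
n = 3), Shannon/Pielou alpha diversity, Bray–Curtis beta distances, and
the core/shared/unique taxon bookkeeping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceTable, DegradationRecord
from .measures import _boost_path, default_mi_bins
from .ensemble import _batched_bray_curtis, _batched_mi, _batched_pearson, _batched_spearman

__all__ = [
    "FunctionAssociation",
    "taxon_function_scores",
    "top_tables",
    "group_compare",
    "community_metrics",
    "core_and_unique",
]

_PRESENCE_EPS = 1e-9


@dataclass
class FunctionAssociation:
    """Combined abundance-efficiency evidence for one taxon and fraction."""

    taxon: str
    fraction: str
    measure_z: dict[str, float] = field(default_factory=dict)
    combined: float = math.nan
    pvalue: float = math.nan
    qvalue: float = math.nan

    @property
    def direction(self) -> str:
        return "+" if self.combined >= 0 else "-"


def _align_efficiencies(
    table: AbundanceTable,
    responses: list[DegradationRecord],
    fraction: str,
) -> np.ndarray:
    by_key = {
        (r.generation, r.replicate): r.efficiency
        for r in responses
        if r.fraction == fraction
    }
    eff = []
    for g, rep in zip(table.generations, table.replicates):
        if (g, rep) not in by_key:
            raise ValueError(f"no {fraction} record for sample ({g}, replicate {rep})")
        eff.append(by_key[(g, rep)])
    return np.asarray(eff, dtype=float)


def _signed_z(obs, null):
    """(observed - null mean) / null sd against permutation draws; nan-safe."""
    mu = np.nanmean(null, axis=0)
    sd = np.nanstd(null, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mu) / sd
    return np.where(sd > 0, z, 0.0)


def taxon_function_scores(
    table: AbundanceTable,
    responses: list[DegradationRecord],
    fraction: str,
    permutations: int = 1000,
    seed: int = 0,
    generation: str | None = None,
    gblm_shrinkage: float = 0.1,
    gblm_iterations: int = 100,
) -> list[FunctionAssociation]:
    """Combined coefficient of every taxon against one fraction's efficiency.

    Default pools all generations jointly (the study's n = 12);
    ``generation`` restricts to one transfer.  Constant taxa are excluded
    (no defined association).
    """
    if generation is not None:
        table = table.select_generation(generation)
        responses = [r for r in responses if r.generation == generation]
    if table.mode != "relative":
        table = table.to_relative()
    eff = _align_efficiencies(table, responses, fraction)
    n = table.n_samples
    if n < 6:
        raise ValueError("need at least 6 paired observations")
    rel = table.values
    keep = [k for k in range(rel.shape[1]) if np.ptp(rel[:, k]) > 0]
    dropped = [table.taxon_ids[k] for k in range(rel.shape[1]) if k not in keep]
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "excluding constant taxa from %s association: %s", fraction, dropped
        )
    X = rel[:, keep]
    taxa = [table.taxon_ids[k] for k in keep]
    p = X.shape[1]
    bins = default_mi_bins(n)
    rng = np.random.default_rng(seed)
    P = permutations

    perm_idx = np.array([rng.permutation(n) for _ in range(P)])
    Eperm = eff[perm_idx]                       # (P, n)
    Xb = np.broadcast_to(X, (P, n, p))

    # observed per-measure scores (taxon vs efficiency)
    obs = {
        "pearson": _batched_pearson(eff[None, :], X[None, :, :])[0],
        "spearman": _batched_spearman(eff[None, :], X[None, :, :])[0],
        "bray_curtis": _bc_function(eff[None, :], X[None, :, :])[0],
        "mi": _batched_mi(eff[None, :], X[None, :, :], bins)[0],
    }
    nulls = {
        "pearson": _batched_pearson(Eperm, Xb),
        "spearman": _batched_spearman(Eperm, Xb),
        "bray_curtis": _bc_function(Eperm, Xb),
        "mi": _batched_mi(Eperm, Xb, bins),
    }
    # GBLM: boosted regression of efficiency on all taxa jointly; the
    # permuted-target refits come from one batched boosting call.
    obs["gblm"] = _boost_path(X, eff, gblm_shrinkage, gblm_iterations)
    nulls["gblm"] = _boost_path(X[None, :, :], Eperm, gblm_shrinkage, gblm_iterations)

    z_obs: dict[str, np.ndarray] = {}
    z_null: dict[str, np.ndarray] = {}
    for m in ("pearson", "spearman", "gblm"):
        z_obs[m] = _signed_z(obs[m], nulls[m])
        z_null[m] = _signed_z(nulls[m], nulls[m])
    # Unsigned measures (MI, Bray-Curtis): magnitude from their own null,
    # direction borrowed from Spearman, so negating the response flips
    # every signed z exactly.
    for m in ("mi", "bray_curtis"):
        zm = _signed_z(obs[m], nulls[m])
        z_obs[m] = np.abs(zm) * np.where(z_obs["spearman"] >= 0, 1.0, -1.0)
        zmn = _signed_z(nulls[m], nulls[m])
        z_null[m] = np.abs(zmn) * np.where(z_null["spearman"] >= 0, 1.0, -1.0)

    combined_obs = sum(z_obs[m] for m in z_obs)                   # (p,)
    combined_null = sum(z_null[m] for m in z_null)                # (P, p)

    dev_null = np.abs(combined_null)
    out = []
    for k, taxon in enumerate(taxa):
        pv = float((1 + np.sum(dev_null[:, k] >= abs(combined_obs[k]))) / (P + 1))
        out.append(
            FunctionAssociation(
                taxon=taxon,
                fraction=fraction,
                measure_z={m: float(z_obs[m][k]) for m in z_obs},
                combined=float(combined_obs[k]),
                pvalue=pv,
            )
        )
    _, q, _, _ = multipletests([a.pvalue for a in out], method="fdr_bh")
    for a, qv in zip(out, q):
        a.qvalue = float(qv)
    return out


def _bc_function(E: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Bray–Curtis between efficiency and abundance vectors.

    Efficiencies can be negative, so both vectors are min-shifted to be
    non-negative before the usual 1 - 2 sum(min)/sum formula.
    """
    E = E - np.minimum(E.min(axis=1, keepdims=True), 0.0)
    return _batched_bray_curtis(E, X)


def top_tables(
    assocs: list[FunctionAssociation],
    k: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strongest positive and strongest negative associations, top-k each.

    Mirrors the report layout: taxon, combined coefficient (starred at
    q <= 0.05), fraction.
    """
    if not assocs:
        empty = pd.DataFrame(columns=["taxon", "coefficient", "significant", "fraction"])
        return empty, empty.copy()
    df = pd.DataFrame(
        {
            "taxon": [a.taxon for a in assocs],
            "coefficient": [a.combined for a in assocs],
            "significant": [a.qvalue <= 0.05 for a in assocs],
            "fraction": [a.fraction for a in assocs],
        }
    )
    pos = df.sort_values(["coefficient", "taxon"], ascending=[False, True]).head(k)
    neg = df.sort_values(["coefficient", "taxon"], ascending=[True, True]).head(k)
    return pos.reset_index(drop=True), neg.reset_index(drop=True)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def group_compare(
    groups: list[np.ndarray],
    test: str = "wilcoxon-mann-whitney",
) -> tuple[float, float]:
    """Rank-based comparison of independent groups.

    Wilcoxon–Mann–Whitney (two groups): exact permutation distribution
    for small tie-free samples (n <= 8 per group), mid-rank normal
    approximation with tie correction otherwise.  Kruskal–Wallis (>= 2
    groups): full enumeration of label assignments when feasible
    (<= 50,000 arrangements, no ties across groups needed), chi-square
    approximation otherwise.  Returns ``(statistic, two-sided p)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if test == "wilcoxon-mann-whitney":
        if len(groups) != 2:
            raise ValueError("Wilcoxon-Mann-Whitney compares exactly 2 groups")
        x, y = groups
        pooled = np.concatenate([x, y])
        small = x.size <= 8 and y.size <= 8
        exact = small and np.unique(pooled).size == pooled.size
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal-wallis":
        stat, p_asym = stats.kruskal(*groups)
        sizes = [g.size for g in groups]
        total = math.factorial(sum(sizes))
        for s in sizes:
            total //= math.factorial(s)
        if max(sizes) <= 8 and total <= 50_000:
            p = _exact_kruskal_p(groups, stat)
            return float(stat), p
        return float(stat), float(p_asym)
    raise ValueError(f"unknown test {test!r}")


def _exact_kruskal_p(groups: list[np.ndarray], h_obs: float) -> float:
    """P(H >= observed) by full enumeration of group-label assignments."""
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    n = pooled.size
    ranks = stats.rankdata(pooled)
    tie_term = _kw_tie_correction(pooled)
    count = 0
    total = 0
    for assignment in _multiset_partitions(n, sizes):
        h = _kw_statistic(ranks, assignment, n, tie_term)
        if h >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _kw_statistic(ranks, assignment, n, tie_term):
    h = 0.0
    for idx in assignment:
        r = ranks[list(idx)]
        h += r.sum() ** 2 / len(idx)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else h


def _kw_tie_correction(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - np.sum(counts**3 - counts) / (n**3 - n)


def _multiset_partitions(n: int, sizes: list[int]):
    """All ways to split indices 0..n-1 into ordered groups of given sizes."""
    def rec(available: tuple[int, ...], remaining: list[int]):
        if not remaining:
            yield ()
            return
        k = remaining[0]
        for combo in itertools.combinations(available, k):
            rest = tuple(i for i in available if i not in combo)
            for tail in rec(rest, remaining[1:]):
                yield (combo,) + tail

    yield from rec(tuple(range(n)), sizes)


# ---------------------------------------------------------------------------
# diversity and core-taxon bookkeeping
# ---------------------------------------------------------------------------

def community_metrics(table: AbundanceTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample Shannon H (nats) and Pielou evenness; Bray–Curtis matrix.

    Evenness is ``H / ln(S_observed)`` with observed richness per sample;
    a single-taxon sample has H = 0 and evenness defined as 0.
    """
    if table.mode != "relative":
        table = table.to_relative()
    V = table.values
    H = np.array([-np.sum(row[row > 0] * np.log(row[row > 0])) for row in V])
    S = (V > 0).sum(axis=1)
    evenness = np.where(S > 1, H / np.log(np.maximum(S, 2)), 0.0)
    alpha = pd.DataFrame(
        {
            "generation": table.generations,
            "replicate": table.replicates,
            "shannon": H,
            "evenness": evenness,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    D = squareform(pdist(V, metric="braycurtis"))
    beta = pd.DataFrame(D, index=table.sample_ids, columns=table.sample_ids)
    return alpha, beta


def core_and_unique(
    tables: list[AbundanceTable],
    prevalence_min: float = 0.80,
    abundance_min: float = 0.002,
) -> dict:
    """Core, shared and per-generation unique taxa, Venn-style.

    Core: present (> 0 after 1e-9 rounding) in more than ``prevalence_min``
    of all samples pooled across generations AND mean relative abundance
    over all samples above ``abundance_min``.  Shared: present in every
    generation; unique: present in exactly one.
    """
    if not tables:
        raise ValueError("need at least one table")
    universe = tables[0].taxon_ids
    for t in tables[1:]:
        if t.taxon_ids != universe:
            raise ValueError("tables must share one taxon universe")
    rels = [t.to_relative() if t.mode != "relative" else t for t in tables]
    stacked = np.vstack([t.values for t in rels])
    present_all = stacked > _PRESENCE_EPS
    prevalence = present_all.mean(axis=0)
    mean_abund = stacked.mean(axis=0)
    core = {
        universe[k]
        for k in range(len(universe))
        if prevalence[k] > prevalence_min and mean_abund[k] > abundance_min
    }
    per_gen_present = [
        {universe[k] for k in range(len(universe)) if np.any(t.values[:, k] > _PRESENCE_EPS)}
        for t in rels
    ]
    shared = set.intersection(*per_gen_present)
    unique = []
    for gi, present in enumerate(per_gen_present):
        others = set().union(*(s for gj, s in enumerate(per_gen_present) if gj != gi))
        unique.append(present - others)
    labels = [t.generation_labels()[0] if len(t.generation_labels()) == 1 else f"table{n}"
              for n, t in enumerate(rels)]
    return {
        "core": core,
        "shared": shared,
        "unique": dict(zip(labels, unique)),
        "counts": {
            "core": len(core),
            "shared": len(shared),
            "unique": {lab: len(u) for lab, u in zip(labels, unique)},
        },
    }
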