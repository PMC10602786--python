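"""Synthetic compositional communities with planted structure.

Emulates the shape of a serial-transfer enrichment study: a fixed panel of
genera observed over successive transfer generations (default four,
``G1``..``G4``) in triplicate, with

* pairwise taxon-taxon associations planted as correlations of the
  log-scale latent abundances,
* per-taxon multiplicative drift across generations (keystones rising or
  fading, as dominant genera do under repeated transfers), and
* degradation-efficiency responses (per oil fraction) linearly driven by
  standardized keystone log-abundances, optionally with pairwise synergy
  terms.

Counts are drawn multinomially at a fixed sequencing depth from the
closed latent composition, so downstream methods face real compositional
artefacts.  Every draw flows from one ``numpy.random.default_rng(seed)``
stream (PCG64), so a fixed spec reproduces bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AbundanceTable, DegradationRecord, ValidationError, OIL_FRACTIONS

__all__ = [
    "SyntheticSpec",
    "generate_latent",
    "compose_and_count",
    "generate_responses",
    "simulate_study",
    "study_spec",
    "CONTROL_RESIDUALS",
]

# Fixed control residual masses (g per culture) used to back-compute
# treatment residuals from simulated efficiencies: 10 g crude oil per
# litre of medium, split across SARA fractions in field-typical ratios.
CONTROL_RESIDUALS = {
    "TPH": 10.0,
    "saturates": 5.5,
    "aromatics": 2.5,
    "resins": 1.2,
    "asphaltenes": 0.8,
}

# Baseline efficiencies (fraction degraded absent any keystone effect).
DEFAULT_BASELINES = {
    "TPH": 0.25,
    "saturates": 0.17,
    "aromatics": 0.08,
    "resins": 0.0,
    "asphaltenes": 0.0,
}


@dataclass
class SyntheticSpec:
    """Ground-truth description of one synthetic community experiment.

    ``planted_edges`` are ``(taxon_i, taxon_j, rho)`` latent log-scale
    correlations; ``keystone_effects`` are ``(taxon, fraction, beta)``
    with beta in efficiency units per SD of log-latent abundance;
    ``generation_drift`` maps a taxon to a per-generation multiplicative
    factor (1.0 = flat); ``synergy_terms`` are
    ``(taxon_i, taxon_j, fraction, beta_ij)`` on the standardized product
    of latents.
    """

    n_taxa: int = 30
    n_generations: int = 4
    replicates: int = 3
    depth: int = 50_000
    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)
    keystone_effects: list[tuple[str, str, float]] = field(default_factory=list)
    generation_drift: dict[str, float] = field(default_factory=dict)
    synergy_terms: list[tuple[str, str, str, float]] = field(default_factory=list)
    noise_sd: float = 0.05
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    base_log_mean_sd: float = 1.5
    latent_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValidationError("need at least 2 taxa")
        if self.depth < 1000:
            raise ValidationError("sequencing depth must be >= 1000")
        for a, b, rho in self.planted_edges:
            if not -1.0 <= rho <= 1.0:
                raise ValidationError(f"planted correlation {rho} outside [-1, 1]")
            if a == b:
                raise ValidationError("planted edge must join two distinct taxa")
        names = set(self.taxon_ids)
        for t, frac, beta in self.keystone_effects:
            if t not in names:
                raise ValidationError(f"unknown keystone taxon {t!r}")
            if frac not in OIL_FRACTIONS:
                raise ValidationError(f"unknown fraction {frac!r}")
            if not np.isfinite(beta):
                raise ValidationError("effect size must be finite")
        for a, b, frac, beta in self.synergy_terms:
            if a not in names or b not in names:
                raise ValidationError("unknown taxon in synergy term")

    @property
    def taxon_ids(self) -> list[str]:
        return [f"taxon_{i:02d}" for i in range(self.n_taxa)]

    @property
    def n_samples(self) -> int:
        return self.n_generations * self.replicates

    @property
    def generations(self) -> list[str]:
        return [f"G{g + 1}" for g in range(self.n_generations)]

    def sample_metadata(self) -> tuple[list[str], list[str], list[int]]:
        sample_ids, gens, reps = [], [], []
        for g in self.generations:
            for r in range(1, self.replicates + 1):
                sample_ids.append(f"{g}_r{r}")
                gens.append(g)
                reps.append(r)
        return sample_ids, gens, reps

    def correlation_matrix(self) -> np.ndarray:
        """Taxon log-latent correlation implied by the planted edges.

        Repaired toward the identity by shrinkage if not positive
        definite; raises if no shrinkage below 0.99 restores it.
        """
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        R = np.eye(self.n_taxa)
        for a, b, rho in self.planted_edges:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
        for lam in np.linspace(0.0, 0.99, 100):
            shrunk = (1 - lam) * R + lam * np.eye(self.n_taxa)
            if np.linalg.eigvalsh(shrunk)[0] > 1e-8:
                return shrunk
        raise ValidationError("planted correlation matrix cannot be repaired to PD")


def generate_latent(spec: SyntheticSpec) -> np.ndarray:
    """Strictly positive latent abundance matrix, samples x taxa.

    Log-latents are multivariate normal with the planted correlation,
    per-taxon base means drawn once from ``N(0, base_log_mean_sd^2)``
    (uneven communities, a few dominant genera), and generation drift
    applied as ``drift_t ** g`` with ``g = 0`` for the first generation.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.correlation_matrix()
    L = np.linalg.cholesky(R)
    base_mu = rng.normal(0.0, spec.base_log_mean_sd, size=spec.n_taxa)
    z = rng.standard_normal((spec.n_samples, spec.n_taxa)) @ L.T
    log_latent = base_mu + spec.latent_log_sd * z
    _, gens, _ = spec.sample_metadata()
    gen_index = {g: i for i, g in enumerate(spec.generations)}
    drift = np.ones((spec.n_samples, spec.n_taxa))
    idx = {t: i for i, t in enumerate(spec.taxon_ids)}
    for taxon, rate in spec.generation_drift.items():
        if taxon not in idx:
            raise ValidationError(f"unknown drift taxon {taxon!r}")
        for s, g in enumerate(gens):
            drift[s, idx[taxon]] = rate ** gen_index[g]
    return np.exp(log_latent) * drift


def compose_and_count(latent: np.ndarray, depth: int, seed: int) -> AbundanceTable:
    """Multinomial read counts at fixed depth from the closed latent rows."""
    latent = np.asarray(latent, dtype=float)
    if np.any(latent <= 0):
        raise ValidationError("latent abundances must be strictly positive")
    rng = np.random.default_rng(seed)
    probs = latent / latent.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in probs]).astype(float)
    n, p = counts.shape
    # metadata defaults assume rows grouped in triplicate generations
    sample_ids = [f"s{i + 1}" for i in range(n)]
    gens = [f"G{i // 3 + 1}" if n % 3 == 0 else "G1" for i in range(n)]
    reps = [i % 3 + 1 if n % 3 == 0 else i + 1 for i in range(n)]
    return AbundanceTable(
        sample_ids=sample_ids,
        taxon_ids=[f"taxon_{i:02d}" for i in range(p)],
        values=counts,
        generations=gens,
        replicates=reps,
        mode="counts",
    )


def _standardize_columns(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a - a.mean(axis=0)) / sd
    return np.where(sd > 0, z, 0.0)


def generate_responses(latent: np.ndarray, spec: SyntheticSpec) -> list[DegradationRecord]:
    """Degradation records whose efficiencies respond to keystone latents.

    Per sample and fraction::

        eff = clip(baseline + sum beta_t z(log latent_t)
                            + sum beta_ij z(log(latent_i latent_j))
                            + N(0, noise_sd), -0.2, 1)

    where z(.) standardizes across samples.  The control residual is the
    fixed fraction mass; the treatment residual is back-computed so that
    the efficiency identity holds exactly.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.shape != (spec.n_samples, spec.n_taxa):
        raise ValidationError("latent shape does not match spec")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    idx = {t: i for i, t in enumerate(spec.taxon_ids)}
    Z = _standardize_columns(np.log(latent))
    sample_ids, gens, reps = spec.sample_metadata()
    fractions = sorted({f for _, f, _ in spec.keystone_effects} | set(spec.baselines))
    records: list[DegradationRecord] = []
    for frac in fractions:
        eff = np.full(spec.n_samples, spec.baselines.get(frac, 0.0))
        for taxon, f, beta in spec.keystone_effects:
            if f == frac:
                eff = eff + beta * Z[:, idx[taxon]]
        for a, b, f, beta in spec.synergy_terms:
            if f == frac:
                prod = _standardize_columns(
                    np.log(latent[:, idx[a]] * latent[:, idx[b]])[:, None]
                )[:, 0]
                eff = eff + beta * prod
        if spec.noise_sd > 0:
            eff = eff + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        eff = np.clip(eff, -0.2, 1.0)
        control = CONTROL_RESIDUALS[frac]
        for s in range(spec.n_samples):
            records.append(
                DegradationRecord(
                    generation=gens[s],
                    replicate=reps[s],
                    fraction=frac,
                    residual_control=control,
                    residual_treatment=control * (1.0 - eff[s]),
                )
            )
    return records


def simulate_study(spec: SyntheticSpec) -> tuple[AbundanceTable, list[DegradationRecord], dict]:
    """Full simulated experiment: counts table, degradation records, truth.

    The truth dict records planted edges, keystone effects and synergy
    terms for downstream recovery scoring.
    """
    latent = generate_latent(spec)
    counts = compose_and_count(latent, spec.depth, seed=int(np.random.SeedSequence([spec.seed, 13]).generate_state(1)[0] % (2**31)))
    sample_ids, gens, reps = spec.sample_metadata()
    table = AbundanceTable(
        sample_ids=sample_ids,
        taxon_ids=spec.taxon_ids,
        values=counts.values,
        generations=gens,
        replicates=reps,
        mode="counts",
    )
    records = generate_responses(latent, spec)
    truth = {
        "planted_edges": [[a, b, rho] for a, b, rho in spec.planted_edges],
        "keystone_effects": [[t, f, b] for t, f, b in spec.keystone_effects],
        "synergy_terms": [[a, b, f, x] for a, b, f, x in spec.synergy_terms],
        "seed": spec.seed,
    }
    return table, records, truth


def study_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Default fixture mirroring the enrichment-study shape.

    Four generations x three replicates (12 samples), 30 genera at depth
    50,000, ten planted associations of magnitude 0.8 (seven positive,
    three negative), keystone degraders whose abundance drifts downward
    over transfers and drives TPH/saturates/aromatics efficiency, and a
    competitor whose abundance rises and suppresses degradation.
    """
    # disjoint pairs keep the implied correlation matrix block-diagonal and
    # positive definite, so the planted magnitudes hold without shrinkage
    planted = [
        ("taxon_00", "taxon_01", 0.8),
        ("taxon_02", "taxon_03", 0.8),
        ("taxon_04", "taxon_05", 0.8),
        ("taxon_06", "taxon_07", -0.8),
        ("taxon_08", "taxon_09", 0.8),
        ("taxon_10", "taxon_11", -0.8),
        ("taxon_12", "taxon_13", 0.8),
        ("taxon_14", "taxon_15", -0.8),
        ("taxon_16", "taxon_17", 0.8),
        ("taxon_18", "taxon_19", 0.8),
    ]
    keystones = [
        ("taxon_00", "TPH", 0.4),
        ("taxon_00", "saturates", 0.35),
        ("taxon_02", "aromatics", 0.4),
        ("taxon_06", "TPH", -0.25),
    ]
    drift = {"taxon_00": 0.6, "taxon_02": 0.55, "taxon_06": 1.5}
    defaults = dict(
        n_taxa=30,
        n_generations=4,
        replicates=3,
        depth=50_000,
        planted_edges=planted,
        keystone_effects=keystones,
        generation_drift=drift,
        noise_sd=0.05,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)
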