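"""Domain types and readers/writers shared by every pipeline stage.

The central containers are :class:`AbundanceTable` (samples x taxa
relative-abundance or count matrix with generation/replicate metadata),
:class:`DegradationRecord` (residual oil masses and the derived degradation
efficiency for one sample and oil fraction) and :class:`ConsortiumNetwork`
(a signed, weighted, undirected association graph over taxa).

Feature tables are tab-separated: first column sample ID, second column
generation label, optional third column ``replicate``, remaining columns
one taxon each.  Networks round-trip through GraphML or a five-column edge
list (taxonA, taxonB, sign, weight, q).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "DegradationRecord",
    "ConsortiumNetwork",
    "PipelineConfig",
    "ValidationError",
    "degradation_efficiency",
    "read_abundance_table",
    "write_abundance_table",
    "read_degradation_records",
    "write_degradation_records",
    "read_network",
    "write_network",
]

OIL_FRACTIONS = ("TPH", "saturates", "aromatics", "resins", "asphaltenes")

_ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """An input violates a domain invariant."""


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with per-sample metadata.

    Parameters
    ----------
    sample_ids:
        Unique sample identifiers, one per row.
    taxon_ids:
        Unique taxon identifiers, one per column.
    values:
        Non-negative matrix, shape ``(n_samples, n_taxa)``.  In
        ``relative`` mode every row sums to one (closure); in ``counts``
        mode entries are read counts.
    generations:
        Generation label per sample (e.g. ``G1``..``G4``).
    replicates:
        Replicate index per sample.
    mode:
        ``"counts"`` or ``"relative"``.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    generations: list[str]
    replicates: list[int]
    mode: str = "relative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.generations = [str(g) for g in self.generations]
        self.replicates = [int(r) for r in self.replicates]
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValidationError("need at least 2 samples and 2 taxa")
        if len(self.sample_ids) != n or len(self.generations) != n or len(self.replicates) != n:
            raise ValidationError("sample metadata length mismatch")
        if len(self.taxon_ids) != p:
            raise ValidationError("taxon_ids length mismatch")
        if len(set(self.taxon_ids)) != p:
            raise ValidationError("duplicate taxon identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite abundance value")
        if np.any(self.values < 0):
            raise ValidationError("negative abundance value")
        sums = self.values.sum(axis=1)
        if np.any(sums <= 0):
            raise ValidationError("sample with all-zero abundances")
        if self.mode == "relative":
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValidationError("relative-mode rows must sum to 1")
        elif self.mode != "counts":
            raise ValidationError(f"unknown mode {self.mode!r}")

    # -- derived views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_relative(self) -> "AbundanceTable":
        """Close each row to sum one.  Idempotent."""
        rows = self.values / self.values.sum(axis=1, keepdims=True)
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=list(self.taxon_ids),
            values=rows,
            generations=list(self.generations),
            replicates=list(self.replicates),
            mode="relative",
        )

    def select_generation(self, generation: str) -> "AbundanceTable":
        mask = [g == generation for g in self.generations]
        if sum(mask) < 2:
            raise ValidationError(f"fewer than 2 samples in generation {generation!r}")
        idx = np.flatnonzero(mask)
        return AbundanceTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            taxon_ids=list(self.taxon_ids),
            values=self.values[idx],
            generations=[self.generations[i] for i in idx],
            replicates=[self.replicates[i] for i in idx],
            mode=self.mode,
        )

    def generation_labels(self) -> list[str]:
        """Distinct generation labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.generations:
            seen.setdefault(g)
        return list(seen)

    def taxon_vector(self, taxon: str) -> np.ndarray:
        return self.values[:, self.taxon_ids.index(taxon)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)
        df.insert(0, "replicate", self.replicates)
        df.insert(0, "generation", self.generations)
        df.index.name = "sample_id"
        return df

    def __eq__(self, other: object) -> bool:  # bitwise round-trip equality
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and self.generations == other.generations
            and self.replicates == other.replicates
            and self.mode == other.mode
            and np.array_equal(self.values, other.values)
        )


def degradation_efficiency(control: float, treatment: float) -> float:
    """Fraction of an oil component removed relative to the abiotic control.

    ``(control - treatment) / control`` where both arguments are residual
    masses (g).  May be negative when the treatment residual exceeds the
    control (observed for resins/asphaltenes); never exceeds 1.
    """
    if not control > 0:
        raise ValueError(f"control residual must be positive, got {control}")
    if treatment < 0:
        raise ValueError(f"treatment residual must be non-negative, got {treatment}")
    return (control - treatment) / control


@dataclass
class DegradationRecord:
    """Residual oil masses for one sample and fraction, with efficiency."""

    generation: str
    replicate: int
    fraction: str
    residual_control: float
    residual_treatment: float
    efficiency: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fraction not in OIL_FRACTIONS:
            raise ValidationError(f"unknown oil fraction {self.fraction!r}")
        if not self.residual_control > 0:
            raise ValidationError("control residual must be positive")
        computed = degradation_efficiency(self.residual_control, self.residual_treatment)
        if self.efficiency is None:
            self.efficiency = computed
        elif abs(self.efficiency - computed) > 1e-9:
            raise ValidationError("stored efficiency inconsistent with residuals")


@dataclass
class ConsortiumNetwork:
    """Signed weighted undirected association network over taxa.

    Edges carry ``sign`` (``"+"``/``"-"``), ``weight`` (> 0, standardized
    association strength) and ``q`` (BH-adjusted merged p-value).  Taxa
    with no significant association remain as isolated nodes.
    """

    graph: nx.Graph

    @classmethod
    def from_edges(
        cls,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str, str, float, float]],
    ) -> "ConsortiumNetwork":
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for a, b, sign, weight, q in edges:
            g.add_edge(str(a), str(b), sign=sign, weight=float(weight), q=float(q))
        net = cls(g)
        net.validate()
        return net

    def validate(self) -> None:
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise ValidationError(f"self-edge on {a!r}")
            if data.get("sign") not in ("+", "-"):
                raise ValidationError(f"edge ({a},{b}) sign must be '+' or '-'")
            if not data.get("weight", 0) > 0:
                raise ValidationError(f"edge ({a},{b}) weight must be > 0")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_records(self) -> list[tuple[str, str, str, float, float]]:
        """Deterministically ordered (a, b, sign, weight, q) tuples."""
        recs = []
        for a, b, d in self.graph.edges(data=True):
            a, b = sorted((a, b))
            recs.append((a, b, d["sign"], float(d["weight"]), float(d["q"])))
        return sorted(recs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConsortiumNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_records() == other.edge_records()


@dataclass
class PipelineConfig:
    """Tunable knobs shared across stages.

    ``permutations``/``bootstraps`` size the compositionality-preserving
    null and the bootstrap stabilisation; ``mi_bins`` is the
    equal-frequency bin count for mutual information (``None`` means
    ``floor(sqrt(n))`` capped at 8); ``gblm_*`` parametrise componentwise
    L2 boosting; ``q_threshold`` is the BH edge cutoff.
    """

    permutations: int = 200
    bootstraps: int = 100
    mi_bins: int | None = None
    q_threshold: float = 0.05
    seed: int = 0
    gblm_iterations: int = 100
    gblm_shrinkage: float = 0.1
    measures: tuple[str, ...] = ("bray_curtis", "pearson", "spearman", "mi", "gblm")
    use_bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.permutations < 100 or self.bootstraps < 100:
            raise ValidationError("permutations and bootstraps must each be >= 100")
        if self.mi_bins is not None and self.mi_bins < 2:
            raise ValidationError("mi_bins must be >= 2")
        if not 0 < self.q_threshold < 1:
            raise ValidationError("q_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["measures"] = list(self.measures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "measures" in d:
            d["measures"] = tuple(d["measures"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

def read_abundance_table(path: str | Path, dialect: str = "tsv") -> AbundanceTable:
    """Read a samples x taxa feature table.

    ``tsv``: header row of taxa with leading ``sample_id``, ``generation``
    and optional ``replicate`` columns.  ``biom-like``: a minimal
    BIOM-style JSON with ``rows`` (taxa), ``columns`` (samples) and a
    dense ``data`` matrix (taxa x samples, as BIOM orients it).
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        cols = list(df.columns)
        if len(cols) < 3 or cols[1] != "generation":
            raise ValidationError("expected columns: sample_id, generation, [replicate], taxa...")
        sample_ids = df.iloc[:, 0].astype(str).tolist()
        generations = df["generation"].astype(str).tolist()
        if "replicate" in cols[:3]:
            replicates = df["replicate"].astype(int).tolist()
            taxa = cols[3:]
        else:
            replicates = _default_replicates(generations)
            taxa = cols[2:]
        values = df[taxa].to_numpy(dtype=float)
    elif dialect == "biom-like":
        doc = json.loads(path.read_text())
        taxa = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        generations = [c.get("metadata", {}).get("generation", "G1") for c in doc["columns"]]
        replicates = [int(c.get("metadata", {}).get("replicate", i + 1))
                      for i, c in enumerate(doc["columns"])]
        values = np.asarray(doc["data"], dtype=float).T  # -> samples x taxa
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    mode = "relative" if np.allclose(values.sum(axis=1), 1.0, atol=1e-6) else "counts"
    return AbundanceTable(
        sample_ids=sample_ids,
        taxon_ids=list(taxa),
        values=values,
        generations=generations,
        replicates=replicates,
        mode=mode,
    )


def _default_replicates(generations: Sequence[str]) -> list[int]:
    counts: dict[str, int] = {}
    out = []
    for g in generations:
        counts[g] = counts.get(g, 0) + 1
        out.append(counts[g])
    return out


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.to_csv(Path(path), sep="\t", index=True, float_format="%.17g")


# ---------------------------------------------------------------------------
# Degradation-record I/O (CSV: generation,replicate,fraction,control,treatment)
# ---------------------------------------------------------------------------

def read_degradation_records(path: str | Path) -> list[DegradationRecord]:
    df = pd.read_csv(Path(path))
    required = {"generation", "replicate", "fraction", "residual_control", "residual_treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"degradation file missing columns: {sorted(missing)}")
    return [
        DegradationRecord(
            generation=str(row.generation),
            replicate=int(row.replicate),
            fraction=str(row.fraction),
            residual_control=float(row.residual_control),
            residual_treatment=float(row.residual_treatment),
        )
        for row in df.itertuples()
    ]


def write_degradation_records(records: Sequence[DegradationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "generation": [r.generation for r in records],
            "replicate": [r.replicate for r in records],
            "fraction": [r.fraction for r in records],
            "residual_control": [r.residual_control for r in records],
            "residual_treatment": [r.residual_treatment for r in records],
            "efficiency": [r.efficiency for r in records],
        }
    )
    df.to_csv(Path(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------

def write_network(net: ConsortiumNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or a 5-column edge list.

    The edge list carries one header line and one row per edge
    (taxonA, taxonB, sign, weight, q); isolated nodes are declared on
    ``# node:`` comment lines so the read-back reproduces the node set.
    """
    net.validate()
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "edgelist":
        lines = ["taxonA\ttaxonB\tsign\tweight\tq"]
        in_edges = set()
        for a, b, sign, weight, q in net.edge_records():
            in_edges.update((a, b))
            lines.append(f"{a}\t{b}\t{sign}\t{weight!r}\t{q!r}")
        for node in net.nodes:
            if node not in in_edges:
                lines.append(f"# node: {node}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str = "graphml") -> ConsortiumNetwork:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, str)
        net = ConsortiumNetwork(nx.Graph(g))
        net.validate()
        return net
    if fmt == "edgelist":
        nodes: list[str] = []
        edges: list[tuple[str, str, str, float, float]] = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("taxonA\t"):
                continue
            if line.startswith("# node: "):
                nodes.append(line[len("# node: "):])
                continue
            a, b, sign, weight, q = line.split("\t")
            edges.append((a, b, sign, float(weight), float(q)))
            nodes.extend((a, b))
        return ConsortiumNetwork.from_edges(dict.fromkeys(nodes), edges)
    raise ValueError(f"unknown network format {fmt!r}")
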