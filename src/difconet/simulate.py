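"""Synthetic two-condition RNA-seq data with planted ground truth.

The generator emulates the statistical structure the downstream stages
assume: negative-binomial counts (variance mu + alpha mu^2) for two
conditions with replicated samples (default 3 per condition), a planted
fraction of differentially expressed genes at a known log2 fold change,
gene-set collections constructed to be enriched in the planted DEGs, typed
relation tables over arbitrary entities, and condition-specific
co-expression modules driven by a shared per-sample lognormal latent
factor.  Everything is deterministic given the seed, so parameter-recovery
tests run fully offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .genesets import GeneSetCollection
from .relations import RELATION_TYPES, UNDIRECTED_TYPES, RelationTable


@dataclass
class SimulationConfig:
    """Design of one synthetic dataset.

    Defaults mirror a small two-group RNA-seq screen: 2 conditions x 3
    replicates, 10% planted DEGs, gene means log-uniform over 10^0.5..10^3.5
    and a single global NB dispersion.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    deg_fraction: float = 0.1
    lfc_magnitude: float = 1.0
    dispersion: float = 0.05
    baseline_mean_log_range: tuple[float, float] = (0.5, 3.5)
    n_modules: int = 3
    module_size: int = 10
    module_condition: str | tuple[str, ...] = "A"
    module_sigma: float = 0.5
    per_gene_dispersion_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_genes) != self.n_genes or self.n_genes <= 0:
            raise ValueError("n_genes must be a positive integer")
        if int(self.n_replicates) != self.n_replicates or self.n_replicates <= 0:
            raise ValueError("n_replicates must be a positive integer")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.baseline_mean_log_range
        if lo > hi:
            raise ValueError("baseline_mean_log_range must be (lo, hi) with lo <= hi")
        if self.n_modules < 0 or (self.n_modules > 0 and self.module_size < 2):
            raise ValueError("modules need n_modules >= 0 and module_size >= 2")
        conditions = self.module_conditions
        if any(c not in ("A", "B") for c in conditions):
            raise ValueError("module_condition labels must be 'A' or 'B'")
        if self.n_modules > 0:
            # modules are drawn from the planted DEG pool (see generate_counts),
            # or from all genes in a null design
            pool = self.n_deg if self.n_deg else self.n_genes
            if self.n_modules * self.module_size > pool:
                raise ValueError("planted modules do not fit inside the planted DEG pool")

    @property
    def n_deg(self) -> int:
        return int(round(self.deg_fraction * self.n_genes))

    @property
    def module_conditions(self) -> tuple[str, ...]:
        if isinstance(self.module_condition, str):
            return (self.module_condition,) * self.n_modules
        cond = tuple(self.module_condition)
        if len(cond) != self.n_modules:
            raise ValueError("module_condition must be one label or one per module")
        return cond


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generator, for recovery scoring."""

    deg_ids_up: set[str]
    deg_ids_down: set[str]
    true_lfc: dict[str, float]
    module_membership: dict[str, str]
    module_conditions: dict[str, str]
    hub_ids: set[str]
    universe: list[str]
    enriched_set_ids: set[str] = field(default_factory=set)

    @property
    def deg_ids(self) -> set[str]:
        return self.deg_ids_up | self.deg_ids_down

    def to_json(self, path: str | Path) -> None:
        payload = {
            "deg_ids_up": sorted(self.deg_ids_up),
            "deg_ids_down": sorted(self.deg_ids_down),
            "true_lfc": dict(sorted(self.true_lfc.items())),
            "module_membership": dict(sorted(self.module_membership.items())),
            "module_conditions": dict(sorted(self.module_conditions.items())),
            "hub_ids": sorted(self.hub_ids),
            "universe": list(self.universe),
            "enriched_set_ids": sorted(self.enriched_set_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            deg_ids_up=set(d["deg_ids_up"]),
            deg_ids_down=set(d["deg_ids_down"]),
            true_lfc=d["true_lfc"],
            module_membership=d["module_membership"],
            module_conditions=d["module_conditions"],
            hub_ids=set(d["hub_ids"]),
            universe=list(d["universe"]),
            enriched_set_ids=set(d["enriched_set_ids"]),
        )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, variance mu + alpha mu^2) draws; Poisson where alpha == 0."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha <= 0
    out[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        r = 1.0 / alpha[~poisson]
        p = r / (r + mu[~poisson])
        out[~poisson] = rng.negative_binomial(r, p)
    return out


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, PlantedTruth]:
    """Draw one synthetic count matrix and its planted truth.

    Condition-B means of planted DEGs equal the condition-A means times
    2^(+/- lfc_magnitude), split 50/50 up/down.  Module genes are taken
    from the planted-DEG pool (the co-expression stage runs on called DEGs,
    so condition-specific modules must live inside that set to be visible);
    their means are multiplied, in the module's active condition only, by a
    per-sample lognormal factor centred to have mean 1 so marginal means
    are unchanged.  The first gene of every module is recorded as its hub.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]

    lo, hi = config.baseline_mean_log_range
    base_mean = 10.0 ** rng.uniform(lo, hi, config.n_genes)

    n_deg = config.n_deg
    deg_idx = rng.choice(config.n_genes, size=n_deg, replace=False)
    n_up = (n_deg + 1) // 2
    up_idx = deg_idx[:n_up]
    down_idx = deg_idx[n_up:]

    lfc = np.zeros(config.n_genes)
    lfc[up_idx] = config.lfc_magnitude
    lfc[down_idx] = -config.lfc_magnitude

    # module genes: disjoint draws from the planted DEG pool (or all genes
    # in a null design with no DEGs)
    module_membership: dict[str, str] = {}
    module_conditions: dict[str, str] = {}
    hub_ids: set[str] = set()
    module_idx: list[np.ndarray] = []
    if config.n_modules > 0:
        pool = deg_idx if n_deg else np.arange(config.n_genes)
        chosen = rng.choice(pool, size=config.n_modules * config.module_size, replace=False)
        for m, cond in enumerate(config.module_conditions):
            mid = f"M{m + 1}"
            members = chosen[m * config.module_size:(m + 1) * config.module_size]
            module_idx.append(members)
            module_conditions[mid] = cond
            for j, gi in enumerate(members):
                module_membership[genes[gi]] = mid
                if j == 0:
                    hub_ids.add(genes[gi])

    n = config.n_replicates
    sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    condition = pd.Series(["A"] * n + ["B"] * n, index=sample_ids, name="condition")

    mean_a = base_mean
    mean_b = base_mean * 2.0 ** lfc
    mu = np.column_stack([np.tile(mean_a[:, None], (1, n)), np.tile(mean_b[:, None], (1, n))])

    # per-sample lognormal latent factor, mean-centred so E[factor] = 1
    sigma = config.module_sigma
    for members, (mid, cond) in zip(module_idx, module_conditions.items()):
        offset = 0 if cond == "A" else n
        factors = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n))
        mu[np.ix_(members, offset + np.arange(n))] *= factors[None, :]

    if config.per_gene_dispersion_sigma > 0:
        alpha = config.dispersion * np.exp(
            rng.normal(-0.5 * config.per_gene_dispersion_sigma ** 2,
                       config.per_gene_dispersion_sigma, config.n_genes)
        )
        alpha = alpha[:, None]
    else:
        alpha = np.full((config.n_genes, 1), float(config.dispersion))

    counts = _nb_draw(rng, mu, np.broadcast_to(alpha, mu.shape))
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids), condition)

    truth = PlantedTruth(
        deg_ids_up={genes[i] for i in up_idx},
        deg_ids_down={genes[i] for i in down_idx},
        true_lfc={genes[i]: float(lfc[i]) for i in deg_idx},
        module_membership=module_membership,
        module_conditions=module_conditions,
        hub_ids=hub_ids,
        universe=list(genes),
    )
    return cm, truth


def generate_genesets(truth: PlantedTruth, n_sets: int, set_size_range: tuple[int, int],
                      n_enriched: int, seed: int, enriched_deg_frac: float = 0.5,
                      kind: str = "go_like") -> GeneSetCollection:
    """Gene-set collection with ``n_enriched`` sets enriched in planted DEGs.

    Enriched sets draw at least ``enriched_deg_frac`` of their members from
    the planted DEG ids, the remainder (and all other sets) uniformly from
    the universe.  Updates ``truth.enriched_set_ids`` in place.
    """
    if n_enriched > n_sets:
        raise ValueError("n_enriched must be <= n_sets")
    lo, hi = set_size_range
    universe = list(truth.universe)
    if hi > len(universe):
        raise ValueError("set size exceeds universe size")
    rng = np.random.default_rng(seed)
    degs = sorted(truth.deg_ids)
    non_degs = sorted(set(universe) - set(degs))
    width = len(str(max(n_sets, 1)))
    sets: dict[str, frozenset[str]] = {}
    enriched_ids: set[str] = set()
    for i in range(n_sets):
        name = f"S{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            n_from_deg = min(int(np.ceil(enriched_deg_frac * size)), len(degs))
            members = list(rng.choice(degs, size=n_from_deg, replace=False))
            rest_pool = [g for g in non_degs if g not in members]
            members += list(rng.choice(rest_pool, size=size - n_from_deg, replace=False))
            enriched_ids.add(name)
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        sets[name] = frozenset(members)
    truth.enriched_set_ids |= enriched_ids
    return GeneSetCollection(sets, frozenset(universe), kind=kind)


def generate_relations(entities: list[str], n_edges: int,
                       type_weights: dict[str, float] | None = None,
                       seed: int = 0) -> RelationTable:
    """Random typed relation table without duplicate (source, target, type)
    triples; each edge's type is drawn with the given weights."""
    if type_weights is None:
        type_weights = {t: 1.0 for t in RELATION_TYPES}
    unknown = set(type_weights) - set(RELATION_TYPES)
    if unknown:
        raise ValueError(f"unknown relation type(s) in weights: {sorted(unknown)}")
    n = len(entities)
    if n_edges > n * (n - 1):
        raise ValueError("n_edges exceeds the number of ordered entity pairs")
    rng = np.random.default_rng(seed)
    types = sorted(type_weights)
    w = np.array([type_weights[t] for t in types], dtype=float)
    w = w / w.sum()
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    while len(rows) < n_edges:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        etype = types[rng.choice(len(types), p=w)]
        triple = (entities[i], entities[j], etype)
        if triple in seen:
            continue
        seen.add(triple)
        rows.append(triple)
    table = pd.DataFrame(rows, columns=["source", "target", "type"])
    table["directed"] = ~table["type"].isin(UNDIRECTED_TYPES)
    return RelationTable(table)
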