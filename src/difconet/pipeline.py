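"""End-to-end orchestration of the analysis stages.

One config drives the whole pipeline: differential-expression screen,
direction-split enrichment against GO-like and pathway-like collections,
typed interaction networks at gene and pathway level, and the differential
co-expression report with core-regulator calls.  In synthetic mode the
inputs are generated in-run with planted ground truth and a recovery
scorecard is written alongside the results.  All outputs are plain text
(TSV / GMT / GraphML / JSON) and byte-identical across reruns at a fixed
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import (build_condition_network, differential_report,
                           shared_variance_genes, write_coexpression_network,
                           write_report)
from .counts import CountMatrix, read_counts_tsv, write_counts_tsv
from .deg import call_degs, estimate_size_factors, write_deg_table
from .enrich import fisher_enrich, split_by_direction, write_enrichment
from .genesets import GeneSetCollection, read_gmt, write_gmt
from .networks import build_network, rank_by_degree, write_network
from .relations import read_relations, write_relations
from .simulate import (SimulationConfig, generate_counts, generate_genesets,
                       generate_relations)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and run mode for one pipeline run.

    Threshold defaults are the screen's printed values: |log2FC| >= 0.585,
    DEG FDR <= 0.05, GO p <= 0.01, pathway FDR <= 0.05, network p <= 0.05,
    |r| >= 0.9, DifDegree >= 12, DifKcore >= 8.
    """

    outdir: str = "difconet_run"
    mode: str = "synthetic"  # or "user-data"
    counts: str | None = None
    conditions: str | None = None
    go_gmt: str | None = None
    pathway_gmt: str | None = None
    gene_relations: str | None = None
    pathway_relations: str | None = None
    lfc_min: float = 0.585
    fdr_max: float = 0.05
    go_p_max: float = 0.01
    pathway_fdr_max: float = 0.05
    network_p_max: float = 0.05
    r_min: float = 0.9
    coexp_alpha: float = 0.05
    dif_degree_min: int = 12
    dif_kcore_min: int = 8
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "user-data"):
            raise ValueError("mode must be 'synthetic' or 'user-data'")
        for name in ("fdr_max", "go_p_max", "pathway_fdr_max", "network_p_max", "coexp_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("lfc_min", "r_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dif_degree_min", "dif_kcore_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _stage(name: str, outdir: Path):
    """Context that marks the run FAILED (with the stage name) on error."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / "FAILED").write_text(f"stage: {name}\nerror: {exc}\n")
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact directory; returns its path."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    provenance: dict = {
        "config": asdict(config),
        "versions": _versions(),
        "warnings": [],
        "counts": {},
    }

    truth = None
    with _stage("inputs", outdir):
        if config.mode == "synthetic":
            sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
            cm, truth = generate_counts(sim)
            rng_offset = sim.seed
            go = generate_genesets(truth, n_sets=40, set_size_range=(15, 40),
                                   n_enriched=3, seed=rng_offset + 1, kind="go_like")
            pathway = generate_genesets(truth, n_sets=25, set_size_range=(15, 40),
                                        n_enriched=3, seed=rng_offset + 2, kind="pathway_like")
            gene_rel = generate_relations(list(truth.universe), n_edges=min(
                4 * len(truth.universe), len(truth.universe) * (len(truth.universe) - 1)),
                seed=rng_offset + 3)
            pathway_rel = generate_relations(sorted(pathway.sets), n_edges=60,
                                             seed=rng_offset + 4)
            write_counts_tsv(cm, outdir / "counts.tsv", outdir / "conditions.tsv")
            write_gmt(go, outdir / "go_sets.gmt")
            write_gmt(pathway, outdir / "pathway_sets.gmt")
            write_relations(gene_rel, outdir / "gene_relations.tsv")
            write_relations(pathway_rel, outdir / "pathway_relations.tsv")
            truth.to_json(outdir / "truth.json")
        else:
            if not (config.counts and config.conditions):
                raise ValueError("user-data mode requires counts and conditions paths")
            cm = read_counts_tsv(config.counts, config.conditions)
            go = read_gmt(config.go_gmt, kind="go_like") if config.go_gmt else None
            pathway = read_gmt(config.pathway_gmt, kind="pathway_like") if config.pathway_gmt else None
            gene_rel = read_relations(config.gene_relations) if config.gene_relations else None
            pathway_rel = read_relations(config.pathway_relations) if config.pathway_relations else None

    with _stage("deg_calling", outdir):
        degs = call_degs(cm, lfc_min=config.lfc_min, fdr_max=config.fdr_max)
        write_deg_table(degs, outdir / "degs.tsv")
        up, down = split_by_direction(degs)
        provenance["counts"].update(
            genes_input=int(cm.counts.shape[0]),
            genes_tested=int(len(degs)),
            genes_dropped_all_zero=len(degs.attrs.get("dropped_all_zero", [])),
            degs_called=len(up) + len(down),
            degs_up=len(up),
            degs_down=len(down),
        )

    enrichments: dict[tuple[str, str], pd.DataFrame] = {}
    with _stage("enrichment", outdir):
        universe = frozenset(degs.index)
        for kind, coll in (("go", go), ("pathway", pathway)):
            if coll is None:
                continue
            # universe restricted to tested genes (post zero-filter)
            coll = GeneSetCollection(
                {n: m & universe for n, m in coll.sets.items() if m & universe},
                universe, kind=coll.kind,
            )
            for direction, ids in (("up", up), ("down", down)):
                res = fisher_enrich(ids, coll, direction,
                                    p_max=config.go_p_max, fdr_max=config.pathway_fdr_max)
                enrichments[(kind, direction)] = res
                write_enrichment(res, outdir / f"enrichment_{kind}_{direction}.tsv")
                provenance["counts"][f"enrichment_{kind}_{direction}_input"] = len(ids)

    with _stage("interaction_networks", outdir):
        if gene_rel is not None:
            sig = pd.DataFrame({
                "id": sorted(up) + sorted(down),
                "regulation": ["up"] * len(up) + ["down"] * len(down),
            })
            net = build_network(sig, gene_rel, level="gene")
            write_network(net, outdir / "gene_network.graphml",
                          outdir / "gene_network_edges.tsv", outdir / "gene_network_nodes.tsv")
            provenance["counts"]["gene_network_edges_skipped"] = len(net.skipped_edges)
            if net.skipped_edges:
                provenance["warnings"].append(
                    f"gene network: {len(net.skipped_edges)} relation(s) skipped "
                    "(endpoint not significant)")
            provenance["counts"]["gene_network_nodes"] = net.graph.number_of_nodes()
            provenance["counts"]["gene_network_edges"] = net.graph.number_of_edges()
        if pathway_rel is not None and enrichments:
            frames = []
            for (kind, direction), res in enrichments.items():
                if kind != "pathway":
                    continue
                frames.append(res.assign(regulation=direction)[["set_id", "regulation", "p_value"]])
            sig = pd.concat(frames).rename(columns={"set_id": "p_id"})
            sig = sig.sort_values("p_value").drop_duplicates("p_id")
            sig = sig.rename(columns={"p_id": "id"})
            net = build_network(sig, pathway_rel, p_threshold=config.network_p_max,
                                level="pathway")
            write_network(net, outdir / "pathway_network.graphml",
                          outdir / "pathway_network_edges.tsv",
                          outdir / "pathway_network_nodes.tsv")
            if net.skipped_edges:
                provenance["warnings"].append(
                    f"pathway network: {len(net.skipped_edges)} relation(s) skipped "
                    "(endpoint not significant)")
            ranking = rank_by_degree(net)
            pd.DataFrame(ranking, columns=["id", "degree"]).to_csv(
                outdir / "pathway_network_ranking.tsv", sep="\t", index=False)
            provenance["counts"]["pathway_network_nodes"] = net.graph.number_of_nodes()
            provenance["counts"]["pathway_network_edges"] = net.graph.number_of_edges()

    report = None
    with _stage("coexpression", outdir):
        called = sorted(up | down)
        if called:
            s = estimate_size_factors(cm)
            nodes = shared_variance_genes(cm, called, s)
            net_a = build_condition_network(cm, nodes, "A", r_min=config.r_min,
                                            alpha=config.coexp_alpha, size_factors=s)
            net_b = build_condition_network(cm, nodes, "B", r_min=config.r_min,
                                            alpha=config.coexp_alpha, size_factors=s)
            report = differential_report(net_a, net_b,
                                         dif_degree_min=config.dif_degree_min,
                                         dif_kcore_min=config.dif_kcore_min)
            write_coexpression_network(net_a, outdir / "coexp_A.graphml",
                                       outdir / "coexp_A_edges.tsv")
            write_coexpression_network(net_b, outdir / "coexp_B.graphml",
                                       outdir / "coexp_B_edges.tsv")
            write_report(report, outdir / "coexpression_report.tsv")
            summary = {"A": report.summary_A, "B": report.summary_B,
                       "core_regulators": report.core_regulators()}
            (outdir / "coexpression_summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n")
            provenance["counts"]["coexpression_nodes"] = len(nodes)

    with _stage("provenance", outdir):
        if truth is not None:
            scorecard = score_against_truth(degs, enrichments, report, truth)
            (outdir / "scorecard.json").write_text(
                json.dumps(scorecard, indent=2, sort_keys=True) + "\n")
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return outdir


def score_against_truth(degs: pd.DataFrame, enrichments, report, truth) -> dict:
    """Recovery scorecard: DEG sensitivity / false-discovery proportion,
    planted-enriched-set ranks, and planted-hub core-regulator recovery."""
    up, down = split_by_direction(degs)
    called = up | down
    true_degs = truth.deg_ids & set(degs.index)
    tp = len(called & true_degs)
    scorecard: dict = {
        "deg_sensitivity": tp / len(true_degs) if true_degs else None,
        "deg_fdp": (len(called) - tp) / len(called) if called else 0.0,
        "deg_called": len(called),
        "deg_planted": len(true_degs),
    }
    ranks = {}
    for (kind, direction), res in (enrichments or {}).items():
        ordered = list(res["set_id"])
        ranks[f"{kind}_{direction}"] = {
            s: ordered.index(s) + 1 for s in truth.enriched_set_ids if s in ordered
        }
    scorecard["enriched_set_ranks"] = ranks
    if report is not None:
        hubs_in_report = sorted(truth.hub_ids & set(report.per_gene.index))
        scorecard["planted_hubs_in_network"] = hubs_in_report
        scorecard["planted_hubs_called"] = sorted(
            set(report.core_regulators()) & truth.hub_ids)
    return scorecard


def _versions() -> dict:
    import networkx
    import numpy
    import pandas
    import scipy
    return {
        "difconet": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
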