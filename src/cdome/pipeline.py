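"""File-level orchestration of the CDome analysis stages.

``run_pipeline`` executes the requested stages in dependency order —
simulate → triage / coverage → matrix summary → cluster / network /
enrich / half-life — on a single output directory, and returns a manifest
listing every produced artifact with its SHA-256 checksum.  All randomness
flows from one root seed: per-stage seeds are derived deterministically
with :class:`numpy.random.SeedSequence`, so a fixed seed yields
byte-identical artifacts and manifest across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from cdome import enrichment, litmining, simulate
from cdome.clustering import (
    adjusted_rand_index,
    agglomerate,
    cut_k,
    pairwise_distance,
    write_newick,
)
from cdome.expression import ExpressionMatrix, group_union, matrix_summary, to_binary
from cdome.halflife import HalfLifeTable, monte_carlo_subset_test, subset_means
from cdome.litmining import HitCountMatrix
from cdome.network import build_commonality_graph, write_gml

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("cdome.pipeline")

ALL_STAGES = ("simulate", "triage", "coverage", "matrix", "cluster", "network", "enrich", "halflife")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Parameters for every stage, plus the root seed.

    Stage-spec seeds are ignored in favour of seeds derived from ``seed``,
    so one integer reproduces the whole run.
    """

    seed: int = 0
    corpus: simulate.CorpusSpec = field(
        default_factory=lambda: simulate.CorpusSpec(n_pos=400, n_neg=400)
    )
    matrix: simulate.MatrixSpec = field(
        default_factory=lambda: simulate.MatrixSpec(cells_per_group=(6, 6, 5, 5, 5, 5, 5))
    )
    halflife: simulate.HalfLifeSpec = field(default_factory=simulate.HalfLifeSpec)
    # triage
    train_pos: int = 200
    train_neg: int = 200
    alpha: float = 1.0
    # clustering / network
    unknown_policy: str = "as_negative"
    metric: str = "euclidean"
    linkage: str = "complete"
    k: int = 7
    min_shared: int = 1
    # enrichment
    n_terms: int = 50
    planted_extra: int = 0  # noise genes added to the planted term
    min_term_size: int = 1
    # half-life test
    reps: int = 10_000
    tail: str = "two-sided"
    aggregator: str = "arithmetic"
    # hit counts
    mean_hits: float = 30.0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML/JSON config with per-stage sections; kwargs override."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        kwargs = {}
        for key, value in raw.items():
            if key == "corpus":
                kwargs[key] = simulate.CorpusSpec(**value)
            elif key == "matrix":
                if isinstance(value.get("cells_per_group"), list):
                    value = {**value, "cells_per_group": tuple(value["cells_per_group"])}
                kwargs[key] = simulate.MatrixSpec(**value)
            elif key == "halflife":
                kwargs[key] = simulate.HalfLifeSpec(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrix"]["cells_per_group"] = list(self.matrix.group_sizes)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    # one derived sub-seed per consumer of randomness, all < 2**31
    names = ("corpus", "matrix", "halflife", "hits", "annotation", "split", "mc")
    state = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(s) for s in state)))


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: RunConfig, out_dir: str | Path, stages: Sequence[str] = ALL_STAGES
) -> dict:
    """Run the requested stages and write ``manifest.json`` to ``out_dir``.

    Returns the manifest: seed, config, and for every artifact its relative
    path, byte size and SHA-256.  A stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are flagged as partial in the exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in ALL_STAGES if s in stages]
    if any(s != "simulate" for s in stages) and "simulate" not in stages:
        raise ValueError("every analysis stage depends on 'simulate'")

    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, Path] = {}
    state: dict = {}

    def record(name: str, path: Path) -> None:
        artifacts[name] = path

    for stage in stages:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, seeds, out, state, record)
        except Exception as exc:  # noqa: BLE001 — re-raised with stage context
            partial = sorted(str(p.relative_to(out)) for p in artifacts.values())
            raise PipelineError(
                f"stage {stage!r} failed: {exc}; partial outputs: {partial}"
            ) from exc
        logger.info("stage %s finished in %.2fs (seed %d)", stage, time.perf_counter() - t0, config.seed)

    manifest = {
        "seed": config.seed,
        "config": config.as_dict(),
        "artifacts": {
            name: {
                "path": str(path.relative_to(out)),
                "bytes": path.stat().st_size,
                "sha256": _sha256(path),
            }
            for name, path in sorted(artifacts.items())
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# -- stages ------------------------------------------------------------------


def _stage_simulate(config: RunConfig, seeds, out: Path, state: dict, record) -> None:
    corpus = simulate.simulate_corpus(
        dataclasses.replace(config.corpus, seed=seeds["corpus"])
    )
    litmining.write_corpus(corpus.records, out / "corpus.tsv")
    record("corpus", out / "corpus.tsv")

    sim = simulate.simulate_expression_matrix(
        dataclasses.replace(config.matrix, seed=seeds["matrix"])
    )
    sim.matrix.to_tsv(out / "expression_matrix.tsv")
    record("expression_matrix", out / "expression_matrix.tsv")

    hits = simulate.simulate_hit_counts(sim, mean_hits=config.mean_hits, seed=seeds["hits"])
    hits.to_tsv(out / "hit_counts.tsv")
    record("hit_counts", out / "hit_counts.tsv")

    table, subset = simulate.simulate_halflife_table(
        dataclasses.replace(config.halflife, seed=seeds["halflife"])
    )
    table.to_tsv(out / "halflife_table.tsv")
    record("halflife_table", out / "halflife_table.tsv")

    markers = sim.matrix.molecules
    annotation = simulate.simulate_annotation(
        genes=markers,
        n_terms=config.n_terms,
        planted_term_size=len(sim.core_markers[0]) + config.planted_extra,
        planted_set=sim.core_markers[0],
        seed=seeds["annotation"],
    )
    enrichment.write_annotation_tsv(annotation, out / "annotation.tsv")
    record("annotation", out / "annotation.tsv")

    truth = {
        "corpus": corpus.ground_truth(),
        "matrix": sim.ground_truth(),
        "halflife_subset": subset,
    }
    simulate.write_ground_truth(truth, out / "ground_truth.json")
    record("ground_truth", out / "ground_truth.json")

    state.update(corpus=corpus, sim=sim, hits=hits, table=table, subset=subset, annotation=annotation)


def _stage_triage(config: RunConfig, seeds, out: Path, state: dict, record) -> None:
    records = state["corpus"].records
    pos = [r for r in records if r.label is litmining.Label.POSITIVE]
    neg = [r for r in records if r.label is litmining.Label.NEGATIVE]
    if len(pos) < config.train_pos + 1 or len(neg) < config.train_neg + 1:
        raise ValueError(
            f"corpus too small for a {config.train_pos}+{config.train_neg} training draw "
            "with a non-empty held-out set"
        )
    rng = np.random.default_rng(seeds["split"])
    pos_idx = rng.permutation(len(pos))
    neg_idx = rng.permutation(len(neg))
    train = [pos[i] for i in pos_idx[: config.train_pos]] + [
        neg[i] for i in neg_idx[: config.train_neg]
    ]
    held = [pos[i] for i in pos_idx[config.train_pos :]] + [
        neg[i] for i in neg_idx[config.train_neg :]
    ]
    model = litmining.train_nb(train, alpha=config.alpha)
    metrics = litmining.evaluate(model, held)
    _write_json(
        {"train_size": len(train), "held_out_size": len(held), **metrics.as_dict()},
        out / "triage_metrics.json",
    )
    record("triage_metrics", out / "triage_metrics.json")
    state["triage_metrics"] = metrics


def _stage_coverage(config: RunConfig, seeds, out: Path, state: dict, record) -> None:
    hits: HitCountMatrix = state["hits"]
    cov = litmining.coverage_fraction(hits)
    _write_json(
        {"numerator": cov.numerator, "denominator": cov.denominator, "fraction": cov.fraction},
        out / "coverage.json",
    )
    record("coverage", out / "coverage.json")
    ranking = litmining.rank_cells(hits)
    ranking.to_csv(out / "cell_ranking.tsv", sep="\t", index=False, lineterminator="\n")
    record("cell_ranking", out / "cell_ranking.tsv")
    state["coverage"] = cov


def _stage_matrix(config: RunConfig, seeds, out: Path, state: dict, record) -> None:
    summary = matrix_summary(state["sim"].matrix)
    _write_json(summary.as_dict(), out / "matrix_summary.json")
    record("matrix_summary", out / "matrix_summary.json")


def _stage_cluster(config: RunConfig, seeds, out: Path, state: dict, record) -> None:
    sim = state["sim"]
    grid, cells, _markers = to_binary(sim.matrix, config.unknown_policy)
    D = pairwise_distance(grid, metric=config.metric)
    dendro = agglomerate(D, linkage=config.linkage, leaves=cells)
    write_newick(dendro, out / "dendrogram.nwk")
    record("dendrogram", out / "dendrogram.nwk")

    labels = cut_k(dendro, config.k)
    with open(out / "clusters.tsv", "w", encoding="utf-8") as fh:
        fh.write("cell\tcluster\n")
        for cell, lab in zip(cells, labels):
            fh.write(f"{cell}\t{lab}\n")
    record("clusters", out / "clusters.tsv")

    truth = [sim.labels[c] for c in cells]
    ari = adjusted_rand_index(truth, labels)
    _write_json(
        {"k": config.k, "metric": config.metric, "linkage": config.linkage, "ari_vs_planted": ari},
        out / "cluster_recovery.json",
    )
    record("cluster_recovery", out / "cluster_recovery.json")
    state["cluster_labels"] = dict(zip(cells, (int(v) for v in labels)))
    state["cluster_ari"] = ari


def _stage_network(config: RunConfig, seeds, out: Path, state: dict, record) -> None:
    graph = build_commonality_graph(
        state["sim"].matrix,
        min_shared=config.min_shared,
        cluster_labels=state.get("cluster_labels"),
        unknown_policy=config.unknown_policy,
    )
    write_gml(graph, out / "commonality.gml")
    record("commonality_graph", out / "commonality.gml")
    state["graph"] = graph


def _stage_enrich(config: RunConfig, seeds, out: Path, state: dict, record) -> None:
    sim = state["sim"]
    grouping: dict[str, list[str]] = {}
    for cell, g in sim.labels.items():
        grouping.setdefault(f"group{g + 1}", []).append(cell)
    unions = group_union(sim.matrix, grouping)
    background = enrichment.GeneSet("all_markers", frozenset(sim.matrix.molecules))
    enrichment.write_gmt(
        [enrichment.GeneSet(name, frozenset(genes)) for name, genes in sorted(unions.items())],
        out / "group_unions.gmt",
    )
    record("group_unions", out / "group_unions.gmt")

    query = enrichment.GeneSet("group1", frozenset(unions["group1"]))
    rows = enrichment.enrich(query, background, state["annotation"], config.min_term_size)
    enrichment.write_enrichment_tsv(rows, out / "enrichment.tsv")
    record("enrichment", out / "enrichment.tsv")
    state["enrichment_rows"] = rows


def _stage_halflife(config: RunConfig, seeds, out: Path, state: dict, record) -> None:
    table: HalfLifeTable = state["table"]
    subset = state["subset"]
    mrna_mean, protein_mean = subset_means(table, subset, config.aggregator)
    result = monte_carlo_subset_test(
        table,
        subset,
        reps=config.reps,
        tail=config.tail,
        aggregator=config.aggregator,
        seed=seeds["mc"],
    )
    result.to_json(out / "halflife_mc.json")
    record("halflife_mc", out / "halflife_mc.json")
    state["halflife_result"] = result
    state["halflife_means"] = (mrna_mean, protein_mean)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "triage": _stage_triage,
    "coverage": _stage_coverage,
    "matrix": _stage_matrix,
    "cluster": _stage_cluster,
    "network": _stage_network,
    "enrich": _stage_enrich,
    "halflife": _stage_halflife,
}
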