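"""Synthetic generators for every pipeline input, with retained ground truth.

The curated inputs of a CDome study — a manually labeled abstract corpus, a
cells × CD-molecule call matrix, a per-gene half-life table and term
annotations — are not publicly deposited.  These generators produce
structurally faithful stand-ins:

* abstracts as bag-of-words draws from class-conditional multinomials, the
  same family the triage classifier assumes, so recovery is analytically
  predictable;
* block-structured marker matrices with one private POSITIVE core per
  lineage group, plus flip noise and UNKNOWN masking;
* log-normal half-lives (positive support, right-skewed) with a planted
  subset whose geometric means are shifted;
* flat term annotations with one planted enriched term over uniform noise.

Each generator is driven by a single integer seed through one
``numpy.random.Generator`` in documented draw order, and returns its ground
truth (labels, pre-noise matrix, subset ids) so downstream recovery tests
never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cdome.enrichment import AnnotationMap
from cdome.expression import ExpressionMatrix, Status
from cdome.halflife import HalfLifeTable
from cdome.litmining import AbstractRecord, HitCountMatrix, Label

__all__ = [
    "CorpusSpec",
    "MatrixSpec",
    "HalfLifeSpec",
    "SimulatedCorpus",
    "SimulatedMatrix",
    "simulate_corpus",
    "simulate_expression_matrix",
    "simulate_halflife_table",
    "simulate_annotation",
    "simulate_hit_counts",
]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


# -- corpus ------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusSpec:
    """Conditions for the labeled abstract corpus.

    ``signal_strength`` is the odds multiplier applied to the designated
    signal words in the positive class; 1 means the classes are identical
    and triage cannot beat chance.
    """

    n_pos: int = 200
    n_neg: int = 200
    vocab_size: int = 2000
    n_signal_words: int = 50
    signal_strength: float = 8.0
    doc_length: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_pos >= 0, f"n_pos must be >= 0, got {self.n_pos}")
        _require(self.n_neg >= 0, f"n_neg must be >= 0, got {self.n_neg}")
        _require(self.vocab_size > 0, f"vocab_size must be > 0, got {self.vocab_size}")
        _require(self.n_signal_words > 0, f"n_signal_words must be > 0, got {self.n_signal_words}")
        _require(
            self.n_signal_words <= self.vocab_size,
            f"n_signal_words ({self.n_signal_words}) must not exceed vocab_size ({self.vocab_size})",
        )
        _require(self.signal_strength >= 1, f"signal_strength must be >= 1, got {self.signal_strength}")
        _require(self.doc_length > 0, f"doc_length must be > 0, got {self.doc_length}")


@dataclass
class SimulatedCorpus:
    records: list[AbstractRecord]
    signal_words: list[str]
    vocab: list[str]
    spec: CorpusSpec

    def ground_truth(self) -> dict:
        return {
            "signal_words": self.signal_words,
            "labels": {r.id: r.label.value for r in self.records},
            "spec": asdict(self.spec),
        }


def simulate_corpus(spec: CorpusSpec) -> SimulatedCorpus:
    """Generate exactly ``n_pos`` positive and ``n_neg`` negative abstracts.

    Both classes draw tokens from a multinomial over ``vocab_size`` words;
    the positive class up-weights the first ``n_signal_words`` words by
    ``signal_strength`` (renormalised).  Document lengths are Poisson with
    mean ``doc_length``, floored at 1 token.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = [f"w{i:05d}" for i in range(spec.vocab_size)]
    signal_words = vocab[: spec.n_signal_words]

    base = np.full(spec.vocab_size, 1.0 / spec.vocab_size)
    pos = base.copy()
    pos[: spec.n_signal_words] *= spec.signal_strength
    pos /= pos.sum()

    vocab_arr = np.array(vocab)
    records: list[AbstractRecord] = []
    # draw order: all positives first, then all negatives
    for label, n_docs, probs in (
        (Label.POSITIVE, spec.n_pos, pos),
        (Label.NEGATIVE, spec.n_neg, base),
    ):
        for i in range(n_docs):
            length = max(1, int(rng.poisson(spec.doc_length)))
            tokens = vocab_arr[rng.choice(spec.vocab_size, size=length, p=probs)]
            records.append(
                AbstractRecord(id=f"{label.value[:3]}-{i:05d}", text=" ".join(tokens), label=label)
            )
    return SimulatedCorpus(records=records, signal_words=signal_words, vocab=vocab, spec=spec)


# -- expression matrix -------------------------------------------------------


@dataclass(frozen=True)
class MatrixSpec:
    """Conditions for the planted-lineage ternary expression matrix.

    ``cells_per_group`` is either a single count applied to every group or a
    per-group sequence (e.g. ``(6, 6, 5, 5, 5, 5, 5)`` for a 37-cell study
    with 7 groups).  Each group owns a private core of
    ``round(core_frac * n_markers)`` markers POSITIVE on all its cells;
    everything else is NEGATIVE before noise.  Calls are then flipped with
    probability ``flip_noise`` and masked UNKNOWN with probability
    ``missing_rate``.
    """

    n_groups: int = 7
    cells_per_group: int | tuple[int, ...] = 5
    n_markers: int = 261
    core_frac: float = 0.1
    flip_noise: float = 0.05
    missing_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_groups > 0, f"n_groups must be > 0, got {self.n_groups}")
        _require(self.n_markers > 0, f"n_markers must be > 0, got {self.n_markers}")
        sizes = self.group_sizes
        _require(all(s > 0 for s in sizes), f"cells_per_group entries must be > 0, got {sizes}")
        _require(
            len(sizes) == self.n_groups,
            f"cells_per_group has {len(sizes)} entries for n_groups={self.n_groups}",
        )
        for name in ("core_frac", "flip_noise", "missing_rate"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")
        _require(
            self.n_groups == 1 or self.core_size > 0,
            "core_frac yields core size 0: groups would be indistinguishable",
        )
        _require(
            self.n_groups * self.core_size <= self.n_markers,
            f"n_groups x core size ({self.n_groups}x{self.core_size}) exceeds n_markers ({self.n_markers})",
        )

    @property
    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.cells_per_group, int):
            return (self.cells_per_group,) * self.n_groups
        return tuple(self.cells_per_group)

    @property
    def core_size(self) -> int:
        return int(round(self.core_frac * self.n_markers))


@dataclass
class SimulatedMatrix:
    matrix: ExpressionMatrix
    labels: dict[str, int]  # cell -> planted group index
    truth: pd.DataFrame  # pre-noise 0/1 grid
    core_markers: dict[int, list[str]]
    spec: MatrixSpec

    def ground_truth(self) -> dict:
        return {
            "labels": self.labels,
            "core_markers": {str(g): m for g, m in self.core_markers.items()},
            "spec": {**asdict(self.spec), "cells_per_group": list(self.spec.group_sizes)},
        }


def simulate_expression_matrix(spec: MatrixSpec) -> SimulatedMatrix:
    """Plant lineage blocks, then apply flip noise and UNKNOWN masking.

    Draw order: one flip mask over the whole grid, then one missingness
    mask.  The pre-noise grid and group labels are retained as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.group_sizes
    n_cells = sum(sizes)
    cells = []
    labels: dict[str, int] = {}
    for g, size in enumerate(sizes):
        for i in range(size):
            name = f"G{g + 1}_cell{i + 1:02d}"
            cells.append(name)
            labels[name] = g
    markers = [f"CD{j + 1}" for j in range(spec.n_markers)]

    truth = np.zeros((n_cells, spec.n_markers), dtype=np.int8)
    core_markers: dict[int, list[str]] = {}
    row = 0
    for g, size in enumerate(sizes):
        lo, hi = g * spec.core_size, (g + 1) * spec.core_size
        truth[row : row + size, lo:hi] = 1
        core_markers[g] = markers[lo:hi]
        row += size

    flips = rng.random(truth.shape) < spec.flip_noise
    noisy = np.where(flips, 1 - truth, truth)
    missing = rng.random(truth.shape) < spec.missing_rate
    calls = np.where(missing, Status.UNKNOWN.value, noisy).astype(np.int8)

    matrix = ExpressionMatrix(pd.DataFrame(calls, index=cells, columns=markers))
    truth_df = pd.DataFrame(truth, index=cells, columns=markers)
    return SimulatedMatrix(
        matrix=matrix, labels=labels, truth=truth_df, core_markers=core_markers, spec=spec
    )


def simulate_hit_counts(
    sim: SimulatedMatrix, mean_hits: float = 30.0, seed: int = 0
) -> HitCountMatrix:
    """Literature hit counts consistent with a simulated matrix.

    Examined pairs (non-UNKNOWN calls) receive at least one hit, with
    geometrically distributed extra hits of mean ``mean_hits`` — a heavy
    right tail echoing how citation counts concentrate on a few well-studied
    pairs.  Unexamined pairs receive zero hits.
    """
    _require(mean_hits >= 1, f"mean_hits must be >= 1, got {mean_hits}")
    rng = np.random.default_rng(seed)
    grid = sim.matrix.calls.to_numpy()
    examined = grid != Status.UNKNOWN.value
    extra = rng.geometric(p=min(1.0, 1.0 / mean_hits), size=grid.shape)
    counts = np.where(examined, extra, 0)
    return HitCountMatrix(
        pd.DataFrame(counts, index=sim.matrix.cells, columns=sim.matrix.molecules)
    )


# -- half-lives --------------------------------------------------------------


@dataclass(frozen=True)
class HalfLifeSpec:
    """Conditions for the per-gene half-life table.

    Half-lives are log-normal; the ``*_mean_h`` parameters are geometric
    means (the exponential of the log-mean), in hours.  A planted subset of
    ``subset_size`` genes is drawn with its own means — by default the
    CD-like regime of fast protein turnover (16 h) against a slow global
    background (46 h).
    """

    n_genes: int = 5000
    subset_size: int = 30
    global_mrna_mean_h: float = 9.0
    global_protein_mean_h: float = 46.0
    subset_mrna_mean_h: float = 18.0
    subset_protein_mean_h: float = 16.0
    log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes > 0, f"n_genes must be > 0, got {self.n_genes}")
        _require(self.subset_size >= 0, f"subset_size must be >= 0, got {self.subset_size}")
        _require(
            self.subset_size <= self.n_genes,
            f"subset_size ({self.subset_size}) must not exceed n_genes ({self.n_genes})",
        )
        for name in (
            "global_mrna_mean_h",
            "global_protein_mean_h",
            "subset_mrna_mean_h",
            "subset_protein_mean_h",
        ):
            _require(getattr(self, name) > 0, f"{name} must be > 0, got {getattr(self, name)}")
        _require(self.log_sd >= 0, f"log_sd must be >= 0, got {self.log_sd}")


def simulate_halflife_table(spec: HalfLifeSpec) -> tuple[HalfLifeTable, list[str]]:
    """Generate the half-life table and return it with the planted subset ids.

    Draw order: subset gene indices (without replacement), then mRNA
    log-deviates for all genes, then protein log-deviates.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]
    subset_idx = np.sort(rng.choice(spec.n_genes, size=spec.subset_size, replace=False))
    in_subset = np.zeros(spec.n_genes, dtype=bool)
    in_subset[subset_idx] = True

    mrna_mu = np.where(
        in_subset, np.log(spec.subset_mrna_mean_h), np.log(spec.global_mrna_mean_h)
    )
    protein_mu = np.where(
        in_subset, np.log(spec.subset_protein_mean_h), np.log(spec.global_protein_mean_h)
    )
    mrna = np.exp(mrna_mu + spec.log_sd * rng.standard_normal(spec.n_genes))
    protein = np.exp(protein_mu + spec.log_sd * rng.standard_normal(spec.n_genes))

    table = HalfLifeTable(
        pd.DataFrame({"gene": genes, "mrna_halflife_h": mrna, "protein_halflife_h": protein})
    )
    subset_genes = [genes[i] for i in subset_idx]
    return table, subset_genes


# -- annotations -------------------------------------------------------------


def simulate_annotation(
    genes: Sequence[str],
    n_terms: int,
    planted_term_size: int,
    planted_set: Sequence[str],
    seed: int = 0,
    background_term_size: tuple[int, int] = (5, 50),
) -> AnnotationMap:
    """Flat term annotations with one planted enriched term.

    ``n_terms`` background terms each annotate a uniform random gene subset
    whose size is uniform on ``background_term_size``; the planted term
    (named ``T_planted``) covers ``planted_set`` padded with random noise
    genes up to ``planted_term_size``.  Draw order: background term sizes
    and members in term order, then the planted term's padding.
    """
    genes = list(genes)
    planted_set = list(planted_set)
    missing = sorted(set(planted_set) - set(genes))
    _require(not missing, f"planted_set genes absent from the universe: {missing}")
    _require(
        planted_term_size >= len(planted_set),
        f"planted_term_size ({planted_term_size}) smaller than planted_set ({len(planted_set)})",
    )
    _require(planted_term_size <= len(genes), "planted_term_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes)

    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    lo, hi = background_term_size
    hi = min(hi, len(genes))
    lo = min(lo, hi)
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = gene_arr[rng.choice(len(genes), size=size, replace=False)]
        name = f"T{t:04d}"
        terms[name] = frozenset(members)
        descriptions[name] = f"background term {t}"

    if planted_set:
        pool = sorted(set(genes) - set(planted_set))
        n_noise = planted_term_size - len(planted_set)
        noise = list(np.array(pool)[rng.choice(len(pool), size=n_noise, replace=False)]) if n_noise else []
        terms["T_planted"] = frozenset(planted_set) | frozenset(noise)
        descriptions["T_planted"] = "planted enriched term"
    return AnnotationMap(terms=terms, descriptions=descriptions)


# -- sidecar serialization ---------------------------------------------------


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Serialize generator ground truth as a JSON sidecar (sorted keys)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
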