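"""Literature-corpus triage and knowledge-gap mapping.

Covers three stages of the literature workflow:

1. Query construction — one ``"<cell> AND <molecule>"`` query per
   (cell-or-alias, molecule-or-alias) pair, for downstream PubMed counting.
   No live client is included; hit counts enter as a :class:`HitCountMatrix`
   file so the analysis is deterministic and network-free.
2. Abstract triage — a multinomial naive Bayes classifier with additive
   (Laplace) smoothing over a shared vocabulary, trained on labeled
   abstracts and applied to unlabeled ones.  Ties break toward POSITIVE:
   predicted positives are reviewed manually downstream, so a false positive
   costs a little reviewer time while a false negative loses data.
3. Coverage mapping — what fraction of all (cell, marker) pairs has any
   literature at all, per-cell characterization rankings, and the
   availability bands used for heat-map rendering.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cdome.expression import Registry

__all__ = [
    "Label",
    "AbstractRecord",
    "NBModel",
    "HitCountMatrix",
    "Metrics",
    "Coverage",
    "Band",
    "build_queries",
    "tokenize",
    "train_nb",
    "classify",
    "evaluate",
    "coverage_fraction",
    "rank_cells",
    "bin_hits",
    "read_corpus",
    "write_corpus",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class Label(str, enum.Enum):
    POSITIVE = "positive"  # abstract contains CD expression data
    NEGATIVE = "negative"


@dataclass(frozen=True)
class AbstractRecord:
    """A PubMed-style abstract with an optional triage label."""

    id: str
    text: str
    label: Label | None = None

    def __post_init__(self) -> None:
        if self.label is not None and not self.text:
            raise ValueError(f"labeled record {self.id!r} must have non-empty text")


def tokenize(text: str) -> list[str]:
    """Lowercased maximal alphanumeric runs, order preserved.

    ``"CD8+ T cells"`` → ``["cd8", "t", "cells"]``.  Idempotent on its own
    space-joined output.
    """
    return _TOKEN_RE.findall(text.lower())


def build_queries(cells: Registry, molecules: Registry) -> list[str]:
    """One ``"<cell> AND <molecule>"`` query per label pair.

    Every alias of both the cell and the molecule is queried.  Order is
    deterministic: registry order, canonical name before aliases, molecule
    labels varying fastest.
    """
    queries = []
    for cell in cells:
        for cell_label in cell.labels:
            for mol in molecules:
                for mol_label in mol.labels:
                    queries.append(f"{cell_label} AND {mol_label}")
    return queries


# -- naive Bayes classifier --------------------------------------------------


@dataclass
class NBModel:
    """Two-class multinomial naive Bayes with additive smoothing.

    ``log_prior[c]`` and ``log_prob[c][j]`` (token j given class c) are kept
    in log space; exponentiated, each distribution sums to one.
    """

    vocab: dict[str, int]
    log_prior: dict[Label, float]
    log_prob: dict[Label, np.ndarray]
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("smoothing constant alpha must be > 0")


def train_nb(corpus: Iterable[AbstractRecord], alpha: float = 1.0) -> NBModel:
    """Fit the triage classifier on a labeled corpus.

    Priors come from class frequencies; token probabilities are class token
    counts with additive smoothing ``alpha`` over the union vocabulary.
    """
    if alpha <= 0:
        raise ValueError("smoothing constant alpha must be > 0")
    records = [r for r in corpus if r.label is not None]
    by_class: dict[Label, list[AbstractRecord]] = {Label.POSITIVE: [], Label.NEGATIVE: []}
    for rec in records:
        by_class[rec.label].append(rec)
    if not by_class[Label.POSITIVE] or not by_class[Label.NEGATIVE]:
        raise ValueError("training corpus must contain at least one record of each class")

    vocab: dict[str, int] = {}
    tokenized: dict[Label, list[list[str]]] = {}
    for label, recs in by_class.items():
        tokenized[label] = [tokenize(r.text) for r in recs]
        for toks in tokenized[label]:
            for tok in toks:
                vocab.setdefault(tok, len(vocab))

    n_total = len(records)
    log_prior = {label: math.log(len(recs) / n_total) for label, recs in by_class.items()}
    log_prob: dict[Label, np.ndarray] = {}
    v = len(vocab)
    for label in (Label.POSITIVE, Label.NEGATIVE):
        counts = np.zeros(v)
        for toks in tokenized[label]:
            for tok in toks:
                counts[vocab[tok]] += 1
        log_prob[label] = np.log(counts + alpha) - math.log(counts.sum() + alpha * v)
    return NBModel(vocab=vocab, log_prior=log_prior, log_prob=log_prob, alpha=alpha)


def classify(model: NBModel, record: AbstractRecord) -> tuple[Label, float]:
    """Label a record and return the posterior probability of POSITIVE.

    Joint log-likelihoods are accumulated under conditional token
    independence; out-of-vocabulary tokens carry no evidence.  An exact tie
    goes to POSITIVE.
    """
    scores: dict[Label, float] = {}
    for label in (Label.POSITIVE, Label.NEGATIVE):
        score = model.log_prior[label]
        lp = model.log_prob[label]
        for tok in tokenize(record.text):
            j = model.vocab.get(tok)
            if j is not None:
                score += lp[j]
        scores[label] = score
    # posterior in log space, stabilised by the max
    m = max(scores.values())
    exp = {label: math.exp(s - m) for label, s in scores.items()}
    posterior_pos = exp[Label.POSITIVE] / (exp[Label.POSITIVE] + exp[Label.NEGATIVE])
    label = Label.POSITIVE if scores[Label.POSITIVE] >= scores[Label.NEGATIVE] else Label.NEGATIVE
    return label, posterior_pos


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate(model: NBModel, records: Sequence[AbstractRecord]) -> Metrics:
    """Confusion counts and derived metrics on fully labeled records.

    POSITIVE is "contains CD expression data"; sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot evaluate on an empty record set")
    if any(r.label is None for r in records):
        raise ValueError("every evaluation record must be labeled")
    tp = fp = tn = fn = 0
    for rec in records:
        predicted, _ = classify(model, rec)
        if rec.label is Label.POSITIVE:
            if predicted is Label.POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if predicted is Label.NEGATIVE:
                tn += 1
            else:
                fp += 1
    total = tp + fp + tn + fn
    return Metrics(
        accuracy=(tp + tn) / total,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


# -- hit-count matrix and coverage -------------------------------------------


class HitCountMatrix:
    """Per (cell, molecule) literature hit counts for gap mapping."""

    def __init__(self, counts: pd.DataFrame):
        arr = counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("hit counts must be nonnegative")
        self.counts = counts.astype(np.int64)

    @property
    def cells(self) -> list[str]:
        return list(self.counts.index)

    @property
    def molecules(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HitCountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="cell", encoding="utf-8", lineterminator="\n")


@dataclass
class Coverage:
    """Exact rational coverage: pairs with literature / all pairs."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator


def coverage_fraction(hits: HitCountMatrix, threshold: int = 1) -> Coverage:
    """Fraction of (cell, molecule) pairs with at least ``threshold`` hits."""
    arr = hits.counts.to_numpy()
    if arr.size == 0:
        raise ValueError("coverage of an empty hit matrix is undefined")
    return Coverage(numerator=int((arr >= threshold).sum()), denominator=int(arr.size))


def rank_cells(hits: HitCountMatrix) -> pd.DataFrame:
    """Rank cells by characterization: molecules with ≥1 hit, then total hits.

    Ties break by cell name so the ranking is deterministic.
    """
    totals = hits.counts.sum(axis=1)
    n_mol = (hits.counts >= 1).sum(axis=1)
    table = pd.DataFrame(
        {"cell": hits.cells, "total_hits": totals.to_numpy(), "n_molecules_hit": n_mol.to_numpy()}
    )
    table = table.sort_values(
        by=["n_molecules_hit", "total_hits", "cell"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    return table


class Band(str, enum.Enum):
    """Availability bands for the heat-map rendering of hit counts."""

    NONE = "none"  # 0 hits
    LOW = "low"  # 1–9
    MID = "mid"  # 10–100, sub-banded light→dark
    HIGH = "high"  # 101–999
    TOP = "top"  # 1000+


def bin_hits(count: int) -> Band:
    """Map a hit count to its availability band."""
    if count < 0:
        raise ValueError(f"hit count must be nonnegative, got {count}")
    if count == 0:
        return Band.NONE
    if count < 10:
        return Band.LOW
    if count <= 100:
        return Band.MID
    if count < 1000:
        return Band.HIGH
    return Band.TOP


def mid_shade(count: int) -> float:
    """Position within the MID band on a light→dark 0–1 scale."""
    if bin_hits(count) is not Band.MID:
        raise ValueError(f"count {count} is not in the 10–100 band")
    return (count - 10) / 90


# -- corpus I/O --------------------------------------------------------------
# One record per line: id TAB label TAB text; label may be "?" for unlabeled.


def write_corpus(records: Iterable[AbstractRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            label = rec.label.value if rec.label is not None else "?"
            fh.write(f"{rec.id}\t{label}\t{rec.text}\n")


def read_corpus(path: str | Path) -> list[AbstractRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t", 2)
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label<TAB>text'")
            rec_id, label, text = parts
            records.append(
                AbstractRecord(
                    id=rec_id,
                    text=text,
                    label=None if label == "?" else Label(label),
                )
            )
    return records
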