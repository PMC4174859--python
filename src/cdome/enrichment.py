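"""Hypergeometric gene-set enrichment with Benjamini–Hochberg FDR control.

The test: a query set of ``n`` genes is drawn from a background of ``N``
genes of which ``B`` carry a term; the probability of observing ``b`` or
more term genes in the query is the upper tail of the hypergeometric
distribution,

    p = sum_{i=b}^{min(B, n)} C(B, i) C(N-B, n-i) / C(N, n),

computed stably in log space.  Only enrichment (the upper tail) is tested,
not depletion.  Per-term p-values are then adjusted by the
Benjamini–Hochberg step-up over the terms actually tested.

Annotations are flat term → gene-set maps; no ontology-graph propagation
(parent-term inheritance) is performed — a deliberate divergence from full
GO tooling, documented as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "GeneSet",
    "AnnotationMap",
    "EnrichmentRow",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "read_gmt",
    "write_gmt",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet.name must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class AnnotationMap:
    """Flat term → gene-set mapping with optional descriptions."""

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        if self.descriptions is None:
            self.descriptions = {}

    def description(self, term: str) -> str:
        return self.descriptions.get(term, "")

    def restrict_to(self, universe: Iterable[str]) -> "AnnotationMap":
        """Intersect every term's genes with a declared universe."""
        uni = frozenset(universe)
        return AnnotationMap(
            terms={t: g & uni for t, g in self.terms.items()},
            descriptions=dict(self.descriptions),
        )


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(N: int, B: int, n: int, b: int) -> float:
    """P[X >= b] for X ~ Hypergeometric(N, B, n), summed in log space.

    ``N``: background size; ``B``: background genes with the term; ``n``:
    query size; ``b``: query genes with the term.
    """
    if not (0 <= B <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: need 0 <= B <= N and 0 <= n <= N, got N={N}, B={B}, n={n}")
    if not (0 <= b <= min(n, B)):
        raise ValueError(f"inconsistent counts: need 0 <= b <= min(n, B), got b={b}, n={n}, B={B}")
    if b == 0:
        return 1.0
    # support of X given the margins: max(0, n - (N - B)) .. min(B, n)
    i = np.arange(b, min(B, n) + 1)
    i = i[n - i <= N - B]
    if len(i) == 0:
        return 0.0
    log_terms = _log_comb(B, i) + _log_comb(N - B, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, returned in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j``, capped at 1; ties keep a stable
    ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"p-values must lie in [0, 1], got {bad}")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentRow:
    """One tested term: counts, raw p and BH-adjusted q."""

    term: str
    description: str
    N: int  # background size
    B: int  # background genes with term
    n: int  # query size after intersection with background
    b: int  # query genes with term
    p: float
    q: float


def enrich(
    query: GeneSet,
    background: GeneSet,
    annotation: AnnotationMap,
    min_term_size: int = 1,
) -> list[EnrichmentRow]:
    """Test every annotation term for over-representation in the query.

    The query is silently intersected with the background (genes outside it
    are dropped with a warning — partial gene-name mapping is the norm for
    CD designations); terms with fewer than ``min_term_size`` background
    genes are not tested.  BH adjustment runs over the tested terms only.
    Rows are sorted by p, then term name.
    """
    if not background.genes:
        raise ValueError("background gene set must be non-empty")
    effective = query.genes & background.genes
    dropped = sorted(query.genes - background.genes)
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the background were dropped: {dropped[:10]}",
            stacklevel=2,
        )
    if not effective:
        raise ValueError(
            f"query/background intersection is empty; dropped genes: {dropped}"
        )

    N = len(background.genes)
    n = len(effective)
    rows: list[EnrichmentRow] = []
    for term in sorted(annotation.terms):
        term_genes = annotation.terms[term] & background.genes
        B = len(term_genes)
        if B < min_term_size:
            continue
        b = len(term_genes & effective)
        p = hypergeom_upper_tail(N, B, n, b)
        rows.append(
            EnrichmentRow(
                term=term,
                description=annotation.description(term),
                N=N,
                B=B,
                n=n,
                b=b,
                p=p,
                q=float("nan"),
            )
        )
    qs = bh_adjust([r.p for r in rows])
    for row, q in zip(rows, qs):
        row.q = float(q)
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


# -- file formats ------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT format (name TAB description TAB genes...)."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            sets.append(GeneSet(name=parts[0], genes=frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            desc = descriptions.get(gs.name, "")
            fh.write("\t".join([gs.name, desc, *sorted(gs.genes)]) + "\n")


def read_annotation_tsv(path: str | Path) -> AnnotationMap:
    """Read a two-column (gene TAB term) annotation file."""
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            gene, term = parts
            terms.setdefault(term, set()).add(gene)
    return AnnotationMap(terms={t: frozenset(g) for t, g in terms.items()})


def write_annotation_tsv(annotation: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(annotation.terms):
            for gene in sorted(annotation.terms[term]):
                fh.write(f"{gene}\t{term}\n")


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    """Write results in the tabular layout of standard enrichment reports."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tdescription\tp\tfdr_q\tb\tn\tB\tN\n")
        for r in rows:
            fh.write(
                f"{r.term}\t{r.description}\t{r.p:.6g}\t{r.q:.6g}\t{r.b}\t{r.n}\t{r.B}\t{r.N}\n"
            )
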