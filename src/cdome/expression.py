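"""Central data model: cell and CD-molecule registries and the ternary expression matrix.

The matrix is deliberately ternary rather than binary: a (cell, marker) pair
that has never been examined is UNKNOWN, not NEGATIVE.  Missingness is the
object of study in knowledge-gap mapping, so the distinction is preserved
everywhere and collapsed only explicitly, via :func:`to_binary` with a named
policy.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Status",
    "CellType",
    "CDMolecule",
    "Registry",
    "ExpressionCall",
    "ExpressionMatrix",
    "MatrixDialect",
    "MatrixSummary",
    "load_matrix",
    "write_matrix",
    "to_binary",
    "group_union",
    "matrix_summary",
    "load_cell_registry",
    "write_cell_registry",
    "load_molecule_registry",
    "write_molecule_registry",
]


class Status(enum.IntEnum):
    """Ternary expression call. UNKNOWN means "never examined", not "absent"."""

    NEGATIVE = 0
    POSITIVE = 1
    UNKNOWN = -1


@dataclass(frozen=True)
class CellType:
    """A hematopoietic cell type with aliases, lineage group and disease state."""

    name: str
    aliases: frozenset[str] = frozenset()
    group: str = "ungrouped"
    disease_state: str = "healthy"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("CellType.name must be non-empty")
        object.__setattr__(self, "aliases", frozenset(self.aliases))
        lowered = {a.lower() for a in self.aliases}
        if self.name.lower() in lowered:
            raise ValueError(f"cell name {self.name!r} must not appear among its own aliases")
        if self.disease_state not in ("healthy", "malignant"):
            raise ValueError(f"disease_state must be 'healthy' or 'malignant', got {self.disease_state!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        """Canonical name first, then aliases in sorted order."""
        return (self.name, *sorted(self.aliases))


@dataclass(frozen=True)
class CDMolecule:
    """A CD designation (e.g. CD52), optionally mapped to a gene name."""

    cd_id: str
    gene_name: str | None = None
    aliases: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cd_id:
            raise ValueError("CDMolecule.cd_id must be non-empty")
        object.__setattr__(self, "aliases", frozenset(self.aliases))

    @property
    def labels(self) -> tuple[str, ...]:
        return (self.cd_id, *sorted(self.aliases))


class Registry:
    """Ordered collection of named entries with case-insensitive alias lookup.

    Alias resolution is exact (after lowercasing); there is no fuzzy matching,
    so resolution is deterministic and testable.
    """

    def __init__(self, entries: Iterable[CellType | CDMolecule]):
        self.entries: list = list(entries)
        self._by_label: dict[str, object] = {}
        seen: set[str] = set()
        for entry in self.entries:
            canonical = entry.labels[0]
            if canonical.lower() in seen:
                raise ValueError(f"duplicate registry entry {canonical!r}")
            seen.add(canonical.lower())
            for label in entry.labels:
                self._by_label.setdefault(label.lower(), entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def resolve(self, label: str):
        """Return the entry whose canonical name or alias matches ``label``."""
        try:
            return self._by_label[label.lower()]
        except KeyError:
            raise KeyError(f"label {label!r} not found in registry") from None

    @property
    def names(self) -> list[str]:
        return [e.labels[0] for e in self.entries]


@dataclass(frozen=True)
class ExpressionCall:
    """One curated data point: a marker's status on a cell, with provenance."""

    cell: str
    molecule: str
    status: Status
    fraction: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.fraction is not None:
            if self.status is Status.UNKNOWN:
                raise ValueError("a fraction cannot accompany an UNKNOWN call")
            if not 0.0 <= self.fraction <= 1.0:
                raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class MatrixDialect:
    """Tokens used to encode calls in TSV files (overridable)."""

    positive: str = "1"
    negative: str = "0"
    unknown: str = "NA"

    def to_status(self) -> dict[str, Status]:
        return {
            self.positive: Status.POSITIVE,
            self.negative: Status.NEGATIVE,
            self.unknown: Status.UNKNOWN,
        }

    def from_status(self) -> dict[Status, str]:
        return {v: k for k, v in self.to_status().items()}


@dataclass
class MatrixSummary:
    n_cells: int
    n_molecules: int
    n_data_points: int  # non-UNKNOWN calls
    n_positive: int
    n_negative: int
    n_sources: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class ExpressionMatrix:
    """Cells × CD molecules grid of ternary calls.

    Parameters
    ----------
    calls
        DataFrame with cell names as index, molecule ids as columns and
        values in ``{-1, 0, 1}`` (:class:`Status` codes).
    cell_registry, molecule_registry
        Optional registries carrying aliases/groups; orders must match the
        grid axes when provided.
    records
        Optional list of the underlying :class:`ExpressionCall` data points
        (provenance); used for source counting only.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        cell_registry: Registry | None = None,
        molecule_registry: Registry | None = None,
        records: Sequence[ExpressionCall] | None = None,
    ):
        calls = calls.astype(np.int8)
        if calls.index.duplicated().any():
            dups = sorted(calls.index[calls.index.duplicated()].unique())
            raise ValueError(f"duplicate cell labels: {dups}")
        if calls.columns.duplicated().any():
            dups = sorted(calls.columns[calls.columns.duplicated()].unique())
            raise ValueError(f"duplicate molecule labels: {dups}")
        bad = ~np.isin(calls.to_numpy(), [s.value for s in Status])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid status code at cell {calls.index[i]!r}, molecule {calls.columns[j]!r}"
            )
        if cell_registry is not None and cell_registry.names != list(calls.index):
            raise ValueError("cell registry order does not match matrix rows")
        if molecule_registry is not None and molecule_registry.names != list(calls.columns):
            raise ValueError("molecule registry order does not match matrix columns")
        self.calls = calls
        self.cell_registry = cell_registry
        self.molecule_registry = molecule_registry
        self.records = list(records) if records is not None else None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        records: Iterable[ExpressionCall],
        cells: Sequence[str],
        molecules: Sequence[str],
    ) -> "ExpressionMatrix":
        """Build a matrix from individual data points; unlisted pairs are UNKNOWN.

        Duplicate (cell, molecule) entries are rejected.
        """
        records = list(records)
        grid = pd.DataFrame(
            np.full((len(cells), len(molecules)), Status.UNKNOWN.value, dtype=np.int8),
            index=list(cells),
            columns=list(molecules),
        )
        seen: set[tuple[str, str]] = set()
        for rec in records:
            key = (rec.cell, rec.molecule)
            if key in seen:
                raise ValueError(f"duplicate entry for cell {rec.cell!r}, molecule {rec.molecule!r}")
            seen.add(key)
            grid.loc[rec.cell, rec.molecule] = rec.status.value
        return cls(grid, records=records)

    # -- basic properties --------------------------------------------------

    @property
    def cells(self) -> list[str]:
        return list(self.calls.index)

    @property
    def molecules(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.calls.equals(other.calls)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, dialect: MatrixDialect = MatrixDialect()) -> None:
        write_matrix(self, path, dialect)

    @classmethod
    def from_tsv(cls, path: str | Path, dialect: MatrixDialect = MatrixDialect()) -> "ExpressionMatrix":
        return load_matrix(path, dialect)


def load_matrix(path: str | Path, dialect: MatrixDialect = MatrixDialect()) -> ExpressionMatrix:
    """Read a ternary expression matrix from TSV.

    Layout: header row of molecule ids, first column of cell names, calls
    encoded with the dialect's tokens.  Malformed tokens and duplicate labels
    are rejected with coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    mapping = dialect.to_status()
    coded = pd.DataFrame(
        np.full(df.shape, Status.UNKNOWN.value, dtype=np.int8),
        index=df.index,
        columns=df.columns,
    )
    for token, status in mapping.items():
        coded = coded.where(df != token, status.value)
    unknown_tokens = ~df.isin(mapping.keys())
    if unknown_tokens.to_numpy().any():
        i, j = np.argwhere(unknown_tokens.to_numpy())[0]
        raise ValueError(
            f"malformed status token {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    return ExpressionMatrix(coded)


def write_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: MatrixDialect = MatrixDialect()
) -> None:
    """Write the matrix as UTF-8, newline-terminated TSV."""
    rev = dialect.from_status()
    out = matrix.calls.map(lambda v: rev[Status(v)])
    out.to_csv(path, sep="\t", index_label="cell", encoding="utf-8", lineterminator="\n")


def to_binary(
    matrix: ExpressionMatrix, unknown_policy: str = "as_negative"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Collapse the ternary grid to 0/1 under an explicit UNKNOWN policy.

    Policies
    --------
    ``as_negative``
        UNKNOWN → 0 (the conservative default for clustering).
    ``drop_marker``
        Remove every molecule column containing an UNKNOWN call.
    ``drop_cell``
        Remove every cell row containing an UNKNOWN call.

    Returns the 0/1 grid together with the retained cell and molecule labels,
    so downstream labels stay aligned with the grid.
    """
    grid = matrix.calls.to_numpy()
    cells, molecules = matrix.cells, matrix.molecules
    unknown = grid == Status.UNKNOWN.value
    if unknown_policy == "as_negative":
        out = (grid == Status.POSITIVE.value).astype(np.int8)
    elif unknown_policy == "drop_marker":
        keep = ~unknown.any(axis=0)
        out = (grid[:, keep] == Status.POSITIVE.value).astype(np.int8)
        molecules = [m for m, k in zip(molecules, keep) if k]
    elif unknown_policy == "drop_cell":
        keep = ~unknown.any(axis=1)
        out = (grid[keep, :] == Status.POSITIVE.value).astype(np.int8)
        cells = [c for c, k in zip(cells, keep) if k]
    else:
        raise ValueError(f"unknown_policy must be as_negative|drop_marker|drop_cell, got {unknown_policy!r}")
    if out.size == 0 and grid.size > 0:
        raise ValueError(f"policy {unknown_policy!r} leaves an empty grid")
    return out, cells, molecules


def group_union(
    matrix: ExpressionMatrix, grouping: Mapping[str, Sequence[str]]
) -> dict[str, set[str]]:
    """Union of markers POSITIVE on at least one cell of each group.

    These unions serve as the gene sets for lineage-group enrichment.
    UNKNOWN never contributes; a group with no member cells yields an empty
    set with a warning.
    """
    unions: dict[str, set[str]] = {}
    for group, members in grouping.items():
        missing = [c for c in members if c not in matrix.calls.index]
        if missing:
            raise KeyError(f"group {group!r} references cells absent from the matrix: {missing}")
        if len(members) == 0:
            warnings.warn(f"group {group!r} has no member cells; union is empty", stacklevel=2)
            unions[group] = set()
            continue
        sub = matrix.calls.loc[list(members)]
        positive = (sub == Status.POSITIVE.value).any(axis=0)
        unions[group] = set(positive.index[positive])
    return unions


def matrix_summary(matrix: ExpressionMatrix) -> MatrixSummary:
    """Exact counts of cells, molecules, data points (non-UNKNOWN calls) and sources."""
    grid = matrix.calls.to_numpy()
    n_pos = int((grid == Status.POSITIVE.value).sum())
    n_neg = int((grid == Status.NEGATIVE.value).sum())
    sources = (
        {r.source_id for r in matrix.records if r.source_id} if matrix.records is not None else set()
    )
    return MatrixSummary(
        n_cells=matrix.shape[0],
        n_molecules=matrix.shape[1],
        n_data_points=n_pos + n_neg,
        n_positive=n_pos,
        n_negative=n_neg,
        n_sources=len(sources),
    )


# -- registry TSV I/O -------------------------------------------------------
# Format: one entry per line; aliases pipe-separated; UTF-8, newline-terminated.


def write_cell_registry(registry: Registry, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\taliases\tgroup\tdisease_state\n")
        for cell in registry:
            fh.write(
                f"{cell.name}\t{'|'.join(sorted(cell.aliases))}\t{cell.group}\t{cell.disease_state}\n"
            )


def load_cell_registry(path: str | Path) -> Registry:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cells = [
        CellType(
            name=row["name"],
            aliases=frozenset(a for a in row["aliases"].split("|") if a),
            group=row["group"] or "ungrouped",
            disease_state=row["disease_state"] or "healthy",
        )
        for _, row in df.iterrows()
    ]
    return Registry(cells)


def write_molecule_registry(registry: Registry, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cd_id\tgene_name\taliases\n")
        for mol in registry:
            fh.write(f"{mol.cd_id}\t{mol.gene_name or ''}\t{'|'.join(sorted(mol.aliases))}\n")


def load_molecule_registry(path: str | Path) -> Registry:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mols = [
        CDMolecule(
            cd_id=row["cd_id"],
            gene_name=row["gene_name"] or None,
            aliases=frozenset(a for a in row["aliases"].split("|") if a),
        )
        for _, row in df.iterrows()
    ]
    return Registry(mols)
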