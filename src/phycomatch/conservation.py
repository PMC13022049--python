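"""Per-column identity/similarity over multiple alignments, and column maps.

Used to quantify how conserved the residues at αβ-dimer contact interfaces
are across cyanobacterial strains.  Identity is mean pairwise identity over
the non-gap residues in a column; similarity is the same count with matches
extended to a physicochemical class partition.  Columns and unaligned
positions are 1-based; gap characters '-' and '.' are both accepted ('.'
normalized to '-').
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import AlignIO

__all__ = [
    "GAP",
    "DEFAULT_SIMILARITY_CLASSES",
    "MultipleAlignment",
    "ConservationSummary",
    "map_position",
    "position_to_column",
    "column_identity",
    "column_similarity",
    "column_stats",
    "interface_conservation_summary",
    "similarity_class_map",
]

GAP = "-"

#: Physicochemical grouping used for "similar" residues: small/aliphatic,
#: aromatic, sulfur-containing, hydroxyl, basic, acidic/amide, proline.
DEFAULT_SIMILARITY_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("GAVLI"),
    frozenset("FYW"),
    frozenset("CM"),
    frozenset("ST"),
    frozenset("KRH"),
    frozenset("DENQ"),
    frozenset("P"),
)


def similarity_class_map(
    classes: Sequence[Iterable[str]] = DEFAULT_SIMILARITY_CLASSES,
) -> dict[str, int]:
    """Letter → class index; validates that the classes partition the 20 codes."""
    mapping: dict[str, int] = {}
    for i, cls in enumerate(classes):
        for letter in cls:
            if letter in mapping:
                raise ValueError(f"residue {letter!r} appears in two classes")
            mapping[letter] = i
    if len(mapping) != 20:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(mapping)
        raise ValueError(f"classes must cover all 20 residues; missing {sorted(missing)}")
    return mapping


@dataclass(frozen=True)
class MultipleAlignment:
    """An in-memory alignment: parallel tuples of ids and equal-length rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.rows:
            raise ValueError("ids and rows must be nonempty and parallel")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise ValueError("all rows must have equal length")
        object.__setattr__(
            self, "rows",
            tuple(r.upper().replace(".", GAP) for r in self.rows),
        )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def column(self, column: int) -> str:
        """Residues of a 1-based column, one per row (gaps included)."""
        if not 1 <= column <= self.length:
            raise IndexError(f"column {column} outside 1..{self.length}")
        return "".join(r[column - 1] for r in self.rows)

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "MultipleAlignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls(tuple(rec.id for rec in aln),
                   tuple(str(rec.seq) for rec in aln))

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


def map_position(alignment: MultipleAlignment, seq_id: str,
                 column: int) -> int | None:
    """Alignment column → 1-based unaligned position for one row.

    Returns None when the row has a gap at that column.
    """
    row = alignment.row(seq_id)
    if not 1 <= column <= alignment.length:
        raise IndexError(f"column {column} outside 1..{alignment.length}")
    if row[column - 1] == GAP:
        return None
    return column - row[:column].count(GAP)


def position_to_column(alignment: MultipleAlignment, seq_id: str,
                       position: int) -> int:
    """Inverse of :func:`map_position` for non-gap positions."""
    row = alignment.row(seq_id)
    count = 0
    for i, ch in enumerate(row, start=1):
        if ch != GAP:
            count += 1
            if count == position:
                return i
    raise IndexError(
        f"{seq_id!r} has only {count} residues; position {position} out of range"
    )


def _pair_fraction(residues: str, key=lambda r: r) -> float | None:
    """Fraction of same-key pairs among non-gap residues; None if <2 residues."""
    obs = [r for r in residues if r != GAP]
    n = len(obs)
    if n < 2:
        return None
    counts = Counter(key(r) for r in obs)
    same = sum(c * (c - 1) // 2 for c in counts.values())
    return same / (n * (n - 1) // 2)


def column_identity(alignment: MultipleAlignment, column: int) -> float:
    """Mean pairwise identity (%) of a column; NaN if fewer than 2 residues."""
    frac = _pair_fraction(alignment.column(column))
    return float("nan") if frac is None else 100.0 * frac


def column_similarity(
    alignment: MultipleAlignment,
    column: int,
    classes: Sequence[Iterable[str]] = DEFAULT_SIMILARITY_CLASSES,
) -> float:
    """Mean pairwise same-class fraction (%) of a column; NaN if <2 residues."""
    cmap = similarity_class_map(classes)
    frac = _pair_fraction(alignment.column(column), key=lambda r: cmap[r])
    return float("nan") if frac is None else 100.0 * frac


def column_stats(
    alignment: MultipleAlignment,
    classes: Sequence[Iterable[str]] = DEFAULT_SIMILARITY_CLASSES,
    mode: str = "pairwise",
) -> pd.DataFrame:
    """Per-column statistics table.

    ``mode="pairwise"`` (default) scores matching pairs; ``mode="modal"``
    scores the modal-residue (or modal-class) frequency instead, for
    sensitivity analysis.
    """
    if mode not in ("pairwise", "modal"):
        raise ValueError("mode must be 'pairwise' or 'modal'")
    cmap = similarity_class_map(classes)
    rows = []
    for col in range(1, alignment.length + 1):
        residues = alignment.column(col)
        obs = [r for r in residues if r != GAP]
        counts = Counter(residues)
        modal = counts.most_common(1)[0][0]
        if mode == "pairwise":
            idf = _pair_fraction(residues)
            simf = _pair_fraction(residues, key=lambda r: cmap[r])
        else:
            if len(obs) < 2:
                idf = simf = None
            else:
                idf = Counter(obs).most_common(1)[0][1] / len(obs)
                simf = Counter(cmap[r] for r in obs).most_common(1)[0][1] / len(obs)
        rows.append({
            "column": col,
            "identity_pct": float("nan") if idf is None else 100.0 * idf,
            "similarity_pct": float("nan") if simf is None else 100.0 * simf,
            "modal_residue": modal,
            "gap_fraction": residues.count(GAP) / len(residues),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConservationSummary:
    mean_identity_pct: float
    mean_similarity_pct: float
    n_columns: int
    skipped_columns: tuple[int, ...]


def interface_conservation_summary(
    alignment: MultipleAlignment,
    interface_columns: Sequence[int],
    classes: Sequence[Iterable[str]] = DEFAULT_SIMILARITY_CLASSES,
    mode: str = "pairwise",
) -> ConservationSummary:
    """Unweighted mean identity/similarity over a set of alignment columns.

    Columns with fewer than two non-gap residues are undefined; they are
    reported as skipped and excluded from the means.  Raises if every
    requested column is undefined.
    """
    if not interface_columns:
        raise ValueError("interface column set is empty")
    stats = column_stats(alignment, classes, mode).set_index("column")
    ids, sims, skipped = [], [], []
    for col in interface_columns:
        if not 1 <= col <= alignment.length:
            raise IndexError(f"column {col} outside 1..{alignment.length}")
        ident = stats.at[col, "identity_pct"]
        if math.isnan(ident):
            skipped.append(col)
            continue
        ids.append(ident)
        sims.append(stats.at[col, "similarity_pct"])
    if not ids:
        raise ValueError("all requested columns have fewer than 2 residues")
    return ConservationSummary(
        mean_identity_pct=float(sum(ids) / len(ids)),
        mean_similarity_pct=float(sum(sims) / len(sims)),
        n_columns=len(ids),
        skipped_columns=tuple(skipped),
    )
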