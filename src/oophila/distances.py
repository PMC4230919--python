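"""Alignment masking and uncorrected pairwise distances.

Uncorrected ("p") distance between two aligned rows is the proportion of
mismatches among comparable sites, where a site is comparable only when both
residues are unambiguous bases (A, C, G, T).  Gaps and IUPAC ambiguity codes
are excluded per pair (pairwise deletion); they never count as match or
mismatch.  Ambiguously aligned regions are removed beforehand with an
explicit column mask supplied by the user — the mask is an input, never
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import AlignedSeqSet
from .util import round_half_away

__all__ = [
    "ColumnMask",
    "DistanceMatrix",
    "GroupRangeTable",
    "UndefinedDistanceError",
    "apply_mask",
    "p_distance_pair",
    "p_distance_matrix",
    "subclade_range_table",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


class UndefinedDistanceError(ValueError):
    """A pair of rows shares no comparable (unambiguous, ungapped) sites."""


class PairDistance(NamedTuple):
    distance: float
    comparable_sites: int


@dataclass(frozen=True)
class ColumnMask:
    """Retained 0-based column indices (strictly increasing)."""

    keep: tuple[int, ...]

    def __post_init__(self) -> None:
        prev = -1
        for idx in self.keep:
            if idx <= prev:
                raise ValueError(f"mask indices must be strictly increasing at {idx}")
            prev = idx

    def __len__(self) -> int:
        return len(self.keep)

    @classmethod
    def from_ranges(cls, ranges: Iterable[tuple[int, int]]) -> "ColumnMask":
        """Build from 1-based inclusive (start, end) ranges, the user-facing convention."""
        keep: set[int] = set()
        for start, end in ranges:
            if start < 1 or end < start:
                raise ValueError(f"invalid 1-based range ({start}, {end})")
            keep.update(range(start - 1, end))
        return cls(keep=tuple(sorted(keep)))

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnMask":
        """Read a mask file of one 1-based inclusive ``start<TAB>end`` range per line."""
        ranges = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                start_s, end_s = line.split("\t")
                ranges.append((int(start_s), int(end_s)))
        return cls.from_ranges(ranges)


def apply_mask(aln: AlignedSeqSet, mask: ColumnMask) -> AlignedSeqSet:
    """Restrict an alignment to the mask's retained columns (ids preserved)."""
    if mask.keep and mask.keep[-1] >= aln.length:
        raise IndexError(
            f"mask index {mask.keep[-1]} out of range for alignment of length {aln.length}"
        )
    rows = ["".join(row[i] for i in mask.keep) for row in aln.rows]
    return AlignedSeqSet(ids=list(aln.ids), rows=rows)


def _encode(rows: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(
        len(rows), -1
    )


def p_distance_pair(x: str, y: str) -> PairDistance:
    """Uncorrected p-distance between two equal-length residue rows.

    Raises :class:`UndefinedDistanceError` when the pair shares no comparable
    site — a distance of 0 or silent NaN would be misleading there.
    """
    if len(x) != len(y):
        raise ValueError(f"rows have unequal lengths ({len(x)} vs {len(y)})")
    if len(x) == 0:
        raise ValueError("rows are empty")
    ax = np.frombuffer(x.encode("ascii"), dtype=np.uint8)
    ay = np.frombuffer(y.encode("ascii"), dtype=np.uint8)
    comparable = np.isin(ax, _ACGT) & np.isin(ay, _ACGT)
    m = int(comparable.sum())
    if m == 0:
        raise UndefinedDistanceError("no comparable sites between the pair")
    mismatches = int(((ax != ay) & comparable).sum())
    return PairDistance(distance=mismatches / m, comparable_sites=m)


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected p-distance matrix with comparable-site counts."""

    ids: list[str]
    d: np.ndarray  # proportions in [0, 1], zero diagonal
    m: np.ndarray  # comparable-site counts per pair

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.m = np.asarray(self.m)
        n = len(self.ids)
        if self.d.shape != (n, n) or self.m.shape != (n, n):
            raise ValueError("matrix shape does not match the number of ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.8f")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid, drow in zip(self.ids, self.d):
                fh.write(sid + "  " + "  ".join(f"{v:.8f}" for v in drow) + "\n")


def p_distance_matrix(aln: AlignedSeqSet) -> DistanceMatrix:
    """All-pairs uncorrected p-distances under pairwise deletion."""
    n = len(aln)
    if n < 2:
        raise ValueError("need at least two sequences")
    if aln.length == 0:
        raise ValueError("alignment has zero columns")
    arr = _encode(aln.rows)
    valid = np.isin(arr, _ACGT)
    d = np.zeros((n, n), dtype=float)
    m = np.zeros((n, n), dtype=np.int64)
    m[np.diag_indices(n)] = valid.sum(axis=1)
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            comparable = valid[i] & valid[j]
            mij = int(comparable.sum())
            if mij == 0:
                undefined.append((aln.ids[i], aln.ids[j]))
                continue
            mism = int(((arr[i] != arr[j]) & comparable).sum())
            d[i, j] = d[j, i] = mism / mij
            m[i, j] = m[j, i] = mij
    if undefined:
        raise UndefinedDistanceError(
            f"pairs with zero comparable sites: {undefined}"
        )
    return DistanceMatrix(ids=list(aln.ids), d=d, m=m)


@dataclass
class GroupRangeTable:
    """Min–max percent p-distance per group pair (within-group cells exclude self-pairs).

    ``cells`` maps an ordered (by ``labels``) group pair to ``(min_pct, max_pct)``;
    a within-group cell for a singleton group is None (no pairs, reported NA).
    """

    labels: list[str]
    cells: dict[tuple[str, str], tuple[float, float] | None] = field(default_factory=dict)

    def cell(self, a: str, b: str) -> tuple[float, float] | None:
        key = (a, b) if self.labels.index(a) <= self.labels.index(b) else (b, a)
        return self.cells[key]

    def format_cell(self, a: str, b: str, ndigits: int = 2) -> str:
        cell = self.cell(a, b)
        if cell is None:
            return "NA"
        lo, hi = (round_half_away(v, ndigits) for v in cell)
        return f"{lo:.{ndigits}f}-{hi:.{ndigits}f}%"

    def to_dataframe(self) -> pd.DataFrame:
        """Upper-triangle layout mirroring the published range table."""
        data = {}
        for col in self.labels:
            data[col] = [
                self.format_cell(row, col)
                if self.labels.index(row) <= self.labels.index(col)
                else "-"
                for row in self.labels
            ]
        return pd.DataFrame(data, index=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def subclade_range_table(
    dm: DistanceMatrix, grouping: Mapping[str, str]
) -> GroupRangeTable:
    """Per-group-pair min/max percent distances (the between-subclade range stage)."""
    missing = [sid for sid in dm.ids if sid not in grouping]
    if missing:
        raise ValueError(f"ids without a group label: {missing}")
    labels = sorted({grouping[sid] for sid in dm.ids})
    members: dict[str, list[int]] = {g: [] for g in labels}
    for idx, sid in enumerate(dm.ids):
        members[grouping[sid]].append(idx)

    cells: dict[tuple[str, str], tuple[float, float] | None] = {}
    for ai, a in enumerate(labels):
        for b in labels[ai:]:
            if a == b:
                idxs = members[a]
                vals = [
                    dm.d[i, j] for k, i in enumerate(idxs) for j in idxs[k + 1 :]
                ]
            else:
                vals = [dm.d[i, j] for i in members[a] for j in members[b]]
            if not vals:
                cells[(a, b)] = None
            else:
                cells[(a, b)] = (100.0 * min(vals), 100.0 * max(vals))
    return GroupRangeTable(labels=labels, cells=cells)
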