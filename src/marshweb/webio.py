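"""Reading, validating and writing binary food webs.

A food web is a labelled square binary matrix ``A`` with the single
orientation convention used throughout the package:

    ``A[i, j] = 1``  iff species *i* (the consumer / predator) eats
    species *j* (the resource / prey).

Rows are consumers, columns are resources.  Diagonal entries are legal
(cannibalism) and count once toward the number of observed links.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FoodWeb",
    "FoodWebFormatError",
    "read_adjacency",
    "read_edgelist",
    "write_adjacency",
    "read_species_table",
]


class FoodWebFormatError(ValueError):
    """Raised when an input file violates the food-web matrix format."""


@dataclass(frozen=True)
class FoodWeb:
    """A labelled binary consumer x resource matrix.

    Parameters
    ----------
    labels
        Ordered, unique, non-empty species identifiers. Case-sensitive
        exact strings; no normalisation is applied.
    A
        ``(n, n)`` array with entries in ``{0, 1}``; ``A[i, j] = 1`` means
        species ``labels[i]`` eats species ``labels[j]``.
    category
        Optional per-species tag (e.g. basal / invertebrate / fish / bird).
    name
        Optional web identifier used in report tables.
    """

    labels: tuple[str, ...]
    A: np.ndarray
    category: tuple[str, ...] | None = None
    name: str = "web"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.int8)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        n = len(self.labels)
        if n == 0:
            raise FoodWebFormatError("food web has no species")
        if A.ndim != 2 or A.shape != (n, n):
            raise FoodWebFormatError(
                f"adjacency must be {n}x{n} to match labels, got {A.shape}"
            )
        if len(set(self.labels)) != n:
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise FoodWebFormatError(f"duplicate species labels: {dupes}")
        if any(lbl == "" for lbl in self.labels):
            raise FoodWebFormatError("empty species label")
        bad = ~np.isin(A, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FoodWebFormatError(
                f"non-binary entry at row {self.labels[i]!r}, "
                f"column {self.labels[j]!r}"
            )
        if self.category is not None and len(self.category) != n:
            raise FoodWebFormatError("category length must match labels")

    # -- basic counts ----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.labels)

    @property
    def n_links(self) -> int:
        """Observed links L_o (diagonal counted once)."""
        return int(self.A.sum())

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def with_link(self, consumer: str, resource: str) -> "FoodWeb":
        """Return a copy with one extra consumer->resource link."""
        A = self.A.copy()
        A[self.index(consumer), self.index(resource)] = 1
        return FoodWeb(self.labels, A, self.category, self.name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.A, other.A)

    def __hash__(self) -> int:  # frozen dataclass needs explicit hash with __eq__
        return hash((self.labels, self.A.tobytes()))


_DIALECTS = {"csv": ",", "tsv": "\t"}


def read_adjacency(
    path,
    dialect: str = "csv",
    *,
    transpose: bool = False,
    name: str | None = None,
) -> FoodWeb:
    """Read a labelled adjacency matrix (header row + header column).

    Body cells must be 0, 1 or blank; blanks read as 0 (spreadsheet
    exports routinely omit zeros).  Row labels and column labels must
    match in order.  ``transpose=True`` flips the orientation for files
    that encode columns-eat-rows.
    """
    sep = _DIALECTS.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be one of {sorted(_DIALECTS)}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise FoodWebFormatError(f"{path}: empty file")
    header = [c.strip() for c in rows[0][1:]]
    labels, body = [], []
    for r, row in enumerate(rows[1:], start=2):
        if not row or all(c.strip() == "" for c in row):
            continue
        labels.append(row[0].strip())
        cells = [c.strip() for c in row[1:]]
        if len(cells) != len(header):
            raise FoodWebFormatError(
                f"{path}: row {labels[-1]!r} has {len(cells)} cells, "
                f"expected {len(header)}"
            )
        parsed = []
        for c, cell in zip(header, cells):
            if cell == "":
                parsed.append(0)
            elif cell in ("0", "1"):
                parsed.append(int(cell))
            else:
                raise FoodWebFormatError(
                    f"{path}: non-binary cell {cell!r} at row {labels[-1]!r}, "
                    f"column {c!r}"
                )
        body.append(parsed)
    if labels != header:
        raise FoodWebFormatError(
            f"{path}: row labels and column labels differ "
            f"(first mismatch near {_first_mismatch(labels, header)})"
        )
    A = np.array(body, dtype=np.int8)
    if transpose:
        A = A.T
    return FoodWeb(tuple(labels), A, name=name or _stem(path))


def _first_mismatch(a: list[str], b: list[str]) -> str:
    for x, y in zip(a, b):
        if x != y:
            return f"{x!r} vs {y!r}"
    return f"lengths {len(a)} vs {len(b)}"


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def read_edgelist(path, *, name: str | None = None) -> FoodWeb:
    """Read a two-column ``consumer<TAB>resource`` edge list.

    The node set is the union of labels in order of first appearance;
    duplicate edges collapse to one.  Self-loops (cannibalism) are kept.
    """
    labels: list[str] = []
    seen: dict[str, int] = {}
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FoodWebFormatError(
                    f"{path}:{lineno}: expected 'consumer<TAB>resource', "
                    f"got {line!r}"
                )
            consumer, resource = (p.strip() for p in parts)
            for lbl in (consumer, resource):
                if lbl not in seen:
                    seen[lbl] = len(labels)
                    labels.append(lbl)
            edges.append((consumer, resource))
    if not labels:
        raise FoodWebFormatError(f"{path}: empty edge list")
    A = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for consumer, resource in edges:
        A[seen[consumer], seen[resource]] = 1
    return FoodWeb(tuple(labels), A, name=name or _stem(path))


def write_adjacency(web: FoodWeb, path, dialect: str = "csv") -> None:
    """Write a web as a labelled matrix; round-trips bit-exactly."""
    sep = _DIALECTS.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be one of {sorted(_DIALECTS)}")
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=sep, lineterminator="\n")
    writer.writerow(["", *web.labels])
    for i, lbl in enumerate(web.labels):
        writer.writerow([lbl, *web.A[i].tolist()])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_species_table(path) -> pd.DataFrame:
    """Read a species table CSV with columns label, name, category."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if "label" not in df.columns:
        raise FoodWebFormatError(f"{path}: species table needs a 'label' column")
    if df["label"].duplicated().any():
        dupes = sorted(df.loc[df["label"].duplicated(), "label"].unique())
        raise FoodWebFormatError(f"{path}: duplicate labels {dupes}")
    return df
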