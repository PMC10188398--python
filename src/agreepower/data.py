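"""Data containers and CSV I/O for rating data.

Two in-memory containers cover the common layouts of inter-rater data:

``RatingsTable``
    An N x C table of rater counts: row *i*, column *c* holds the number of
    raters who assigned item *i* to category *c*.  Every row sums to the
    (constant) number of raters R.  This layout supports any number of
    raters but does not identify *which* rater chose which category.

``PairTable``
    A C x C cross-classification for exactly two raters: cell (c, c~) holds
    the number (or proportion) of items that rater 1 put in category c and
    rater 2 put in category c~.  This layout identifies the raters and is
    required for Cohen-style chance correction with rater-specific margins.

Categories are ordinal and identified by column position; the category
distance |c - c~| is defined on positions, so the column order of the input
file is semantically meaningful.  Indices are 1-based in the public API and
in reports, 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "RatingsTable",
    "PairTable",
    "SummaryTriple",
    "load_ratings",
    "load_pair_table",
    "save_ratings",
    "save_pair_table",
    "pair_table_to_ratings",
    "drop_empty_categories",
]

#: tolerance for a proportion table to sum to one
PROPORTION_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when input data violate the contracts of the coefficient class."""


@dataclass(frozen=True)
class RatingsTable:
    """N x C rater-count table; ``counts[i, c]`` raters put item i in category c."""

    counts: np.ndarray
    category_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("ratings table must be two-dimensional")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise ValidationError("rater counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("rater counts must be nonnegative")
        n, c = counts.shape
        if n < 1:
            raise ValidationError("need at least one item")
        if c < 3:
            raise ValidationError("need at least three ordinal categories")
        row_sums = counts.sum(axis=1)
        if not np.all(row_sums == row_sums[0]):
            raise ValidationError("inconsistent rater count: rows must share one sum")
        if row_sums[0] < 2:
            raise ValidationError("need at least two raters")
        object.__setattr__(self, "counts", counts)
        labels = self.category_labels or tuple(str(j + 1) for j in range(c))
        if len(labels) != c:
            raise ValidationError("category_labels length must equal the number of columns")
        object.__setattr__(self, "category_labels", tuple(labels))

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def n_raters(self) -> int:
        return int(self.counts[0].sum())

    def reversed_categories(self) -> "RatingsTable":
        """Same data with the category order flipped (label order reversed)."""
        return RatingsTable(self.counts[:, ::-1].copy(), self.category_labels[::-1])


@dataclass(frozen=True)
class PairTable:
    """C x C two-rater cross-classification (counts or proportions).

    Cell (c, c~) is the mass of items which rater 1 assigned to category c
    and rater 2 assigned to category c~.  Row marginals describe rater 1,
    column marginals rater 2.
    """

    cross_counts: np.ndarray
    is_proportions: bool = False
    category_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        x = np.asarray(self.cross_counts, dtype=float)
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise ValidationError("pair table must be square")
        if x.shape[0] < 3:
            raise ValidationError("need at least three ordinal categories")
        if np.any(x < 0):
            raise ValidationError("pair table cells must be nonnegative")
        total = x.sum()
        if total <= 0:
            raise ValidationError("pair table grand total must be positive")
        if self.is_proportions and abs(total - 1.0) > PROPORTION_TOL:
            raise ValidationError("proportion table must sum to one")
        if not self.is_proportions and not np.all(np.mod(x, 1) == 0):
            raise ValidationError("count table must hold integers; pass proportions explicitly")
        object.__setattr__(self, "cross_counts", x)
        labels = self.category_labels or tuple(str(j + 1) for j in range(x.shape[0]))
        if len(labels) != x.shape[0]:
            raise ValidationError("category_labels length must equal the number of columns")
        object.__setattr__(self, "category_labels", tuple(labels))

    @property
    def n_categories(self) -> int:
        return self.cross_counts.shape[0]

    @property
    def grand_total(self) -> float:
        return float(self.cross_counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        """Rater-1 category masses (same scale as the cells)."""
        return self.cross_counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        """Rater-2 category masses (same scale as the cells)."""
        return self.cross_counts.sum(axis=0)

    def as_proportions(self) -> "PairTable":
        """Normalize counts to proportions; a proportion table is returned as is."""
        if self.is_proportions:
            return self
        return PairTable(self.cross_counts / self.grand_total, True, self.category_labels)

    def reversed_categories(self) -> "PairTable":
        return PairTable(
            self.cross_counts[::-1, ::-1].copy(), self.is_proportions, self.category_labels[::-1]
        )


@dataclass(frozen=True)
class SummaryTriple:
    """Published summary statistics sufficient for coefficient recovery.

    The coefficient value at a reported power parameter gamma, together with
    the first derivative and the curvature ratio (second over first
    derivative) at that gamma, determine a quadratic approximation of the
    coefficient at any other gamma — no raw data needed.

    ``curvature_ratio`` may be ``None`` when the first derivative is zero
    (the ratio is then undefined and the quadratic term is dropped).
    """

    gamma: float
    coefficient_value: float
    d1: float
    curvature_ratio: float | None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError("power parameter must be nonnegative")
        if self.coefficient_value > 1 + 1e-12:
            raise ValidationError("coefficient value cannot exceed one")


def _read_csv(path, header: bool) -> np.ndarray:
    df = pd.read_csv(path, header=0 if header else None)
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:  # non-numeric cells
        raise ValidationError(f"non-numeric table in {path}") from exc


def load_ratings(path, header: bool = False) -> RatingsTable:
    """Read an N x C rater-count CSV (comma-separated, period decimals).

    Row sums must be constant; N, C and R are inferred from the table shape.
    """
    return RatingsTable(_read_csv(path, header))


def load_pair_table(path, as_proportions: bool = False, header: bool = False) -> PairTable:
    """Read a square C x C two-rater CSV.

    With ``as_proportions`` the table is treated (and validated) as
    proportions; integer count tables are also normalized on request.
    """
    x = _read_csv(path, header)
    if as_proportions and abs(x.sum() - 1.0) > PROPORTION_TOL:
        x = x / x.sum()
    return PairTable(x, is_proportions=as_proportions)


def save_ratings(table: RatingsTable, path) -> None:
    pd.DataFrame(table.counts).to_csv(path, header=False, index=False)


def save_pair_table(table: PairTable, path) -> None:
    pd.DataFrame(table.cross_counts).to_csv(path, header=False, index=False)


def drop_empty_categories(data: "RatingsTable | PairTable"):
    """Remove categories no rater ever used, relabelling the table.

    Chance correction is undefined when a category has zero marginal mass;
    the default behaviour is to refuse such input.  This helper is the
    explicit opt-in escape hatch: it deletes the empty columns (and rows,
    for a pair table) and renumbers the remaining ordinal positions — note
    that this changes the category distances and therefore the coefficient.
    """
    if isinstance(data, RatingsTable):
        used = data.counts.sum(axis=0) > 0
        if used.sum() < 3:
            raise ValidationError("fewer than three used categories remain")
        labels = tuple(lbl for lbl, u in zip(data.category_labels, used) if u)
        return RatingsTable(data.counts[:, used], labels)
    used = (data.row_marginals + data.col_marginals) > 0
    if used.sum() < 3:
        raise ValidationError("fewer than three used categories remain")
    labels = tuple(lbl for lbl, u in zip(data.category_labels, used) if u)
    return PairTable(data.cross_counts[np.ix_(used, used)], data.is_proportions, labels)


def pair_table_to_ratings(table: PairTable) -> RatingsTable:
    """Expand an integer-count pair table into the item-level rater-count layout.

    Each diagonal cell (c, c) contributes that many rows with a 2 in
    position c; each off-diagonal cell (c, c~) contributes rows with a 1 in
    both positions.  The observed distance profile of the result equals the
    profile computed from the pair table directly.
    """
    if table.is_proportions:
        raise ValidationError("cannot expand proportions to items; counts required")
    x = table.cross_counts.astype(np.int64)
    c_n = table.n_categories
    rows = []
    for c in range(c_n):
        for ct in range(c_n):
            k = int(x[c, ct])
            if k == 0:
                continue
            row = np.zeros(c_n, dtype=np.int64)
            if c == ct:
                row[c] = 2
            else:
                row[c] = 1
                row[ct] = 1
            rows.extend([row] * k)
    return RatingsTable(np.array(rows), table.category_labels)
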