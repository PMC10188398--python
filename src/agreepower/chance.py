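"""Chance models: category proportions and expected distance profiles.

Every coefficient in the class corrects observed weighted agreement by the
agreement expected when two raters choose categories independently with
marginal probabilities p (first rater) and q (second rater).  The five
supported operationalizations:

==============  =====  ==========================================================
model           R      p_c and q_c
==============  =====  ==========================================================
s               >= 2   p_c = q_c = 1/C (all categories equally likely)
cohen           2      p = rater-1 marginals, q = rater-2 marginals
scott           2      p = q = pooled two-rater marginals
fleiss          >= 2   p_c = q_c = sum_i R_ic / (N R)
uniform_prior   >= 2   p_c = q_c = (1 + sum_i R_ic) / (C + N R)
==============  =====  ==========================================================

All proportions must be strictly positive: a category never chosen by any
rater leaves the chance correction undefined, and we surface that as a
validation error rather than smoothing (the uniform-prior model, which adds
one pseudo-rating per category, can never produce a zero).

Scott's pi coincides with Fleiss' kappa restricted to two raters; both run
through one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PairTable, RatingsTable, ValidationError

__all__ = ["MODELS", "ChanceMarginals", "marginals", "expected_cell", "expected_profile"]

MODELS = ("s", "cohen", "scott", "fleiss", "uniform_prior")

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class ChanceMarginals:
    """Chance-model category proportions p (rater 1) and q (rater 2)."""

    model: str
    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if p.shape != q.shape or p.ndim != 1 or p.size < 3:
            raise ValidationError("p and q must be equal-length vectors, C >= 3")
        for name, v in (("p", p), ("q", q)):
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to one")
            if np.any(v <= 0):
                raise ValidationError(
                    "category never used; chance correction undefined for zero proportions"
                )
        object.__setattr__(self, "p", p / p.sum())
        object.__setattr__(self, "q", q / q.sum())

    @property
    def n_categories(self) -> int:
        return self.p.size

    @property
    def diagonal_expected(self) -> float:
        """Expected fraction of exact agreements, sum_c p_c q_c."""
        return float(self.p @ self.q)

    def reversed_categories(self) -> "ChanceMarginals":
        return ChanceMarginals(self.model, self.p[::-1].copy(), self.q[::-1].copy())


def _pooled_counts(data: RatingsTable | PairTable) -> tuple[np.ndarray, float]:
    """Total ratings per category and the total number of ratings N*R."""
    if isinstance(data, RatingsTable):
        return data.counts.sum(axis=0).astype(float), float(data.n_items * data.n_raters)
    if data.is_proportions:
        raise ValidationError("this chance model needs counts, not proportions")
    totals = data.row_marginals + data.col_marginals
    return totals, float(2 * data.grand_total)


def marginals(data: RatingsTable | PairTable, model: str) -> ChanceMarginals:
    """Chance-model category proportions for ``data``.

    ``cohen`` needs a rater-distinguished :class:`PairTable`; a rater-count
    table cannot be split into the two raters' margins without guessing.
    ``scott`` needs two raters (a pair table or an R = 2 rater-count table).
    """
    if model not in MODELS:
        raise ValidationError(f"unknown chance model {model!r}; choose from {MODELS}")
    C = data.n_categories

    if model == "s":
        u = np.full(C, 1.0 / C)
        return ChanceMarginals(model, u, u.copy())

    if model == "cohen":
        if not isinstance(data, PairTable):
            raise ValidationError("cohen requires a rater-distinguished pair table")
        total = data.grand_total
        return ChanceMarginals(model, data.row_marginals / total, data.col_marginals / total)

    if model == "scott":
        if isinstance(data, RatingsTable) and data.n_raters != 2:
            raise ValidationError("scott is a two-rater coefficient")
        if isinstance(data, PairTable):
            total = data.grand_total
            pooled = (data.row_marginals + data.col_marginals) / (2.0 * total)
        else:
            pooled = data.counts.sum(axis=0) / (data.n_items * data.n_raters)
        return ChanceMarginals(model, pooled, pooled.copy())

    if model == "fleiss":
        if isinstance(data, PairTable):
            total = data.grand_total
            pooled = (data.row_marginals + data.col_marginals) / (2.0 * total)
        else:
            pooled = data.counts.sum(axis=0) / (data.n_items * data.n_raters)
        return ChanceMarginals(model, pooled, pooled.copy())

    # uniform prior: one pseudo-rating per category, needs integer counts
    totals, nr = _pooled_counts(data)
    u = (1.0 + totals) / (C + nr)
    return ChanceMarginals(model, u, u.copy())


def expected_cell(marg: ChanceMarginals, c: int, c_tilde: int) -> float:
    """Chance mass of the unordered category pair (c, c~), 1-based, c > c~.

    One rater chooses c and the other c~ in either role:
    E(c, c~) = p_c q_c~ + q_c p_c~, strictly positive.
    """
    if not (1 <= c_tilde < c <= marg.n_categories):
        raise ValidationError("expected_cell requires 1 <= c_tilde < c <= C")
    p, q = marg.p, marg.q
    return float(p[c - 1] * q[c_tilde - 1] + q[c - 1] * p[c_tilde - 1])


def expected_profile(marg: ChanceMarginals) -> np.ndarray:
    """Expected distance profile E_(l), l = 1 .. C-1.

    E_(l) sums the chance mass of every category pair exactly l positions
    apart; all entries are strictly positive and the profile satisfies
    sum_l E_(l) = 1 - sum_c p_c q_c.
    """
    C = marg.n_categories
    p, q = marg.p, marg.q
    out = np.empty(C - 1)
    for l in range(1, C):
        idx = np.arange(l, C)
        out[l - 1] = float(np.sum(p[idx] * q[idx - l] + q[idx] * p[idx - l]))
    return out
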