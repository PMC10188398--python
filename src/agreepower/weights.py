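"""The distance-power family of agreement weights.

A disagreement between categories c and c~ (positions on an ordinal scale
with C categories) receives the weight

    w(c, c~) = 1 - (|c - c~| / (C - 1)) ** gamma,       gamma > 0,

so exact agreement gets full credit (w = 1), the maximal distance C - 1
gets none (w = 0), and the single power parameter gamma interpolates a
continuum of schemes.  Named members of the family: gamma -> 0 gives
identity weights (the unweighted coefficient), gamma = 0.5 radical,
gamma = 1 linear, gamma = 2 quadratic weights.  Larger gamma is more
lenient: every off-diagonal weight is strictly increasing in gamma.

gamma = 0 is handled as an exact special case (identity weights) rather
than a numerical limit, so unweighted coefficients are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ValidationError

__all__ = ["WeightScheme", "PRESETS", "weight", "weight_matrix"]

#: named power-parameter presets
PRESETS: dict[str, float] = {"identity": 0.0, "radical": 0.5, "linear": 1.0, "quadratic": 2.0}


@dataclass(frozen=True)
class WeightScheme:
    """Power parameter gamma >= 0 together with the number of categories C."""

    gamma: float
    n_categories: int

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError("power parameter must be nonnegative")
        if self.n_categories < 3:
            raise ValidationError("need at least three ordinal categories")

    @classmethod
    def from_preset(cls, name: str, n_categories: int) -> "WeightScheme":
        try:
            return cls(PRESETS[name], n_categories)
        except KeyError:
            raise ValidationError(f"unknown weighting preset {name!r}") from None


def weight(scheme: WeightScheme, c: int, c_tilde: int) -> float:
    """Weight for the (1-based) category pair (c, c~)."""
    C = scheme.n_categories
    if not (1 <= c <= C and 1 <= c_tilde <= C):
        raise ValidationError(f"category index out of range 1..{C}")
    d = abs(c - c_tilde)
    if scheme.gamma == 0:
        return 1.0 if d == 0 else 0.0
    return 1.0 - (d / (C - 1)) ** scheme.gamma


def weight_matrix(scheme: WeightScheme) -> np.ndarray:
    """Full C x C weight matrix: symmetric, unit diagonal, Toeplitz in |c - c~|."""
    C = scheme.n_categories
    d = np.abs(np.subtract.outer(np.arange(C), np.arange(C)))
    if scheme.gamma == 0:
        return np.eye(C)
    return 1.0 - (d / (C - 1)) ** scheme.gamma
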