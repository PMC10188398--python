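"""Synthetic rating generator and embedded worked-example fixtures.

The generator draws Dirichlet–multinomial rating tables: for each item an
item-specific category distribution is drawn from a Dirichlet with
parameters ``marginal_concentration / agreement_strength``, then the R
rater choices are drawn multinomially from it.  One knob therefore spans
the agreement spectrum — as ``agreement_strength`` grows the item
distributions collapse onto single categories, so the raters of an item
agree almost perfectly while the category frequencies still follow the
normalized concentration; as it shrinks the items all share the common
marginal distribution and agreement falls to chance level.  Unimodal
concentrations over the ordered categories induce distance structure
(near-diagonal disagreements dominate).  Randomness comes from numpy's
PCG64 ``default_rng`` seeded from the config, so tables are reproducible.

The embedded fixtures are two classic worked examples from the agreement
literature: a two-rater, three-category contingency table (Cohen's
psychiatric-diagnosis illustration) given as observed proportions, and the
distance profile of a four-rater, five-category data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PairTable, RatingsTable, ValidationError
from .profiles import DistanceProfile
from .weights import WeightScheme, weight_matrix

__all__ = ["GeneratorConfig", "generate_ratings", "example_fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the Dirichlet–multinomial rating generator."""

    n_items: int = 100
    n_categories: int = 5
    n_raters: int = 2
    marginal_concentration: tuple[float, ...] = field(default=())
    agreement_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_categories < 3 or self.n_raters < 2:
            raise ValidationError("need N >= 1 items, C >= 3 categories, R >= 2 raters")
        conc = self.marginal_concentration or tuple([1.0] * self.n_categories)
        if len(conc) != self.n_categories:
            raise ValidationError("marginal_concentration must have one entry per category")
        if any(a <= 0 for a in conc):
            raise ValidationError("Dirichlet concentrations must be positive")
        if self.agreement_strength <= 0:
            raise ValidationError("agreement_strength must be positive")
        object.__setattr__(self, "marginal_concentration", tuple(float(a) for a in conc))


def generate_ratings(config: GeneratorConfig) -> RatingsTable:
    """Draw a reproducible N x C rater-count table from the generator."""
    rng = np.random.default_rng(config.seed)
    alpha = np.asarray(config.marginal_concentration) / config.agreement_strength
    theta = rng.dirichlet(alpha, size=config.n_items)
    counts = np.vstack([rng.multinomial(config.n_raters, t) for t in theta])
    return RatingsTable(counts)


# -- embedded worked-example fixtures ---------------------------------------

# two raters, three categories: observed cross-classification proportions
# (rows rater 1, columns rater 2); margins (.50,.30,.20) / (.40,.30,.30)
_TWO_RATER_3CAT = np.array(
    [
        [0.25, 0.13, 0.12],
        [0.12, 0.02, 0.16],
        [0.03, 0.15, 0.02],
    ]
)

# four raters, five categories: published distance profile (sufficient
# statistics) of the pooled-marginal (Fleiss) chance model
_FOUR_RATER_5CAT_O = np.array([0.155, 0.253, 0.011, 0.000])
_FOUR_RATER_5CAT_E = np.array([0.110, 0.378, 0.062, 0.162])

FIXTURE_NAMES = (
    "two_rater_3cat_pair",
    "four_rater_5cat_profile",
    "weight_matrices_c5",
)


def example_fixture(name: str):
    """Return an embedded worked-example object by name.

    ``two_rater_3cat_pair``
        :class:`PairTable` of observed proportions for the two-rater,
        three-category example.
    ``four_rater_5cat_profile``
        :class:`DistanceProfile` of the four-rater, five-category example.
    ``weight_matrices_c5``
        dict of the C = 5 weight matrices for the named presets.
    """
    if name == "two_rater_3cat_pair":
        return PairTable(_TWO_RATER_3CAT.copy(), is_proportions=True)
    if name == "four_rater_5cat_profile":
        return DistanceProfile.from_vectors(_FOUR_RATER_5CAT_O, _FOUR_RATER_5CAT_E)
    if name == "weight_matrices_c5":
        return {
            preset: weight_matrix(WeightScheme.from_preset(preset, 5))
            for preset in ("identity", "radical", "linear", "quadratic")
        }
    raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
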