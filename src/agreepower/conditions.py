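"""Direction/curvature condition checks, qualitative labels, and Taylor recovery.

The sign of the first derivative D1 (does the coefficient rise or fall as
the weighting gets more lenient?) admits exact conditions on the distance
profile, with simpler specializations for three categories, for monotone
observed/expected ratios, and for the equal-chance (S) model.  Each check
is reported as a :class:`ConditionVerdict` identified by what it tests:

==============================  ==========================================================
condition id                    tests
==============================  ==========================================================
general_increasing/_decreasing  necessary & sufficient sign condition on the
                                pairwise weighted sum (any C, any chance model)
three_cat_increasing/...        C = 3: O_(1)/E_(1) vs O_(2)/E_(2)
monotone_ratio_increasing/...   sufficient: O_(l)/E_(l) strictly decreasing
                                (resp. increasing) in the distance l
s_general_increasing/...        S model: the weighted sum with pair counts C - l
s_three_cat_increasing/...      S model, C = 3: O_(1)/2 vs O_(2)
s_monotone_increasing/...       S model: O_(l)/(C - l) monotone in l
curvature_intensifying/...      D1 and D2 share a sign (susceptibility grows
                                with gamma) or have opposite signs (it weakens)
peak_gamma                      C = 3: location of maximum susceptibility,
                                gamma* = ln(E_(1)/E_(2)) / ln 2
s_peak_gamma                    S model, C = 3: the peak sits exactly at
                                linear weights, gamma* = 1
==============================  ==========================================================

Strict inequalities that land on an exact tie are reported as not holding,
with a tie flag: at a tie D1 = 0 and neither direction claim is true.

Qualitative labels follow the conventional cutoffs: susceptibility is
moderate when |D1| < .05, high when .05 <= |D1| < .10, very high when
|D1| >= .10; curvature is minor when |D2/D1| < .10, otherwise intensifying
or weakening by the sign of the ratio.

Finally, :func:`taylor_estimate` recovers the coefficient at an unreported
power parameter from published summaries alone — the coefficient value,
first derivative, and curvature ratio at the reported gamma are sufficient
statistics for the quadratic approximation

    I_w(gamma + d) ~= I_w(gamma) + D1(gamma) * (d + (D2/D1) * d**2 / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SummaryTriple, ValidationError
from .profiles import DistanceProfile
from .susceptibility import D1_ZERO_TOL, components, gamma_star

__all__ = [
    "ConditionVerdict",
    "SusceptibilityLabels",
    "check_conditions",
    "classify",
    "taylor_estimate",
    "taylor_deviation",
]



@dataclass(frozen=True)
class ConditionVerdict:
    """Outcome of one condition check.

    ``holds`` is ``None`` when the condition does not apply to the input
    (wrong C or chance model).  ``statistic`` is the evaluated left-hand
    side for inequality conditions, or the computed quantity (e.g. the peak
    gamma) for the location conditions.  ``tie`` marks an exact equality in
    a strict inequality.
    """

    condition_id: str
    applicable: bool
    holds: bool | None = None
    statistic: float | None = None
    tie: bool = False


@dataclass(frozen=True)
class SusceptibilityLabels:
    """Qualitative summary: degree, direction and change of susceptibility."""

    degree: str  # moderate | high | very high
    direction: str  # positive | negative | zero
    change: str  # intensifying | weakening | minor
    note: str = ""


def _strict_pair(cond_id_pos: str, cond_id_neg: str, stat: float) -> list[ConditionVerdict]:
    tie = stat == 0.0  # ties are exact equalities, not a band
    return [
        ConditionVerdict(cond_id_pos, True, holds=stat > 0, statistic=stat, tie=tie),
        ConditionVerdict(cond_id_neg, True, holds=stat < 0, statistic=stat, tie=tie),
    ]


def _monotone_pair(cond_id_pos: str, cond_id_neg: str, values: np.ndarray) -> list[ConditionVerdict]:
    diffs = np.diff(values)
    decreasing = bool(np.all(diffs < 0))
    increasing = bool(np.all(diffs > 0))
    tie = bool(np.any(diffs == 0))
    return [
        ConditionVerdict(cond_id_pos, True, holds=decreasing, tie=tie),
        ConditionVerdict(cond_id_neg, True, holds=increasing, tie=tie),
    ]


def check_conditions(
    profile: DistanceProfile, gamma: float, model: str = ""
) -> list[ConditionVerdict]:
    """Evaluate every applicable direction/curvature condition at ``gamma``.

    ``model`` enables the equal-chance specializations when set to ``"s"``.
    """
    C = profile.n_categories
    o, e = profile.observed, profile.expected
    ratios = profile.ratios
    l_idx = np.arange(1, C, dtype=float)
    is_s = model == "s"
    verdicts: list[ConditionVerdict] = []

    # general sign condition: the D1 numerator (positive factors stripped)
    stat = 0.0
    for m in range(2, C):
        for l in range(1, m):
            stat += (
                np.log(m / l)
                * l**gamma
                * m**gamma
                * e[l - 1]
                * e[m - 1]
                * (ratios[l - 1] - ratios[m - 1])
            )
    verdicts += _strict_pair("general_increasing", "general_decreasing", float(stat))

    # three-category specialization: single ratio gap
    if C == 3:
        gap = float(ratios[0] - ratios[1])
        verdicts += _strict_pair("three_cat_increasing", "three_cat_decreasing", gap)
    else:
        verdicts += [
            ConditionVerdict("three_cat_increasing", False),
            ConditionVerdict("three_cat_decreasing", False),
        ]

    # sufficient monotone-ratio condition
    verdicts += _monotone_pair("monotone_ratio_increasing", "monotone_ratio_decreasing", ratios)

    # equal-chance (S) specializations
    if is_s:
        avg = o / (C - l_idx)  # average observed frequency per category pair
        stat_s = 0.0
        for m in range(2, C):
            for l in range(1, m):
                stat_s += (
                    np.log(m / l)
                    * l**gamma
                    * m**gamma
                    * (C - l)
                    * (C - m)
                    * (avg[l - 1] - avg[m - 1])
                )
        verdicts += _strict_pair("s_general_increasing", "s_general_decreasing", float(stat_s))
        if C == 3:
            verdicts += _strict_pair(
                "s_three_cat_increasing", "s_three_cat_decreasing", float(o[0] / 2.0 - o[1])
            )
        else:
            verdicts += [
                ConditionVerdict("s_three_cat_increasing", False),
                ConditionVerdict("s_three_cat_decreasing", False),
            ]
        verdicts += _monotone_pair("s_monotone_increasing", "s_monotone_decreasing", avg)
    else:
        verdicts += [
            ConditionVerdict(cid, False)
            for cid in (
                "s_general_increasing",
                "s_general_decreasing",
                "s_three_cat_increasing",
                "s_three_cat_decreasing",
                "s_monotone_increasing",
                "s_monotone_decreasing",
            )
        ]

    # curvature: susceptibility intensifies iff D1 and D2 share a sign
    comp = components(profile, gamma)
    d1 = float(comp["d1_contribution"].sum())
    d2 = float(comp["d2_contribution"].sum())
    prod = d1 * d2
    tie = prod == 0.0
    verdicts.append(
        ConditionVerdict("curvature_intensifying", True, holds=prod > 0, statistic=prod, tie=tie)
    )
    verdicts.append(
        ConditionVerdict("curvature_weakening", True, holds=prod < 0, statistic=prod, tie=tie)
    )

    # peak of susceptibility (three categories only)
    if C == 3:
        gs = gamma_star(profile)
        verdicts.append(ConditionVerdict("peak_gamma", True, holds=True, statistic=gs))
        if is_s:
            verdicts.append(ConditionVerdict("s_peak_gamma", True, holds=True, statistic=gs))
        else:
            verdicts.append(ConditionVerdict("s_peak_gamma", False))
    else:
        verdicts.append(ConditionVerdict("peak_gamma", False))
        verdicts.append(ConditionVerdict("s_peak_gamma", False))
    return verdicts


def classify(d1: float, curvature_ratio: float | None) -> SusceptibilityLabels:
    """Qualitative labels for the degree, direction and change of susceptibility.

    Degree brackets are half-open as conventionally tabulated: moderate
    strictly below .05, high from .05 up to (not including) .10, very high
    from .10.  Change is minor whenever |D2/D1| < .10 regardless of sign;
    an undefined ratio (D1 = 0) is labelled minor with a note.
    """
    a = abs(d1)
    if a < 0.05:
        degree = "moderate"
    elif a < 0.10:
        degree = "high"
    else:
        degree = "very high"
    direction = "zero" if d1 == 0 else ("positive" if d1 > 0 else "negative")
    note = ""
    if curvature_ratio is None:
        change = "minor"
        note = "curvature ratio undefined (first derivative is zero)"
    elif abs(curvature_ratio) < 0.10:
        change = "minor"
    else:
        change = "intensifying" if curvature_ratio > 0 else "weakening"
    return SusceptibilityLabels(degree, direction, change, note)


def taylor_estimate(summary: SummaryTriple, delta_gamma: float) -> float:
    """Quadratic (second-order Taylor) recovery of the coefficient at gamma + d.

    Needs only the published triple (I_w, D1, D2/D1) at the reported gamma.
    When the curvature ratio is undefined the quadratic term is dropped and
    the estimate is first-order.
    """
    d = delta_gamma
    if summary.curvature_ratio is None:
        return summary.coefficient_value + summary.d1 * d
    return summary.coefficient_value + summary.d1 * (
        d + 0.5 * summary.curvature_ratio * d * d
    )


def taylor_deviation(truth: float, estimate: float) -> float:
    """Signed deviation of the recovery heuristic: estimate minus exact value."""
    return estimate - truth


def summary_from_report(report) -> SummaryTriple:
    """Convenience: turn a susceptibility report into the publishable triple."""
    return SummaryTriple(
        report.gamma, report.coefficient, report.d1, report.curvature_ratio
    )
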