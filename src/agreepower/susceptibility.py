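"""Analytic sensitivity of the coefficient to the power parameter.

The coefficient I_w(gamma) = 1 - (sum_l l**g O_l) / (sum_l l**g E_l) is a
smooth function of the power parameter gamma, and both derivatives have
closed forms that decompose over pairs of category distances (l, m) with
l < m.  With T = sum_s s**g E_(s):

    D1(g) = sum_{m=2..C-1} sum_{l<m}  ln(m/l)
            * (l**g E_l / T) * (m**g E_m / T) * (O_l/E_l - O_m/E_m)

and each D2 component is the matching D1 component times the multiplier

    [ sum_s ln(l*m / s**2) s**g E_(s) ] / T.

D1 measures *susceptibility*: how strongly the coefficient value depends on
the chosen weighting scheme, and in which direction.  The ratio D2/D1
measures curvature: positive means the dependence intensifies as gamma
grows, negative means it weakens.  For three categories only one pair
(l, m) = (1, 2) exists, the coefficient is monotone in gamma, and the
susceptibility magnitude peaks at

    gamma* = ln(E_(1) / E_(2)) / ln 2,

which may be negative when the chance profile is bottom-heavy (strongly
bimodal marginals).  No closed-form peak exists for C > 3; a numeric
curvature-sign scan is provided as a heuristic extension instead.

Components are enumerated with the larger distance m outer and l < m
inner — the order in which the pairwise decomposition is conventionally
tabulated — so component tables are reproducible across runs.  The
derivative formulas are well defined at gamma = 0 (l**0 = 1), giving the
slope at identity weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ValidationError
from .profiles import DistanceProfile, coefficient
from .weights import WeightScheme

__all__ = [
    "D1_ZERO_TOL",
    "SusceptibilityReport",
    "first_derivative",
    "second_derivative",
    "curvature_ratio",
    "gamma_star",
    "gamma_star_surface",
    "curvature_sign_scan",
    "susceptibility_report",
]

#: below this magnitude D1 is treated as zero and the curvature ratio as undefined
D1_ZERO_TOL = 1e-14

_COMPONENT_COLUMNS = ["l", "m", "ratio_gap", "d1_contribution", "multiplier", "d2_contribution"]


def _pairs(C: int):
    """Distance pairs (l, m), l < m, larger distance outer."""
    for m in range(2, C):
        for l in range(1, m):
            yield l, m


def components(profile: DistanceProfile, gamma: float) -> pd.DataFrame:
    """Pairwise-distance decomposition of both derivatives at ``gamma``.

    One row per distance pair (l, m), l < m, with the observed/expected
    ratio gap, the contribution to D1, the D2 multiplier, and the
    contribution to D2.  Sums of the contribution columns give D1 and D2.
    """
    # well defined for any real gamma (all distances are >= 1); negative
    # gamma only arises when evaluating D1 at a negative gamma*
    C = profile.n_categories
    e = profile.expected
    ratios = profile.ratios
    s = np.arange(1, C, dtype=float)
    sg_e = s**gamma * e  # s^gamma E_(s)
    T = float(sg_e.sum())
    rows = []
    for l, m in _pairs(C):
        gap = float(ratios[l - 1] - ratios[m - 1])
        d1_part = np.log(m / l) * (sg_e[l - 1] / T) * (sg_e[m - 1] / T) * gap
        mult = float(np.log(l * m / s**2) @ sg_e) / T
        rows.append((l, m, gap, d1_part, mult, d1_part * mult))
    return pd.DataFrame(rows, columns=_COMPONENT_COLUMNS)


def first_derivative(profile: DistanceProfile, gamma: float) -> tuple[float, pd.DataFrame]:
    """D1(gamma) = dI_w/dgamma with its pairwise component table."""
    comp = components(profile, gamma)
    return float(comp["d1_contribution"].sum()), comp


def second_derivative(profile: DistanceProfile, gamma: float) -> tuple[float, pd.DataFrame]:
    """D2(gamma) = d^2 I_w/dgamma^2 with its pairwise component table."""
    comp = components(profile, gamma)
    return float(comp["d2_contribution"].sum()), comp


def curvature_ratio(profile: DistanceProfile, gamma: float) -> float | None:
    """D2(gamma) / D1(gamma); ``None`` (undefined) when D1 vanishes."""
    comp = components(profile, gamma)
    d1 = float(comp["d1_contribution"].sum())
    if abs(d1) < D1_ZERO_TOL:
        return None
    return float(comp["d2_contribution"].sum()) / d1


def gamma_star(profile: DistanceProfile) -> float:
    """Power parameter of maximum susceptibility, three-category closed form.

    gamma* = ln(E_(1)/E_(2)) / ln 2.  Only defined for C = 3, where the
    coefficient is monotone in gamma and |D1| has a single peak.
    """
    if profile.n_categories != 3:
        raise ValidationError(
            "gamma_star closed form is defined only for three categories"
        )
    e1, e2 = profile.expected
    return float(np.log(e1 / e2) / np.log(2.0))


def gamma_star_surface(grid_resolution: int) -> pd.DataFrame:
    """gamma* over the open simplex of symmetric three-category marginals.

    For p = q = (p1, p2, 1 - p1 - p2) the chance profile is
    E_(1) = 2 (p1 p2 + p2 p3) and E_(2) = 2 p1 p3.  Returns the columns
    (p1, p2, gamma_star) on a regular grid excluding the simplex boundary,
    suitable for contour plotting.
    """
    if grid_resolution < 2:
        raise ValidationError("grid_resolution must be at least 2")
    step = 1.0 / grid_resolution
    vals = np.arange(1, grid_resolution) * step
    rows = []
    for p1 in vals:
        for p2 in vals:
            p3 = 1.0 - p1 - p2
            if p3 <= step / 2:  # stay strictly inside the simplex
                continue
            e1 = 2.0 * (p1 * p2 + p2 * p3)
            e2 = 2.0 * p1 * p3
            rows.append((p1, p2, float(np.log(e1 / e2) / np.log(2.0))))
    return pd.DataFrame(rows, columns=["p1", "p2", "gamma_star"])


def curvature_sign_scan(
    profile: DistanceProfile, gammas=None
) -> pd.DataFrame:
    """Sign of D2 over a gamma grid, flagging sign changes.

    Heuristic extension for C > 3, where no closed-form susceptibility peak
    exists: a sign change of D2 between grid points brackets a local
    extremum of D1.  Columns: gamma, d1, d2, sign_change.
    """
    if gammas is None:
        gammas = np.linspace(0.0, 6.0, 61)
    gammas = np.asarray(gammas, dtype=float)
    d1s, d2s = [], []
    for g in gammas:
        comp = components(profile, float(g))
        d1s.append(float(comp["d1_contribution"].sum()))
        d2s.append(float(comp["d2_contribution"].sum()))
    d2s = np.array(d2s)
    change = np.zeros(gammas.size, dtype=bool)
    change[1:] = np.sign(d2s[1:]) * np.sign(d2s[:-1]) < 0
    return pd.DataFrame(
        {"gamma": gammas, "d1": d1s, "d2": d2s, "sign_change": change}
    )


@dataclass(frozen=True)
class SusceptibilityReport:
    """Coefficient value, derivatives, curvature and peak location at one gamma.

    ``curvature_ratio`` is ``None`` when D1 vanishes; ``gamma_star`` and
    ``d1_at_gamma_star`` are ``None`` unless C = 3.
    """

    gamma: float
    coefficient: float
    d1: float
    d2: float
    curvature_ratio: float | None
    gamma_star: float | None
    d1_at_gamma_star: float | None
    components: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "coefficient": self.coefficient,
            "d1": self.d1,
            "d2": self.d2,
            "curvature_ratio": self.curvature_ratio,
            "gamma_star": self.gamma_star,
            "d1_at_gamma_star": self.d1_at_gamma_star,
            "components": self.components.to_dict(orient="records"),
        }


def susceptibility_report(profile: DistanceProfile, gamma: float) -> SusceptibilityReport:
    """Full susceptibility summary of a distance profile at one gamma."""
    comp = components(profile, gamma)
    d1 = float(comp["d1_contribution"].sum())
    d2 = float(comp["d2_contribution"].sum())
    ratio = d2 / d1 if abs(d1) >= D1_ZERO_TOL else None
    gs = d1_star = None
    if profile.n_categories == 3:
        gs = gamma_star(profile)
        d1_star = first_derivative(profile, gs)[0]
    iw = coefficient(profile, WeightScheme(gamma, profile.n_categories))
    return SusceptibilityReport(gamma, iw, d1, d2, ratio, gs, d1_star, comp)
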