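"""QTc-dependent health-state utility curves.

Utility declines as the corrected QT interval (QTc) grows, because QTc beyond
about 500 ms sharply raises the risk of torsade de pointes.  The baseline
curve is a decreasing sigmoid inflected at 500 ms — concave (risk-averse)
below the inflection, convex (risk-seeking) above it:

    U(QTc) = Min + (Max − Min) / (1 + exp(Slope · (QTc − ref)))

Two curves are carried: one for improved delirium (default Min 30, Max 100)
and one for unimproved delirium (default Min 0, Max 30), so the improved
curve dominates everywhere.  For sensitivity analysis of the risk attitude,
alternative families with fixed second-derivative sign are provided: linear
(zero), exponential convex (positive) and exponential concave (negative),
anchored to the same endpoint utilities on a bounded QTc domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UtilityParams",
    "UtilityPair",
    "FAMILIES",
    "sigmoid_utility",
    "variant_utility",
    "utility_value",
    "utility_table",
    "default_pair",
    "default_sweep_patterns",
]

FAMILIES = ("sigmoid", "linear", "exp_convex", "exp_concave")

#: anchoring domain (ms) for the linear/exponential variant families
DEFAULT_DOMAIN = (380.0, 620.0)

#: curvature constant of the exponential variants; |k| fixes how far they
#: bow away from the linear anchor line
EXP_CURVATURE = 3.0

#: Table-style presentation grid; infinities map to the curve limits
DEFAULT_QTC_GRID = (-math.inf, 420.0, 450.0, 480.0, 510.0, 540.0, 570.0, math.inf)


class UtilityError(ValueError):
    """Raised for invalid utility parameters or unknown curve families."""


@dataclass(frozen=True)
class UtilityParams:
    """Parameters of one utility curve over QTc.

    ``u_max`` is the utility as QTc → −∞ and ``u_min`` the utility as
    QTc → +∞ (the curves decrease).  ``slope`` is the sigmoid steepness in
    1/ms; ``qtc_ref`` the inflection point in ms (500 by default, where
    torsade risk takes off).
    """

    u_min: float
    u_max: float
    slope: float = 0.05
    qtc_ref: float = 500.0

    def __post_init__(self) -> None:
        if not (self.u_min < self.u_max):
            raise UtilityError(f"u_min must be < u_max (got {self.u_min} >= {self.u_max})")
        if not (self.slope > 0):
            raise UtilityError(f"slope must be > 0 (got {self.slope})")


@dataclass(frozen=True)
class UtilityPair:
    """Improved/unimproved curve pair plus the curve family in force."""

    improved: UtilityParams = UtilityParams(u_min=30.0, u_max=100.0)
    unimproved: UtilityParams = UtilityParams(u_min=0.0, u_max=30.0)
    family: str = "sigmoid"
    domain: tuple[float, float] = DEFAULT_DOMAIN

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UtilityError(f"unknown utility family {self.family!r}; expected one of {FAMILIES}")
        a, b = self.domain
        if not (a < b):
            raise UtilityError(f"domain must be an increasing interval (got {self.domain})")
        # pointwise dominance of the improved curve holds whenever its range
        # sits at or above the unimproved range with matching shape parameters
        if self.improved.u_min < self.unimproved.u_min or self.improved.u_max <= self.unimproved.u_max:
            raise UtilityError(
                "improved curve must dominate the unimproved curve "
                f"(improved [{self.improved.u_min}, {self.improved.u_max}] vs "
                f"unimproved [{self.unimproved.u_min}, {self.unimproved.u_max}])"
            )

    def values(self, qtc):
        """(improved, unimproved) utilities at ``qtc`` (scalar or array)."""
        return (
            utility_value(qtc, self.improved, self.family, self.domain),
            utility_value(qtc, self.unimproved, self.family, self.domain),
        )


def default_pair() -> UtilityPair:
    """The baseline sigmoid pair: improved Min 30/Max 100, unimproved 0/30, slope 0.05."""
    return UtilityPair()


def sigmoid_utility(qtc, params: UtilityParams):
    """Decreasing sigmoid utility, inflected at ``params.qtc_ref``.

    Accepts scalars or numpy arrays; values lie strictly in
    ``(u_min, u_max)`` for finite QTc and reach the limits at ±∞.
    """
    q = np.asarray(qtc, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates to the u_min limit
        out = params.u_min + (params.u_max - params.u_min) / (
            1.0 + np.exp(params.slope * (q - params.qtc_ref))
        )
    # exp overflow at extreme QTc saturates to the limits, which is exact
    out = np.where(np.isposinf(q), params.u_min, out)
    out = np.where(np.isneginf(q), params.u_max, out)
    return float(out) if np.isscalar(qtc) or np.ndim(qtc) == 0 else out


def variant_utility(qtc, params: UtilityParams, family: str,
                    domain: tuple[float, float] = DEFAULT_DOMAIN):
    """Risk-attitude variant curves: linear, exp_convex or exp_concave.

    Each is strictly decreasing on the anchoring ``domain`` [a, b] with
    value ``u_max`` at a and ``u_min`` at b, and clamps to those limits
    outside.  The exponential forms are

        u(q) = u_min + (u_max − u_min) · (exp(k·s) − 1) / (exp(k) − 1),

    with ``s`` the normalised reversed position (b − q)/(b − a) and the sign
    of ``k`` selecting the second-derivative sign (k > 0 convex, k < 0
    concave in q).
    """
    if family == "sigmoid":
        return sigmoid_utility(qtc, params)
    if family not in FAMILIES:
        raise UtilityError(f"unknown utility family {family!r}; expected one of {FAMILIES}")
    a, b = domain
    q = np.asarray(qtc, dtype=float)
    s = np.clip((b - q) / (b - a), 0.0, 1.0)  # 1 at a (best), 0 at b (worst)
    span = params.u_max - params.u_min
    if family == "linear":
        frac = s
    else:
        k = EXP_CURVATURE if family == "exp_convex" else -EXP_CURVATURE
        frac = np.expm1(k * s) / math.expm1(k)
    out = params.u_min + span * frac
    return float(out) if np.isscalar(qtc) or np.ndim(qtc) == 0 else out


def utility_value(qtc, params: UtilityParams, family: str = "sigmoid",
                  domain: tuple[float, float] = DEFAULT_DOMAIN):
    """Dispatch to the requested curve family."""
    if family == "sigmoid":
        return sigmoid_utility(qtc, params)
    return variant_utility(qtc, params, family, domain)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def utility_table(pair: UtilityPair, grid: Sequence[float] = DEFAULT_QTC_GRID,
                  rounded: bool = True) -> pd.DataFrame:
    """Tabulate the pair's utilities over a QTc grid.

    With ``rounded=True`` values are presented as integers (half away from
    zero), the convention of the published default-utility table; infinite
    grid entries report the curve limits.
    """
    if len(grid) == 0:
        raise UtilityError("grid must be non-empty")
    rows = []
    for q in grid:
        ui, uu = pair.values(q)
        if rounded:
            ui, uu = _round_half_away(ui), _round_half_away(uu)
        label = {-math.inf: "-inf", math.inf: "inf"}.get(q, q)
        rows.append({"qtc": label, "improved": ui, "unimproved": uu})
    return pd.DataFrame(rows)


def default_sweep_patterns(
    improved_mins: Iterable[float] = (10.0, 30.0, 50.0),
    unimproved_maxs: Iterable[float] = (10.0, 30.0, 50.0),
    slopes: Iterable[float] = (0.025, 0.05, 0.1),
) -> list[UtilityPair]:
    """Cross-product of utility-parameter patterns for the sensitivity sweep.

    Combinations where the unimproved maximum falls below the improved
    minimum are excluded: they would open a dead utility band no health
    state can reach, which no elicitation would produce.
    """
    patterns = []
    for imp_min in improved_mins:
        for unimp_max in unimproved_maxs:
            if unimp_max < imp_min:
                continue
            for slope in slopes:
                patterns.append(
                    UtilityPair(
                        improved=UtilityParams(u_min=imp_min, u_max=100.0, slope=slope),
                        unimproved=UtilityParams(u_min=0.0, u_max=unimp_max, slope=slope),
                    )
                )
    return patterns
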