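"""The single-stage decision tree and its deterministic evaluation.

A clinician chooses one option (a drug or placebo) at the decision node; the
chance node then resolves to improved or unimproved delirium with the
option's transition probability ``p``.  The QTc interval on treatment is the
baseline value plus the drug's mean QTc shift, and each leaf is valued by
the corresponding utility curve:

    EU = p · U_improved(baseline + Δqtc) + (1 − p) · U_unimproved(baseline + Δqtc)

Placebo is modelled as ``p = p0`` with zero QTc shift and takes part in every
ranking.  Evaluating all options over a grid of baseline QTc values yields a
utility matrix whose per-baseline argmax identifies the preferred option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .effect_table import EffectSizeRecord, EffectTable
from .utility import UtilityPair, default_pair

__all__ = [
    "PLACEBO_LABEL",
    "EvaluationGrid",
    "expected_utility",
    "evaluate_treatment",
    "evaluate_grid",
    "rank_treatments",
]

PLACEBO_LABEL = "Placebo"

#: physiologic plausibility band for baseline QTc (ms); outside it we warn
_PHYSIOLOGIC = (300.0, 700.0)


class DecisionModelError(ValueError):
    """Raised for invalid decision-model inputs."""


@dataclass(frozen=True)
class EvaluationGrid:
    """Ordered baseline-QTc values (ms) at which the tree is evaluated."""

    baselines: tuple[float, ...] = (420.0, 450.0, 480.0, 510.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "baselines", tuple(float(b) for b in self.baselines))
        if len(self.baselines) == 0:
            raise DecisionModelError("grid must contain at least one baseline")
        if any(b2 <= b1 for b1, b2 in zip(self.baselines, self.baselines[1:])):
            raise DecisionModelError(f"baselines must be strictly increasing: {self.baselines}")
        lo, hi = _PHYSIOLOGIC
        if any(not (lo <= b <= hi) for b in self.baselines):
            warnings.warn(
                f"baseline QTc outside the physiologic range {_PHYSIOLOGIC}: {self.baselines}",
                stacklevel=2,
            )

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "EvaluationGrid":
        """A regular grid, e.g. for exporting smooth utility curves."""
        return cls(tuple(np.arange(start, stop + 0.5 * step, step)))


def expected_utility(p, qtc_on_drug, pair: UtilityPair | None = None):
    """Probability-weighted utility of the improved/unimproved leaves.

    Linear (a convex combination) in ``p``; accepts scalars or broadcastable
    arrays for both ``p`` and ``qtc_on_drug``.
    """
    pair = pair or default_pair()
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0.0) | (p_arr > 1.0)):
        raise DecisionModelError(f"probability must lie in [0, 1], got {p!r}")
    u_imp, u_unimp = pair.values(qtc_on_drug)
    out = p_arr * u_imp + (1.0 - p_arr) * u_unimp
    return float(out) if out.ndim == 0 else out


def evaluate_treatment(record: EffectSizeRecord, baseline_qtc, pair: UtilityPair | None = None):
    """Point-estimate expected utility of one drug at a baseline QTc.

    The on-treatment QTc is the baseline plus the drug's mean shift.
    """
    return expected_utility(record.p, np.asarray(baseline_qtc, dtype=float) + record.dqtc, pair)


def placebo_utility(baseline_qtc, pair: UtilityPair | None = None, p0: float = 0.5):
    """Expected utility of placebo: probability ``p0``, zero QTc shift."""
    return expected_utility(p0, baseline_qtc, pair)


def evaluate_grid(
    table: EffectTable,
    grid: EvaluationGrid | None = None,
    pair: UtilityPair | None = None,
) -> pd.DataFrame:
    """Expected-utility matrix: options as rows (placebo first), baselines as columns."""
    grid = grid or EvaluationGrid()
    pair = pair or default_pair()
    baselines = np.asarray(grid.baselines)
    rows = {PLACEBO_LABEL: placebo_utility(baselines, pair, table.p0)}
    for rec in table:
        rows[rec.name] = evaluate_treatment(rec, baselines, pair)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(grid.baselines))


def rank_treatments(
    matrix: pd.DataFrame, baseline: float, precision: int | None = 2
) -> list[tuple[str, float]]:
    """Options ranked by utility at one baseline, best first.

    Utilities are compared at the reporting precision (``precision`` decimal
    places, default 2, the convention of the deterministic outputs): effect
    sizes enter the model with three significant decimals, so differences
    below a hundredth of a utility unit are not resolvable and count as
    ties.  Ties keep matrix (i.e. input-table) order; placebo is ranked
    with the drugs.  Pass ``precision=None`` to compare exact values.
    ``baseline`` must be one of the matrix columns.
    """
    if baseline not in matrix.columns:
        raise DecisionModelError(
            f"baseline {baseline} not in evaluated grid {list(matrix.columns)}"
        )
    col = matrix[baseline]
    key = col if precision is None else col.round(precision)
    order = sorted(range(len(col)), key=lambda i: (-key.iloc[i], i))
    return [(matrix.index[i], float(col.iloc[i])) for i in order]
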