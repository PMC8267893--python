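"""Probabilistic sensitivity analysis (PSA) by Monte Carlo simulation.

Effect-size uncertainty is propagated through the decision tree: each draw
samples every drug's transition probability and QTc shift from normal
distributions whose 95% intervals match the plausible ranges, re-evaluates
the tree, and records which option attains the highest utility.  Placebo's
utility is deterministic (its probability ``p0`` and zero QTc shift carry no
sampled uncertainty) but competes in the per-draw argmax.

Probabilities are sampled on the log-odds-ratio scale by default — the
plausible ranges are symmetric there, while no natural-scale normal can
match both of their asymmetric probability bounds — and mapped back through
the odds-ratio transform, which also keeps every sampled probability inside
(0, 1).  A truncated-normal-on-p alternative is available for robustness
comparison.  QTc shifts are sampled on the natural millisecond scale.

A deterministic Gauss–Hermite quadrature oracle of the same expectation is
provided to cross-check Monte Carlo means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import roots_hermitenorm

from .decision import PLACEBO_LABEL, EvaluationGrid, expected_utility, placebo_utility
from .effect_table import (
    EffectSizeRecord,
    EffectTable,
    logit_scale_params,
    or_to_probability,
    qtc_scale_params,
)
from .utility import UtilityPair, default_pair

__all__ = ["PsaConfig", "PsaResult", "sample_effects", "run_psa", "quadrature_oracle"]

DEFAULT_SEED = 20210625


class PsaError(ValueError):
    """Raised for invalid PSA configuration."""


@dataclass(frozen=True)
class PsaConfig:
    """Monte Carlo settings.

    ``probability_scale`` selects where the probability's normal lives:
    ``"log_or"`` (default) or ``"truncated_normal_p"``.  With
    ``share_draws_across_baselines`` (default) one draw matrix is reused for
    every baseline column, so columns differ only through the utility
    argument.
    """

    n_draws: int = 10_000
    seed: int = DEFAULT_SEED
    probability_scale: Literal["log_or", "truncated_normal_p"] = "log_or"
    share_draws_across_baselines: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.n_draws, int) and self.n_draws >= 1):
            raise PsaError(f"n_draws must be a positive integer, got {self.n_draws!r}")
        if self.probability_scale not in ("log_or", "truncated_normal_p"):
            raise PsaError(f"unknown probability_scale {self.probability_scale!r}")


@dataclass(frozen=True)
class PsaResult:
    """Summary of one PSA run.

    ``summary`` holds one row per (treatment, baseline) with columns
    ``mean``, ``sd``, ``mc_se``, ``p_highest`` and ``p_beats_placebo``
    (the last two in percent); the placebo rows carry its fixed utility with
    sd 0.  ``config`` echoes the settings that produced it.
    """

    summary: pd.DataFrame
    config: PsaConfig
    baselines: tuple[float, ...]
    names: tuple[str, ...]  # placebo first

    def cell(self, name: str, baseline: float) -> pd.Series:
        sub = self.summary[(self.summary["name"] == name) & (self.summary["baseline"] == baseline)]
        if sub.empty:
            raise KeyError((name, baseline))
        return sub.iloc[0]

    def table3_style(self) -> pd.DataFrame:
        """Presentation copy shaped like the published PSA table.

        Placebo shows its fixed utility; drugs show ``mean (SD)`` to two
        decimals; percentages are rounded to integers.
        """
        blocks = []
        for name in self.names:
            rows = {}
            for b in self.baselines:
                c = self.cell(name, b)
                if name == PLACEBO_LABEL:
                    rows.setdefault("Utility (fixed)", {})[b] = f"{c['mean']:.2f}"
                else:
                    rows.setdefault("Utility, mean (SD)", {})[b] = f"{c['mean']:.2f} ({c['sd']:.2f})"
                rows.setdefault("Highest utility", {})[b] = f"{round(c['p_highest'])}%"
                if name != PLACEBO_LABEL:
                    rows.setdefault("Higher than placebo", {})[b] = f"{round(c['p_beats_placebo'])}%"
            df = pd.DataFrame(rows).T
            df.index = pd.MultiIndex.from_product([[name], df.index])
            blocks.append(df)
        return pd.concat(blocks)


def sample_effects(
    table: EffectTable, config: PsaConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (p, Δqtc) draws for every treatment.

    Returns two arrays of shape ``(n_treatments, n_draws)`` in table order.
    Draws are independent across treatments and between the two quantities;
    degenerate intervals reproduce the point estimates exactly.
    """
    n = config.n_draws
    p_draws = np.empty((len(table), n))
    q_draws = np.empty((len(table), n))
    for i, rec in enumerate(table):
        if config.probability_scale == "log_or":
            mean, sd = logit_scale_params(rec, table.p0)
            if sd == 0.0:
                p_draws[i] = rec.p
            else:
                lor = rng.normal(mean, sd, size=n)
                odds = np.exp(lor) * table.p0 / (1.0 - table.p0)
                p_draws[i] = odds / (1.0 + odds)
        else:  # truncated normal directly on the probability scale
            sd = (rec.p_hi - rec.p_lo) / (2.0 * 1.959964)
            if sd == 0.0:
                p_draws[i] = rec.p
            else:
                a, b = (0.0 - rec.p) / sd, (1.0 - rec.p) / sd
                p_draws[i] = stats.truncnorm.rvs(a, b, loc=rec.p, scale=sd, size=n, random_state=rng)
        q_mean, q_sd = qtc_scale_params(rec)
        q_draws[i] = rec.dqtc if q_sd == 0.0 else rng.normal(q_mean, q_sd, size=n)
    return p_draws, q_draws


def run_psa(
    table: EffectTable,
    grid: EvaluationGrid | None = None,
    pair: UtilityPair | None = None,
    config: PsaConfig | None = None,
) -> PsaResult:
    """Run the Monte Carlo PSA over a baseline-QTc grid.

    Per draw and baseline, each drug's utility is the decision-tree expected
    utility at its sampled ``(p, Δqtc)``; placebo's is the fixed
    deterministic value.  ``p_highest`` counts per-draw argmax wins among
    all options (ties to the earlier option, placebo first);
    ``p_beats_placebo`` counts draws strictly above placebo.
    """
    grid = grid or EvaluationGrid()
    pair = pair or default_pair()
    config = config or PsaConfig()
    rng = np.random.default_rng(config.seed)

    names = (PLACEBO_LABEL, *table.names)
    p_draws, q_draws = sample_effects(table, config, rng)

    records = []
    for baseline in grid.baselines:
        if not config.share_draws_across_baselines:
            p_draws, q_draws = sample_effects(table, config, rng)
        u_placebo = placebo_utility(baseline, pair, table.p0)
        # options × draws utility matrix, placebo's constant row first
        util = np.vstack(
            [
                np.full(config.n_draws, u_placebo),
                expected_utility(p_draws, baseline + q_draws, pair),
            ]
        )
        winner = util.argmax(axis=0)
        for j, name in enumerate(names):
            u = util[j]
            sd = float(u.std(ddof=1)) if config.n_draws > 1 else 0.0
            records.append(
                {
                    "name": name,
                    "baseline": baseline,
                    "mean": float(u.mean()),
                    "sd": sd,
                    "mc_se": sd / math.sqrt(config.n_draws),
                    "p_highest": 100.0 * float((winner == j).mean()),
                    "p_beats_placebo": (
                        np.nan if name == PLACEBO_LABEL else 100.0 * float((u > u_placebo).mean())
                    ),
                }
            )
    return PsaResult(
        summary=pd.DataFrame(records),
        config=config,
        baselines=grid.baselines,
        names=names,
    )


def quadrature_oracle(
    record: EffectSizeRecord,
    baseline: float,
    pair: UtilityPair | None = None,
    p0: float = 0.5,
    n_nodes: int = 60,
) -> float:
    """Expected utility under the log-OR sampling distribution, by quadrature.

    Tensor-product Gauss–Hermite integration of the decision-tree utility
    over the independent (log-OR, Δqtc) normal density — a deterministic
    cross-check for Monte Carlo means.  Degenerate distributions collapse to
    the point-estimate utility.
    """
    pair = pair or default_pair()
    lor_mean, lor_sd = logit_scale_params(record, p0)
    q_mean, q_sd = qtc_scale_params(record)

    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / math.sqrt(2.0 * math.pi)  # normalise to a probability measure

    def p_nodes(sd: float) -> tuple[np.ndarray, np.ndarray]:
        if sd == 0.0:
            return np.array([record.p]), np.array([1.0])
        odds = np.exp(lor_mean + sd * nodes) * p0 / (1.0 - p0)
        return odds / (1.0 + odds), weights

    def q_nodes(sd: float) -> tuple[np.ndarray, np.ndarray]:
        if sd == 0.0:
            return np.array([q_mean]), np.array([1.0])
        return q_mean + sd * nodes, weights

    ps, wp = p_nodes(lor_sd)
    qs, wq = q_nodes(q_sd)
    util = expected_utility(ps[:, None], baseline + qs[None, :], pair)
    return float(wp @ util @ wq)
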