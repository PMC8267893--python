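"""Run configuration, sensitivity sweeps, and report assembly.

A :class:`RunConfig` collects everything a run needs — effect-table path,
utility settings, baseline grid, PSA settings, output directory — and
round-trips through YAML.  :func:`run_sensitivity_sweep` re-evaluates the
tree under many utility-parameter patterns and curve families to check how
robust the per-baseline ranking is; :func:`render_reports` writes the
deterministic utility matrix, the utility table, the PSA summary (both the
presentation copy and an unrounded machine CSV), the sweep summary, and a
run manifest sufficient to reproduce every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from collections import Counter
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .decision import EvaluationGrid, evaluate_grid, rank_treatments
from .effect_table import EffectTable, load_effect_table, reference_table
from .psa import PsaConfig, PsaResult, run_psa
from .utility import (
    FAMILIES,
    UtilityPair,
    UtilityParams,
    default_pair,
    default_sweep_patterns,
    utility_table,
)

__all__ = ["RunConfig", "run_sensitivity_sweep", "render_reports", "SweepReport"]

log = logging.getLogger("qtcda")


@dataclass(frozen=True)
class RunConfig:
    """Complete, serialisable description of one analysis run."""

    effect_table: str | None = None  # path; None -> packaged reference table
    p0: float = 0.5
    improved_min: float = 30.0
    improved_max: float = 100.0
    unimproved_min: float = 0.0
    unimproved_max: float = 30.0
    slope: float = 0.05
    family: str = "sigmoid"
    baselines: tuple[float, ...] = (420.0, 450.0, 480.0, 510.0)
    n_draws: int = 10_000
    seed: int = 20_210_625
    probability_scale: str = "log_or"
    output_dir: str = "qtcda_out"

    def pair(self) -> UtilityPair:
        return UtilityPair(
            improved=UtilityParams(u_min=self.improved_min, u_max=self.improved_max, slope=self.slope),
            unimproved=UtilityParams(u_min=self.unimproved_min, u_max=self.unimproved_max, slope=self.slope),
            family=self.family,
        )

    def grid(self) -> EvaluationGrid:
        return EvaluationGrid(tuple(self.baselines))

    def psa_config(self) -> PsaConfig:
        return PsaConfig(
            n_draws=self.n_draws, seed=self.seed, probability_scale=self.probability_scale
        )

    def table(self) -> EffectTable:
        if self.effect_table is None:
            return reference_table(p0=self.p0)
        return load_effect_table(self.effect_table, p0=self.p0)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["baselines"] = list(self.baselines)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "baselines" in d:
            d["baselines"] = tuple(float(b) for b in d["baselines"])
        return cls(**d)


@dataclass(frozen=True)
class SweepReport:
    """Per-pattern argmax bookkeeping from a utility-settings sweep."""

    results: pd.DataFrame  # one row per pattern × family × baseline
    modal_argmax: dict[float, str]
    default_argmax: dict[float, str]
    ranking_stable: bool  # modal argmax equals the default-setting argmax everywhere
    n_patterns: int
    n_skipped: int


def run_sensitivity_sweep(
    table: EffectTable,
    grid: EvaluationGrid | None = None,
    patterns: Sequence[UtilityPair] | None = None,
    families: Sequence[str] = FAMILIES,
) -> SweepReport:
    """Evaluate the tree under many utility settings and summarise rankings.

    Each pattern is crossed with each curve family; invalid combinations are
    skipped with a warning.  The report records, per baseline, the modal
    best option across all settings and whether it matches the best option
    under the default sigmoid settings.
    """
    grid = grid or EvaluationGrid()
    if patterns is None:
        patterns = default_sweep_patterns()
    if len(patterns) == 0:
        raise ValueError("sweep requires at least one utility pattern")

    default_matrix = evaluate_grid(table, grid, default_pair())
    default_argmax = {b: rank_treatments(default_matrix, b)[0][0] for b in grid.baselines}

    rows, skipped = [], 0
    for i, pattern in enumerate(patterns):
        for family in families:
            try:
                pair = replace(pattern, family=family)
            except ValueError as exc:
                skipped += 1
                log.warning("skipping pattern %d / family %s: %s", i, family, exc)
                continue
            matrix = evaluate_grid(table, grid, pair)
            for b in grid.baselines:
                best, best_u = rank_treatments(matrix, b)[0]
                rows.append(
                    {
                        "pattern": i,
                        "family": family,
                        "improved_min": pair.improved.u_min,
                        "unimproved_max": pair.unimproved.u_max,
                        "slope": pair.improved.slope,
                        "baseline": b,
                        "argmax": best,
                        "utility": best_u,
                    }
                )
    results = pd.DataFrame(rows)
    modal = {
        b: Counter(results.loc[results["baseline"] == b, "argmax"]).most_common(1)[0][0]
        for b in grid.baselines
    }
    return SweepReport(
        results=results,
        modal_argmax=modal,
        default_argmax=default_argmax,
        ranking_stable=all(modal[b] == default_argmax[b] for b in grid.baselines),
        n_patterns=len(patterns),
        n_skipped=skipped,
    )


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True, default=str).encode()).hexdigest()[:16]


def render_reports(
    config: RunConfig,
    matrix: pd.DataFrame | None = None,
    psa: PsaResult | None = None,
    sweep: SweepReport | None = None,
) -> dict[str, Path]:
    """Write all completed analyses to ``config.output_dir`` and a manifest.

    Machine CSVs are unrounded; presentation copies carry the published
    rounding conventions.  Returns the mapping of artifact name to path.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    pair = config.pair()
    ut = utility_table(pair)
    ut_path = out / "utility_table.csv"
    ut.to_csv(ut_path, index=False)
    written["utility_table"] = ut_path

    if matrix is not None:
        p = out / "utility_matrix.csv"
        matrix.to_csv(p, index_label="option")
        written["utility_matrix"] = p
    if psa is not None:
        p = out / "psa_summary.csv"
        psa.summary.to_csv(p, index=False)
        written["psa_summary"] = p
        p = out / "psa_table.csv"
        psa.table3_style().to_csv(p, index_label=("option", "metric"))
        written["psa_table"] = p
    if sweep is not None:
        p = out / "sweep_results.csv"
        sweep.results.to_csv(p, index=False)
        written["sweep_results"] = p
        p = out / "sweep_summary.json"
        p.write_text(
            json.dumps(
                {
                    "modal_argmax": {str(k): v for k, v in sweep.modal_argmax.items()},
                    "default_argmax": {str(k): v for k, v in sweep.default_argmax.items()},
                    "ranking_stable": sweep.ranking_stable,
                    "n_patterns": sweep.n_patterns,
                    "n_skipped": sweep.n_skipped,
                },
                indent=2,
            )
        )
        written["sweep_summary"] = p

    manifest = {
        "qtcda_version": __version__,
        "python": platform.python_version(),
        "config": {**asdict(config), "baselines": list(config.baselines)},
        "config_hash": _config_hash(config),
        "artifacts": {k: str(v) for k, v in written.items()},
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = mp
    for k, v in manifest["config"].items():
        log.info("config %s = %r", k, v)
    return written
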