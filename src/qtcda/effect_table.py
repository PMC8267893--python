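"""Treatment effect-size tables and the odds-ratio ↔ probability transform.

Each treatment is summarised by two effect sizes pooled upstream by network
meta-analyses: an odds ratio for improvement of delirium versus placebo
(equivalently a transition probability once a placebo rate ``p0`` is fixed)
and a mean shift of the heart-rate-corrected QT interval (QTc) in
milliseconds.  Uncertainty intervals for the probability are symmetric on the
log-odds-ratio scale, as meta-analytic confidence intervals are; QTc-shift
intervals are symmetric on the natural (millisecond) scale.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "EffectSizeRecord",
    "EffectTable",
    "or_to_probability",
    "probability_to_or",
    "logit_scale_params",
    "load_effect_table",
    "write_effect_table",
    "reference_table",
]

#: two-sided 95% normal quantile used everywhere an interval is (un)packed
Z95 = 1.959964

#: maximum tolerated asymmetry of the implied log-OR interval, as absolute
#: distance between the interval midpoint and the point estimate (log-OR units)
LOG_OR_SYMMETRY_TOL = 0.03


class EffectTableError(ValueError):
    """Raised when an effect table or one of its records is invalid."""


def or_to_probability(or_value: float, p0: float) -> float:
    """Convert an odds ratio versus placebo into a transition probability.

    With placebo improvement probability ``p0``, the treatment's probability
    satisfies ``OR = [p/(1-p)] / [p0/(1-p0)]``, hence
    ``p = A/(1+A)`` with ``A = OR * p0/(1-p0)``.

    Parameters
    ----------
    or_value : float
        Odds ratio, strictly positive.
    p0 : float
        Placebo transition probability, in (0, 1).

    Returns
    -------
    float
        Transition probability in (0, 1); strictly increasing in ``or_value``.
    """
    if not (or_value > 0) or not math.isfinite(or_value):
        raise EffectTableError(f"odds ratio must be finite and > 0, got {or_value!r}")
    _check_open_unit(p0, "p0")
    a = or_value * p0 / (1.0 - p0)
    return a / (1.0 + a)


def probability_to_or(p: float, p0: float) -> float:
    """Exact algebraic inverse of :func:`or_to_probability`."""
    _check_open_unit(p, "p")
    _check_open_unit(p0, "p0")
    return (p / (1.0 - p)) / (p0 / (1.0 - p0))


def _check_open_unit(x: float, name: str) -> None:
    if not (0.0 < x < 1.0):
        raise EffectTableError(f"{name} must lie strictly in (0, 1), got {x!r}")


@dataclass(frozen=True)
class EffectSizeRecord:
    """One treatment's improvement probability and QTc shift with 95% bounds.

    Attributes
    ----------
    name : str
        Treatment label.
    p, p_lo, p_hi : float
        Transition probability to improved status and its plausible-range
        bounds, all in (0, 1) with ``p_lo <= p <= p_hi``.
    dqtc, dqtc_lo, dqtc_hi : float
        Mean QTc shift in ms and its 95% CI bounds, ``dqtc_lo <= dqtc <= dqtc_hi``.
    """

    name: str
    p: float
    p_lo: float
    p_hi: float
    dqtc: float
    dqtc_lo: float
    dqtc_hi: float

    def __post_init__(self) -> None:
        if not self.name:
            raise EffectTableError("treatment name must be non-empty")
        for f in ("p", "p_lo", "p_hi", "dqtc", "dqtc_lo", "dqtc_hi"):
            v = getattr(self, f)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise EffectTableError(f"{self.name}: field {f!r} must be a finite number, got {v!r}")
        for f in ("p", "p_lo", "p_hi"):
            _check_open_unit(getattr(self, f), f"{self.name}.{f}")
        if not (self.p_lo <= self.p <= self.p_hi):
            raise EffectTableError(
                f"{self.name}: probability bounds must satisfy p_lo <= p <= p_hi "
                f"(got {self.p_lo}, {self.p}, {self.p_hi})"
            )
        if not (self.dqtc_lo <= self.dqtc <= self.dqtc_hi):
            raise EffectTableError(
                f"{self.name}: QTc-shift bounds must satisfy lo <= point <= hi "
                f"(got {self.dqtc_lo}, {self.dqtc}, {self.dqtc_hi})"
            )
        self._check_log_symmetry()

    def _check_log_symmetry(self) -> None:
        # The plausible range is read as a log-symmetric OR interval; a grossly
        # asymmetric one means the table was built on a different scale.
        if self.p_lo == self.p_hi:
            return
        logit = lambda x: math.log(x / (1.0 - x))  # noqa: E731
        mid = 0.5 * (logit(self.p_lo) + logit(self.p_hi))
        if abs(mid - logit(self.p)) > LOG_OR_SYMMETRY_TOL:
            raise EffectTableError(
                f"{self.name}: probability range is not log-OR symmetric "
                f"(midpoint {mid:.4f} vs point {logit(self.p):.4f})"
            )

    @property
    def is_degenerate(self) -> bool:
        """True when both uncertainty intervals have zero width."""
        return self.p_lo == self.p_hi and self.dqtc_lo == self.dqtc_hi


def logit_scale_params(record: EffectSizeRecord, p0: float) -> tuple[float, float]:
    """Normal parameters of the record's uncertainty on the log-OR scale.

    The mean is the log odds ratio implied by the point probability; the
    standard deviation is the half-width of the implied log-OR interval
    divided by the 95% normal quantile.  A degenerate interval yields sd 0.
    """
    mean = math.log(probability_to_or(record.p, p0))
    if record.p_lo == record.p_hi:
        return mean, 0.0
    lo = math.log(probability_to_or(record.p_lo, p0))
    hi = math.log(probability_to_or(record.p_hi, p0))
    return mean, (hi - lo) / (2.0 * Z95)


def qtc_scale_params(record: EffectSizeRecord) -> tuple[float, float]:
    """Normal (mean, sd) of the QTc shift, in ms, from its 95% CI."""
    return record.dqtc, (record.dqtc_hi - record.dqtc_lo) / (2.0 * Z95)


@dataclass(frozen=True)
class EffectTable:
    """Ordered collection of treatment records plus the placebo rate ``p0``.

    Record order is significant: it defines reporting order and breaks ties.
    """

    records: tuple[EffectSizeRecord, ...]
    p0: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        _check_open_unit(self.p0, "p0")
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise EffectTableError(f"duplicate treatment names: {sorted(dupes)}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> EffectSizeRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame in record order."""
        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "p": r.p,
                    "p_lo": r.p_lo,
                    "p_hi": r.p_hi,
                    "dqtc": r.dqtc,
                    "dqtc_lo": r.dqtc_lo,
                    "dqtc_hi": r.dqtc_hi,
                }
                for r in self.records
            ]
        )


_PROB_COLS = ("p", "p_lo", "p_hi")
_OR_COLS = ("or", "or_lo", "or_hi")
_QTC_COLS = ("dqtc", "dqtc_lo", "dqtc_hi")


def load_effect_table(
    source: Union[str, Path, io.IOBase, pd.DataFrame],
    p0: float = 0.5,
    sep: str | None = None,
) -> EffectTable:
    """Read and validate a treatment effect table.

    Accepts a CSV/TSV path, an open text handle, or a DataFrame.  Columns
    (case-insensitive): ``name``, the QTc-shift triple ``dqtc, dqtc_lo,
    dqtc_hi``, and either a probability triple ``p, p_lo, p_hi`` or an
    odds-ratio triple ``or, or_lo, or_hi`` which is converted through
    :func:`or_to_probability` with the table's ``p0``.  Row order is kept.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if sep is None:
            # sniff comma vs tab from the header so the C engine (whose float
            # parsing is correctly rounded) can be used for exact round trips
            if isinstance(source, (str, Path)):
                header = Path(source).open("r", encoding="utf-8").readline()
            else:
                pos = source.tell()
                header = source.readline()
                source.seek(pos)
            sep = "\t" if "\t" in header else ","
        df = pd.read_csv(source, sep=sep, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]

    if "name" not in df.columns:
        raise EffectTableError("missing required column 'name'")
    missing_qtc = [c for c in _QTC_COLS if c not in df.columns]
    if missing_qtc:
        raise EffectTableError(f"missing required columns: {missing_qtc}")

    has_p = all(c in df.columns for c in _PROB_COLS)
    has_or = all(c in df.columns for c in _OR_COLS)
    if not (has_p or has_or):
        raise EffectTableError(
            f"need either probability columns {_PROB_COLS} or odds-ratio columns {_OR_COLS}"
        )

    records = []
    value_cols = list(_PROB_COLS if has_p else _OR_COLS) + list(_QTC_COLS)
    for idx, row in df.iterrows():
        vals = {}
        for c in value_cols:
            try:
                vals[c] = float(row[c])
            except (TypeError, ValueError) as exc:
                raise EffectTableError(
                    f"row {idx} ({row['name']!r}): column {c!r} is not numeric: {row[c]!r}"
                ) from exc
        if has_p:
            p, p_lo, p_hi = vals["p"], vals["p_lo"], vals["p_hi"]
        else:
            p = or_to_probability(vals["or"], p0)
            p_lo = or_to_probability(vals["or_lo"], p0)
            p_hi = or_to_probability(vals["or_hi"], p0)
        try:
            records.append(
                EffectSizeRecord(
                    name=str(row["name"]),
                    p=p,
                    p_lo=p_lo,
                    p_hi=p_hi,
                    dqtc=vals["dqtc"],
                    dqtc_lo=vals["dqtc_lo"],
                    dqtc_hi=vals["dqtc_hi"],
                )
            )
        except EffectTableError as exc:
            raise EffectTableError(f"row {idx}: {exc}") from exc
    return EffectTable(records=tuple(records), p0=p0)


def write_effect_table(table: EffectTable, path: Union[str, Path]) -> None:
    """Write the table as CSV so that :func:`load_effect_table` round-trips it."""
    table.to_frame().to_csv(path, index=False)


def reference_table(p0: float = 0.5) -> EffectTable:
    """The packaged six-antipsychotic effect table used throughout the docs.

    Improvement probabilities come from a network meta-analysis of delirium
    RCTs; QTc shifts from a network meta-analysis of antipsychotic safety.
    """
    with resources.files("qtcda.data").joinpath("table1.csv").open("r") as fh:
        return load_effect_table(fh, p0=p0)
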