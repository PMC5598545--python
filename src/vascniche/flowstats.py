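"""Flow-cytometry-style event-table statistics.

Gating by marker thresholds, geometric mean fluorescence intensity (MFI),
control-normalized geometric MFI (the uptake / specific-signal readout),
population fractions and absolute counts.  Input is any table with one row
per cell and one column per marker, e.g. a CSV loaded with pandas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DegenerateInputError,
    InvalidParameterError,
    UndefinedRatioError,
)


@dataclass(frozen=True)
class GateRule:
    """A single marker threshold: ``marker op threshold``.

    op is one of ``">"``, ``"<"`` or ``"between"`` (which needs
    ``threshold=(lo, hi)`` with lo < hi).
    """

    marker: str
    op: str
    threshold: float | tuple[float, float]

    def __post_init__(self):
        if self.op not in (">", "<", "between"):
            raise InvalidParameterError(f"unknown gate comparator {self.op!r}")
        if self.op == "between":
            lo, hi = self.threshold
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InvalidParameterError("between gate needs finite lo < hi")
        elif not np.isfinite(self.threshold):
            raise InvalidParameterError("gate threshold must be finite")

    def apply(self, events: pd.DataFrame) -> pd.Series:
        if self.marker not in events.columns:
            raise InvalidParameterError(
                f"unknown marker {self.marker!r}; table has {list(events.columns)}"
            )
        col = events[self.marker]
        if self.op == ">":
            return col > self.threshold
        if self.op == "<":
            return col < self.threshold
        lo, hi = self.threshold
        return (col > lo) & (col < hi)


def gate(events: pd.DataFrame, rules: list[GateRule]) -> pd.DataFrame:
    """Conjunction of gate rules; row order is preserved.  Idempotent."""
    keep = pd.Series(True, index=events.index)
    for rule in rules:
        keep &= rule.apply(events)
    return events.loc[keep]


def geometric_mfi(events: pd.DataFrame, marker: str) -> float:
    """Geometric mean fluorescence intensity: exp(mean(log(I + eps))).

    eps is the smallest positive intensity in the column times 1e-3 (zero
    if the column has no zeros), so all-positive columns are unaffected
    while zero intensities do not blow up the log.
    """
    if len(events) == 0:
        raise DegenerateInputError("geometric MFI of an empty event table")
    if marker not in events.columns:
        raise InvalidParameterError(f"unknown marker {marker!r}")
    x = np.asarray(events[marker], dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("intensities must be non-negative")
    eps = 0.0
    if np.any(x == 0):
        positive = x[x > 0]
        if positive.size == 0:
            return 0.0
        eps = positive.min() * 1e-3
    return float(np.exp(np.mean(np.log(x + eps))))


def normalized_mfi(
    sample: pd.DataFrame, control: pd.DataFrame, marker: str
) -> float:
    """Sample geometric MFI divided by the control's (specific uptake).

    Because both numerator and denominator are geometric means of the same
    detector channel, the ratio is invariant to any common positive
    rescaling of both tables (detector gain cancels).
    """
    denom = geometric_mfi(control, marker)
    if denom == 0:
        raise UndefinedRatioError("control geometric MFI is zero")
    return geometric_mfi(sample, marker) / denom


def population_fraction(
    events: pd.DataFrame,
    numerator_rules: list[GateRule],
    denominator_rules: list[GateRule],
) -> float:
    """Percentage of the denominator gate that also passes the numerator."""
    denom = gate(events, denominator_rules)
    if len(denom) == 0:
        raise UndefinedRatioError("denominator gate selected no events")
    num = gate(denom, numerator_rules)
    return 100.0 * len(num) / len(denom)


def absolute_count(fraction_percent: float, total_cells: int) -> int:
    """Absolute cell number from a gated percentage of a total count."""
    if not (0.0 <= fraction_percent <= 100.0):
        raise InvalidParameterError("fraction must lie in [0, 100]")
    if total_cells < 0:
        raise InvalidParameterError("total_cells must be >= 0")
    return int(round(total_cells * fraction_percent / 100.0))
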