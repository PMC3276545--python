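"""Cytometry phenotyping: gating, median-ratio phenotypes, and Z statistics.

An event table is a :class:`pandas.DataFrame` with one row per flow-cytometry
event and log10-scale columns ``fsc`` (forward scatter, a proxy for cell
size) and one or more fluorescence channels (``yfp``, ``cfp``). A culture's
fluorescence phenotype is the median over gated events of the per-event ratio
of log10 fluorescence to log10 FSC; standardizing a culture's phenotype
against replicate control cultures yields a Z-score, and |Z| above a normal
critical value calls the culture a mutant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GateWindow",
    "PhenotypeMeasurement",
    "ZResult",
    "EmptyGateError",
    "gate_events",
    "median_ratio_phenotype",
    "zscore",
    "variance_zscore",
    "z_threshold",
    "call_mutant",
    "phenotype_table",
]

#: default FSC gate, in log10 arbitrary units
DEFAULT_GATE = (5.30, 5.55)


class EmptyGateError(ValueError):
    """Raised when a gate retains no events from a non-empty table."""


@dataclass(frozen=True)
class GateWindow:
    """Closed FSC interval, in log10 units, used to cull extreme-size events."""

    fsc_low: float = DEFAULT_GATE[0]
    fsc_high: float = DEFAULT_GATE[1]

    def __post_init__(self) -> None:
        if not self.fsc_low < self.fsc_high:
            raise ValueError("fsc_low must be strictly below fsc_high")

    @classmethod
    def from_percentiles(cls, fsc_values, low_pct: float = 20.0,
                         high_pct: float = 80.0) -> "GateWindow":
        """Data-driven gate at FSC percentiles (alternative gating mode)."""
        lo, hi = np.percentile(np.asarray(fsc_values, dtype=float),
                               [low_pct, high_pct])
        return cls(float(lo), float(hi))


@dataclass(frozen=True)
class PhenotypeMeasurement:
    """Culture-level median-ratio phenotype and its per-event variance."""

    genotype_id: str
    replicate: int
    channel: str
    value: float
    variance: float
    n_events_used: int


@dataclass(frozen=True)
class ZResult:
    genotype_id: str
    channel: str
    z_median: float
    z_variance: float | None
    n_controls: int


def gate_events(events: pd.DataFrame, window: GateWindow | None = None) -> pd.DataFrame:
    """Retain events with FSC inside the closed gate window, order preserved."""
    if window is None:
        window = GateWindow()
    if len(events) == 0:
        raise ValueError("event table is empty")
    kept = events[(events["fsc"] >= window.fsc_low)
                  & (events["fsc"] <= window.fsc_high)]
    if len(kept) == 0:
        raise EmptyGateError(
            f"gate [{window.fsc_low}, {window.fsc_high}] retained no events")
    return kept


def median_ratio_phenotype(events: pd.DataFrame, channel: str = "yfp", *,
                           genotype_id: str = "", replicate: int = 0,
                           mode: str = "ratio-of-logs") -> PhenotypeMeasurement:
    """Median fluorescence/FSC phenotype of a (gated) event table.

    ``mode="ratio-of-logs"`` takes the median of per-event
    log10(fluorescence)/log10(FSC) ratios. ``mode="log-of-ratio"`` takes
    the median of log10(fluorescence) - log10(FSC) instead (the log of the
    linear-scale ratio); both are exposed because "median ratio after log
    transformation" admits either reading.
    """
    if channel not in events.columns:
        raise KeyError(f"channel column {channel!r} missing from event table")
    if len(events) == 0:
        raise ValueError("no events to phenotype")
    f = events["fsc"].to_numpy(dtype=float)
    y = events[channel].to_numpy(dtype=float)
    if mode == "ratio-of-logs":
        ratio = y / f
    elif mode == "log-of-ratio":
        ratio = y - f
    else:
        raise ValueError(f"unknown phenotype mode {mode!r}")
    return PhenotypeMeasurement(
        genotype_id=genotype_id,
        replicate=replicate,
        channel=channel,
        value=float(np.median(ratio)),
        variance=float(np.var(ratio, ddof=1)) if len(ratio) > 1 else 0.0,
        n_events_used=len(ratio),
    )


def zscore(value: float, control_values) -> float:
    """Standardized effect of a phenotype against replicate control cultures.

    z = (value - mean(controls)) / sd(controls), sample sd (n-1 denominator).
    """
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least 2 control values")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("control values have zero standard deviation")
    return float((value - controls.mean()) / sd)


def variance_zscore(variance: float, control_variances) -> float:
    """Standardized effect on within-culture variance, same form as `zscore`."""
    return zscore(variance, control_variances)


def z_threshold(alpha_two_sided: float) -> float:
    """Standard-normal critical value for a two-sided test at level alpha.

    alpha=0.01 gives 2.576 (conventionally quoted as 2.58), 0.05 gives 1.96,
    0.10 gives 1.645.
    """
    if not 0 < alpha_two_sided <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return float(sps.norm.ppf(1 - alpha_two_sided / 2))


def call_mutant(z: float, threshold: float) -> tuple[bool, int]:
    """Mutant call: |z| strictly above threshold; direction is sign(z).

    A |z| exactly equal to the threshold is not a mutant, keeping the mutant
    and recessive calls complementary at the boundary.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return bool(abs(z) > threshold), int(np.sign(z))


def phenotype_table(events: pd.DataFrame, channel: str = "yfp", *,
                    window: GateWindow | None = None,
                    mode: str = "ratio-of-logs") -> pd.DataFrame:
    """Per-culture phenotypes for a table with genotype_id/replicate columns.

    Gates each culture independently and returns one row per culture with
    columns genotype_id, replicate, channel, value, variance, n_events_used.
    """
    rows = []
    for (gid, rep), grp in events.groupby(["genotype_id", "replicate"], sort=True):
        gated = gate_events(grp, window)
        m = median_ratio_phenotype(gated, channel, genotype_id=str(gid),
                                   replicate=int(rep), mode=mode)
        rows.append(m.__dict__)
    return pd.DataFrame(rows)
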