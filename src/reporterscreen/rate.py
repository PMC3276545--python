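"""Mutation-rate inference from paired treated/control phenotype distributions.

The mutagenized population shows an excess of cells in both tails of the
fluorescence-phenotype distribution relative to untreated controls. The
tail excess frequency f estimates the fraction of treated cells carrying at
least one activity-affecting mutation; under a Poisson model of mutation
counts, lambda = -ln(1 - f) is the mean number of such mutations per genome,
and dividing by the mutagen's fold-elevation of a calibrated marker
(canavanine resistance) converts lambda to a spontaneous per-genome,
per-generation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq
from scipy.stats import percentileofscore

__all__ = [
    "DistributionComparison",
    "PoissonLoad",
    "SortPlan",
    "DegenerateScreenError",
    "tail_excess_frequency",
    "poisson_mutation_load",
    "calibration_fold",
    "spontaneous_rate",
    "sorted_tail_purity",
    "expected_direction_fraction",
]

DEFAULT_N_BINS = 256


class DegenerateScreenError(ValueError):
    """Raised when the difference curve lacks two interior zero crossings."""


@dataclass
class DistributionComparison:
    """Binned treated-minus-control comparison with its spline fit."""

    bin_edges: np.ndarray
    treated_counts: np.ndarray
    control_counts: np.ndarray  # scaled to the treated total
    difference_curve: np.ndarray
    spline_fit: np.ndarray  # spline evaluated at bin centers
    crossings: tuple[float, float] | None
    crossing_percentiles: tuple[float, float] | None  # of the control sample
    overflow_excess: tuple[float, float] = (0.0, 0.0)  # beyond the binned range
    degenerate: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class PoissonLoad:
    """Poisson summary of the per-genome load of activity-affecting mutations."""

    f: float
    p0: float
    lam: float
    p1: float
    p_gt1: float
    fold: float | None = None
    spontaneous_rate: float | None = None


@dataclass(frozen=True)
class SortPlan:
    """One tail of a FACS collection: thresholds, yield, and purity inputs.

    ``control_tail_pct`` (s_c) and ``treated_tail_pct`` (s_t) are the
    percentages of the control and treated populations beyond the sorting
    threshold; ``colony_rate`` is the fraction of sorted events that grew.
    """

    tail: str  # "low" or "high"
    control_tail_pct: float
    treated_tail_pct: float
    colony_rate: float
    n_events_sorted: int

    @property
    def purity(self) -> float:
        return sorted_tail_purity(self.treated_tail_pct, self.control_tail_pct)

    @property
    def expected_mutants(self) -> float:
        return self.n_events_sorted * self.colony_rate * self.purity


def _locate_crossing_pair(grid: np.ndarray, values: np.ndarray,
                          spline, center: float) -> tuple[float, float] | None:
    """Innermost pair of zero crossings bracketing ``center``."""
    signs = np.sign(values)
    idx = np.nonzero(np.diff(signs) != 0)[0]
    roots = []
    for i in idx:
        a, b = grid[i], grid[i + 1]
        fa, fb = spline(a), spline(b)
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(spline, a, b)))
    roots = sorted(set(roots))
    lower = [r for r in roots if r < center]
    upper = [r for r in roots if r > center]
    if not lower or not upper:
        return None
    return lower[-1], upper[0]


def tail_excess_frequency(treated_phenotypes, control_phenotypes, *,
                          n_bins: int = DEFAULT_N_BINS,
                          spline_smoothing: float | None = None,
                          use_spline_excess: bool = False,
                          clip_percentiles: tuple[float, float] = (0.1, 99.9),
                          ) -> tuple[float, DistributionComparison]:
    """Estimate the frequency f of treated cells with altered phenotype.

    The two samples are binned on a shared equal-width grid, control counts
    are scaled to the treated total, and a cubic smoothing spline (smoothing
    chosen by generalized cross-validation unless ``spline_smoothing`` is
    given) is fitted to the per-bin count difference. The spline's innermost
    zero crossings around the control median delimit the central mass; f is
    the positive raw-bin excess outside the crossings divided by the treated
    total (``use_spline_excess=True`` integrates the positive spline instead).

    The binned range covers the ``clip_percentiles`` span of the pooled
    sample (like the plotted range of a cytometer, which excludes a small
    fraction of extreme events): cells beyond it are unambiguous tail excess
    and are counted directly, after subtracting any scaled control overflow,
    without letting a handful of extreme outliers destroy the bin resolution
    of the central mass.

    Returns ``(f, comparison)``; identical samples yield f = 0 with the
    comparison flagged degenerate, while any other screen lacking a crossing
    pair raises :class:`DegenerateScreenError`.
    """
    treated = np.asarray(treated_phenotypes, dtype=float)
    control = np.asarray(control_phenotypes, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([treated, control])
    q_lo, q_hi = np.percentile(pooled, clip_percentiles)
    lo = max(min(treated.min(), control.min()), float(q_lo))
    hi = min(max(treated.max(), control.max()), float(q_hi))
    if lo >= hi:
        raise ValueError("samples have zero range")
    edges = np.linspace(lo, hi, n_bins + 1)
    t_counts, _ = np.histogram(treated, bins=edges)
    c_counts_raw, _ = np.histogram(control, bins=edges)
    scale = treated.size / control.size
    c_counts = c_counts_raw * scale
    diff = t_counts - c_counts
    centers = 0.5 * (edges[:-1] + edges[1:])
    over_lo = float((treated < lo).sum() - (control < lo).sum() * scale)
    over_hi = float((treated > hi).sum() - (control > hi).sum() * scale)
    overflow = (over_lo, over_hi)

    if not (np.any(diff != 0) or over_lo != 0 or over_hi != 0):
        comp = DistributionComparison(edges, t_counts, c_counts, diff,
                                      np.zeros_like(diff), None, None,
                                      degenerate=True)
        return 0.0, comp

    lam = spline_smoothing  # None -> GCV
    spline = make_smoothing_spline(centers, diff, lam=lam)
    grid = np.linspace(centers[0], centers[-1], 1000)
    spline_grid = spline(grid)
    center = float(np.median(control))
    pair = _locate_crossing_pair(grid, spline_grid, spline, center)
    if pair is None:
        raise DegenerateScreenError(
            "difference curve lacks two interior zero crossings around the "
            "control median; screen too weak or degenerate")
    x_lo, x_hi = pair

    if use_spline_excess:
        fine = np.linspace(centers[0], centers[-1], 8192)
        vals = np.clip(spline(fine), 0.0, None)
        vals[(fine > x_lo) & (fine < x_hi)] = 0.0
        excess = np.trapezoid(vals, fine) / (edges[1] - edges[0])
    else:
        outside = (centers < x_lo) | (centers > x_hi)
        excess = np.clip(diff[outside], 0.0, None).sum()
    excess += max(over_lo, 0.0) + max(over_hi, 0.0)
    f = float(excess / treated.size)

    pct = (float(percentileofscore(control, x_lo, kind="mean")),
           float(percentileofscore(control, x_hi, kind="mean")))
    comp = DistributionComparison(edges, t_counts, c_counts, diff,
                                  spline(centers), (x_lo, x_hi), pct,
                                  overflow_excess=overflow)
    return f, comp


def poisson_mutation_load(f: float) -> PoissonLoad:
    """Poisson load implied by a mutant frequency f.

    p0 = 1 - f is the fraction of genomes with no relevant mutation, so the
    mean load is lam = -ln(p0); p1 = lam*exp(-lam) genomes carry exactly one
    mutation and p_gt1 = 1 - p0 - p1 carry more than one.
    """
    if not 0 <= f < 1:
        raise ValueError("f must lie in [0, 1)")
    p0 = 1.0 - f
    lam = -np.log(p0)
    p1 = lam * np.exp(-lam)
    return PoissonLoad(f=f, p0=p0, lam=float(lam), p1=float(p1),
                       p_gt1=float(1.0 - p0 - p1))


def calibration_fold(observed_marker_frequency: float,
                     reported_spontaneous_marker_rate: float) -> float:
    """Fold elevation of a marker mutation rate by the mutagen."""
    if observed_marker_frequency <= 0 or reported_spontaneous_marker_rate <= 0:
        raise ValueError("marker frequency and rate must be positive")
    return observed_marker_frequency / reported_spontaneous_marker_rate


def spontaneous_rate(lam: float, fold: float) -> float:
    """Spontaneous rate per haploid genome per generation: lam / fold."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    return lam / fold


def with_calibration(load: PoissonLoad, fold: float) -> PoissonLoad:
    """Attach a calibration fold and the implied spontaneous rate."""
    return PoissonLoad(f=load.f, p0=load.p0, lam=load.lam, p1=load.p1,
                       p_gt1=load.p_gt1, fold=fold,
                       spontaneous_rate=spontaneous_rate(load.lam, fold))


def sorted_tail_purity(s_t: float, s_c: float) -> float:
    """Expected mutant fraction among cells sorted from one tail.

    With the sorting threshold capturing s_c (%) of the control population
    and s_t (%) of the treated population, the non-mutant background accounts
    for s_c of the s_t, so purity = (s_t - s_c) / s_t. Negative values
    (control tail wider than treated) are clipped to 0.
    """
    if s_t <= 0:
        raise ValueError("treated tail fraction must be positive")
    if s_c < 0:
        raise ValueError("control tail fraction must be non-negative")
    purity = (s_t - s_c) / s_t
    if purity < 0:
        import warnings
        warnings.warn("control tail exceeds treated tail; purity clipped to 0",
                      stacklevel=2)
        return 0.0
    return purity


def expected_direction_fraction(plan_low: SortPlan, plan_high: SortPlan
                                ) -> dict[str, float]:
    """Expected share of recovered mutants in each tail.

    Each tail contributes n_sorted x colony_rate x purity expected mutants;
    the returned dict maps "low"/"high" to each tail's share of the total.
    """
    e_low = plan_low.expected_mutants
    e_high = plan_high.expected_mutants
    total = e_low + e_high
    if total == 0:
        raise ValueError("no mutants expected in either tail")
    return {"low": e_low / total, "high": e_high / total}
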