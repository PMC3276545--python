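"""Effect spectra, dominance, and cross-allele analysis of the mutant classes.

Haploid Z-scores measure each mutant's effect on reporter activity; diploid
YFP Z-scores from heterozygous crosses against a CFP-marked reference measure
how much of that effect persists in the heterozygote (dominance), and diploid
CFP Z-scores measure effects on the reference allele (a signature of
trans-acting and copy-number mutations). Haploid-vs-diploid slopes come from
a model II (major-axis) regression, since both axes are noisy measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import fisher_exact_test, mww_test

__all__ = [
    "model2_regression",
    "recessivity_call",
    "class_effect_comparison",
    "colony_rate_comparison",
    "cfp_cross_effect",
    "build_summary_table",
    "RegressionFit",
]

CLASS_ORDER = ("coding", "cnv", "cis", "trans")


@dataclass(frozen=True)
class RegressionFit:
    class_label: str
    slope: float
    n: int
    method: str


def model2_regression(x_values, y_values, method: str = "ma") -> float:
    """Model II regression slope of y on x.

    ``method="ma"`` (major axis) takes the slope of the leading eigenvector
    of the 2x2 covariance matrix; ``method="sma"`` (standardized major axis)
    uses sign(cov) * sd(y)/sd(x). MA is appropriate when both variables are
    on the same scale (here, Z-scores); note that MA is not invariant to
    rescaling one axis only, which is why SMA is offered as an alternative.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx == 0 or syy == 0:
        raise ValueError("degenerate input: a variable has zero variance")
    if method == "sma":
        return float(np.sign(sxy) * np.sqrt(syy / sxx)) if sxy != 0 else float(np.sqrt(syy / sxx))
    if method != "ma":
        raise ValueError(f"unknown model II method {method!r}")
    if sxy == 0:
        # principal axis aligns with the higher-variance coordinate
        return 0.0 if sxx >= syy else float("inf")
    return float((syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2))
                 / (2 * sxy))


def recessivity_call(z_yfp_diploid: float, threshold: float = 2.58) -> bool:
    """Recessive iff the heterozygote shows no significant YFP effect (|z| < t)."""
    if not np.isfinite(z_yfp_diploid):
        raise ValueError("z must be finite")
    return abs(z_yfp_diploid) < threshold


def class_effect_comparison(group_a_abs_z, group_b_abs_z,
                            sided: str = "two-sided") -> float:
    """MWW rank-sum p-value comparing two classes' effect magnitudes."""
    return mww_test(group_a_abs_z, group_b_abs_z, sided=sided)


def colony_rate_comparison(a_success: int, a_total: int,
                           b_success: int, b_total: int) -> float:
    """Two-sided Fisher exact p for a difference in colony-formation rates."""
    return fisher_exact_test(a_success, a_total, b_success, b_total)


def cfp_cross_effect(z_cfp: float, z_yfp: float,
                     threshold: float = 2.58) -> str:
    """Categorize a mutant's effect on the reference (CFP) allele.

    Returns "no_cfp_effect" when |z_cfp| does not exceed the threshold,
    otherwise "same_direction" or "opposite_direction" relative to the
    diploid YFP effect.
    """
    if not (np.isfinite(z_cfp) and np.isfinite(z_yfp)):
        raise ValueError("z-scores must be finite")
    if abs(z_cfp) <= threshold:
        return "no_cfp_effect"
    return "same_direction" if z_cfp * z_yfp > 0 else "opposite_direction"


def _empty_row(label: str) -> dict:
    return {"class": label, "count": 0, "fraction": 0.0,
            "median_abs_z_haploid": 0.0, "fraction_z_positive": 0.0,
            "n_diploid": 0, "median_abs_z_diploid": 0.0,
            "slope_haploid_diploid": np.nan, "fraction_recessive": 0.0,
            "median_abs_z_cfp": 0.0, "slope_yfp_cfp_diploid": np.nan,
            "fraction_altering_cfp": 0.0}


def build_summary_table(assignments: pd.DataFrame,
                        haploid_z: pd.DataFrame,
                        diploid_measurements: pd.DataFrame | None = None,
                        *, threshold: float = 2.58,
                        regression_method: str = "ma") -> pd.DataFrame:
    """Per-class summary of frequency, effects, dominance, and CFP effects.

    Parameters
    ----------
    assignments
        Columns ``genotype_id`` and ``class`` (may include "ambiguous").
    haploid_z
        Columns ``genotype_id`` and ``z`` (haploid YFP Z-score).
    diploid_measurements
        Optional columns ``genotype_id``, ``z_yfp_diploid``, ``z_cfp_diploid``.
        Genotypes without diploid data are excluded from the diploid
        statistics only.

    Class frequency denominators follow the evidence requirements: coding and
    cis calls need only the transgene sequence, so their denominator is all
    assigned genotypes; cnv and trans calls additionally need a copy-number
    assay, so their denominator excludes the ambiguous genotypes.
    """
    merged = assignments.merge(haploid_z, on="genotype_id", how="left")
    if merged["z"].isna().any():
        missing = merged.loc[merged["z"].isna(), "genotype_id"].tolist()
        raise ValueError(f"genotypes lack a haploid Z-score: {missing[:5]}")
    if diploid_measurements is not None:
        merged = merged.merge(diploid_measurements, on="genotype_id", how="left")
    else:
        merged["z_yfp_diploid"] = np.nan
        merged["z_cfp_diploid"] = np.nan

    n_all = len(merged)
    n_assayed = int((merged["class"] != "ambiguous").sum())
    rows = []
    for label in CLASS_ORDER:
        grp = merged[merged["class"] == label]
        row = _empty_row(label)
        if len(grp) == 0:
            rows.append(row)
            continue
        denom = n_all if label in ("coding", "cis") else n_assayed
        z = grp["z"].to_numpy()
        row.update(count=len(grp),
                   fraction=len(grp) / denom if denom else 0.0,
                   median_abs_z_haploid=float(np.median(np.abs(z))),
                   fraction_z_positive=float((z > 0).mean()))
        dip = grp.dropna(subset=["z_yfp_diploid"])
        row["n_diploid"] = len(dip)
        if len(dip) > 0:
            zd = dip["z_yfp_diploid"].to_numpy()
            row["median_abs_z_diploid"] = float(np.median(np.abs(zd)))
            row["fraction_recessive"] = float(
                np.mean([recessivity_call(v, threshold) for v in zd]))
            zc = dip["z_cfp_diploid"].to_numpy()
            if np.isfinite(zc).all():
                row["median_abs_z_cfp"] = float(np.median(np.abs(zc)))
                row["fraction_altering_cfp"] = float((np.abs(zc) > threshold).mean())
            if len(dip) >= 3:
                zh = dip["z"].to_numpy()
                try:
                    row["slope_haploid_diploid"] = model2_regression(
                        zh, zd, method=regression_method)
                    if np.isfinite(zc).all():
                        row["slope_yfp_cfp_diploid"] = model2_regression(
                            zd, zc, method=regression_method)
                except ValueError:
                    pass
        rows.append(row)
    return pd.DataFrame(rows)
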