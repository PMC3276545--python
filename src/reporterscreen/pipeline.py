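"""End-to-end orchestration: simulate -> phenotype -> rate -> classify -> dominance.

Each stage consumes and produces plain DataFrames (written as TSV by the CLI),
so stages can be re-run individually; a single seed makes a full run
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import default_annotation
from .classify import (CopyNumberThresholds, assign_class, call_copy_number)
from .dominance import build_summary_table
from .phenotype import (GateWindow, call_mutant, phenotype_table,
                        variance_zscore, z_threshold, zscore)
from .rate import (DegenerateScreenError, poisson_mutation_load,
                   tail_excess_frequency, with_calibration)
from .simulate import ScreenDataset, SimulationConfig, simulate_screen

__all__ = ["RunConfig", "PipelineError", "compute_z_table",
           "classify_screen", "estimate_rate", "run_screen_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    gate: GateWindow = field(default_factory=GateWindow)
    alpha: float = 0.01
    n_bins: int = 256
    spline_smoothing: float | None = None
    copy_number: CopyNumberThresholds = field(default_factory=CopyNumberThresholds)
    regression_method: str = "ma"
    phenotype_mode: str = "ratio-of-logs"
    min_events_haploid: int = 5_000
    min_events_diploid: int = 9_000
    min_control_replicates: int = 10
    calibration_fold: float | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_control_replicates < 2:
            raise ValueError("min_control_replicates must be >= 2")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)
    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compute_z_table(culture_events: pd.DataFrame,
                    control_events: pd.DataFrame,
                    channel: str = "yfp", *,
                    gate: GateWindow | None = None,
                    alpha: float = 0.01,
                    mode: str = "ratio-of-logs",
                    min_events: int = 0,
                    min_control_replicates: int = 2) -> pd.DataFrame:
    """Per-genotype Z statistics against replicate control cultures.

    Returns one row per genotype with the phenotype value, its Z-score
    against the control replicates, the variance Z-score, and the mutant
    call at the two-sided normal threshold for ``alpha``.
    """
    ctl = phenotype_table(control_events, channel, window=gate, mode=mode)
    if len(ctl) < min_control_replicates:
        raise ValueError(
            f"only {len(ctl)} control replicates; need {min_control_replicates}")
    ctl_values = ctl["value"].to_numpy()
    ctl_variances = ctl["variance"].to_numpy()
    phen = phenotype_table(culture_events, channel, window=gate, mode=mode)
    threshold = z_threshold(alpha)
    rows = []
    for _, row in phen.iterrows():
        if min_events and row["n_events_used"] < min_events:
            continue
        z = zscore(row["value"], ctl_values)
        zv = variance_zscore(row["variance"], ctl_variances)
        is_mut, direction = call_mutant(z, threshold)
        rows.append({"genotype_id": row["genotype_id"],
                     "replicate": row["replicate"],
                     "channel": channel,
                     "value": row["value"],
                     "variance": row["variance"],
                     "n_events_used": row["n_events_used"],
                     "z": z, "z_variance": zv,
                     "mutant": is_mut, "direction": direction,
                     "n_controls": len(ctl)})
    return pd.DataFrame(rows)


def classify_screen(dataset: ScreenDataset, *,
                    thresholds: CopyNumberThresholds | None = None,
                    annotation=None) -> pd.DataFrame:
    """Assign a functional class to every genotype in the mutant collection."""
    if annotation is None:
        annotation = default_annotation()
    mut_by_gid = {m.genotype_id: m for m in dataset.transgene_mutations}
    pyro = dataset.pyro_assays.set_index("genotype_id")
    rows = []
    for rec in dataset.truth:
        gid = rec.genotype_id
        mutation = mut_by_gid.get(gid)
        cnv = None
        if gid in pyro.index:
            cnv = call_copy_number(int(pyro.loc[gid, "yfp_reads"]),
                                   int(pyro.loc[gid, "cfp_reads"]),
                                   thresholds, genotype_id=gid)
        assignment = assign_class(mutation, cnv, genotype_id=gid)
        rows.append({"genotype_id": gid,
                     "class": assignment.class_label,
                     "has_transgene_mutation": mutation is not None,
                     "mutation_region": mutation.region if mutation else "",
                     "coding_effect": mutation.coding_effect if mutation else "",
                     "copies": cnv.copies if cnv else "",
                     "yfp_fraction": cnv.yfp_fraction if cnv else np.nan,
                     "true_class": rec.class_label})
    return pd.DataFrame(rows)


def estimate_rate(dataset: ScreenDataset, *, gate: GateWindow | None = None,
                  n_bins: int = 256, spline_smoothing: float | None = None,
                  calibration_fold: float | None = None,
                  mode: str = "ratio-of-logs") -> dict:
    """Tail-excess mutant frequency and Poisson load from the populations."""
    from .phenotype import gate_events, median_ratio_phenotype  # noqa: F401

    def _per_cell_phenotype(events: pd.DataFrame) -> np.ndarray:
        gated = gate_events(events, gate)
        f = gated["fsc"].to_numpy()
        y = gated["yfp"].to_numpy()
        return y / f if mode == "ratio-of-logs" else y - f

    treated = _per_cell_phenotype(dataset.treated_events)
    control = _per_cell_phenotype(dataset.control_events)
    try:
        f, comparison = tail_excess_frequency(
            treated, control, n_bins=n_bins, spline_smoothing=spline_smoothing)
    except DegenerateScreenError:
        # a screen with no detectable tail excess (e.g. an unmutagenized
        # population) yields a zero rate, not a pipeline abort
        f = 0.0
        comparison = None
    load = poisson_mutation_load(f)
    if calibration_fold is not None:
        load = with_calibration(load, calibration_fold)
    return {"f": load.f, "p0": load.p0, "lam": load.lam, "p1": load.p1,
            "p_gt1": load.p_gt1, "fold": load.fold,
            "spontaneous_rate": load.spontaneous_rate,
            "crossings": comparison.crossings if comparison else None,
            "crossing_percentiles": (comparison.crossing_percentiles
                                     if comparison else None),
            "degenerate": comparison.degenerate if comparison else True}


def run_screen_pipeline(config: RunConfig,
                        out_dir: str | Path | None = None) -> dict:
    """Run the full simulated screen and analysis; optionally write artifacts.

    Returns a report bundle with the simulated dataset, per-genotype Z
    tables, the rate report, class assignments, the per-class summary table,
    and a provenance record.
    """
    timings: dict[str, float] = {}

    def timed(stage, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        return result

    sim = config.simulation
    if sim.seed != config.seed:
        sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})

    dataset = timed("simulate", simulate_screen, sim)
    haploid_z = timed(
        "phenotype", compute_z_table,
        dataset.haploid_cultures, dataset.haploid_controls, "yfp",
        gate=config.gate, alpha=config.alpha, mode=config.phenotype_mode,
        min_control_replicates=min(config.min_control_replicates,
                                   sim.n_control_replicates))
    diploid_z_yfp = timed(
        "phenotype_diploid_yfp", compute_z_table,
        dataset.diploid_cultures, dataset.diploid_controls, "yfp",
        gate=config.gate, alpha=config.alpha, mode=config.phenotype_mode,
        min_control_replicates=min(config.min_control_replicates,
                                   sim.n_control_replicates))
    diploid_z_cfp = timed(
        "phenotype_diploid_cfp", compute_z_table,
        dataset.diploid_cultures, dataset.diploid_controls, "cfp",
        gate=config.gate, alpha=config.alpha, mode=config.phenotype_mode,
        min_control_replicates=min(config.min_control_replicates,
                                   sim.n_control_replicates))
    rate_report = timed("rate", estimate_rate, dataset, gate=config.gate,
                        n_bins=config.n_bins,
                        spline_smoothing=config.spline_smoothing,
                        calibration_fold=config.calibration_fold,
                        mode=config.phenotype_mode)
    assignments = timed("classify", classify_screen, dataset,
                        thresholds=config.copy_number)

    diploid = diploid_z_yfp[["genotype_id", "z"]].rename(
        columns={"z": "z_yfp_diploid"}).merge(
        diploid_z_cfp[["genotype_id", "z"]].rename(
            columns={"z": "z_cfp_diploid"}), on="genotype_id")
    summary = timed(
        "dominance", build_summary_table,
        assignments[["genotype_id", "class"]],
        haploid_z[["genotype_id", "z"]], diploid,
        threshold=z_threshold(config.alpha),
        regression_method=config.regression_method)

    provenance = {"package_version": __version__,
                  "seed": config.seed,
                  "config_hash": _config_hash(config),
                  "stage_seconds": timings}
    report = {"dataset": dataset, "haploid_z": haploid_z,
              "diploid_z_yfp": diploid_z_yfp, "diploid_z_cfp": diploid_z_cfp,
              "rate": rate_report, "assignments": assignments,
              "summary": summary, "provenance": provenance}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        haploid_z.to_csv(out / "haploid_z.tsv", sep="\t", index=False,
                         float_format=fmt)
        diploid_z_yfp.to_csv(out / "diploid_z_yfp.tsv", sep="\t", index=False,
                             float_format=fmt)
        diploid_z_cfp.to_csv(out / "diploid_z_cfp.tsv", sep="\t", index=False,
                             float_format=fmt)
        assignments.to_csv(out / "classes.tsv", sep="\t", index=False,
                           float_format=fmt)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                       float_format=fmt)
        serializable = {k: v for k, v in rate_report.items()}
        with open(out / "rate.json", "w") as fh:
            json.dump(serializable, fh, indent=2, default=str)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
    return report
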