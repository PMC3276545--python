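"""Synthetic mutagenesis screens with known ground truth.

The generator emulates the statistical structure of a fluorescent-reporter
EMS screen in yeast: per-cell event tables whose log10 YFP is linear in
log10 forward scatter; a treated population in which each cell carries a
Poisson-distributed number of activity-affecting mutations drawn from four
functional classes (coding, copy-number, cis-regulatory, trans-acting) with
class-specific effect sizes, directions, and dominance; replicate clonal
control cultures; diploid crosses against a CFP-marked reference strain;
pyrosequencing read counts for the YFP/CFP allele fraction; and transgene
mutation records on a promoter/CDS/terminator annotation. Every simulated
mutant carries a truth record, so downstream estimators can be scored
against what was planted.

Effects are multiplicative on linear-scale reporter activity, i.e. additive
shifts of log10 YFP; cells carrying several mutations combine them
multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import ReporterAnnotation, default_annotation
from .classify import TransgeneMutation, coding_effect

__all__ = [
    "EffectModel",
    "SimulationConfig",
    "TruthRecord",
    "ScreenDataset",
    "simulate_control_population",
    "simulate_treated_population",
    "simulate_diploid_cross",
    "simulate_pyro_assay",
    "simulate_transgene_mutation",
    "simulate_control_cultures",
    "simulate_screen",
]

CLASS_LABELS = ("coding", "cnv", "cis", "trans")

_TRANSITION = {"G": "A", "C": "T"}


@dataclass(frozen=True)
class EffectModel:
    """Distribution of one class's multiplicative effect on reporter activity.

    ``family`` names the distribution of the log10 effect magnitude:
    "normal" (mean, sd, truncated below at ``minimum``), "lognormal"
    (log-median, sigma), or "fixed" (constant). ``p_positive`` is the
    probability the effect increases activity.
    """

    family: str
    params: tuple[float, ...]
    p_positive: float

    def sample_magnitude(self, rng: np.random.Generator) -> float:
        if self.family == "normal":
            mean, sd, minimum = self.params
            for _ in range(1000):
                m = rng.normal(mean, sd)
                if m >= minimum:
                    return float(m)
            return float(minimum)
        if self.family == "lognormal":
            log_median, sigma = self.params
            return float(np.exp(rng.normal(log_median, sigma)))
        if self.family == "fixed":
            return float(self.params[0])
        raise ValueError(f"unknown effect family {self.family!r}")

    def sample_shift(self, rng: np.random.Generator) -> float:
        """Signed log10 shift of reporter activity."""
        sign = 1.0 if rng.random() < self.p_positive else -1.0
        return sign * self.sample_magnitude(rng)


def _default_effects() -> dict[str, EffectModel]:
    # magnitudes are log10 activity shifts, calibrated so that with the
    # default culture noise the class-median |Z| land near coding ~48,
    # cnv ~8, cis ~8, trans ~5
    return {
        "coding": EffectModel("normal", (1.8, 0.4, 0.4), 0.0),
        # duplication doubles dosage on average, with position/expression
        # variability around it
        "cnv": EffectModel("normal", (float(np.log10(2.0)), 0.10, 0.12), 1.0),
        "cis": EffectModel("normal", (0.30, 0.10, 0.05), 0.5),
        "trans": EffectModel("lognormal", (float(np.log(0.175)), 0.5), 0.73),
    }


def _default_weights() -> dict[str, float]:
    # relative class frequencies among classified mutants
    return {"coding": 0.07, "cnv": 0.10, "cis": 0.02, "trans": 0.81}


def _default_dominance() -> dict[str, float]:
    # trans-acting mutations are modeled fully recessive; allele-specific
    # classes act in the heterozygote
    return {"coding": 1.0, "cnv": 1.0, "cis": 1.0, "trans": 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic screen; defaults emulate the study design."""

    seed: int = 0
    n_cells_control: int = 50_000
    n_cells_treated: int = 50_000
    mean_load: float = 0.0303
    class_weights: dict = field(default_factory=_default_weights)
    effect_params: dict = field(default_factory=_default_effects)
    dominance: dict = field(default_factory=_default_dominance)
    # log-linear FSC -> YFP event model (log10 arbitrary units)
    fsc_mean: float = 5.43
    fsc_sd: float = 0.10
    yfp_slope: float = 1.0
    yfp_intercept: float = -1.0
    yfp_resid_sd: float = 0.04
    cfp_intercept: float = -1.05
    # culture-to-culture noise of the median-ratio phenotype
    culture_noise_sd: float = 0.007
    diploid_culture_noise_sd: float = 0.0047
    n_control_replicates: int = 20
    n_mutant_genotypes: int = 231
    events_per_culture: int = 5_000
    events_per_diploid_culture: int = 9_000
    pyro_reads: int = 1_000
    cnv_cfp_effect: float = 0.80
    cnv_copies: int = 2

    def __post_init__(self) -> None:
        if abs(sum(self.class_weights.values()) - 1.0) > 1e-12:
            raise ValueError("class_weights must sum to 1")
        if set(self.class_weights) != set(CLASS_LABELS):
            raise ValueError(f"class_weights must cover {CLASS_LABELS}")
        if self.mean_load < 0:
            raise ValueError("mean_load must be non-negative")
        for name in ("fsc_sd", "yfp_resid_sd", "culture_noise_sd",
                     "diploid_culture_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for cls, d in self.dominance.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"dominance[{cls}] must lie in [0, 1]")
        if self.n_control_replicates < 2:
            raise ValueError("need at least 2 control replicates")
        if self.cnv_cfp_effect <= 0:
            raise ValueError("cnv_cfp_effect must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated genotype."""

    genotype_id: str
    n_mutations: int
    class_labels: tuple[str, ...]
    effect: float  # combined multiplicative effect on haploid activity
    dominance: float
    transgene_mutation: TransgeneMutation | None = None
    copies_yfp: int = 1

    def __post_init__(self) -> None:
        if self.n_mutations != len(self.class_labels):
            raise ValueError("n_mutations inconsistent with class labels")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.copies_yfp < 1:
            raise ValueError("copies_yfp must be >= 1")

    @property
    def class_label(self) -> str:
        """Primary class label (single-mutation genotypes have exactly one)."""
        return self.class_labels[0] if self.class_labels else "none"


@dataclass
class ScreenDataset:
    """A complete simulated screen plus its truth table."""

    config: SimulationConfig
    control_events: pd.DataFrame
    treated_events: pd.DataFrame
    treated_truth: list
    haploid_cultures: pd.DataFrame   # mutant collection, genotype_id/replicate
    haploid_controls: pd.DataFrame
    diploid_cultures: pd.DataFrame   # yfp + cfp channels
    diploid_controls: pd.DataFrame
    pyro_assays: pd.DataFrame
    transgene_mutations: list
    truth: list


# ---------------------------------------------------------------------------
# event-level building blocks

def _draw_events(config: SimulationConfig, n: int, rng: np.random.Generator,
                 yfp_shift: float = 0.0, cfp_shift: float | None = None
                 ) -> pd.DataFrame:
    fsc = rng.normal(config.fsc_mean, config.fsc_sd, n)
    yfp = (config.yfp_intercept + config.yfp_slope * fsc
           + rng.normal(0.0, config.yfp_resid_sd, n) + yfp_shift)
    cols = {"fsc": fsc, "yfp": yfp}
    if cfp_shift is not None:
        cols["cfp"] = (config.cfp_intercept + config.yfp_slope * fsc
                       + rng.normal(0.0, config.yfp_resid_sd, n) + cfp_shift)
    return pd.DataFrame(cols)


def simulate_control_population(config: SimulationConfig, n: int,
                                rng: np.random.Generator | None = None
                                ) -> pd.DataFrame:
    """Per-cell events for an unmutagenized population.

    log10 FSC is normal; log10 YFP = intercept + slope * log10 FSC + noise.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _draw_events(config, n, rng)


def _sample_class(config: SimulationConfig, rng: np.random.Generator) -> str:
    labels = list(config.class_weights)
    probs = np.array([config.class_weights[c] for c in labels])
    return labels[rng.choice(len(labels), p=probs)]


def _sample_mutation_shift(config: SimulationConfig, label: str,
                           rng: np.random.Generator) -> float:
    return config.effect_params[label].sample_shift(rng)


def simulate_treated_population(config: SimulationConfig, n: int,
                                rng: np.random.Generator | None = None
                                ) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Per-cell events for a mutagenized population, plus per-cell truth.

    Each cell carries K ~ Poisson(mean_load) activity-affecting mutations;
    each mutation draws a class from the class weights and a multiplicative
    effect from that class's distribution, and all effects on a cell multiply
    (log10 shifts add). Truth records are returned for the mutated cells;
    cells absent from the truth list carry no mutation.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    events = _draw_events(config, n, rng)
    k = rng.poisson(config.mean_load, n)
    truth: list[TruthRecord] = []
    shifts = np.zeros(n)
    for idx in np.nonzero(k > 0)[0]:
        labels = tuple(_sample_class(config, rng) for _ in range(k[idx]))
        shift = sum(_sample_mutation_shift(config, lab, rng) for lab in labels)
        shifts[idx] = shift
        copies = config.cnv_copies if "cnv" in labels else 1
        truth.append(TruthRecord(
            genotype_id=f"cell{idx:07d}", n_mutations=int(k[idx]),
            class_labels=labels, effect=float(10.0 ** shift),
            dominance=min(config.dominance[lab] for lab in labels),
            copies_yfp=copies))
    events["yfp"] = events["yfp"] + shifts
    return events, truth


def simulate_diploid_cross(truth_record: TruthRecord, config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           n: int | None = None) -> pd.DataFrame:
    """Events for a mutant x CFP-reference diploid heterozygote.

    The YFP channel reports the mutant-derived allele and the CFP channel the
    reference allele. Allele-specific classes (coding, cis) shift YFP only,
    scaled by their dominance; a trans-acting mutation shifts both channels by
    its dominance-scaled effect; a copy-number mutant multiplies YFP by its
    copy number and CFP by ``cnv_cfp_effect``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n is None:
        n = config.events_per_diploid_culture
    yfp_shift = 0.0
    cfp_shift = 0.0
    per_mutation = (np.log10(truth_record.effect) / truth_record.n_mutations
                    if truth_record.n_mutations else 0.0)
    for label in truth_record.class_labels:
        d = truth_record.dominance
        if label == "cnv":
            # the extra copy's dosage effect is carried by the YFP allele
            yfp_shift += d * per_mutation
            cfp_shift += np.log10(config.cnv_cfp_effect)
        elif label == "trans":
            yfp_shift += d * per_mutation
            cfp_shift += d * per_mutation
        else:  # coding, cis: allele-specific
            yfp_shift += d * per_mutation
    # culture-level replicate noise, independent per channel
    yfp_shift += rng.normal(0.0, config.diploid_culture_noise_sd) * config.fsc_mean
    cfp_shift += rng.normal(0.0, config.diploid_culture_noise_sd) * config.fsc_mean
    return _draw_events(config, n, rng, yfp_shift=yfp_shift, cfp_shift=cfp_shift)


def simulate_pyro_assay(copies_yfp: int, config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[int, int]:
    """Pyrosequencing read counts for the YFP/CFP allele fraction.

    A heterozygote with ``copies_yfp`` focal copies against one reference
    copy yields YFP reads ~ Binomial(total, copies/(copies+1)).
    """
    if copies_yfp < 1:
        raise ValueError("copies_yfp must be >= 1")
    if config.pyro_reads < 1:
        raise ValueError("pyro_reads must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = copies_yfp / (copies_yfp + 1)
    yfp_reads = int(rng.binomial(config.pyro_reads, p))
    return yfp_reads, config.pyro_reads - yfp_reads


def simulate_transgene_mutation(class_label: str,
                                annotation: ReporterAnnotation,
                                rng: np.random.Generator,
                                genotype_id: str = ""
                                ) -> TransgeneMutation | None:
    """Transgene mutation record implied by a functional class.

    EMS causes G/C -> A/T transitions, so coding mutants receive a G->A or
    C->T substitution inside the CDS verified (by translation) to change the
    protein, and cis mutants a substitution inside the promoter. Trans-acting
    and copy-number mutants leave the transgene sequence intact.
    """
    if class_label in ("trans", "cnv"):
        return None
    if class_label == "coding":
        cds = annotation.cds_sequence
        if len(cds) == 0:
            raise ValueError("annotation has an empty CDS")
        gc_offsets = [i for i, b in enumerate(cds) if b in "GC"]
        for _ in range(10_000):
            off = gc_offsets[rng.integers(len(gc_offsets))]
            pos = annotation.cds_span[0] + off
            ref = cds[off]
            alt = _TRANSITION[ref]
            effect = coding_effect(pos, ref, alt, annotation)
            if effect in ("nonsynonymous", "nonsense"):
                return TransgeneMutation(genotype_id, pos, ref, alt,
                                         region="cds", coding_effect=effect)
        raise RuntimeError("no protein-changing transition found in CDS")
    if class_label == "cis":
        lo, hi = annotation.promoter_span
        pos = 0
        while pos == 0:
            pos = int(rng.integers(lo, hi + 1))
        ref = "G" if rng.random() < 0.5 else "C"
        return TransgeneMutation(genotype_id, pos, ref, _TRANSITION[ref],
                                 region="promoter", coding_effect="n/a")
    raise ValueError(f"unknown class label {class_label!r}")


# ---------------------------------------------------------------------------
# culture- and screen-level generation

def _culture_events(config: SimulationConfig, rng: np.random.Generator,
                    genotype_id: str, replicate: int, n_events: int,
                    activity_shift: float, noise_sd: float) -> pd.DataFrame:
    culture_offset = rng.normal(0.0, noise_sd) * config.fsc_mean
    ev = _draw_events(config, n_events, rng,
                      yfp_shift=activity_shift + culture_offset)
    ev.insert(0, "replicate", replicate)
    ev.insert(0, "genotype_id", genotype_id)
    return ev


def simulate_control_cultures(config: SimulationConfig, n_cultures: int,
                              rng: np.random.Generator | None = None,
                              n_events: int | None = None,
                              prefix: str = "control") -> pd.DataFrame:
    """Replicate clonal control cultures as one stacked event table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_events is None:
        n_events = config.events_per_culture
    frames = [_culture_events(config, rng, prefix, rep, n_events, 0.0,
                              config.culture_noise_sd)
              for rep in range(n_cultures)]
    return pd.concat(frames, ignore_index=True)


def _collection_truth(config: SimulationConfig, annotation: ReporterAnnotation,
                      rng: np.random.Generator) -> list[TruthRecord]:
    """Truth records for the isolated mutant collection (one mutation each)."""
    records = []
    for i in range(config.n_mutant_genotypes):
        gid = f"mut{i:04d}"
        label = _sample_class(config, rng)
        shift = _sample_mutation_shift(config, label, rng)
        mutation = simulate_transgene_mutation(label, annotation, rng, gid)
        records.append(TruthRecord(
            genotype_id=gid, n_mutations=1, class_labels=(label,),
            effect=float(10.0 ** shift), dominance=config.dominance[label],
            transgene_mutation=mutation,
            copies_yfp=config.cnv_copies if label == "cnv" else 1))
    return records


def simulate_screen(config: SimulationConfig,
                    annotation: ReporterAnnotation | None = None
                    ) -> ScreenDataset:
    """Generate a complete screen: populations, cultures, assays, and truth.

    One seed sequence drives the whole dataset; per-stage and per-genotype
    RNG streams are spawned deterministically from it, so a given seed is
    bit-reproducible regardless of which components are consumed.
    """
    if annotation is None:
        annotation = default_annotation()
    ss = np.random.SeedSequence(config.seed)
    (ss_pop, ss_truth, ss_hap, ss_hapctl, ss_dip, ss_dipctl,
     ss_pyro) = ss.spawn(7)
    rng_pop = np.random.default_rng(ss_pop)

    control_events = simulate_control_population(
        config, config.n_cells_control, rng_pop)
    treated_events, treated_truth = simulate_treated_population(
        config, config.n_cells_treated, rng_pop)

    truth = _collection_truth(config, annotation,
                              np.random.default_rng(ss_truth))

    hap_streams = ss_hap.spawn(len(truth))
    hap_frames = []
    for rec, child in zip(truth, hap_streams):
        rng = np.random.default_rng(child)
        hap_frames.append(_culture_events(
            config, rng, rec.genotype_id, 0, config.events_per_culture,
            np.log10(rec.effect), config.culture_noise_sd))
    haploid_cultures = pd.concat(hap_frames, ignore_index=True)

    haploid_controls = simulate_control_cultures(
        config, config.n_control_replicates,
        np.random.default_rng(ss_hapctl))

    dip_streams = ss_dip.spawn(len(truth))
    dip_frames = []
    for rec, child in zip(truth, dip_streams):
        ev = simulate_diploid_cross(rec, config,
                                    np.random.default_rng(child))
        ev.insert(0, "replicate", 0)
        ev.insert(0, "genotype_id", rec.genotype_id)
        dip_frames.append(ev)
    diploid_cultures = pd.concat(dip_frames, ignore_index=True)

    rng_dipctl = np.random.default_rng(ss_dipctl)
    dipctl_frames = []
    for rep in range(config.n_control_replicates):
        ref = TruthRecord(genotype_id="control", n_mutations=0,
                          class_labels=(), effect=1.0, dominance=0.0)
        ev = simulate_diploid_cross(ref, config, rng_dipctl)
        ev.insert(0, "replicate", rep)
        ev.insert(0, "genotype_id", "control")
        dipctl_frames.append(ev)
    diploid_controls = pd.concat(dipctl_frames, ignore_index=True)

    rng_pyro = np.random.default_rng(ss_pyro)
    pyro_rows = []
    for rec in truth:
        y, c = simulate_pyro_assay(rec.copies_yfp, config, rng_pyro)
        pyro_rows.append({"genotype_id": rec.genotype_id,
                          "yfp_reads": y, "cfp_reads": c})
    pyro_assays = pd.DataFrame(pyro_rows)

    transgene_mutations = [rec.transgene_mutation for rec in truth
                           if rec.transgene_mutation is not None]

    return ScreenDataset(
        config=config,
        control_events=control_events,
        treated_events=treated_events,
        treated_truth=treated_truth,
        haploid_cultures=haploid_cultures,
        haploid_controls=haploid_controls,
        diploid_cultures=diploid_cultures,
        diploid_controls=diploid_controls,
        pyro_assays=pyro_assays,
        transgene_mutations=transgene_mutations,
        truth=truth,
    )
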