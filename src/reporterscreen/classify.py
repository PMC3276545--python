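"""Functional classification of mutants: coding / CNV / cis-regulatory / trans.

Evidence comes from two assays. Sequencing the reporter transgene yields at
most one substitution per mutant, located relative to the transcription start
site and, if inside the CDS, translated to decide whether it changes the
protein. Pyrosequencing of YFP/CFP heterozygous diploids yields allele read
counts whose YFP fraction clusters at n/(n+1) for n focal-reporter copies
against one reference copy: 1/2 for a single copy, 2/3 for a duplication.
A mutant with a nonsynonymous or nonsense CDS change is "coding"; with a
promoter substitution, "cis"; with an extra reporter copy, "cnv"; with
neither, "trans". Mutants lacking both a transgene mutation and a usable
copy-number assay cannot be told apart from CNVs and are "ambiguous".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .annotation import ReporterAnnotation

__all__ = [
    "TransgeneMutation",
    "CopyNumberCall",
    "CopyNumberThresholds",
    "MutantClassAssignment",
    "locate_mutation",
    "coding_effect",
    "call_copy_number",
    "assign_class",
    "gc_content",
]

CLASSES = ("coding", "cnv", "cis", "trans", "ambiguous")


@dataclass(frozen=True)
class TransgeneMutation:
    genotype_id: str
    position: int  # TSS-relative, no 0
    ref: str
    alt: str
    region: str = ""  # promoter / cds / terminator / none
    coding_effect: str = "n/a"  # nonsynonymous / synonymous / nonsense / n/a

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.position == 0:
            raise ValueError("position 0 is undefined")


@dataclass(frozen=True)
class CopyNumberThresholds:
    """Decision rule for the pyrosequencing YFP allele fraction.

    The midpoint 7/12 between the one-copy (1/2) and two-copy (2/3)
    expectations separates the clusters; fractions within ``ci_guard``
    binomial standard errors of the midpoint are left indeterminate.
    """

    t_low: float = 7.0 / 12.0
    t_high: float = 7.0 / 12.0
    ci_guard: float = 2.0
    min_reads: int = 100


@dataclass(frozen=True)
class CopyNumberCall:
    genotype_id: str
    yfp_reads: int
    cfp_reads: int
    yfp_fraction: float
    copies: int | str  # 1, 2, or "indeterminate"
    qc_flag: str = ""


@dataclass(frozen=True)
class MutantClassAssignment:
    genotype_id: str
    class_label: str
    evidence: dict


def locate_mutation(position: int, annotation: ReporterAnnotation) -> str:
    """Region of a TSS-relative position: promoter, cds, terminator, or none."""
    if position == 0:
        raise ValueError("position 0 is undefined in TSS-relative coordinates")
    for name, span in (("promoter", annotation.promoter_span),
                       ("cds", annotation.cds_span),
                       ("terminator", annotation.terminator_span)):
        if span[0] <= position <= span[1]:
            return name
    return "none"


def coding_effect(position: int, ref: str, alt: str,
                  annotation: ReporterAnnotation) -> str:
    """Effect of a CDS substitution: nonsynonymous, synonymous, or nonsense.

    The affected codon is translated before and after the substitution with
    the standard nuclear genetic code. The reference base must match the
    annotated CDS sequence; a mismatch is a data-integrity error.
    """
    if locate_mutation(position, annotation) != "cds":
        raise ValueError(f"position {position} is not in the CDS")
    idx, sub, codon = annotation.codon_at(position)
    if codon[sub] != ref.upper():
        raise ValueError(
            f"ref {ref!r} does not match CDS base {codon[sub]!r} at "
            f"position {position} (codon {idx + 1})")
    mutated = codon[:sub] + alt.upper() + codon[sub + 1:]
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(mutated).translate())
    if aa_after == "*" and aa_before != "*":
        return "nonsense"
    return "synonymous" if aa_before == aa_after else "nonsynonymous"


def call_copy_number(yfp_reads: int, cfp_reads: int,
                     thresholds: CopyNumberThresholds | None = None, *,
                     genotype_id: str = "") -> CopyNumberCall:
    """Call reporter copy number from pyrosequencing allele read counts."""
    if thresholds is None:
        thresholds = CopyNumberThresholds()
    total = yfp_reads + cfp_reads
    if total == 0:
        raise ValueError("zero total reads")
    if yfp_reads < 0 or cfp_reads < 0:
        raise ValueError("read counts must be non-negative")
    frac = yfp_reads / total
    if total < thresholds.min_reads:
        return CopyNumberCall(genotype_id, yfp_reads, cfp_reads, frac,
                              "indeterminate", qc_flag="low_reads")
    se = np.sqrt(max(frac * (1 - frac), 1e-12) / total)
    lo = thresholds.t_low - thresholds.ci_guard * se
    hi = thresholds.t_high + thresholds.ci_guard * se
    if frac < lo:
        copies: int | str = 1
    elif frac > hi:
        copies = 2
    else:
        copies = "indeterminate"
    return CopyNumberCall(genotype_id, yfp_reads, cfp_reads, frac, copies)


def assign_class(mutation: TransgeneMutation | None,
                 cnv: CopyNumberCall | None, *,
                 genotype_id: str = "",
                 strict_silent: bool = False) -> MutantClassAssignment:
    """Assign a functional class from transgene-mutation and copy-number evidence.

    Precedence is coding > cis > cnv > trans. A synonymous CDS change does
    not count as coding evidence and falls through to the copy-number branch
    (with ``strict_silent`` it is flagged as "silent" in the evidence).
    A missing copy-number assay with no transgene mutation is "ambiguous":
    such a genotype could be either a CNV or a trans mutant.
    """
    if mutation is None and cnv is None:
        return MutantClassAssignment(genotype_id, "ambiguous",
                                     {"reason": "no evidence"})
    gid = genotype_id or (mutation.genotype_id if mutation else cnv.genotype_id)
    evidence: dict = {}
    if mutation is not None:
        if mutation.region == "promoter" and mutation.coding_effect not in ("n/a", ""):
            raise ValueError(
                f"{gid}: promoter mutation carries a coding_effect annotation")
        evidence["mutation"] = mutation
        if mutation.region == "cds" and mutation.coding_effect in (
                "nonsynonymous", "nonsense"):
            return MutantClassAssignment(gid, "coding", evidence)
        if mutation.region == "promoter":
            return MutantClassAssignment(gid, "cis", evidence)
        if mutation.region == "cds" and mutation.coding_effect == "synonymous":
            if strict_silent:
                evidence["silent"] = True
    if cnv is not None:
        evidence["copy_number"] = cnv
        if cnv.copies == 2:
            return MutantClassAssignment(gid, "cnv", evidence)
        return MutantClassAssignment(gid, "trans", evidence)
    # transgene mutation present but outside informative regions, no assay
    return MutantClassAssignment(gid, "ambiguous", evidence)


def gc_content(sequence: str) -> float:
    """Percent G+C of an unambiguous nucleotide sequence."""
    seq = sequence.upper()
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains non-ACGT characters")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
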