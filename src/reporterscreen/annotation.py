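"""Reporter-gene annotation in transcription-start-site coordinates.

The reporter construct is a promoter / fluorescent-protein CDS / terminator
fusion. All positions are counted from the transcription start site (+1),
negative upstream, and position 0 does not exist (the coordinate jumps from
-1 directly to +1), following the convention used for promoter mutation maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq

Span = tuple[int, int]

_SYNTHETIC_CDS_RESOURCE = "synthetic_venus_cds.fasta"


def _span_len(span: Span) -> int:
    """Length of an inclusive TSS-relative span (no position 0)."""
    lo, hi = span
    n = hi - lo + 1
    if lo < 0 < hi:
        n -= 1  # coordinate system skips 0
    return n


@dataclass(frozen=True)
class ReporterAnnotation:
    """Three-span annotation of the reporter transgene.

    Parameters
    ----------
    promoter_span, cds_span, terminator_span
        Inclusive (start, end) intervals in TSS-relative coordinates.
    cds_sequence
        Nucleotide sequence of the CDS, length divisible by 3.
    tss_offset_to_atg
        TSS-relative position of the A of the start codon. Must equal
        ``cds_span[0]``; kept explicit because the TSS-to-ATG distance is a
        property of the construct, not a universal constant.
    """

    promoter_span: Span
    cds_span: Span
    terminator_span: Span
    cds_sequence: str
    tss_offset_to_atg: int

    def __post_init__(self) -> None:
        for span in (self.promoter_span, self.cds_span, self.terminator_span):
            if span[0] > span[1]:
                raise ValueError(f"span {span} is reversed")
            if span[0] == 0 or span[1] == 0:
                raise ValueError("TSS-relative coordinates have no position 0")
        if not (self.promoter_span[1] < self.cds_span[0]
                and self.cds_span[1] < self.terminator_span[0]):
            raise ValueError("spans must be ordered promoter < cds < terminator")
        cds = self.cds_sequence.upper()
        if len(cds) == 0:
            raise ValueError("annotation has an empty CDS")
        if len(cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if len(cds) != _span_len(self.cds_span):
            raise ValueError("cds_sequence length does not match cds_span")
        if self.tss_offset_to_atg != self.cds_span[0]:
            raise ValueError("tss_offset_to_atg must equal the CDS start")
        object.__setattr__(self, "cds_sequence", cds)

    # -- coordinate helpers -------------------------------------------------

    def contains(self, span: Span, position: int) -> bool:
        if position == 0:
            raise ValueError("position 0 is undefined in TSS-relative coordinates")
        return span[0] <= position <= span[1]

    def cds_offset(self, position: int) -> int:
        """0-based offset into the CDS of a TSS-relative position."""
        if not self.contains(self.cds_span, position):
            raise ValueError(f"position {position} is not inside the CDS")
        off = position - self.cds_span[0]
        if self.cds_span[0] < 0 < position:
            off -= 1
        return off

    def codon_at(self, position: int) -> tuple[int, int, str]:
        """Return (codon index, within-codon offset, codon) for a CDS position."""
        off = self.cds_offset(position)
        idx, sub = divmod(off, 3)
        return idx, sub, self.cds_sequence[3 * idx:3 * idx + 3]

    def translate(self) -> str:
        return str(Seq(self.cds_sequence).translate())


def load_synthetic_cds() -> str:
    """Load the bundled synthetic Venus-type YFP CDS.

    This is a constructed stand-in sequence, not the natural Venus gene: it
    reproduces the length (238 codons + stop) and GC content (35.56%) of the
    reporter CDS and carries a G at TSS +348 whose transition is synonymous.
    """
    ref = resources.files("reporterscreen.data") / _SYNTHETIC_CDS_RESOURCE
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def default_annotation() -> ReporterAnnotation:
    """Annotation of the simulated reporter construct.

    Promoter spans -680..-1 (a TDH3-like 5' intergenic region), a 33-nt
    5' UTR (+1..+33, assigned to no feature), the CDS at +34..+750, and a
    CYC1-like terminator at +751..+1000.
    """
    return ReporterAnnotation(
        promoter_span=(-680, -1),
        cds_span=(34, 750),
        terminator_span=(751, 1000),
        cds_sequence=load_synthetic_cds(),
        tss_offset_to_atg=34,
    )
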