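"""Plain-text interchange for screen artifacts.

All intermediate artifacts are TSV (event tables, truth tables, phenotype
tables, transgene mutations, classifications) or JSON (rate reports,
provenance), so every pipeline stage can be re-run from files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .classify import TransgeneMutation
from .simulate import TruthRecord

__all__ = [
    "write_events", "read_events",
    "write_truth", "read_truth",
    "write_mutations", "read_mutations",
]

_FLOAT_FMT = "%.10g"


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    rows = []
    for rec in truth:
        mut = rec.transgene_mutation
        rows.append({
            "genotype_id": rec.genotype_id,
            "n_mutations": rec.n_mutations,
            "class_labels": ",".join(rec.class_labels),
            "effect": rec.effect,
            "dominance": rec.dominance,
            "copies_yfp": rec.copies_yfp,
            "mut_position": mut.position if mut else "",
            "mut_ref": mut.ref if mut else "",
            "mut_alt": mut.alt if mut else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=_FLOAT_FMT)


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        mut = None
        if row["mut_position"] != "":
            mut = TransgeneMutation(
                genotype_id=row["genotype_id"],
                position=int(row["mut_position"]),
                ref=row["mut_ref"], alt=row["mut_alt"])
        labels = tuple(s for s in str(row["class_labels"]).split(",") if s)
        records.append(TruthRecord(
            genotype_id=row["genotype_id"],
            n_mutations=int(row["n_mutations"]),
            class_labels=labels,
            effect=float(row["effect"]),
            dominance=float(row["dominance"]),
            transgene_mutation=mut,
            copies_yfp=int(row["copies_yfp"])))
    return records


def write_mutations(mutations: list[TransgeneMutation], path: str | Path) -> None:
    rows = [{"genotype_id": m.genotype_id, "position": m.position,
             "ref": m.ref, "alt": m.alt, "region": m.region,
             "coding_effect": m.coding_effect} for m in mutations]
    pd.DataFrame(rows, columns=["genotype_id", "position", "ref", "alt",
                                "region", "coding_effect"]
                 ).to_csv(path, sep="\t", index=False)


def read_mutations(path: str | Path) -> list[TransgeneMutation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [TransgeneMutation(genotype_id=row["genotype_id"],
                              position=int(row["position"]),
                              ref=row["ref"], alt=row["alt"],
                              region=row.get("region", ""),
                              coding_effect=row.get("coding_effect", "n/a"))
            for _, row in df.iterrows()]
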