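"""ClinVar-style annotation of kept variants and diagnosis summaries.

Joins called variants to a packaged, frozen annotation table keyed by
(pos, ref, alt) and tallies clinical significance categories and associated
diagnoses, distinguishing variants where a diagnosis is the only one provided
from those where it appears in combination with others.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .variants import DEL, INS, SNV, MtVariant, VariantKey

SIGNIFICANCE_VOCAB = {
    "Benign",
    "Likely benign",
    "Pathogenic",
    "Conflicting interpretations of pathogenicity",
    "Drug response",
    "Not provided",
}

NO_DIAGNOSIS = "Not provided"


@dataclass(frozen=True)
class ClinVarRecord:
    key: VariantKey
    rsid: str
    clinvar_id: str
    significance: str
    diagnoses: tuple[str, ...]


@dataclass
class ClinVarTable:
    records: dict[VariantKey, ClinVarRecord] = field(default_factory=dict)

    def get(self, key: VariantKey) -> ClinVarRecord | None:
        return self.records.get(key)

    def __len__(self) -> int:
        return len(self.records)


def load_clinvar_table(path: str | Path) -> ClinVarTable:
    """Parse the annotation TSV; duplicate (pos, ref, alt) keys are an error."""
    table = ClinVarTable()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.empty and "pos" not in df.columns:
        return table
    for row in df.itertuples(index=False):
        key = VariantKey(int(row.pos), row.ref, row.alt, row.variant_type)
        if key in table.records:
            raise ValueError(f"duplicate annotation key {key}")
        if row.significance not in SIGNIFICANCE_VOCAB:
            raise ValueError(f"unknown significance {row.significance!r}")
        table.records[key] = ClinVarRecord(
            key=key,
            rsid=row.rsid,
            clinvar_id=row.clinvar_id,
            significance=row.significance,
            diagnoses=tuple(d.strip() for d in row.diagnoses.split("|") if d.strip()),
        )
    return table


def packaged_clinvar_table() -> ClinVarTable:
    """The packaged synthetic ClinVar-style table."""
    with importlib.resources.as_file(
        importlib.resources.files("cfmito") / "data" / "clinvar_synthetic.tsv"
    ) as p:
        return load_clinvar_table(p)


def annotate_variants(
    variants: Iterable[MtVariant | VariantKey], table: ClinVarTable
) -> pd.DataFrame:
    """Exact-key join of variants to the annotation table.

    One row per input variant; unmatched variants carry ``annotated=False``.
    Annotating an already-annotated set again gives the same result
    (the join is idempotent in the variant keys).
    """
    rows = []
    for v in variants:
        key = v.key if isinstance(v, MtVariant) else v
        rec = table.get(key)
        rows.append(
            {
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "variant_type": key.vtype,
                "annotated": rec is not None,
                "rsid": rec.rsid if rec else "",
                "clinvar_id": rec.clinvar_id if rec else "",
                "significance": rec.significance if rec else "",
                "diagnoses": "|".join(rec.diagnoses) if rec else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pos", "ref", "alt", "variant_type", "annotated",
            "rsid", "clinvar_id", "significance", "diagnoses",
        ],
    )


@dataclass
class DiagnosisSummary:
    """Cohort-level tallies over annotated variants.

    ``diagnosis_counts`` rows: diagnosis, n_only (only diagnosis provided for
    the variant), n_combination, total; sorted by total desc then name asc.
    """

    diagnosis_counts: pd.DataFrame
    significance_proportions: pd.Series
    fraction_with_diagnosis: float
    n_annotated: int
    patient_counts: pd.Series | None = None


def summarize_diagnoses(
    annotated: pd.DataFrame, sample_ids: Sequence[str] | None = None
) -> DiagnosisSummary:
    """Tally diagnoses and significance over annotated variants.

    A variant with k diagnoses contributes to all k rows — as "only" when
    k == 1 and "in combination" otherwise.  With ``sample_ids`` (one per row
    of ``annotated``), patient-level diagnosis frequencies (fraction of
    distinct patients carrying >= 1 variant with the diagnosis) are added.
    """
    ann = annotated[annotated["annotated"]].copy()
    n_annotated = len(ann)
    counts: dict[str, list[int]] = {}
    for _, row in ann.iterrows():
        diags = [d for d in row["diagnoses"].split("|") if d and d != NO_DIAGNOSIS]
        for d in diags:
            slot = counts.setdefault(d, [0, 0])
            slot[0 if len(diags) == 1 else 1] += 1
    table = pd.DataFrame(
        [(d, c[0], c[1], c[0] + c[1]) for d, c in counts.items()],
        columns=["diagnosis", "n_only", "n_combination", "total"],
    ).sort_values(["total", "diagnosis"], ascending=[False, True]).reset_index(drop=True)
    sig = (
        ann["significance"].value_counts(normalize=True).sort_index()
        if n_annotated
        else pd.Series(dtype=float)
    )
    has_diag = ann["diagnoses"].map(
        lambda s: any(d and d != NO_DIAGNOSIS for d in s.split("|"))
    )
    frac = float(has_diag.mean()) if n_annotated else 0.0
    patient_counts = None
    if sample_ids is not None:
        ann_sid = annotated.assign(sample_id=list(sample_ids))
        ann_sid = ann_sid[ann_sid["annotated"]]
        per: dict[str, set[str]] = {}
        for _, row in ann_sid.iterrows():
            for d in row["diagnoses"].split("|"):
                if d and d != NO_DIAGNOSIS:
                    per.setdefault(d, set()).add(row["sample_id"])
        n_patients = len(set(sample_ids))
        patient_counts = pd.Series(
            {d: len(s) / n_patients for d, s in per.items()}, dtype=float
        ).sort_values(ascending=False)
    return DiagnosisSummary(
        diagnosis_counts=table,
        significance_proportions=sig,
        fraction_with_diagnosis=frac,
        n_annotated=n_annotated,
        patient_counts=patient_counts,
    )
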