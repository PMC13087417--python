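"""Rule-based classification of ACTB/ACTG1 variant carriers into
non-muscle actinopathy (NMA) subtypes.

The classifier is a deterministic, totally-defined rule engine: every
valid record receives exactly one label plus an auditable trace of the
rules that fired. Phenotype flags are tri-state (present/absent/unknown);
rule predicates treat ``unknown`` as not-present, matching the counting
convention used for incomplete clinical information, while the raw
tri-state values are preserved for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GENES",
    "VARIANT_CLASSES",
    "PHENOTYPE_FLAGS",
    "LABELS",
    "PAV_LABELS",
    "IndividualRecord",
    "NMAAssignment",
    "CohortReport",
    "classify",
    "classify_cohort",
]

GENES = ("ACTB", "ACTG1")

VARIANT_CLASSES = (
    "missense",
    "inframe_indel",
    "stop_gain",
    "frameshift",
    "start_loss",
    "splice",
    "whole_gene_deletion",
)

PROTEIN_ALTERING_CLASSES = ("missense", "inframe_indel")

PHENOTYPE_FLAGS = (
    "bwcff_gestalt",
    "actb_lof_gestalt",
    "frontal_pachygyria",
    "isolated_hearing_loss",
    "dystonia",
    "deafness",
    "thrombocytopenia",
    "developmental_delay",
    "congenital_anomalies",
)

TRI_STATE = ("present", "absent", "unknown")

LABELS = (
    "ACTB_pLoF_disorder",
    "BWCFF1",
    "BWCFF2",
    "DDS1",
    "ACTG1_HL",
    "unNMA",
    "ACTG1_pLoF_likely_benign",
    "del17q25_contiguous",
    "unclassifiable",
)

#: subtype labels reachable by protein-altering (missense/in-frame) variants
PAV_LABELS = (
    "BWCFF1",
    "BWCFF2",
    "ACTG1_HL",
    "DDS1",
    "ACTB_pLoF_disorder",
    "unNMA",
)

#: the single protein change compatible with dystonia-deafness syndrome 1
DDS1_PROTEIN_CHANGE = "Arg183Trp"

NMD_CALLS = ("subject_to_NMD", "escapes_NMD", "not_applicable")


@dataclass(frozen=True)
class IndividualRecord:
    """One study subject: genotype plus tri-state phenotype flags."""

    subject_id: str
    gene: str
    variant_class: str
    protein_change: Optional[str] = None
    nmd_call: str = "not_applicable"
    bwcff_gestalt: str = "unknown"
    actb_lof_gestalt: str = "unknown"
    frontal_pachygyria: str = "unknown"
    isolated_hearing_loss: str = "unknown"
    dystonia: str = "unknown"
    deafness: str = "unknown"
    thrombocytopenia: str = "unknown"
    developmental_delay: str = "unknown"
    congenital_anomalies: str = "unknown"

    def __post_init__(self):
        if self.gene not in GENES:
            raise ValueError(f"gene must be one of {GENES}, got {self.gene!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.nmd_call not in NMD_CALLS:
            raise ValueError(f"unknown nmd_call {self.nmd_call!r}")
        is_pav = self.variant_class in PROTEIN_ALTERING_CLASSES
        if is_pav != (self.protein_change is not None):
            raise ValueError(
                "protein_change must be set exactly for missense/in-frame "
                f"records (subject {self.subject_id})"
            )
        for name in PHENOTYPE_FLAGS:
            if getattr(self, name) not in TRI_STATE:
                raise ValueError(
                    f"flag {name} must be one of {TRI_STATE} "
                    f"(subject {self.subject_id})"
                )

    def flag(self, name: str) -> bool:
        """Predicate view of a tri-state flag: unknown counts as absent."""
        return getattr(self, name) == "present"

    @property
    def is_protein_altering(self) -> bool:
        return self.variant_class in PROTEIN_ALTERING_CLASSES


@dataclass(frozen=True)
class NMAAssignment:
    label: str
    rule_trace: tuple
    provisional: bool = False

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")


def classify(record: IndividualRecord) -> NMAAssignment:
    """Assign one NMA label; pure and total on valid records.

    Rules fire in fixed order:

    1. gene + variant-class routing (pLoF point variants and whole-gene
       deletions),
    2. ACTB missense/in-frame with the LoF-type gestalt and no frontal
       pachygyria -> functional-LoF arm of the ACTB pLoF disorder,
    3. ACTB Arg183Trp with dystonia or deafness -> DDS1,
    4. BWCFF gestalt and/or frontal pachygyria -> BWCFF1/BWCFF2 by gene,
    5. ACTG1 missense with isolated hearing loss and no other flag -> HL,
    6. remaining missense/in-frame -> provisional unNMA,
    7. anything else -> unclassifiable.
    """
    trace = []
    g, vc = record.gene, record.variant_class

    # rule 1: genotype routing
    if g == "ACTG1" and vc in ("stop_gain", "frameshift"):
        trace.append("R1a:actg1-plof-point")
        return NMAAssignment("ACTG1_pLoF_likely_benign", tuple(trace))
    if g == "ACTG1" and vc == "whole_gene_deletion":
        trace.append("R1b:actg1-whole-gene-deletion")
        return NMAAssignment("del17q25_contiguous", tuple(trace))
    if g == "ACTB" and vc in (
        "stop_gain",
        "frameshift",
        "start_loss",
        "whole_gene_deletion",
    ):
        trace.append("R1c:actb-plof")
        return NMAAssignment("ACTB_pLoF_disorder", tuple(trace))
    # splice variants: no dedicated arm; route by NMD call when provided
    if vc == "splice":
        if record.nmd_call in ("subject_to_NMD", "escapes_NMD"):
            if g == "ACTB":
                trace.append("R1d:actb-splice-nmd-routed")
                return NMAAssignment("ACTB_pLoF_disorder", tuple(trace))
            trace.append("R1e:actg1-splice-nmd-routed")
            return NMAAssignment("ACTG1_pLoF_likely_benign", tuple(trace))
        trace.append("R7:splice-without-nmd-call")
        return NMAAssignment("unclassifiable", tuple(trace))

    if not record.is_protein_altering:
        # only ACTG1 start_loss reaches here; no rule covers it
        trace.append("R7:no-matching-arm")
        return NMAAssignment("unclassifiable", tuple(trace))

    # from here on the record is missense or in-frame
    # rule 2: functional-LoF arm
    if (
        g == "ACTB"
        and record.flag("actb_lof_gestalt")
        and not record.flag("frontal_pachygyria")
    ):
        trace.append("R2:actb-functional-lof")
        return NMAAssignment("ACTB_pLoF_disorder", tuple(trace))

    # rule 3: dystonia-deafness syndrome 1
    if (
        g == "ACTB"
        and record.protein_change == DDS1_PROTEIN_CHANGE
        and (record.flag("dystonia") or record.flag("deafness"))
    ):
        trace.append("R3:actb-arg183trp-dds1")
        return NMAAssignment("DDS1", tuple(trace))

    # rule 4: BWCFF by gestalt and/or pachygyria
    if record.flag("bwcff_gestalt") or record.flag("frontal_pachygyria"):
        if g == "ACTB":
            trace.append("R4a:bwcff-actb")
            return NMAAssignment("BWCFF1", tuple(trace))
        trace.append("R4b:bwcff-actg1")
        return NMAAssignment("BWCFF2", tuple(trace))

    # rule 5: isolated hearing loss
    if (
        g == "ACTG1"
        and vc == "missense"
        and record.flag("isolated_hearing_loss")
        and not any(
            record.flag(f) for f in PHENOTYPE_FLAGS if f != "isolated_hearing_loss"
        )
    ):
        trace.append("R5:actg1-isolated-hl")
        return NMAAssignment("ACTG1_HL", tuple(trace))

    # rule 6: provisional unspecified NMA
    trace.append("R6:unspecified-nma")
    return NMAAssignment("unNMA", tuple(trace), provisional=True)


@dataclass
class CohortReport:
    assignments: pd.DataFrame
    label_counts: dict
    gene_crosstab: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "label_counts": dict(self.label_counts),
            "gene_crosstab": {
                str(g): {str(k): int(v) for k, v in row.items()}
                for g, row in self.gene_crosstab.to_dict(orient="index").items()
            },
            "n_subjects": int(len(self.assignments)),
        }


def classify_cohort(records: Sequence[IndividualRecord]) -> CohortReport:
    """Classify a cohort; stable ordering by subject_id.

    Raises ``ValueError`` on duplicate subject ids.
    """
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id(s): {dupes}")

    rows = []
    for r in sorted(records, key=lambda r: r.subject_id):
        a = classify(r)
        rows.append(
            {
                "subject_id": r.subject_id,
                "gene": r.gene,
                "variant_class": r.variant_class,
                "protein_change": r.protein_change,
                "label": a.label,
                "provisional": a.provisional,
                "rule_trace": "|".join(a.rule_trace),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "gene",
            "variant_class",
            "protein_change",
            "label",
            "provisional",
            "rule_trace",
        ],
    )
    counts = {lab: 0 for lab in LABELS}
    if len(df):
        counts.update(df["label"].value_counts().to_dict())
        xtab = pd.crosstab(df["gene"], df["label"])
    else:
        xtab = pd.DataFrame()
    return CohortReport(assignments=df, label_counts=counts, gene_crosstab=xtab)


def records_from_frame(df: pd.DataFrame) -> list:
    """Build validated records from a cohort table (TSV/JSON-derived)."""
    recs = []
    flag_cols = set(PHENOTYPE_FLAGS)
    for _, row in df.iterrows():
        kwargs = {}
        for f in fields(IndividualRecord):
            if f.name in row.index:
                val = row[f.name]
                if pd.isna(val):
                    val = "unknown" if f.name in flag_cols else None
                kwargs[f.name] = val
        recs.append(IndividualRecord(**kwargs))
    return recs


def records_to_frame(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{f.name: getattr(r, f.name) for f in fields(IndividualRecord)} for r in records]
    )
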