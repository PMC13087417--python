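"""Seeded generators for every input family consumed by the analyses.

Each generator emits objects that satisfy the invariants of their target
types (validated on construction) together with the ground truth used by
parameter-recovery tests: transcript models, gnomAD-style population
variant tables, clinical cohort records with known subtype labels,
spherical-cluster embedding sets, and exponential/sigmoid traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from nmascope.biophys_kinetics import KineticTrace, MeltCurve
from nmascope.cohort_classifier import IndividualRecord
from nmascope.gestalt_stats import EmbeddingSet
from nmascope.transcript_saturation import (
    Consequence,
    TranscriptModel,
    enumerate_snvs,
    reverse_complement,
)

__all__ = [
    "TranscriptSpec",
    "PopulationSpec",
    "CohortSpec",
    "EmbeddingSpec",
    "TraceSpec",
    "MeltSpec",
    "GeneratorConfig",
    "DEFAULT_COHORT_COMPOSITION",
    "SUBTYPE_TRUTH_LABELS",
    "DEFAULT_GESTALT_GROUPS",
    "make_transcript",
    "make_population",
    "make_cohort",
    "make_embeddings",
    "make_gestalt_fixture",
    "make_traces",
    "make_melts",
]

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val"
).split()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TranscriptSpec:
    """``n_codons`` counts amino-acid residues; the stop codon is appended,
    so the CDS spans 3*(n_codons+1) nt (375 residues -> 1,128 nt)."""

    n_codons: int = 375
    n_exons: int = 3
    strand: str = "+"
    gene_symbol: str = "SYNACT"
    chrom: str = "chrS"
    window_start: int = 10_001
    utr5_length: int = 60
    utr3_length: int = 90
    intron_length: int = 150


@dataclass
class PopulationSpec:
    """Per-class row counts drawn from the enumeration, plus decoy rows
    (indel-style alleles) that can never match an enumerated SNV."""

    class_counts: Dict[str, int] = field(
        default_factory=lambda: {"missense": 20, "synonymous": 30}
    )
    n_decoys: int = 5
    tags: Tuple[str, ...] = ("controls",)
    n_duplicated_across_tags: int = 0
    allele_number: int = 300_000


@dataclass
class CohortSpec:
    composition: Dict[str, int] = None
    flag_noise: float = 0.0

    def __post_init__(self):
        if self.composition is None:
            self.composition = dict(DEFAULT_COHORT_COMPOSITION)
        if not 0.0 <= self.flag_noise <= 1.0:
            raise ValueError("flag_noise must be in [0, 1]")
        if any(n < 0 for n in self.composition.values()):
            raise ValueError("subtype counts must be >= 0")


@dataclass
class EmbeddingSpec:
    cluster_sizes: Dict[str, int] = field(
        default_factory=lambda: {"A": 20, "B": 20}
    )
    n_dims: int = 512
    concentration: float = 5.0  # within-cluster 1/noise_sd
    directions: Optional[Dict[str, np.ndarray]] = None
    syndrome_of: Optional[Dict[str, str]] = None

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if any(n < 0 for n in self.cluster_sizes.values()):
            raise ValueError("cluster sizes must be >= 0")


@dataclass
class TraceSpec:
    n_traces: int = 1
    rate: float = 0.1
    noise_sd: float = 0.0
    n_points: int = 200
    duration: float = 120.0
    mode: str = "polymerization"
    offset: float = 100.0
    amplitude: float = 900.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class MeltSpec:
    n_curves: int = 1
    tm: float = 60.0
    slope: float = 2.0
    noise_sd: float = 0.0
    t_min: float = 30.0
    t_max: float = 90.0
    step: float = 0.5
    baseline: float = 50.0
    amplitude: float = 1000.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.step <= 0:
            raise ValueError("step must be positive")


@dataclass
class GeneratorConfig:
    seed: int
    transcript: TranscriptSpec = field(default_factory=TranscriptSpec)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    trace: TraceSpec = field(default_factory=TraceSpec)
    melt: MeltSpec = field(default_factory=MeltSpec)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def make_transcript(spec: TranscriptSpec = None, seed: int = 0) -> TranscriptModel:
    """Random valid ORF with start/stop, exon structure and UTRs."""
    spec = spec or TranscriptSpec()
    if spec.n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if spec.n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    rng = np.random.default_rng(seed)

    cds = (
        "ATG"
        + "".join(rng.choice(_SENSE_CODONS, size=spec.n_codons - 1))
        + str(rng.choice(_STOPS))
    )
    cds_len = len(cds)
    if spec.n_exons > cds_len:
        raise ValueError(
            f"cannot partition a {cds_len}-nt CDS into {spec.n_exons} exons"
        )
    # near-even contiguous partition of the CDS across exons
    bounds = np.linspace(0, cds_len, spec.n_exons + 1).round().astype(int)
    segments = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def _rand_seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    # assemble the transcript-strand window and record transcript coords
    parts: List[str] = []
    pos = 0
    exon_t: List[List[int]] = []
    cds_t: List[Tuple[int, int]] = []

    def _append(seq: str) -> Tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        start = pos + 1
        pos += len(seq)
        return start, pos

    utr5_s, utr5_e = (None, None)
    if spec.utr5_length:
        utr5_s, utr5_e = _append(_rand_seq(spec.utr5_length))
    for i, (a, b) in enumerate(segments):
        seg_s, seg_e = _append(cds[a:b])
        cds_t.append((seg_s, seg_e))
        exon_start = utr5_s if (i == 0 and utr5_s is not None) else seg_s
        exon_end = seg_e
        if i == len(segments) - 1 and spec.utr3_length:
            _, utr3_e = _append(_rand_seq(spec.utr3_length))
            exon_end = utr3_e
        exon_t.append([exon_start, exon_end])
        if i < len(segments) - 1:
            intron = "GT" + _rand_seq(max(spec.intron_length - 4, 0)) + "AG"
            _append(intron)

    window = "".join(parts)
    length = len(window)
    ws = spec.window_start
    we = ws + length - 1

    def to_genomic(t1: int, t2: int) -> Tuple[int, int]:
        if spec.strand == "+":
            return ws + t1 - 1, ws + t2 - 1
        return ws + (length - t2), ws + (length - t1)

    exons = sorted(to_genomic(a, b) for a, b in exon_t)
    cds_iv = sorted(to_genomic(a, b) for a, b in cds_t)
    genome_seq = window if spec.strand == "+" else reverse_complement(window)

    return TranscriptModel(
        gene_symbol=spec.gene_symbol,
        chrom=spec.chrom,
        genome_start=ws,
        genome_end=we,
        strand=spec.strand,
        exons=tuple(exons),
        cds_intervals=tuple(cds_iv),
        cds_sequence=cds,
        genome_sequence=genome_seq,
    )


# ---------------------------------------------------------------------------
# population tables
# ---------------------------------------------------------------------------

def make_population(
    spec: PopulationSpec,
    model: TranscriptModel,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict]:
    """Sample observed rows from the coding enumeration at configured
    per-class counts, plus indel-style decoys that never join. Returns the
    table and a truth ledger of per-class counts."""
    rng = np.random.default_rng(seed)
    variants = enumerate_snvs(model, "coding_only")
    by_class: Dict[str, list] = {}
    for v in variants:
        by_class.setdefault(v.consequence.value, []).append(v)

    rows = []
    truth = {"per_class": {}, "n_decoys": spec.n_decoys}
    for cls, n in spec.class_counts.items():
        if cls not in Consequence._value2member_map_:
            raise ValueError(f"unknown consequence class {cls!r}")
        avail = by_class.get(cls, [])
        if n > len(avail):
            raise ValueError(
                f"requested {n} {cls} rows but enumeration offers {len(avail)}"
            )
        picks = rng.choice(len(avail), size=n, replace=False)
        for i in picks:
            v = avail[int(i)]
            ac = int(rng.integers(1, 30))
            rows.append(
                {
                    "chrom": model.chrom,
                    "pos": v.genomic_pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "ac": ac,
                    "an": spec.allele_number,
                    "tag": str(rng.choice(spec.tags)),
                }
            )
        truth["per_class"][cls] = int(n)

    for _ in range(spec.n_decoys):
        pos = int(rng.integers(model.genome_start, model.genome_end + 1))
        ref = model.forward_ref_base(pos)
        rows.append(
            {
                "chrom": model.chrom,
                "pos": pos,
                "ref": ref,
                "alt": ref + "".join(rng.choice(list("ACGT"), size=2)),
                "ac": int(rng.integers(1, 30)),
                "an": spec.allele_number,
                "tag": str(rng.choice(spec.tags)),
            }
        )

    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "ac", "an", "tag"]
    )
    if spec.n_duplicated_across_tags and len(spec.tags) > 1 and len(df):
        k = min(spec.n_duplicated_across_tags, len(df))
        dup = df.head(k).copy()
        other = {t: [x for x in spec.tags if x != t][0] for t in spec.tags}
        dup["tag"] = dup["tag"].map(other)
        df = pd.concat([df, dup], ignore_index=True)
        truth["n_duplicated_across_tags"] = int(k)
    return df, truth


# ---------------------------------------------------------------------------
# clinical cohorts
# ---------------------------------------------------------------------------

#: default composition mirroring the published cohort arithmetic:
#: 290 individuals = 275 SNV carriers (145 ACTB + 130 ACTG1) + 15
#: whole-gene deletions; the six protein-altering subtypes sum to 259.
DEFAULT_COHORT_COMPOSITION: Dict[str, int] = {
    "BWCFF1": 73,
    "BWCFF2": 40,
    "ACTG1_HL": 60,
    "DDS1": 13,
    "ACTB_functional_LoF": 8,
    "unNMA_ACTB": 35,
    "unNMA_ACTG1": 30,
    "ACTB_pLoF_SNV": 16,
    "ACTB_deletion": 8,
    "ACTG1_deletion": 7,
}

#: classifier label each generator subtype must map to under zero noise
SUBTYPE_TRUTH_LABELS: Dict[str, str] = {
    "BWCFF1": "BWCFF1",
    "BWCFF2": "BWCFF2",
    "ACTG1_HL": "ACTG1_HL",
    "DDS1": "DDS1",
    "ACTB_functional_LoF": "ACTB_pLoF_disorder",
    "unNMA_ACTB": "unNMA",
    "unNMA_ACTG1": "unNMA",
    "ACTB_pLoF_SNV": "ACTB_pLoF_disorder",
    "ACTB_deletion": "ACTB_pLoF_disorder",
    "ACTG1_deletion": "del17q25_contiguous",
}

_FLAGS_ABSENT = {
    "bwcff_gestalt": "absent",
    "actb_lof_gestalt": "absent",
    "frontal_pachygyria": "absent",
    "isolated_hearing_loss": "absent",
    "dystonia": "absent",
    "deafness": "absent",
    "thrombocytopenia": "absent",
    "developmental_delay": "absent",
    "congenital_anomalies": "absent",
}

_NOISE_EXEMPT_FLAGS: Tuple[str, ...] = ()


def _random_protein_change(rng: np.random.Generator) -> str:
    while True:
        ref, alt = rng.choice(_AA3, size=2, replace=False)
        pos = int(rng.integers(2, 375))
        token = f"{ref}{pos}{alt}"
        if token != "Arg183Trp":
            return token


def _subtype_record(
    subtype: str, idx: int, rng: np.random.Generator
) -> IndividualRecord:
    sid = f"{subtype}_{idx:03d}"
    flags = dict(_FLAGS_ABSENT)
    if subtype in ("BWCFF1", "BWCFF2"):
        gene = "ACTB" if subtype == "BWCFF1" else "ACTG1"
        flags["bwcff_gestalt"] = "present"
        if idx % 2 == 0:
            flags["frontal_pachygyria"] = "present"
        flags["developmental_delay"] = "present"
        return IndividualRecord(
            sid, gene, "missense", _random_protein_change(rng), **flags
        )
    if subtype == "ACTG1_HL":
        flags["isolated_hearing_loss"] = "present"
        return IndividualRecord(
            sid, "ACTG1", "missense", _random_protein_change(rng), **flags
        )
    if subtype == "DDS1":
        flags["dystonia"] = "present"
        if idx % 2 == 0:
            flags["deafness"] = "present"
        return IndividualRecord(sid, "ACTB", "missense", "Arg183Trp", **flags)
    if subtype == "ACTB_functional_LoF":
        flags["actb_lof_gestalt"] = "present"
        flags["developmental_delay"] = "present"
        vc = "missense" if idx % 3 else "inframe_indel"
        return IndividualRecord(sid, "ACTB", vc, _random_protein_change(rng), **flags)
    if subtype in ("unNMA_ACTB", "unNMA_ACTG1"):
        gene = "ACTB" if subtype == "unNMA_ACTB" else "ACTG1"
        flags["developmental_delay"] = "present"
        return IndividualRecord(
            sid, gene, "missense", _random_protein_change(rng), **flags
        )
    if subtype == "ACTB_pLoF_SNV":
        vc = "stop_gain" if idx % 2 else "frameshift"
        nmd = "escapes_NMD" if idx % 3 == 0 else "subject_to_NMD"
        flags["thrombocytopenia"] = "present" if idx % 2 else "absent"
        flags["developmental_delay"] = "present"
        return IndividualRecord(sid, "ACTB", vc, None, nmd_call=nmd, **flags)
    if subtype == "ACTB_deletion":
        flags["thrombocytopenia"] = "present"
        flags["developmental_delay"] = "present"
        return IndividualRecord(sid, "ACTB", "whole_gene_deletion", None, **flags)
    if subtype == "ACTG1_deletion":
        return IndividualRecord(sid, "ACTG1", "whole_gene_deletion", None, **flags)
    raise ValueError(f"unknown cohort subtype {subtype!r}")


def make_cohort(
    spec: CohortSpec = None, seed: int = 0
) -> Tuple[List[IndividualRecord], pd.DataFrame]:
    """Generate a cohort with known subtype labels.

    Flags are generated to satisfy the classifier rules exactly; with
    ``flag_noise > 0`` each phenotype flag is independently flipped
    present<->absent at that rate (genotype fields are never touched).
    Returns the records and a truth table (subject_id, subtype,
    truth_label).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    # separate stream for flag corruption so genotype draws are identical
    # across noise settings at the same seed
    noise_rng = np.random.default_rng([seed, 1])
    records: List[IndividualRecord] = []
    truth_rows = []
    for subtype, n in spec.composition.items():
        if subtype not in SUBTYPE_TRUTH_LABELS:
            raise ValueError(f"unknown cohort subtype {subtype!r}")
        for i in range(n):
            rec = _subtype_record(subtype, i, rng)
            if spec.flag_noise > 0:
                rec = _corrupt_flags(rec, spec.flag_noise, noise_rng)
            records.append(rec)
            truth_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "subtype": subtype,
                    "truth_label": SUBTYPE_TRUTH_LABELS[subtype],
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["subject_id", "subtype", "truth_label"]
    )
    return records, truth


def _corrupt_flags(
    rec: IndividualRecord, rate: float, rng: np.random.Generator
) -> IndividualRecord:
    from nmascope.cohort_classifier import PHENOTYPE_FLAGS

    flip = {"present": "absent", "absent": "present"}
    changes = {}
    for name in PHENOTYPE_FLAGS:
        val = getattr(rec, name)
        if val in flip and rng.random() < rate:
            changes[name] = flip[val]
    if not changes:
        return rec
    from dataclasses import replace

    return replace(rec, **changes)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

#: image-analysis fixture group sizes (75 images across four groups)
DEFAULT_GESTALT_GROUPS: Dict[str, int] = {
    "BWCFF": 38,
    "ACTB_LoF": 19,
    "unNMA": 15,
    "BWCFF_unNMA": 3,
}


def make_embeddings(
    spec: EmbeddingSpec = None, seed: int = 0
) -> Tuple[EmbeddingSet, Dict]:
    """Unit-normalized vectors from spherical clusters.

    Each cluster has a unit direction; samples are
    ``normalize(direction + noise)`` with isotropic Gaussian noise of
    standard deviation ``1/concentration`` (a von Mises-Fisher-like
    construction: cosine distance only sees directions).
    """
    spec = spec or EmbeddingSpec()
    rng = np.random.default_rng(seed)
    noise_sd = 1.0 / spec.concentration

    directions = {}
    for label in spec.cluster_sizes:
        if spec.directions and label in spec.directions:
            d = np.asarray(spec.directions[label], dtype=float)
        else:
            d = rng.standard_normal(spec.n_dims)
        directions[label] = d / np.linalg.norm(d)

    vecs, ids, cohorts, syndromes = [], [], [], []
    for label, n in spec.cluster_sizes.items():
        syn = (
            spec.syndrome_of[label]
            if spec.syndrome_of and label in spec.syndrome_of
            else label
        )
        for i in range(n):
            v = directions[label] + noise_sd * rng.standard_normal(spec.n_dims)
            vecs.append(v / np.linalg.norm(v))
            ids.append(f"{label}_{i:04d}")
            cohorts.append(label)
            syndromes.append(syn)
    if not vecs:
        raise ValueError("embedding spec produced zero images")
    es = EmbeddingSet(
        vectors=np.vstack(vecs),
        image_ids=ids,
        cohort=np.array(cohorts, dtype=object),
        syndrome=np.array(syndromes, dtype=object),
    )
    truth = {
        "cluster_sizes": dict(spec.cluster_sizes),
        "noise_sd": noise_sd,
        "n_dims": spec.n_dims,
        "directions": {k: v for k, v in directions.items()},
    }
    return es, truth


def make_gestalt_fixture(
    seed: int = 0, concentration: float = 5.0, n_dims: int = 512
) -> Tuple[EmbeddingSet, Dict]:
    """The four-group image-analysis fixture (75 images total)."""
    spec = EmbeddingSpec(
        cluster_sizes=dict(DEFAULT_GESTALT_GROUPS),
        n_dims=n_dims,
        concentration=concentration,
    )
    return make_embeddings(spec, seed=seed)


# ---------------------------------------------------------------------------
# kinetic traces and melt curves
# ---------------------------------------------------------------------------

def make_traces(
    spec: TraceSpec = None, seed: int = 0
) -> Tuple[List[KineticTrace], Dict]:
    """Single-exponential traces plus Gaussian noise; truth records the
    generating rate and half-time."""
    spec = spec or TraceSpec()
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, spec.duration, spec.n_points)
    traces, truth = [], {"rate": spec.rate, "half_time": np.log(2) / spec.rate,
                         "noise_sd": spec.noise_sd, "per_trace": {}}
    for i in range(spec.n_traces):
        if spec.mode == "polymerization":
            y = spec.offset + spec.amplitude * (1.0 - np.exp(-spec.rate * t))
        else:
            y = spec.offset + spec.amplitude * np.exp(-spec.rate * t)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd * spec.amplitude, size=len(t))
        tid = f"trace_{i:03d}"
        traces.append(
            KineticTrace(t, y, mode=spec.mode, metadata={"trace_id": tid})
        )
        truth["per_trace"][tid] = {"rate": spec.rate}
    return traces, truth


def make_melts(
    spec: MeltSpec = None, seed: int = 0
) -> Tuple[List[MeltCurve], Dict]:
    """Two-state sigmoid melt curves; the generating midpoint is the truth
    Tm (the analytic inflection point of the noiseless curve)."""
    spec = spec or MeltSpec()
    rng = np.random.default_rng(seed)
    temp = np.arange(spec.t_min, spec.t_max + spec.step / 2, spec.step)
    curves, truth = [], {"tm": spec.tm, "noise_sd": spec.noise_sd, "per_curve": {}}
    for i in range(spec.n_curves):
        y = spec.baseline + spec.amplitude / (
            1.0 + np.exp(-(temp - spec.tm) / spec.slope)
        )
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd * spec.amplitude, size=len(temp))
        cid = f"melt_{i:03d}"
        curves.append(MeltCurve(temp, y, metadata={"curve_id": cid}))
        truth["per_curve"][cid] = {"tm": spec.tm}
    return curves, truth
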