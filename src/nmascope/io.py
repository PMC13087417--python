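"""Readers and writers for the plain-text interchange formats.

Transcripts travel as FASTA plus a 1-based inclusive interval table;
population variants as VCF or TSV; cohorts as TSV/JSON; embeddings and
traces as CSV. All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from nmascope.biophys_kinetics import KineticTrace, MeltCurve
from nmascope.cohort_classifier import (
    IndividualRecord,
    records_from_frame,
    records_to_frame,
)
from nmascope.gestalt_stats import EmbeddingSet
from nmascope.transcript_saturation import TranscriptModel

__all__ = [
    "read_transcript",
    "write_transcript",
    "read_population",
    "write_population_tsv",
    "write_population_vcf",
    "read_cohort",
    "write_cohort",
    "read_embeddings_csv",
    "write_embeddings_csv",
    "read_traces_csv",
    "write_traces_csv",
    "read_melts_csv",
    "write_melts_csv",
]


# -- transcripts ------------------------------------------------------------

def write_transcript(model: TranscriptModel, fasta: Path, intervals: Path) -> None:
    records = [
        SeqRecord(
            Seq(model.cds_sequence),
            id=f"{model.gene_symbol}_cds",
            description="coding-strand CDS",
        )
    ]
    if model.genome_sequence is not None:
        records.append(
            SeqRecord(
                Seq(model.genome_sequence),
                id=f"{model.gene_symbol}_window",
                description=(
                    f"forward-strand window {model.chrom}:"
                    f"{model.genome_start}-{model.genome_end}"
                ),
            )
        )
    SeqIO.write(records, str(fasta), "fasta")

    with open(intervals, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("gene\tchrom\tstrand\tfeature\tstart\tend\n")
        base = f"{model.gene_symbol}\t{model.chrom}\t{model.strand}"
        fh.write(
            f"{base}\twindow\t{model.genome_start}\t{model.genome_end}\n"
        )
        for s, e in model.exons:
            fh.write(f"{base}\texon\t{s}\t{e}\n")
        for s, e in model.cds_intervals:
            fh.write(f"{base}\tCDS\t{s}\t{e}\n")


def read_transcript(fasta: Path, intervals: Path) -> TranscriptModel:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    tab = pd.read_csv(intervals, sep="\t", comment="#")
    gene = tab["gene"].iloc[0]
    chrom = tab["chrom"].iloc[0]
    strand = tab["strand"].iloc[0]
    win = tab[tab["feature"] == "window"]
    exons = [
        (int(r["start"]), int(r["end"]))
        for _, r in tab[tab["feature"] == "exon"].iterrows()
    ]
    cds_iv = [
        (int(r["start"]), int(r["end"]))
        for _, r in tab[tab["feature"] == "CDS"].iterrows()
    ]
    if len(win):
        gstart, gend = int(win["start"].iloc[0]), int(win["end"].iloc[0])
    else:
        gstart = min(s for s, _ in exons)
        gend = max(e for _, e in exons)

    cds_seq = seqs.get(f"{gene}_cds")
    if cds_seq is None:
        # fall back to the first record
        cds_seq = next(iter(seqs.values()))
    return TranscriptModel(
        gene_symbol=gene,
        chrom=chrom,
        genome_start=gstart,
        genome_end=gend,
        strand=strand,
        exons=tuple(sorted(exons)),
        cds_intervals=tuple(sorted(cds_iv)),
        cds_sequence=cds_seq,
        genome_sequence=seqs.get(f"{gene}_window"),
    )


# -- population variant tables ----------------------------------------------

def read_population(path: Path) -> pd.DataFrame:
    """Read a population variant table from VCF or TSV into the normalized
    (chrom, pos, ref, alt, ac, an[, af][, tag]) layout. Multi-allelic VCF
    records are split; only the first FILTER-agnostic parse is applied."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    missing = {"pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    return df


def _read_vcf(path: Path) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError:  # plain-text fallback
        return _read_vcf_text(path)
    rows = []
    for var in VCF(str(path)):
        acs = var.INFO.get("AC")
        an = var.INFO.get("AN")
        if acs is None:
            acs = [None] * len(var.ALT)
        elif not isinstance(acs, (tuple, list)):
            acs = [acs]
        for alt, ac in zip(var.ALT, acs):
            rows.append(
                {
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": alt,
                    "ac": ac,
                    "an": an,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "an"])


def _read_vcf_text(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
            )
            an = int(info["AN"]) if "AN" in info else None
            acs = info.get("AC", "").split(",") if "AC" in info else []
            alts = f[4].split(",")
            for i, alt in enumerate(alts):
                ac = int(acs[i]) if i < len(acs) and acs[i] else None
                rows.append(
                    {
                        "chrom": f[0],
                        "pos": int(f[1]),
                        "ref": f[3],
                        "alt": alt,
                        "ac": ac,
                        "an": an,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "an"])


def write_population_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_population_vcf(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in df.sort_values(["chrom", "pos"]).iterrows():
            info = []
            if pd.notna(r.get("ac")):
                info.append(f"AC={int(r['ac'])}")
            if pd.notna(r.get("an")):
                info.append(f"AN={int(r['an'])}")
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t"
                f"PASS\t{';'.join(info) or '.'}\n"
            )


# -- cohorts ----------------------------------------------------------------

def write_cohort(records: List[IndividualRecord], path: Path) -> None:
    path = Path(path)
    df = records_to_frame(records)
    if path.suffix.lower() == ".json":
        df.to_json(path, orient="records", indent=2)
    else:
        df.to_csv(path, sep="\t", index=False)


def read_cohort(path: Path) -> List[IndividualRecord]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path, orient="records")
    else:
        df = pd.read_csv(path, sep="\t")
    return records_from_frame(df)


# -- embeddings -------------------------------------------------------------

def write_embeddings_csv(es: EmbeddingSet, path: Path) -> None:
    cols = {"image_id": list(es.image_ids), "cohort": es.cohort, "syndrome": es.syndrome}
    for j in range(es.n_dims):
        cols[f"e{j + 1}"] = es.vectors[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_embeddings_csv(path: Path) -> EmbeddingSet:
    df = pd.read_csv(path)
    dim_cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    dim_cols.sort(key=lambda c: int(c[1:]))
    if not dim_cols:
        raise ValueError("no embedding dimension columns (e1..ek) found")
    return EmbeddingSet(
        vectors=df[dim_cols].to_numpy(dtype=float),
        image_ids=df["image_id"].astype(str).tolist(),
        cohort=df["cohort"].astype(str).to_numpy(dtype=object),
        syndrome=(
            df["syndrome"].astype(str).to_numpy(dtype=object)
            if "syndrome" in df.columns
            else df["cohort"].astype(str).to_numpy(dtype=object)
        ),
    )


# -- kinetic traces and melt curves -----------------------------------------

def write_traces_csv(traces: List[KineticTrace], path: Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.metadata.get("trace_id", "trace"),
                    "time_s": tr.time,
                    "signal": tr.signal,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: Path, mode: str = "polymerization") -> List[KineticTrace]:
    df = pd.read_csv(path)
    out = []
    for tid, sub in df.groupby("trace_id", sort=False):
        out.append(
            KineticTrace(
                sub["time_s"].to_numpy(float),
                sub["signal"].to_numpy(float),
                mode=mode,
                metadata={"trace_id": str(tid)},
            )
        )
    return out


def write_melts_csv(curves: List[MeltCurve], path: Path) -> None:
    frames = []
    for cv in curves:
        frames.append(
            pd.DataFrame(
                {
                    "curve_id": cv.metadata.get("curve_id", "curve"),
                    "temp_C": cv.temperature,
                    "signal": cv.signal,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_melts_csv(path: Path) -> List[MeltCurve]:
    df = pd.read_csv(path)
    out = []
    for cid, sub in df.groupby("curve_id", sort=False):
        out.append(
            MeltCurve(
                sub["temp_C"].to_numpy(float),
                sub["signal"].to_numpy(float),
                metadata={"curve_id": str(cid)},
            )
        )
    return out


def dump_json(obj, path: Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
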