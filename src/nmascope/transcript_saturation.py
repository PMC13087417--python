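"""Exhaustive single-nucleotide saturation of a coding transcript.

Enumerates all three alternate alleles at every reference position of a
transcript model, annotates each with a functional consequence class (with
an NMD-escape call for premature stops), and joins the enumeration against
observed population variant tables.

Coordinates are 1-based inclusive throughout, matching VCF/gnomAD
convention. Alleles in :class:`SimulatedVariant` are reported on the genome
forward strand; minus-strand models are handled by complementing onto the
coding strand before codon lookup.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "Consequence",
    "TranscriptModel",
    "SimulatedVariant",
    "ConsequenceSummary",
    "TranscriptValidationError",
    "annotate_consequence",
    "enumerate_snvs",
    "summarize",
]

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
NUCLEOTIDES = ("A", "C", "G", "T")

#: premature stops at most this many nt upstream of the last exon-exon
#: junction (in CDS coordinates) are predicted to escape NMD
NMD_ESCAPE_WINDOW_NT = 50


def translate_codon(codon: str) -> str:
    return _CODON_TO_AA[codon.upper()]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TranscriptValidationError(ValueError):
    """A transcript model violates a structural invariant."""


class Consequence(str, enum.Enum):
    START_LOSS = "start_loss"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_CANONICAL = "splice_canonical"
    INTRONIC = "intronic"
    UTR = "utr"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: classes for which amino-acid fields must be populated
CODING_CLASSES = frozenset(
    {
        Consequence.START_LOSS,
        Consequence.STOP_GAIN,
        Consequence.STOP_LOSS,
        Consequence.MISSENSE,
        Consequence.SYNONYMOUS,
    }
)


@dataclass(frozen=True)
class TranscriptModel:
    """A coding transcript anchored to a genomic window.

    Parameters
    ----------
    gene_symbol : str
    chrom : str
    genome_start, genome_end : int
        1-based inclusive bounds of the genomic window.
    strand : str
        ``"+"`` or ``"-"``.
    exons : sequence of (start, end)
        Non-overlapping 1-based inclusive genomic intervals, ascending.
    cds_intervals : sequence of (start, end)
        Subset of the exon space covering the ORF including the stop codon.
    cds_sequence : str
        Coding-strand nucleotide sequence of the CDS; must start with ATG,
        end with a stop codon, and contain no internal stop.
    genome_sequence : str, optional
        Forward-strand sequence of the whole window; required for
        ``full_window`` enumeration.
    """

    gene_symbol: str
    chrom: str
    genome_start: int
    genome_end: int
    strand: str
    exons: tuple
    cds_intervals: tuple
    cds_sequence: str
    genome_sequence: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        object.__setattr__(
            self, "cds_intervals", tuple(tuple(e) for e in self.cds_intervals)
        )
        object.__setattr__(self, "cds_sequence", self.cds_sequence.upper())
        if self.genome_sequence is not None:
            object.__setattr__(
                self, "genome_sequence", self.genome_sequence.upper()
            )
        self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptValidationError(
                f"strand must be '+' or '-', got {self.strand!r}"
            )
        if self.genome_start > self.genome_end:
            raise TranscriptValidationError("genome_start > genome_end")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise TranscriptValidationError(f"exon interval ({s},{e}) inverted")
            if s < self.genome_start or e > self.genome_end:
                raise TranscriptValidationError(
                    f"exon ({s},{e}) outside genomic window"
                )
            if prev_end is not None and s <= prev_end:
                raise TranscriptValidationError(
                    "exons overlap or are not sorted ascending"
                )
            prev_end = e
        for s, e in self.cds_intervals:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise TranscriptValidationError(
                    f"CDS interval ({s},{e}) not contained in any exon"
                )
        cds_len = sum(e - s + 1 for s, e in self.cds_intervals)
        if len(self.cds_sequence) != cds_len:
            raise TranscriptValidationError(
                f"cds_sequence length {len(self.cds_sequence)} != "
                f"sum of cds_interval lengths {cds_len}"
            )
        if cds_len % 3 != 0:
            raise TranscriptValidationError(
                f"CDS length {cds_len} not divisible by 3"
            )
        if not self.cds_sequence.startswith("ATG"):
            raise TranscriptValidationError("CDS does not start with ATG")
        codons = [
            self.cds_sequence[i : i + 3] for i in range(0, cds_len, 3)
        ]
        if codons[-1] not in STOP_CODONS:
            raise TranscriptValidationError("CDS does not end with a stop codon")
        for i, codon in enumerate(codons[:-1]):
            if codon in STOP_CODONS:
                raise TranscriptValidationError(
                    f"internal stop codon at codon {i + 1}"
                )
        if self.genome_sequence is not None:
            if len(self.genome_sequence) != self.genome_end - self.genome_start + 1:
                raise TranscriptValidationError(
                    "genome_sequence length does not match window"
                )
            for gpos, cpos in zip(self.cds_genomic_positions, range(1, cds_len + 1)):
                base = self.genome_sequence[gpos - self.genome_start]
                if self.strand == "-":
                    base = base.translate(_COMPLEMENT)
                if base != self.cds_sequence[cpos - 1]:
                    raise TranscriptValidationError(
                        f"genome_sequence disagrees with cds_sequence at "
                        f"genomic position {gpos}"
                    )

    # -- derived coordinate maps (computed lazily, cached on instance) --
    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases ordered 5'->3' on the coding strand."""
        cached = self.__dict__.get("_cds_gpos")
        if cached is None:
            parts = [np.arange(s, e + 1) for s, e in self.cds_intervals]
            arr = np.concatenate(parts) if parts else np.array([], dtype=int)
            if self.strand == "-":
                arr = arr[::-1]
            cached = arr
            object.__setattr__(self, "_cds_gpos", cached)
        return cached

    @property
    def cds_position_map(self) -> Mapping[int, int]:
        """genomic position -> 1-based CDS position."""
        cached = self.__dict__.get("_cds_map")
        if cached is None:
            cached = {
                int(g): i + 1 for i, g in enumerate(self.cds_genomic_positions)
            }
            object.__setattr__(self, "_cds_map", cached)
        return cached

    @property
    def splice_canonical_positions(self) -> frozenset:
        """The two intronic bases flanking each exon-exon junction."""
        cached = self.__dict__.get("_splice_pos")
        if cached is None:
            pos = set()
            for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
                pos.update({e1 + 1, e1 + 2, s2 - 2, s2 - 1})
            cached = frozenset(pos)
            object.__setattr__(self, "_splice_pos", cached)
        return cached

    @property
    def exonic_positions(self) -> frozenset:
        cached = self.__dict__.get("_exon_pos")
        if cached is None:
            pos = set()
            for s, e in self.exons:
                pos.update(range(s, e + 1))
            cached = frozenset(pos)
            object.__setattr__(self, "_exon_pos", cached)
        return cached

    @property
    def last_junction_cds_coord(self) -> Optional[int]:
        """CDS coordinate of the last coding base 5' of the final exon-exon
        junction, or None for intronless CDS."""
        n_segments = len(self.cds_intervals)
        if n_segments < 2:
            return None
        lengths = [e - s + 1 for s, e in self.cds_intervals]
        if self.strand == "-":
            lengths = lengths[::-1]
        return sum(lengths[:-1])

    def forward_ref_base(self, genomic_pos: int) -> str:
        """Forward-strand reference base at a genomic position."""
        if not (self.genome_start <= genomic_pos <= self.genome_end):
            raise ValueError(
                f"position {genomic_pos} outside window "
                f"[{self.genome_start}, {self.genome_end}]"
            )
        if self.genome_sequence is not None:
            return self.genome_sequence[genomic_pos - self.genome_start]
        cds_pos = self.cds_position_map.get(genomic_pos)
        if cds_pos is None:
            raise ValueError(
                f"position {genomic_pos} is non-coding and the model carries "
                "no genome_sequence"
            )
        base = self.cds_sequence[cds_pos - 1]
        if self.strand == "-":
            base = base.translate(_COMPLEMENT)
        return base


@dataclass(frozen=True)
class SimulatedVariant:
    """One enumerated single-nucleotide alternate allele."""

    genomic_pos: int
    ref: str
    alt: str
    cds_pos: Optional[int]
    consequence: Consequence
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    aa_pos: Optional[int] = None
    nmd_call: str = "not_applicable"

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        coding = self.consequence in CODING_CLASSES
        has_aa = self.aa_ref is not None and self.aa_alt is not None
        if coding != has_aa:
            raise ValueError(
                "amino-acid fields must be populated exactly for coding classes"
            )

    @property
    def key(self) -> tuple:
        return (self.genomic_pos, self.ref, self.alt)


def annotate_consequence(
    model: TranscriptModel, genomic_pos: int, ref: str, alt: str
) -> SimulatedVariant:
    """Annotate one substitution with its consequence class.

    ``ref``/``alt`` are forward-strand alleles. Severity precedence when a
    position admits several readings: splice_canonical > start_loss >
    stop_gain > stop_loss > missense > synonymous. A stop_gain additionally
    receives an NMD call via the 50-nt rule applied to the first base of the
    gained stop codon.
    """
    ref, alt = ref.upper(), alt.upper()
    if not (model.genome_start <= genomic_pos <= model.genome_end):
        raise ValueError(
            f"position {genomic_pos} outside window "
            f"[{model.genome_start}, {model.genome_end}]"
        )
    if ref == alt:
        raise ValueError("ref == alt")

    expected = model.forward_ref_base(genomic_pos)
    if ref != expected:
        raise ValueError(
            f"reference mismatch at {genomic_pos}: expected {expected}, got {ref}"
        )

    if genomic_pos in model.splice_canonical_positions:
        return SimulatedVariant(
            genomic_pos, ref, alt, None, Consequence.SPLICE_CANONICAL
        )

    cds_pos = model.cds_position_map.get(genomic_pos)
    if cds_pos is None:
        cls = (
            Consequence.UTR
            if genomic_pos in model.exonic_positions
            else Consequence.INTRONIC
        )
        return SimulatedVariant(genomic_pos, ref, alt, None, cls)

    alt_c = alt.translate(_COMPLEMENT) if model.strand == "-" else alt

    codon_idx = (cds_pos - 1) // 3
    offset = (cds_pos - 1) % 3
    ref_codon = model.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:offset] + alt_c + ref_codon[offset + 1 :]
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    aa_pos = codon_idx + 1

    nmd = "not_applicable"
    if codon_idx == 0:
        cls = Consequence.START_LOSS
    elif aa_ref == "*":
        cls = Consequence.SYNONYMOUS if aa_alt == "*" else Consequence.STOP_LOSS
    elif aa_alt == "*":
        cls = Consequence.STOP_GAIN
        nmd = _nmd_call(model, codon_idx * 3 + 1)
    elif aa_alt == aa_ref:
        cls = Consequence.SYNONYMOUS
    else:
        cls = Consequence.MISSENSE

    return SimulatedVariant(
        genomic_pos, ref, alt, cds_pos, cls, aa_ref, aa_alt, aa_pos, nmd
    )


def _nmd_call(model: TranscriptModel, ptc_cds_pos: int) -> str:
    """50-nt rule: a premature stop escapes NMD if it lies in the last exon
    or within NMD_ESCAPE_WINDOW_NT nt upstream of the last exon-exon
    junction (junction coordinate measured in CDS space)."""
    junction = model.last_junction_cds_coord
    if junction is None:
        return "escapes_NMD"
    if ptc_cds_pos > junction - NMD_ESCAPE_WINDOW_NT:
        return "escapes_NMD"
    return "subject_to_NMD"


def enumerate_snvs(
    model: TranscriptModel, region: str = "coding_only"
) -> list:
    """Enumerate all three alternate alleles at every reference position.

    ``region="coding_only"`` visits CDS positions only (the counting basis
    for the saturation tallies); ``region="full_window"`` visits every
    position of the genomic window and requires ``genome_sequence``.
    Output is deterministically ordered by (genomic_pos, alt).
    """
    if region == "coding_only":
        positions = sorted(int(p) for p in model.cds_genomic_positions)
    elif region == "full_window":
        if model.genome_sequence is None:
            raise ValueError(
                "full_window enumeration requires a genome_sequence"
            )
        positions = list(range(model.genome_start, model.genome_end + 1))
    else:
        raise ValueError(f"unknown region {region!r}")

    out = []
    for pos in positions:
        ref = model.forward_ref_base(pos)
        for alt in NUCLEOTIDES:
            if alt != ref:
                out.append(annotate_consequence(model, pos, ref, alt))
    return out


@dataclass
class ConsequenceSummary:
    """Per-class tallies of an enumeration joined against a population table."""

    total_enumerated: int
    n_reference_positions: int
    class_counts: dict
    observed_counts: dict
    cumulative_af: dict
    per_tag_observed: dict = field(default_factory=dict)
    n_population_rows: int = 0
    n_not_in_enumeration: int = 0
    n_skipped_ref_mismatch: int = 0

    def __post_init__(self):
        if sum(self.class_counts.values()) != self.total_enumerated:
            raise ValueError("class counts do not partition the total")

    def to_dict(self) -> dict:
        return {
            "total_enumerated": self.total_enumerated,
            "n_reference_positions": self.n_reference_positions,
            "class_counts": dict(self.class_counts),
            "observed_counts": dict(self.observed_counts),
            "cumulative_af": dict(self.cumulative_af),
            "per_tag_observed": {k: dict(v) for k, v in self.per_tag_observed.items()},
            "n_population_rows": self.n_population_rows,
            "n_not_in_enumeration": self.n_not_in_enumeration,
            "n_skipped_ref_mismatch": self.n_skipped_ref_mismatch,
        }


def _population_af(row: pd.Series) -> float:
    if "af" in row.index and pd.notna(row.get("af")):
        return float(row["af"])
    ac, an = row.get("ac"), row.get("an")
    if pd.notna(ac) and pd.notna(an) and an:
        return float(ac) / float(an)
    return 0.0


def summarize(
    variants: Sequence[SimulatedVariant],
    population: Optional[pd.DataFrame] = None,
    window_pad: int = 0,
) -> ConsequenceSummary:
    """Tally an enumeration and join it against a population variant table.

    ``population`` needs columns ``pos, ref, alt`` plus ``af`` or
    ``ac``/``an``; an optional ``tag`` column carries sub-table provenance.
    Duplicate rows across sub-tables are deduplicated by (pos, ref, alt)
    for the union tallies but counted per tag. Rows whose ref disagrees
    with the enumerated reference at that position are warned about,
    skipped, and counted. ``window_pad`` widens the position filter applied
    to population rows around the enumerated span.
    """
    class_counts = {c: 0 for c in Consequence}
    for v in variants:
        class_counts[v.consequence] += 1
    positions = {v.genomic_pos for v in variants}
    by_key = {v.key: v for v in variants}
    ref_at = {v.genomic_pos: v.ref for v in variants}

    observed = {c: 0 for c in Consequence}
    cum_af = {c: 0.0 for c in Consequence}
    per_tag: dict = {}
    n_rows = 0
    n_off = 0
    n_skipped = 0

    if population is not None and len(population):
        pop = population.copy()
        pop.columns = [c.lower() for c in pop.columns]
        if positions:
            lo, hi = min(positions) - window_pad, max(positions) + window_pad
            pop = pop[(pop["pos"] >= lo) & (pop["pos"] <= hi)]
        n_rows = len(pop)

        has_tag = "tag" in pop.columns
        if has_tag:
            for tag, sub in pop.groupby("tag"):
                tally = {c: 0 for c in Consequence}
                for _, row in sub.iterrows():
                    v = by_key.get((int(row["pos"]), str(row["ref"]), str(row["alt"])))
                    if v is not None:
                        tally[v.consequence] += 1
                per_tag[str(tag)] = {c.value: n for c, n in tally.items()}

        dedup = pop.drop_duplicates(subset=["pos", "ref", "alt"])
        for _, row in dedup.iterrows():
            pos, ref, alt = int(row["pos"]), str(row["ref"]), str(row["alt"])
            exp = ref_at.get(pos)
            if (
                exp is not None
                and len(ref) == 1
                and len(alt) == 1
                and ref != exp
            ):
                warnings.warn(
                    f"population row at {pos} has ref {ref}, enumeration has "
                    f"{exp}; row skipped",
                    stacklevel=2,
                )
                n_skipped += 1
                continue
            v = by_key.get((pos, ref, alt))
            if v is None:
                n_off += 1
                continue
            observed[v.consequence] += 1
            cum_af[v.consequence] += _population_af(row)

    return ConsequenceSummary(
        total_enumerated=len(variants),
        n_reference_positions=len(positions),
        class_counts={c.value: n for c, n in class_counts.items()},
        observed_counts={c.value: n for c, n in observed.items()},
        cumulative_af={c.value: f for c, f in cum_af.items()},
        per_tag_observed=per_tag,
        n_population_rows=n_rows,
        n_not_in_enumeration=n_off,
        n_skipped_ref_mismatch=n_skipped,
    )


def variants_to_frame(variants: Iterable[SimulatedVariant]) -> pd.DataFrame:
    """Flatten enumerated variants into a tidy table."""
    rows = [
        {
            "genomic_pos": v.genomic_pos,
            "ref": v.ref,
            "alt": v.alt,
            "cds_pos": v.cds_pos,
            "consequence": v.consequence.value,
            "aa_ref": v.aa_ref,
            "aa_alt": v.aa_alt,
            "aa_pos": v.aa_pos,
            "nmd_call": v.nmd_call,
        }
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genomic_pos",
            "ref",
            "alt",
            "cds_pos",
            "consequence",
            "aa_ref",
            "aa_alt",
            "aa_pos",
            "nmd_call",
        ],
    )
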