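"""Unit and property tests for SNV saturation and consequence annotation."""

import collections

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from nmascope.synthetic_data import TranscriptSpec, make_transcript
from nmascope.transcript_saturation import (
    Consequence,
    SimulatedVariant,
    TranscriptModel,
    TranscriptValidationError,
    annotate_consequence,
    enumerate_snvs,
    summarize,
    variants_to_frame,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# independent oracle: rebuild and translate the full mutant ORF
# ---------------------------------------------------------------------------

def oracle_consequence(model: TranscriptModel, pos: int, alt: str) -> str:
    """Classify a substitution by re-translating the whole mutant CDS.

    Written against the raw interval tables only; shares no code with the
    annotator."""
    splice = set()
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        splice |= {e1 + 1, e1 + 2, s2 - 2, s2 - 1}
    if pos in splice:
        return "splice_canonical"

    cds_positions = []
    for s, e in model.cds_intervals:
        cds_positions.extend(range(s, e + 1))
    if model.strand == "-":
        cds_positions = cds_positions[::-1]
    if pos not in cds_positions:
        in_exon = any(s <= pos <= e for s, e in model.exons)
        return "utr" if in_exon else "intronic"

    i = cds_positions.index(pos)  # 0-based CDS index
    alt_c = _COMP[alt] if model.strand == "-" else alt
    cds = model.cds_sequence
    mutant = cds[:i] + alt_c + cds[i + 1 :]
    ref_prot = str(Seq(cds).translate())
    mut_prot = str(Seq(mutant).translate())
    codon = i // 3
    if codon == 0:
        return "start_loss"
    r, m = ref_prot[codon], mut_prot[codon]
    if r == "*":
        return "synonymous" if m == "*" else "stop_loss"
    if m == "*":
        return "stop_gain"
    return "synonymous" if r == m else "missense"


# ---------------------------------------------------------------------------
# enumeration counting
# ---------------------------------------------------------------------------

class TestEnumerationCounts:
    def test_tiny_cds_18_variants(self, tiny_model):
        variants = enumerate_snvs(tiny_model, "coding_only")
        assert len(variants) == 18  # 3 alternates x 6 coding positions

    def test_three_alternates_per_position(self, tiny_model):
        variants = enumerate_snvs(tiny_model, "coding_only")
        per_pos = collections.Counter(v.genomic_pos for v in variants)
        assert set(per_pos.values()) == {3}

    def test_actin_like_positions_and_total(self, actin_like_model):
        variants = enumerate_snvs(actin_like_model, "coding_only")
        assert len({v.genomic_pos for v in variants}) == 1128
        assert len(variants) == 3384

    def test_total_is_three_times_cds_length(self, three_exon_model):
        variants = enumerate_snvs(three_exon_model, "coding_only")
        assert len(variants) == 3 * three_exon_model.cds_length

    def test_class_counts_partition_total(self, three_exon_model):
        variants = enumerate_snvs(three_exon_model, "full_window")
        counts = collections.Counter(v.consequence for v in variants)
        assert sum(counts.values()) == len(variants)

    def test_deterministic_ordering(self, tiny_model):
        variants = enumerate_snvs(tiny_model, "coding_only")
        keys = [(v.genomic_pos, v.alt) for v in variants]
        assert keys == sorted(keys)
        again = enumerate_snvs(tiny_model, "coding_only")
        assert [v.key for v in again] == [v.key for v in variants]

    def test_unknown_region_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="region"):
            enumerate_snvs(tiny_model, "exome")

    def test_full_window_needs_genome_sequence(self, tiny_model):
        bare = TranscriptModel(
            gene_symbol=tiny_model.gene_symbol,
            chrom=tiny_model.chrom,
            genome_start=tiny_model.genome_start,
            genome_end=tiny_model.genome_end,
            strand=tiny_model.strand,
            exons=tiny_model.exons,
            cds_intervals=tiny_model.cds_intervals,
            cds_sequence=tiny_model.cds_sequence,
        )
        with pytest.raises(ValueError, match="genome_sequence"):
            enumerate_snvs(bare, "full_window")


# ---------------------------------------------------------------------------
# model validation
# ---------------------------------------------------------------------------

class TestModelValidation:
    def _kwargs(self, **over):
        kw = dict(
            gene_symbol="G",
            chrom="chr1",
            genome_start=1,
            genome_end=9,
            strand="+",
            exons=((1, 9),),
            cds_intervals=((1, 9),),
            cds_sequence="ATGAAATAA",
        )
        kw.update(over)
        return kw

    def test_valid_minimal(self):
        TranscriptModel(**self._kwargs())

    def test_length_not_divisible_by_three(self):
        with pytest.raises(TranscriptValidationError, match="divisible by 3"):
            TranscriptModel(
                **self._kwargs(
                    genome_end=8, exons=((1, 8),), cds_intervals=((1, 8),),
                    cds_sequence="ATGAAATA",
                )
            )

    def test_missing_start(self):
        with pytest.raises(TranscriptValidationError, match="ATG"):
            TranscriptModel(**self._kwargs(cds_sequence="TTGAAATAA"))

    def test_missing_stop(self):
        with pytest.raises(TranscriptValidationError, match="stop"):
            TranscriptModel(**self._kwargs(cds_sequence="ATGAAAAAA"))

    def test_internal_stop(self):
        with pytest.raises(TranscriptValidationError, match="internal stop"):
            TranscriptModel(**self._kwargs(cds_sequence="ATGTAATAA"))

    def test_length_mismatch_with_intervals(self):
        with pytest.raises(TranscriptValidationError, match="length"):
            TranscriptModel(**self._kwargs(cds_intervals=((1, 6),)))

    def test_overlapping_exons(self):
        with pytest.raises(TranscriptValidationError, match="overlap"):
            TranscriptModel(
                **self._kwargs(exons=((1, 5), (4, 9)), cds_intervals=((1, 9),))
            )


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------

class TestAnnotation:
    def test_start_codon_disruption(self, tiny_model):
        # first CDS base on the coding strand
        pos = int(tiny_model.cds_genomic_positions[0])
        ref = tiny_model.forward_ref_base(pos)
        alt = next(b for b in "ACGT" if b != ref)
        v = annotate_consequence(tiny_model, pos, ref, alt)
        assert v.consequence is Consequence.START_LOSS
        assert v.aa_pos == 1

    def test_synonymous_third_position(self):
        # ATG CTT TAA: Leu codon CTT -> CTG is synonymous (both Leu)
        model = TranscriptModel(
            gene_symbol="G", chrom="c", genome_start=1, genome_end=9,
            strand="+", exons=((1, 9),), cds_intervals=((1, 9),),
            cds_sequence="ATGCTTTAA",
        )
        v = annotate_consequence(model, 6, "T", "G")
        assert v.consequence is Consequence.SYNONYMOUS
        assert (v.aa_ref, v.aa_alt, v.aa_pos) == ("L", "L", 2)

    def test_missense(self):
        model = TranscriptModel(
            gene_symbol="G", chrom="c", genome_start=1, genome_end=9,
            strand="+", exons=((1, 9),), cds_intervals=((1, 9),),
            cds_sequence="ATGCTTTAA",
        )
        v = annotate_consequence(model, 4, "C", "G")  # CTT -> GTT, Leu -> Val
        assert v.consequence is Consequence.MISSENSE
        assert (v.aa_ref, v.aa_alt) == ("L", "V")

    def test_stop_loss_and_stop_retained(self):
        model = TranscriptModel(
            gene_symbol="G", chrom="c", genome_start=1, genome_end=9,
            strand="+", exons=((1, 9),), cds_intervals=((1, 9),),
            cds_sequence="ATGCTTTAA",
        )
        lost = annotate_consequence(model, 8, "A", "C")  # TAA -> TCA
        assert lost.consequence is Consequence.STOP_LOSS
        retained = annotate_consequence(model, 9, "A", "G")  # TAA -> TAG
        assert retained.consequence is Consequence.SYNONYMOUS

    def test_position_outside_window(self, tiny_model):
        with pytest.raises(ValueError, match="outside window"):
            annotate_consequence(
                tiny_model, tiny_model.genome_end + 1, "A", "C"
            )

    def test_reference_mismatch_rejected(self, tiny_model):
        pos = int(tiny_model.cds_genomic_positions[0])
        ref = tiny_model.forward_ref_base(pos)
        wrong = next(b for b in "ACGT" if b != ref)
        ok = next(b for b in "ACGT" if b not in (ref, wrong))
        with pytest.raises(ValueError, match="mismatch"):
            annotate_consequence(tiny_model, pos, wrong, ok)

    def test_splice_canonical_sites(self, three_exon_model):
        m = three_exon_model
        (s1, e1), (s2, e2), _ = m.exons
        for pos in (e1 + 1, e1 + 2, s2 - 2, s2 - 1):
            ref = m.forward_ref_base(pos)
            alt = next(b for b in "ACGT" if b != ref)
            v = annotate_consequence(m, pos, ref, alt)
            assert v.consequence is Consequence.SPLICE_CANONICAL

    def test_utr_and_intronic(self, three_exon_model):
        m = three_exon_model
        # first window base sits in the 5' UTR end of the terminal exon
        # depending on strand; use explicit coordinates instead
        utr_pos = None
        intron_pos = None
        cds = set(int(p) for p in m.cds_genomic_positions)
        exonic = m.exonic_positions
        for pos in range(m.genome_start, m.genome_end + 1):
            if pos in m.splice_canonical_positions:
                continue
            if pos in exonic and pos not in cds and utr_pos is None:
                utr_pos = pos
            if pos not in exonic and intron_pos is None:
                intron_pos = pos
        for pos, expect in ((utr_pos, Consequence.UTR), (intron_pos, Consequence.INTRONIC)):
            ref = m.forward_ref_base(pos)
            alt = next(b for b in "ACGT" if b != ref)
            assert annotate_consequence(m, pos, ref, alt).consequence is expect


class TestNMDRule:
    """Hand application of the 50-nt rule to the fixture's junctions."""

    @staticmethod
    def _junction_cds_coord(model):
        # coding nt upstream of the last exon-exon junction, from the raw tables
        lengths = [e - s + 1 for s, e in model.cds_intervals]
        if model.strand == "-":
            lengths = lengths[::-1]
        return sum(lengths[:-1])

    def _stop_gains(self, model):
        return [
            v
            for v in enumerate_snvs(model, "coding_only")
            if v.consequence is Consequence.STOP_GAIN
        ]

    def test_escape_and_subject_split(self, three_exon_model):
        j = self._junction_cds_coord(three_exon_model)
        gains = self._stop_gains(three_exon_model)
        assert gains, "fixture must produce stop gains"
        saw = set()
        for v in gains:
            ptc = (v.aa_pos - 1) * 3 + 1  # CDS coord of the new stop codon
            expected = "escapes_NMD" if ptc > j - 50 else "subject_to_NMD"
            assert v.nmd_call == expected, (v, ptc, j)
            saw.add(expected)
        assert saw == {"escapes_NMD", "subject_to_NMD"}

    def test_last_exon_always_escapes(self, three_exon_model):
        j = self._junction_cds_coord(three_exon_model)
        for v in self._stop_gains(three_exon_model):
            if (v.aa_pos - 1) * 3 + 1 > j:
                assert v.nmd_call == "escapes_NMD"

    def test_intronless_cds_always_escapes(self, tiny_model):
        model = make_transcript(TranscriptSpec(n_codons=50, n_exons=1), seed=5)
        for v in self._stop_gains(model):
            assert v.nmd_call == "escapes_NMD"

    def test_non_stop_gain_not_applicable(self, three_exon_model):
        for v in enumerate_snvs(three_exon_model, "coding_only"):
            if v.consequence is not Consequence.STOP_GAIN:
                assert v.nmd_call == "not_applicable"


# ---------------------------------------------------------------------------
# oracle equivalence and strand properties
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_full_retranslation_oracle_small_cds(self, seed, strand):
        spec = TranscriptSpec(
            n_codons=18, n_exons=2, strand=strand, utr5_length=15,
            utr3_length=15, intron_length=30,
        )  # 57-nt CDS <= 60
        model = make_transcript(spec, seed=seed)
        for v in enumerate_snvs(model, "full_window"):
            assert v.consequence.value == oracle_consequence(
                model, v.genomic_pos, v.alt
            ), v

    def test_strand_roundtrip_class_multisets(self):
        plus = make_transcript(TranscriptSpec(n_codons=40, strand="+"), seed=77)
        minus = make_transcript(TranscriptSpec(n_codons=40, strand="-"), seed=77)
        cp = collections.Counter(
            v.consequence for v in enumerate_snvs(plus, "full_window")
        )
        cm = collections.Counter(
            v.consequence for v in enumerate_snvs(minus, "full_window")
        )
        assert cp == cm

    def test_codon_table_enumeration_counts(self):
        """Synonymous/missense/nonsense tallies equal direct per-codon
        enumeration over the genetic code."""
        model = make_transcript(TranscriptSpec(n_codons=30, n_exons=1), seed=9)
        cds = model.cds_sequence
        expect = collections.Counter()
        for ci in range(1, len(cds) // 3 - 1):  # interior codons only
            codon = cds[ci * 3 : ci * 3 + 3]
            ref_aa = str(Seq(codon).translate())
            for off in range(3):
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    alt_aa = str(
                        Seq(codon[:off] + b + codon[off + 1 :]).translate()
                    )
                    if alt_aa == "*":
                        expect["stop_gain"] += 1
                    elif alt_aa == ref_aa:
                        expect["synonymous"] += 1
                    else:
                        expect["missense"] += 1
        got = collections.Counter(
            v.consequence.value
            for v in enumerate_snvs(model, "coding_only")
            if 1 < v.aa_pos < model.n_codons
        )
        assert got == expect


# ---------------------------------------------------------------------------
# population summary
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_empty_population(self, tiny_model):
        variants = enumerate_snvs(tiny_model, "coding_only")
        s = summarize(variants, pd.DataFrame(columns=["pos", "ref", "alt", "af"]))
        assert all(n == 0 for n in s.observed_counts.values())
        assert all(f == 0 for f in s.cumulative_af.values())

    def test_hand_join_three_of_five_match(self, three_exon_model):
        variants = enumerate_snvs(three_exon_model, "coding_only")
        missense = [
            v for v in variants if v.consequence is Consequence.MISSENSE
        ][:3]
        rows = [
            {"pos": v.genomic_pos, "ref": v.ref, "alt": v.alt, "af": 1e-4}
            for v in missense
        ]
        # two rows that cannot match: an indel-style alt and an off-window pos
        rows.append(
            {
                "pos": missense[0].genomic_pos,
                "ref": missense[0].ref,
                "alt": missense[0].ref + "GG",
                "af": 1e-4,
            }
        )
        rows.append({"pos": 1, "ref": "A", "alt": "C", "af": 1e-4})
        s = summarize(variants, pd.DataFrame(rows), window_pad=10**9)
        assert s.observed_counts["missense"] == 3
        assert s.cumulative_af["missense"] == pytest.approx(3e-4)
        assert s.n_not_in_enumeration == 2

    def test_duplicate_rows_counted_once(self, three_exon_model):
        variants = enumerate_snvs(three_exon_model, "coding_only")
        v = next(
            x for x in variants if x.consequence is Consequence.SYNONYMOUS
        )
        row = {"pos": v.genomic_pos, "ref": v.ref, "alt": v.alt, "af": 2e-5}
        pop = pd.DataFrame(
            [dict(row, tag="controls"), dict(row, tag="non_neuro")]
        )
        s = summarize(variants, pop)
        assert s.observed_counts["synonymous"] == 1
        assert s.cumulative_af["synonymous"] == pytest.approx(2e-5)
        # but provenance tallies keep both sub-tables
        assert s.per_tag_observed["controls"]["synonymous"] == 1
        assert s.per_tag_observed["non_neuro"]["synonymous"] == 1

    def test_ref_mismatch_warned_and_skipped(self, three_exon_model):
        variants = enumerate_snvs(three_exon_model, "coding_only")
        v = variants[0]
        wrong = next(b for b in "ACGT" if b not in (v.ref, v.alt))
        pop = pd.DataFrame(
            [{"pos": v.genomic_pos, "ref": wrong, "alt": v.alt, "af": 1e-5}]
        )
        with pytest.warns(UserWarning, match="skipped"):
            s = summarize(variants, pop)
        assert s.n_skipped_ref_mismatch == 1
        assert sum(s.observed_counts.values()) == 0

    def test_ac_an_frequency(self, tiny_model):
        variants = enumerate_snvs(tiny_model, "coding_only")
        v = variants[0]
        pop = pd.DataFrame(
            [{"pos": v.genomic_pos, "ref": v.ref, "alt": v.alt, "ac": 3, "an": 1000}]
        )
        s = summarize(variants, pop)
        assert s.cumulative_af[v.consequence.value] == pytest.approx(0.003)


def test_variant_invariants():
    with pytest.raises(ValueError, match="ref == alt"):
        SimulatedVariant(1, "A", "A", None, Consequence.INTRONIC)
    with pytest.raises(ValueError, match="amino-acid"):
        SimulatedVariant(1, "A", "C", 1, Consequence.MISSENSE)


def test_variants_to_frame_columns(tiny_model):
    df = variants_to_frame(enumerate_snvs(tiny_model, "coding_only"))
    assert list(df.columns[:5]) == ["genomic_pos", "ref", "alt", "cds_pos", "consequence"]
    assert len(df) == 18
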