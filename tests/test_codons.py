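"""Codon annotation through introns and the aa-choice / codon-bias split."""

import numpy as np
import pytest
from Bio.Seq import Seq

from gcsignal import (
    Cohort,
    GeneratorConfig,
    RegionLabel,
    STANDARD_CODE,
    aa_gradient_config,
    cds_split,
    codon_bias_config,
    generate_cohort,
    signal_size,
)
from gcsignal.codons import (
    AA_CODE,
    CODE_NAME,
    CodonAnnotationError,
    NONCODING,
    STOP,
    UNASSIGNED,
    annotate_codons,
)
from gcsignal.decomposition import decompose
from gcsignal.genome_model import WINDOW_UP

from conftest import make_record


def oracle_labels(record):
    """Brute-force oracle: splice the CDS, translate with Bio.Seq, map back.

    Collects CDS positions in window order, translates the spliced string
    downstream of the translation start with Biopython, then writes each
    residue's one-letter code back onto its three source positions.
    """
    cds_pos = [
        i for lab, s, e in record.regions if lab is RegionLabel.CDS for i in range(s, e)
    ]
    expected = {i: "UNASSIGNED" for i in cds_pos}
    start = cds_pos.index(record.translation_start)
    coding = cds_pos[start:]
    spliced = "".join(record.sequence[i] for i in coding)
    protein = str(Seq(spliced[: len(spliced) - len(spliced) % 3]).translate())
    for k, aa in enumerate(protein):
        for i in coding[3 * k : 3 * k + 3]:
            expected[i] = "STOP" if aa == "*" else aa
    return expected


class TestAnnotateCodons:
    def test_simple_cds(self):
        rec = make_record(
            [(RegionLabel.CDS, "ATGGAT")], translation_start=WINDOW_UP
        )
        ann = annotate_codons(rec)
        assert list(ann[WINDOW_UP : WINDOW_UP + 6]) == [AA_CODE["M"]] * 3 + [AA_CODE["D"]] * 3
        assert ann[0] == NONCODING

    def test_codon_split_by_intron(self):
        rec = make_record(
            [
                (RegionLabel.CDS, "AT"),
                (RegionLabel.INTRON, "TTTT"),
                (RegionLabel.CDS, "GGAT"),
            ],
            translation_start=WINDOW_UP,
        )
        ann = annotate_codons(rec)
        # A, T (before intron) and G (after) all labelled Met
        assert ann[WINDOW_UP] == AA_CODE["M"]
        assert ann[WINDOW_UP + 1] == AA_CODE["M"]
        assert all(ann[WINDOW_UP + 2 : WINDOW_UP + 6] == NONCODING)
        assert ann[WINDOW_UP + 6] == AA_CODE["M"]
        expected = oracle_labels(rec)
        for i, name in expected.items():
            assert CODE_NAME[ann[i]] == name

    def test_incomplete_trailing_codon_unassigned(self):
        rec = make_record(
            [(RegionLabel.CDS, "ATGGATC")], translation_start=WINDOW_UP
        )
        ann = annotate_codons(rec)
        assert ann[WINDOW_UP + 6] == UNASSIGNED

    def test_pre_start_cds_unassigned(self):
        rec = make_record(
            [(RegionLabel.CDS, "CCATGTAA")], translation_start=WINDOW_UP + 2
        )
        ann = annotate_codons(rec)
        assert all(ann[WINDOW_UP : WINDOW_UP + 2] == UNASSIGNED)
        assert ann[WINDOW_UP + 2] == AA_CODE["M"]
        assert ann[WINDOW_UP + 5] == STOP

    def test_translation_start_outside_cds_raises(self):
        rec = make_record([(RegionLabel.CDS, "ATGGAT")], translation_start=WINDOW_UP)
        rec.translation_start = 10
        with pytest.raises(CodonAnnotationError):
            annotate_codons(rec)

    def test_matches_oracle_on_generated_records(self):
        cohort = generate_cohort(
            GeneratorConfig(seed=13, n_transcripts=30, intron_within_codons=True)
        )
        for rec in cohort.records:
            if rec.translation_start is None:
                continue
            ann = annotate_codons(rec)
            for i, name in oracle_labels(rec).items():
                assert CODE_NAME[ann[i]] == name, rec.transcript_id


class TestAminoAcidAverages:
    def _single_codon_cohort(self, codon: str, n: int = 12) -> Cohort:
        body = "ATG" + codon * ((n - 3) // 3)
        rec = make_record([(RegionLabel.CDS, body)], translation_start=WINDOW_UP)
        return Cohort([rec])

    def test_poly_atg_met_third_gc(self):
        rec = make_record([(RegionLabel.CDS, "ATG" * 5)], translation_start=WINDOW_UP)
        split = cds_split(Cohort([rec]))
        assert split.aa_avg_gc["M"] == pytest.approx(1 / 3, abs=1e-12)

    def test_poly_ttt_phe_zero(self):
        split = cds_split(self._single_codon_cohort("TTT"))
        assert split.aa_avg_gc["F"] == 0.0

    def test_phe_mixed_codons_one_sixth(self):
        rec = make_record(
            [(RegionLabel.CDS, "ATG" + "TTT" + "TTC")], translation_start=WINDOW_UP
        )
        split = cds_split(Cohort([rec]))
        assert split.aa_avg_gc["F"] == pytest.approx(1 / 6, abs=1e-12)

    def test_single_codon_amino_acids_constant(self, medium_cohort):
        split = cds_split(medium_cohort)
        assert split.aa_avg_gc["M"] == pytest.approx(1 / 3, abs=1e-12)
        assert split.aa_avg_gc["W"] == pytest.approx(2 / 3, abs=1e-12)

    def test_averages_in_unit_interval(self, medium_cohort):
        split = cds_split(medium_cohort)
        assert all(0.0 <= v <= 1.0 for v in split.aa_avg_gc.values())


class TestCdsSplitIdentity:
    @pytest.mark.parametrize("seed,T", [(3, 20), (4, 100)])
    def test_c_plus_s_equals_cds_within(self, seed, T):
        cohort = generate_cohort(GeneratorConfig(seed=seed, n_transcripts=T))
        split = cds_split(cohort)
        d = decompose(cohort)
        resid = np.abs(
            split.aa_choice.values
            + split.syn_codon.values
            - d.within_by_region[RegionLabel.CDS].values
        )
        assert np.nanmax(resid) <= 1e-12

    def test_identity_with_split_codons(self):
        cohort = generate_cohort(
            GeneratorConfig(seed=8, n_transcripts=50, intron_within_codons=True)
        )
        split = cds_split(cohort)
        d = decompose(cohort)
        resid = np.abs(
            split.aa_choice.values
            + split.syn_codon.values
            - d.within_by_region[RegionLabel.CDS].values
        )
        assert np.nanmax(resid) <= 1e-12

    def test_single_amino_acid_gives_zero_choice_signal(self):
        """If every residue is the same amino acid, a'(x) = a-ish and c ~ 0
        wherever the window is fully coding with that residue."""
        body = "ATG" + "CTG" * 300  # Met then poly-Leu
        rec = make_record([(RegionLabel.CDS, body[:1001])], translation_start=WINDOW_UP)
        split = cds_split(Cohort([rec]))
        # away from the Met start and trailing partial codon, c is driven
        # only by the tiny Met/a(CDS) offset, bounded well below the
        # per-base signal scale
        mid = split.aa_choice.values[WINDOW_UP + 100 : WINDOW_UP + 900]
        assert np.nanmax(np.abs(mid)) < 0.01


class TestDisentanglement:
    def test_amino_acid_gradient_drives_choice_signal(self):
        split = cds_split(generate_cohort(aa_gradient_config(seed=11)))
        ratio = signal_size(split.aa_choice).sigma / signal_size(split.syn_codon).sigma
        assert ratio >= 5

    def test_codon_bias_drives_synonymous_signal(self):
        split = cds_split(generate_cohort(codon_bias_config(seed=12)))
        ratio = signal_size(split.syn_codon).sigma / signal_size(split.aa_choice).sigma
        assert ratio >= 5

    def test_syn_signal_pools_to_zero(self, medium_cohort):
        """Coding-density-weighted mean of s over p in [0,1000] vanishes.

        Follows from the pooled a'(x) definition: summing s(p) over the
        pooling window cancels term by term.
        """
        split = cds_split(medium_cohort)
        s = split.syn_codon.values[WINDOW_UP:]
        assert abs(np.nansum(s)) < 1e-9
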