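"""Amino-acid-choice vs synonymous-codon split of the CDS GC signal.

Coding bases carry GC content for two separable reasons: *which* amino
acid occupies a codon slot (different amino acids have codon sets with
different average GC content) and *which* synonymous codon encodes it.
Assigning each coding base the pooled average GC content a'(x) of its
amino acid x yields the amino-acid-choice signal c(p); the residual after
removing that expectation is the synonymous-codon signal s(p).  Their sum
equals the CDS within-region constituent position by position.

Reading frames are reconstructed from the annotated translation start by
concatenating CDS bases in window order (introns may interrupt a codon);
each base inherits its codon's amino acid at its original, unspliced
window position.  Bases before the translation start and trailing
incomplete codons are labelled UNASSIGNED; stop-codon bases are labelled
STOP.  Both auxiliary labels get their own pooled averages so the
c + s identity is exact on every CDS base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .decomposition import SignalProfile, cohort_matrices, _LABEL_INDEX
from .genome_model import Cohort, RegionLabel, TranscriptRecord

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")  # 20 one-letter codes, sorted

# integer codes for the per-position annotation vector
AA_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
STOP = 20
UNASSIGNED = 21
NONCODING = 22
CODE_NAME = {**{v: k for k, v in AA_CODE.items()}, STOP: "STOP",
             UNASSIGNED: "UNASSIGNED", NONCODING: "NONCODING"}


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table; stop codons map to '*'."""

    codon_to_aa: dict

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map all 64 codons")
        aas = set(self.codon_to_aa.values())
        if not aas <= set(AMINO_ACIDS) | {"*"}:
            raise ValueError(f"unexpected translation symbols: {aas - set(AMINO_ACIDS) - {'*'}}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(codon_to_aa=mapping)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper()]

    def synonymous_codons(self) -> dict[str, list[str]]:
        """Amino acid (or '*') -> sorted list of its codons."""
        syn: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_to_aa.items()):
            syn.setdefault(aa, []).append(codon)
        return syn


STANDARD_CODE = GeneticCode.standard()


class CodonAnnotationError(ValueError):
    pass


def annotate_codons(
    record: TranscriptRecord, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Per-position amino-acid annotation for one transcript window.

    Returns an int8 vector over array positions with values in
    ``AA_CODE`` / ``STOP`` / ``UNASSIGNED`` / ``NONCODING``.  Codons are
    read off the spliced CDS starting at ``translation_start``; a codon
    split by an intron labels its bases at their unspliced positions.
    """
    L = len(record.sequence)
    ann = np.full(L, NONCODING, dtype=np.int8)
    cds_idx = [
        i
        for lab, start, end in record.regions
        if lab is RegionLabel.CDS
        for i in range(start, end)
    ]
    if not cds_idx:
        return ann
    ann[cds_idx] = UNASSIGNED
    if record.translation_start is None:
        raise CodonAnnotationError(
            f"{record.transcript_id}: translation_start required for codon annotation"
        )
    try:
        offset = cds_idx.index(record.translation_start)
    except ValueError:
        raise CodonAnnotationError(
            f"{record.transcript_id}: translation_start {record.translation_start} "
            "is not a CDS position"
        ) from None
    coding = cds_idx[offset:]
    for k in range(0, len(coding) - len(coding) % 3, 3):
        triplet_idx = coding[k : k + 3]
        codon = "".join(record.sequence[i] for i in triplet_idx)
        if "N" in codon:
            continue  # stays UNASSIGNED
        aa = code.translate(codon)
        value = STOP if aa == "*" else AA_CODE[aa]
        ann[triplet_idx] = value
    return ann


def cohort_codon_matrix(
    cohort: Cohort, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Stack per-record codon annotations into a (T, L) int8 matrix."""
    L = max(len(r.sequence) for r in cohort.records)
    out = np.full((len(cohort.records), L), NONCODING, dtype=np.int8)
    for t, rec in enumerate(cohort.records):
        ann = annotate_codons(rec, code)
        out[t, : len(ann)] = ann
    return out


def _downstream_slice(start: int, L: int) -> slice:
    """Array slice for window positions p in [0, 1000] (inclusive)."""
    lo = max(0, 0 - start)
    hi = min(L, 1000 - start + 1)
    return slice(lo, hi)


@dataclass
class CdsSplit:
    """Amino-acid-choice and synonymous-codon components of the CDS signal."""

    aa_choice: SignalProfile
    syn_codon: SignalProfile
    aa_avg_gc: dict[str, float]
    aa_density: dict[str, SignalProfile]
    aa_base_counts: dict[str, int]


def amino_acid_average_gc(
    cohort: Cohort,
    code: GeneticCode = STANDARD_CODE,
    n_policy: str = "count-zero",
) -> dict[str, float]:
    """Pooled GC fraction a'(x) per amino-acid label, downstream positions only.

    Pooling runs over window positions p = 0..1000 (the downstream part
    including the TSS base).  Labels absent downstream are omitted.  The
    auxiliary labels STOP and UNASSIGNED appear under those names.
    """
    return cds_split(cohort, code, n_policy).aa_avg_gc


def cds_split(
    cohort: Cohort,
    code: GeneticCode = STANDARD_CODE,
    n_policy: str = "count-zero",
) -> CdsSplit:
    """Compute c(p), s(p) and the per-amino-acid averages for a cohort."""
    gc, covered, labels = cohort_matrices(cohort, n_policy)
    ann = cohort_codon_matrix(cohort, code)
    if n_policy == "exclude":
        ann[~covered] = NONCODING
    T, L = gc.shape
    start = cohort.window_start
    cov = covered.sum(axis=0).astype(float)
    cov[cov == 0] = np.nan

    ds = _downstream_slice(start, L)
    aa_avg: dict[str, float] = {}
    aa_counts: dict[str, int] = {}
    aa_density: dict[str, SignalProfile] = {}
    expected = np.zeros(L)  # sum_x a'(x) * density_x(p)
    for value in range(STOP + 2):  # 20 amino acids + STOP + UNASSIGNED
        name = CODE_NAME[value]
        mask = ann == value
        n_ds = int(mask[:, ds].sum())
        if n_ds == 0:
            if mask.any():
                # occurs in the window but never downstream: no pooled
                # average is defined; its expectation terms are zero.
                aa_counts[name] = 0
            continue
        a_prime = float(gc[:, ds][mask[:, ds]].sum() / n_ds)
        aa_avg[name] = a_prime
        aa_counts[name] = n_ds
        dens = mask.sum(axis=0) / cov
        aa_density[name] = SignalProfile(dens, T, f"density_{name}", start)
        expected = expected + a_prime * dens

    cds_mask = labels == _LABEL_INDEX[RegionLabel.CDS]
    cds_dens = cds_mask.sum(axis=0) / cov
    cds_gc_dens = (gc * cds_mask).sum(axis=0) / cov
    a_cds = (
        float(gc[cds_mask].sum() / cds_mask.sum()) if cds_mask.any() else 0.0
    )
    c = expected - a_cds * cds_dens
    s = cds_gc_dens - expected
    return CdsSplit(
        aa_choice=SignalProfile(c, T, "aa_choice", start),
        syn_codon=SignalProfile(s, T, "syn_codon", start),
        aa_avg_gc=aa_avg,
        aa_density=aa_density,
        aa_base_counts=aa_counts,
    )


def aa_choice_signal(cohort: Cohort, code: GeneticCode = STANDARD_CODE) -> SignalProfile:
    """c(p): GC expected from amino-acid occupancy minus the CDS baseline."""
    return cds_split(cohort, code).aa_choice


def syn_codon_signal(cohort: Cohort, code: GeneticCode = STANDARD_CODE) -> SignalProfile:
    """s(p): residual CDS GC after removing each position's amino-acid expectation."""
    return cds_split(cohort, code).syn_codon


def aa_table(split: CdsSplit) -> pd.DataFrame:
    """Per-amino-acid summary table; STOP/UNASSIGNED rows flagged auxiliary."""
    rows = []
    for name in AMINO_ACIDS + ["STOP", "UNASSIGNED"]:
        if name in split.aa_avg_gc:
            rows.append(
                {
                    "amino_acid": name,
                    "a_prime_gc": split.aa_avg_gc[name],
                    "n_bases": split.aa_base_counts.get(name, 0),
                    "auxiliary": name in ("STOP", "UNASSIGNED"),
                }
            )
    return pd.DataFrame(rows, columns=["amino_acid", "a_prime_gc", "n_bases", "auxiliary"])
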