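"""Domain types and file I/O for TSS-centered transcript cohorts.

A cohort is a set of transcripts from one species, each represented as a
window of sequence centered on the transcription start site (TSS).  The
standard window spans positions -1000..+1000 relative to the TSS (2001
bases, sense strand); every base carries exactly one region label out of
{5'end flank, 5'UTR, CDS, intron, 3'UTR, 3'end flank}.  Spliced (mRNA)
windows produced downstream of the pipeline start at the TSS instead and
may be shorter; :class:`TranscriptRecord` therefore records the window
position of its first base.

On disk a cohort is three plain-text files: a FASTA with one record per
transcript, a region TSV (transcript_id, label, start, end in 0-based
half-open window-array coordinates) and a metadata TSV (species,
taxonomic class, translation start, curation status).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Number of bases upstream / downstream of the TSS in a standard window.
WINDOW_UP = 1000
WINDOW_DOWN = 1000
#: Standard window length: upstream flank + TSS base + downstream.
WINDOW_LEN = WINDOW_UP + WINDOW_DOWN + 1

VALID_BASES = frozenset("ACGTN")


class RegionLabel(enum.Enum):
    """The six transcript-region labels tiling a TSS window."""

    FIVE_END = "5end"
    FIVE_UTR = "5utr"
    CDS = "cds"
    INTRON = "intron"
    THREE_UTR = "3utr"
    THREE_END = "3end"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CurationStatus(enum.Enum):
    """RefSeq-style review level of a transcript annotation."""

    PROVISIONAL = "PROVISIONAL"
    REVIEWED = "REVIEWED"
    VALIDATED = "VALIDATED"
    OTHER = "OTHER"
    UNLABELED = "UNLABELED"

    @classmethod
    def from_string(cls, s: str | None) -> "CurationStatus":
        """Map an arbitrary status string onto the five recognised levels.

        The three named RefSeq levels are kept; anything else collapses to
        OTHER, and a missing/empty label becomes UNLABELED.
        """
        if s is None or str(s).strip() in ("", "NA", "nan"):
            return cls.UNLABELED
        s = str(s).strip().upper()
        try:
            return cls(s)
        except ValueError:
            return cls.OTHER


#: Statuses counted as curated when deciding whether an organism is "selected".
CURATED_STATUSES = frozenset(
    {CurationStatus.PROVISIONAL, CurationStatus.REVIEWED, CurationStatus.VALIDATED}
)

#: Curated-fraction threshold above which an organism is "selected", per kingdom.
SELECTION_THRESHOLDS = {"vertebrate": 0.05, "plant": 0.30, "other": None}


class CohortValidationError(ValueError):
    """A record violates the window/region invariants."""


class CohortConsistencyError(ValueError):
    """Cross-file identifiers do not match up."""


class ConfigurationError(ValueError):
    """An unknown kingdom or invalid configuration value."""


@dataclass
class TranscriptRecord:
    """One TSS-centered transcript window.

    ``sequence[i]`` is the base at window position ``p = i + window_start``;
    for the standard pre-mRNA window ``window_start = -1000`` and the TSS is
    ``sequence[1000]``.  ``regions`` are ``(label, start, end)`` intervals in
    0-based half-open array coordinates that must tile the sequence exactly.
    ``translation_start`` is the array index of the first base of the
    initiator codon, or ``None`` when unknown/non-coding.
    """

    transcript_id: str
    species: str
    taxonomic_class: str
    sequence: str
    regions: list[tuple[RegionLabel, int, int]]
    translation_start: int | None = None
    curation_status: CurationStatus = CurationStatus.UNLABELED
    window_start: int = -WINDOW_UP

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.regions = sorted(self.regions, key=lambda r: r[1])

    def validate(self, expect_length: int | None = WINDOW_LEN) -> None:
        """Raise :class:`CohortValidationError` on any invariant breach."""
        L = len(self.sequence)
        tid = self.transcript_id
        if expect_length is not None and L != expect_length:
            raise CohortValidationError(
                f"{tid}: sequence length {L}, expected {expect_length}"
            )
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise CohortValidationError(f"{tid}: invalid bases {bad}")
        cursor = 0
        for label, start, end in self.regions:
            if start != cursor:
                raise CohortValidationError(
                    f"{tid}: region tiling violation at array position {cursor} "
                    f"(next interval starts at {start})"
                )
            if end <= start:
                raise CohortValidationError(f"{tid}: empty/inverted interval {label}")
            cursor = end
        if cursor != L:
            raise CohortValidationError(
                f"{tid}: regions cover [0,{cursor}) but sequence has length {L}"
            )
        if self.window_start < 0:
            # upstream of the TSS everything is 5'end flank
            for label, start, end in self.regions:
                if start < -self.window_start and label is not RegionLabel.FIVE_END:
                    raise CohortValidationError(
                        f"{tid}: upstream position labeled {label.value}, "
                        "expected 5end"
                    )
        if self.translation_start is not None:
            if not any(
                s <= self.translation_start < e
                for lab, s, e in self.regions
                if lab is RegionLabel.CDS
            ):
                raise CohortValidationError(
                    f"{tid}: translation_start {self.translation_start} "
                    "not inside a CDS interval"
                )

    def label_at(self, index: int) -> RegionLabel:
        for label, start, end in self.regions:
            if start <= index < end:
                return label
        raise IndexError(index)


@dataclass
class Cohort:
    """All transcript windows of one species, plus kingdom metadata."""

    records: list[TranscriptRecord]
    kingdom: str = "other"

    @property
    def species(self) -> str:
        return self.records[0].species if self.records else ""

    @property
    def taxonomic_class(self) -> str:
        return self.records[0].taxonomic_class if self.records else ""

    @property
    def window_start(self) -> int:
        return self.records[0].window_start if self.records else -WINDOW_UP

    @property
    def curated_fraction(self) -> float:
        if not self.records:
            return 0.0
        n = sum(1 for r in self.records if r.curation_status in CURATED_STATUSES)
        return n / len(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# File I/O

FASTA_NAME = "sequences.fasta"
REGIONS_NAME = "regions.tsv"
META_NAME = "metadata.tsv"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as FASTA + region TSV + metadata TSV under *out_dir*.

    Returns the mapping of file kind to path.  The output round-trips
    through :func:`read_cohort`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / FASTA_NAME
    SeqIO.write(
        (
            SeqRecord(Seq(r.sequence), id=r.transcript_id, description="")
            for r in cohort.records
        ),
        str(fasta),
        "fasta",
    )
    region_rows = [
        {
            "transcript_id": r.transcript_id,
            "label": lab.value,
            "start": start,
            "end": end,
        }
        for r in cohort.records
        for lab, start, end in r.regions
    ]
    regions_df = pd.DataFrame(
        region_rows, columns=["transcript_id", "label", "start", "end"]
    )
    regions_df.sort_values(["transcript_id", "start"], kind="stable").to_csv(
        out / REGIONS_NAME, sep="\t", index=False
    )
    meta_rows = [
        {
            "transcript_id": r.transcript_id,
            "species": r.species,
            "taxonomic_class": r.taxonomic_class,
            "translation_start": "NA" if r.translation_start is None else r.translation_start,
            "curation_status": r.curation_status.value,
            "window_start": r.window_start,
            "kingdom": cohort.kingdom,
        }
        for r in cohort.records
    ]
    meta_df = pd.DataFrame(
        meta_rows,
        columns=[
            "transcript_id",
            "species",
            "taxonomic_class",
            "translation_start",
            "curation_status",
            "window_start",
            "kingdom",
        ],
    )
    meta_df.to_csv(out / META_NAME, sep="\t", index=False)
    return {"fasta": fasta, "regions": out / REGIONS_NAME, "metadata": out / META_NAME}


def read_cohort(
    fasta_path: str | Path,
    regions_path: str | Path,
    meta_path: str | Path,
    kingdom: str | None = None,
    expect_length: int | None = None,
) -> Cohort:
    """Read and validate a cohort from its three files.

    Every FASTA id must appear in both TSVs.  Records failing the window
    invariants are rejected with an error naming the transcript.  If
    *kingdom* is None it is taken from the metadata TSV (column optional,
    default "other").  *expect_length* defaults to 2001 for standard
    windows; pass ``None`` to accept variable-length (spliced) windows.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    regions_df = pd.read_csv(regions_path, sep="\t", dtype={"transcript_id": str})
    meta_df = pd.read_csv(
        meta_path, sep="\t", dtype={"transcript_id": str}, keep_default_na=False
    )

    meta_ids = set(meta_df["transcript_id"])
    region_ids = set(regions_df["transcript_id"]) if len(regions_df) else set()
    missing = sorted((set(sequences) - meta_ids) | (set(sequences) - region_ids))
    if missing:
        raise CohortConsistencyError(
            f"transcripts present in FASTA but missing from TSVs: {missing[:5]}"
        )

    label_by_name = {lab.value: lab for lab in RegionLabel}
    regions_by_id: dict[str, list[tuple[RegionLabel, int, int]]] = {}
    for row in regions_df.itertuples(index=False):
        if row.label not in label_by_name:
            raise CohortValidationError(f"{row.transcript_id}: unknown region label {row.label!r}")
        regions_by_id.setdefault(row.transcript_id, []).append(
            (label_by_name[row.label], int(row.start), int(row.end))
        )

    if kingdom is None:
        kingdom = str(meta_df["kingdom"].iloc[0]) if "kingdom" in meta_df and len(meta_df) else "other"

    records = []
    if expect_length is None:
        expect_length_eff: int | None = None
    else:
        expect_length_eff = expect_length
    for row in meta_df.itertuples(index=False):
        tid = row.transcript_id
        if tid not in sequences:
            raise CohortConsistencyError(f"{tid} in metadata but not in FASTA")
        ts_raw = str(getattr(row, "translation_start"))
        ts = None if ts_raw in ("NA", "", "nan") else int(float(ts_raw))
        rec = TranscriptRecord(
            transcript_id=tid,
            species=str(row.species),
            taxonomic_class=str(row.taxonomic_class),
            sequence=sequences[tid],
            regions=regions_by_id.get(tid, []),
            translation_start=ts,
            curation_status=CurationStatus.from_string(getattr(row, "curation_status", None)),
            window_start=int(getattr(row, "window_start", -WINDOW_UP)),
        )
        if expect_length is None and expect_length_eff is None and rec.window_start == -WINDOW_UP:
            rec.validate(expect_length=WINDOW_LEN)
        else:
            rec.validate(expect_length=expect_length_eff)
        records.append(rec)
    return Cohort(records=records, kingdom=kingdom)


def read_cohort_dir(cohort_dir: str | Path, **kwargs) -> Cohort:
    """Read a cohort from a directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    return read_cohort(d / FASTA_NAME, d / REGIONS_NAME, d / META_NAME, **kwargs)


# ---------------------------------------------------------------------------
# Curation-based transcript selection


def select_transcripts(cohort: Cohort) -> Cohort:
    """Apply the curation-based selection rule.

    An organism is "selected" when its curated fraction (transcripts marked
    PROVISIONAL, REVIEWED or VALIDATED) exceeds the kingdom threshold —
    5% for vertebrates, 30% for plants.  Selected organisms keep only
    curated transcripts; everything else keeps all transcripts.  The
    operation is idempotent and never increases the transcript count.
    """
    if cohort.kingdom not in SELECTION_THRESHOLDS:
        raise ConfigurationError(
            f"unknown kingdom {cohort.kingdom!r}; expected one of "
            f"{sorted(SELECTION_THRESHOLDS)}"
        )
    threshold = SELECTION_THRESHOLDS[cohort.kingdom]
    if threshold is None or cohort.curated_fraction <= threshold:
        return Cohort(records=list(cohort.records), kingdom=cohort.kingdom)
    kept = [r for r in cohort.records if r.curation_status in CURATED_STATUSES]
    return Cohort(records=kept, kingdom=cohort.kingdom)
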