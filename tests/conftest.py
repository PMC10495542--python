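"""Shared fixtures: hand-built windows and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from gcsignal import (
    Cohort,
    CurationStatus,
    GeneratorConfig,
    RegionLabel,
    TranscriptRecord,
    generate_cohort,
)
from gcsignal.genome_model import WINDOW_LEN, WINDOW_UP

DOWNSTREAM = WINDOW_LEN - WINDOW_UP  # 1001 positions (p = 0..1000)


def make_record(
    downstream: list[tuple[RegionLabel, str]],
    tid: str = "t0",
    species: str = "testsp",
    taxonomic_class: str = "TestClass",
    upstream: str | None = None,
    translation_start: int | None = None,
    curation_status: CurationStatus = CurationStatus.UNLABELED,
) -> TranscriptRecord:
    """Build a full 2001-bp window from downstream (label, sequence) chunks.

    The upstream flank defaults to 1000 'A's; any downstream remainder is
    filled with 'A's labelled 3'end.
    """
    up = upstream if upstream is not None else "A" * WINDOW_UP
    assert len(up) == WINDOW_UP
    regions = [(RegionLabel.FIVE_END, 0, WINDOW_UP)]
    seq_parts = [up]
    cursor = WINDOW_UP
    for label, chunk in downstream:
        regions.append((label, cursor, cursor + len(chunk)))
        seq_parts.append(chunk)
        cursor += len(chunk)
    if cursor < WINDOW_LEN:
        regions.append((RegionLabel.THREE_END, cursor, WINDOW_LEN))
        seq_parts.append("A" * (WINDOW_LEN - cursor))
    rec = TranscriptRecord(
        transcript_id=tid,
        species=species,
        taxonomic_class=taxonomic_class,
        sequence="".join(seq_parts),
        regions=regions,
        translation_start=translation_start,
        curation_status=curation_status,
    )
    rec.validate()
    return rec


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Default-condition cohort, 100 transcripts, fixed seed."""
    return generate_cohort(GeneratorConfig(seed=101, n_transcripts=100))


@pytest.fixture(scope="session")
def medium_cohort() -> Cohort:
    """Default-condition cohort, 500 transcripts, fixed seed."""
    return generate_cohort(GeneratorConfig(seed=202, n_transcripts=500))
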