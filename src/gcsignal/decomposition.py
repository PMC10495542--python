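"""Decomposition of the cohort-averaged GC profile into region components.

The full GC signal at window position p is the fraction of transcripts
whose base at p is G or C.  It splits exactly into

* a **between-region** signal b(p) = sum_r a(r) * d_r(p), where a(r) is the
  region's pooled average GC content over the whole window and d_r(p) the
  fraction of transcripts whose base at p lies in region r, and
* a **within-region** signal w(p) = full(p) - b(p), which captures the
  positional GC structure inside regions after their averages are removed.

Both split further into per-region constituent vectors whose sums recover
b and w.  For cohorts of standard 2001-bp windows the per-position
denominator is the transcript count T; spliced (mRNA) windows may be
shorter, in which case each position is averaged over the records that
actually cover it and uncovered positions are reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import Cohort, RegionLabel, WINDOW_LEN

REGION_ORDER: list[RegionLabel] = list(RegionLabel)
_LABEL_INDEX = {lab: i for i, lab in enumerate(REGION_ORDER)}

_GC_BYTES = frozenset(b"GC")


class EmptyCohortError(ValueError):
    pass


@dataclass
class SignalProfile:
    """A per-position signal over window coordinates.

    ``values[i]`` corresponds to window position ``p = i + start``; for a
    standard window ``start = -1000`` and the vector has length 2001.
    Missing positions are NaN.
    """

    values: np.ndarray
    n_transcripts: int
    label: str = ""
    start: int = -1000

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.values))

    def at(self, p: int) -> float:
        """Value at window position p."""
        return float(self.values[p - self.start])

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DecomposedSignal:
    """Full/between/within signals plus per-region constituents.

    ``coverage`` counts, per position, the records contributing a base;
    it is constant (= T) for standard full-length windows and tapers off
    for spliced cohorts of variable-length windows.
    """

    full: SignalProfile
    between: SignalProfile
    within: SignalProfile
    region_avg_gc: dict[RegionLabel, float]
    between_by_region: dict[RegionLabel, SignalProfile]
    within_by_region: dict[RegionLabel, SignalProfile]
    density_by_region: dict[RegionLabel, SignalProfile]
    coverage: np.ndarray | None = None

    @property
    def n_transcripts(self) -> int:
        return self.full.n_transcripts


def cohort_matrices(cohort: Cohort, n_policy: str = "count-zero"):
    """Vectorize a cohort into (gc, covered, labels) arrays of shape (T, L).

    ``gc`` is 1.0 where the base is G or C, ``covered`` marks positions the
    record actually has a base for (always all-True for standard windows),
    ``labels`` holds region indices into :data:`REGION_ORDER` (-1 where
    uncovered).  ``n_policy`` controls N bases: "count-zero" keeps them in
    denominators contributing 0 GC; "exclude" removes them from both
    numerator and denominator (treated as uncovered).
    """
    if not cohort.records:
        raise EmptyCohortError("cohort has no records")
    if n_policy not in ("count-zero", "exclude"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    L = max(len(r.sequence) for r in cohort.records)
    T = len(cohort.records)
    gc = np.zeros((T, L), dtype=float)
    covered = np.zeros((T, L), dtype=bool)
    labels = np.full((T, L), -1, dtype=np.int8)
    for t, rec in enumerate(cohort.records):
        n = len(rec.sequence)
        seq = np.frombuffer(rec.sequence.encode("ascii"), dtype="S1")
        is_gc = (seq == b"G") | (seq == b"C")
        gc[t, :n] = is_gc
        covered[t, :n] = True
        if n_policy == "exclude":
            covered[t, :n] = seq != b"N"
        for lab, start, end in rec.regions:
            labels[t, start:end] = _LABEL_INDEX[lab]
    if n_policy == "exclude":
        labels[~covered] = -1
        gc[~covered] = 0.0
    return gc, covered, labels


def _coverage(covered: np.ndarray) -> np.ndarray:
    cov = covered.sum(axis=0).astype(float)
    cov[cov == 0] = np.nan
    return cov


def full_gc_signal(cohort: Cohort, n_policy: str = "count-zero") -> SignalProfile:
    """Per-position fraction of G/C bases across the cohort (unsmoothed)."""
    gc, covered, _ = cohort_matrices(cohort, n_policy)
    cov = _coverage(covered)
    return SignalProfile(
        gc.sum(axis=0) / cov, len(cohort), "full", cohort.window_start
    )


def region_average_gc(
    cohort: Cohort, region: RegionLabel, n_policy: str = "count-zero"
) -> float | None:
    """Pooled GC fraction over all window positions labeled *region*.

    Pooling runs over the full window for every region.  Returns None when
    the region is absent from the cohort.
    """
    _, avgs = _region_averages(*cohort_matrices(cohort, n_policy))
    return avgs.get(region)


def _region_averages(gc, covered, labels):
    """Pooled a(r) for every occupied region; returns (counts, {label: a})."""
    avgs: dict[RegionLabel, float] = {}
    counts: dict[RegionLabel, int] = {}
    for lab, idx in _LABEL_INDEX.items():
        mask = labels == idx
        n = int(mask.sum())
        if n:
            avgs[lab] = float(gc[mask].sum() / n)
            counts[lab] = n
    return counts, avgs


def decompose(cohort: Cohort, n_policy: str = "count-zero") -> DecomposedSignal:
    """Compute the full signal and its between/within decomposition.

    Satisfies full(p) = between(p) + within(p) exactly (to float precision)
    and sum_r density_r(p) = 1 at every covered position.
    """
    gc, covered, labels = cohort_matrices(cohort, n_policy)
    T = len(cohort)
    start = cohort.window_start
    cov = _coverage(covered)
    full = gc.sum(axis=0) / cov
    _, avgs = _region_averages(gc, covered, labels)

    between_by: dict[RegionLabel, SignalProfile] = {}
    within_by: dict[RegionLabel, SignalProfile] = {}
    density_by: dict[RegionLabel, SignalProfile] = {}
    L = gc.shape[1]
    between = np.zeros(L)
    for lab, idx in _LABEL_INDEX.items():
        mask = labels == idx
        dens = mask.sum(axis=0) / cov
        gc_dens = (gc * mask).sum(axis=0) / cov
        a = avgs.get(lab, 0.0)
        b_term = a * dens
        w_term = gc_dens - b_term
        between = between + b_term
        between_by[lab] = SignalProfile(b_term, T, f"between_{lab.value}", start)
        within_by[lab] = SignalProfile(w_term, T, f"within_{lab.value}", start)
        density_by[lab] = SignalProfile(dens, T, f"density_{lab.value}", start)
    within = full - between
    return DecomposedSignal(
        full=SignalProfile(full, T, "full", start),
        between=SignalProfile(between, T, "between", start),
        within=SignalProfile(within, T, "within", start),
        region_avg_gc=avgs,
        between_by_region=between_by,
        within_by_region=within_by,
        density_by_region=density_by,
        coverage=covered.sum(axis=0),
    )


def between_region_signal(
    cohort: Cohort, n_policy: str = "count-zero"
) -> tuple[SignalProfile, dict[RegionLabel, SignalProfile]]:
    """b(p) and its per-region terms a(r) * density_r(p)."""
    d = decompose(cohort, n_policy)
    return d.between, d.between_by_region


def within_region_signal(
    cohort: Cohort, n_policy: str = "count-zero"
) -> tuple[SignalProfile, dict[RegionLabel, SignalProfile]]:
    """w(p) = full(p) - b(p) and its per-region constituents."""
    d = decompose(cohort, n_policy)
    return d.within, d.within_by_region


def normalised_within_region_signal(
    cohort: Cohort, region: RegionLabel, n_policy: str = "count-zero"
) -> SignalProfile:
    """Per-bp GC among transcripts that have *region* at each position.

    Positions where no transcript carries the region are NaN (missing),
    not zero.  Where the density is positive this equals the within-region
    constituent divided by density, plus a(r).
    """
    gc, covered, labels = cohort_matrices(cohort, n_policy)
    idx = _LABEL_INDEX[region]
    mask = labels == idx
    denom = mask.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, (gc * mask).sum(axis=0) / np.where(denom > 0, denom, 1), np.nan)
    return SignalProfile(vals, len(cohort), f"norm_within_{region.value}", cohort.window_start)


def smooth_signal(signal: SignalProfile, window: int = 3) -> SignalProfile:
    """Centered moving average; window shrinks at the array edges.

    Used for plotting only — all statistics run on raw signals.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be a positive odd integer, got {window}")
    if window == 1:
        return SignalProfile(signal.values.copy(), signal.n_transcripts, signal.label, signal.start)
    smoothed = (
        pd.Series(signal.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return SignalProfile(smoothed, signal.n_transcripts, signal.label, signal.start)


def signals_to_frame(signals: dict[str, SignalProfile]) -> pd.DataFrame:
    """Tabulate signals as a position-indexed DataFrame (NaN for missing)."""
    if not signals:
        return pd.DataFrame(columns=["position"])
    first = next(iter(signals.values()))
    df = pd.DataFrame({"position": first.positions})
    for name, sig in signals.items():
        if sig.start != first.start or len(sig) != len(first):
            raise ValueError(f"signal {name!r} has mismatched coordinates")
        df[name] = sig.values
    return df


def decomposition_frame(d: DecomposedSignal) -> pd.DataFrame:
    """Standard export table: full/between/within plus all constituents."""
    cols: dict[str, SignalProfile] = {
        "full": d.full,
        "between": d.between,
        "within": d.within,
    }
    for lab in REGION_ORDER:
        cols[f"between_{lab.value}"] = d.between_by_region[lab]
        cols[f"within_{lab.value}"] = d.within_by_region[lab]
        cols[f"density_{lab.value}"] = d.density_by_region[lab]
    return signals_to_frame(cols)
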