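"""Signal-size statistic, intron removal, and the pre-mRNA vs mRNA comparison.

The size of a GC signal is its mean absolute deviation from its own mean
over the 1000 strictly-downstream positions p = 1..1000.  Unlike a
standard deviation it weighs all departures from the mean equally, so a
flat signal scores 0 and a square wave of half-amplitude d scores d.

Splicing removes intron-labelled bases from the downstream part of each
window and re-anchors the remainder at the TSS; comparing signal sizes
before and after tells whether the positional GC structure lives on the
DNA/pre-mRNA (intron-borne, size drops on splicing) or survives on the
mature mRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DecomposedSignal, SignalProfile, decompose
from .genome_model import Cohort, RegionLabel, TranscriptRecord

#: Downstream positions entering the signal-size sum.
SIZE_POSITIONS = (1, 1000)


class UndefinedSignalSizeError(ValueError):
    pass


@dataclass
class SignalSize:
    sigma: float
    signal_label: str
    n_positions: int


def signal_size(signal: SignalProfile, weights: np.ndarray | None = None) -> SignalSize:
    """Mean absolute deviation from the mean over positions p = 1..1000.

    The TSS base (p = 0) and the upstream flank are excluded.  Missing
    (NaN) positions drop out of both the mean and the deviation sum, with
    ``n_positions`` reduced accordingly.  For cohorts of variable-length
    (spliced) windows pass per-position record counts as *weights*: both
    the mean and the deviation average are then record-count weighted, so
    sparsely covered tail positions do not dominate the statistic.
    """
    lo, hi = SIZE_POSITIONS
    i0 = max(lo - signal.start, 0)
    i1 = min(hi - signal.start + 1, len(signal.values))
    window = signal.values[i0:i1] if i1 > i0 else np.empty(0)
    if weights is None:
        w = np.ones_like(window)
    else:
        w = np.asarray(weights, dtype=float)[i0:i1]
    ok = ~np.isnan(window) & (w > 0)
    window, w = window[ok], w[ok]
    if window.size == 0:
        raise UndefinedSignalSizeError(
            f"signal {signal.label!r} has no defined downstream positions"
        )
    if np.all(window == window[0]):  # constant signal: exactly zero by definition
        sigma = 0.0
    else:
        mu = np.average(window, weights=w)
        sigma = float(np.average(np.abs(window - mu), weights=w))
    return SignalSize(
        sigma=sigma,
        signal_label=signal.label,
        n_positions=int(window.size),
    )


@dataclass
class PeakFit:
    """Gaussian fit of a within-region peak over the downstream window."""

    center: float
    amplitude: float
    sd: float
    offset: float


def fit_gaussian_peak(signal: SignalProfile) -> PeakFit:
    """Locate a broad peak in a signal by least-squares Gaussian fitting.

    The raw argmax of a broad peak sitting on per-position sampling noise
    is itself noise-dominated, so the peak position and height are
    estimated by fitting ``A * exp(-(p-c)^2 / (2 s^2)) + b`` over the
    downstream positions p = 1..1000.  The free offset b absorbs the
    centering of within-region constituents, so A measures the full
    excursion of the peak above its local baseline.
    """
    from scipy.optimize import curve_fit

    lo, hi = SIZE_POSITIONS
    i0, i1 = lo - signal.start, hi - signal.start + 1
    y = signal.values[max(i0, 0) : i1]
    p = np.arange(max(lo, signal.start), hi + 1, dtype=float)
    ok = ~np.isnan(y)
    y, p = y[ok], p[ok]
    if y.size < 10:
        raise UndefinedSignalSizeError("too few defined positions for a peak fit")
    smooth = np.convolve(y, np.ones(51) / 51, mode="same")

    def model(x, A, c, s, b):
        return A * np.exp(-((x - c) ** 2) / (2 * s**2)) + b

    p0 = [float(np.ptp(smooth)), float(p[np.argmax(smooth)]), 75.0, float(np.median(smooth))]
    popt, _ = curve_fit(model, p, y, p0=p0, maxfev=20000)
    A, c, s, b = (float(v) for v in popt)
    return PeakFit(center=c, amplitude=A, sd=abs(s), offset=b)


# ---------------------------------------------------------------------------
# Intron removal


def splice_record(record: TranscriptRecord) -> TranscriptRecord:
    """Remove intron bases downstream of the TSS and re-anchor at p = 0.

    The upstream flank is dropped (it does not exist on the mRNA); the
    surviving downstream bases are re-indexed consecutively from p = 0
    with their region labels carried along and the translation start
    remapped.  Intronless records keep their downstream part unchanged.
    """
    tss_idx = max(0, -record.window_start)
    keep: list[int] = []
    keep_labels: list[RegionLabel] = []
    for lab, start, end in record.regions:
        for i in range(max(start, tss_idx), end):
            if lab is not RegionLabel.INTRON:
                keep.append(i)
                keep_labels.append(lab)
    new_seq = "".join(record.sequence[i] for i in keep)
    # run-length encode the carried labels back into intervals
    regions: list[tuple[RegionLabel, int, int]] = []
    for j, lab in enumerate(keep_labels):
        if regions and regions[-1][0] is lab and regions[-1][2] == j:
            regions[-1] = (lab, regions[-1][1], j + 1)
        else:
            regions.append((lab, j, j + 1))
    old_to_new = {old: new for new, old in enumerate(keep)}
    ts = (
        old_to_new.get(record.translation_start)
        if record.translation_start is not None
        else None
    )
    return TranscriptRecord(
        transcript_id=record.transcript_id,
        species=record.species,
        taxonomic_class=record.taxonomic_class,
        sequence=new_seq,
        regions=regions,
        translation_start=ts,
        curation_status=record.curation_status,
        window_start=0,
    )


def splice_to_mrna(cohort: Cohort) -> Cohort:
    """Apply :func:`splice_record` to every record of a cohort."""
    return Cohort(
        records=[splice_record(r) for r in cohort.records], kingdom=cohort.kingdom
    )


# ---------------------------------------------------------------------------
# Paired comparison


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return "NA"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class SplicePair:
    """Decompositions and signal sizes for one organism, pre and post splicing."""

    species: str
    taxonomic_class: str
    kingdom: str
    pre: DecomposedSignal
    post: DecomposedSignal
    sizes_pre: dict[str, float]
    sizes_post: dict[str, float]


_SIZE_KINDS = ("full", "between", "within")


def _decomposition_sizes(d: DecomposedSignal) -> dict[str, float]:
    return {
        kind: signal_size(getattr(d, kind), weights=d.coverage).sigma
        for kind in _SIZE_KINDS
    }


def splice_pair(cohort: Cohort, n_policy: str = "count-zero") -> SplicePair:
    pre = decompose(cohort, n_policy)
    post = decompose(splice_to_mrna(cohort), n_policy)
    return SplicePair(
        species=cohort.species,
        taxonomic_class=cohort.taxonomic_class,
        kingdom=cohort.kingdom,
        pre=pre,
        post=post,
        sizes_pre=_decomposition_sizes(pre),
        sizes_post=_decomposition_sizes(post),
    )


#: Fewest paired organisms for which a group Wilcoxon test is attempted.
MIN_GROUP_SIZE = 6


def compare_pre_post_splice(
    cohorts: list[Cohort],
    group_by: str = "taxonomic_class",
    n_policy: str = "count-zero",
) -> tuple[pd.DataFrame, pd.DataFrame, list[SplicePair]]:
    """Per-organism signal sizes pre/post splicing plus grouped Wilcoxon tests.

    Returns ``(sizes, tests, pairs)``: a long table with one row per
    organism and sequence form, and a test table with one row per
    (group, signal kind) giving the two-sided Wilcoxon signed-rank
    statistic, p-value and significance stars.  Groups smaller than
    ``MIN_GROUP_SIZE`` or with all-zero differences are reported as
    not-testable rather than raising.
    """
    pairs = [splice_pair(c, n_policy) for c in cohorts]
    rows = []
    for pair in pairs:
        for form, sizes in (("pre", pair.sizes_pre), ("post", pair.sizes_post)):
            rows.append(
                {
                    "organism": pair.species,
                    "kingdom": pair.kingdom,
                    "taxonomic_class": pair.taxonomic_class,
                    "form": form,
                    **{f"sigma_{k}": v for k, v in sizes.items()},
                }
            )
    sizes_df = pd.DataFrame(rows)

    test_rows = []
    key = group_by if group_by is not None else "__all__"
    groups: dict[str, list[SplicePair]] = {}
    for pair in pairs:
        g = getattr(pair, group_by) if group_by else "all"
        groups.setdefault(g, []).append(pair)
    for g, members in sorted(groups.items()):
        for kind in _SIZE_KINDS:
            pre_vals = np.array([m.sizes_pre[kind] for m in members])
            post_vals = np.array([m.sizes_post[kind] for m in members])
            diffs = pre_vals - post_vals
            row = {
                "group": g,
                "signal": kind,
                "n": len(members),
                "statistic": np.nan,
                "p_value": np.nan,
                "stars": "NA",
                "testable": False,
            }
            if len(members) >= MIN_GROUP_SIZE and np.any(diffs != 0):
                res = stats.wilcoxon(
                    pre_vals, post_vals, zero_method="wilcox", alternative="two-sided"
                )
                row.update(
                    statistic=float(res.statistic),
                    p_value=float(res.pvalue),
                    stars=significance_stars(float(res.pvalue)),
                    testable=True,
                )
            test_rows.append(row)
    tests_df = pd.DataFrame(
        test_rows,
        columns=["group", "signal", "n", "statistic", "p_value", "stars", "testable"],
    )
    return sizes_df, tests_df, pairs
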