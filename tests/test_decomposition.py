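"""Between/within decomposition: exact identities, oracles, recovery."""

import numpy as np
import pytest

from gcsignal import (
    Cohort,
    GeneratorConfig,
    Modulation,
    RegionLabel,
    between_region_signal,
    decompose,
    full_gc_signal,
    generate_cohort,
    generate_block_toy,
    normalised_within_region_signal,
    region_average_gc,
    smooth_signal,
    within_region_signal,
)
from gcsignal.decomposition import EmptyCohortError, SignalProfile
from gcsignal.genome_model import WINDOW_LEN, WINDOW_UP

from conftest import make_record


def naive_decompose(cohort):
    """Literal per-position double-loop evaluation of the region equations.

    Independent oracle: computes the full signal, pooled region averages,
    and the between/within signals directly from their definitions with
    plain Python loops, no shared code with the vectorized path.
    """
    T = len(cohort.records)
    L = WINDOW_LEN
    gc_counts = [0.0] * L
    label_of = []
    for rec in cohort.records:
        lab = [None] * L
        for r, s, e in rec.regions:
            for i in range(s, e):
                lab[i] = r
        label_of.append(lab)
        for i, base in enumerate(rec.sequence):
            if base in "GC":
                gc_counts[i] += 1
    full = [c / T for c in gc_counts]
    a = {}
    for r in RegionLabel:
        num = den = 0.0
        for t, rec in enumerate(cohort.records):
            for i in range(L):
                if label_of[t][i] is r:
                    den += 1
                    if rec.sequence[i] in "GC":
                        num += 1
        if den:
            a[r] = num / den
    between = [0.0] * L
    for i in range(L):
        for t in range(T):
            between[i] += a[label_of[t][i]] / T
    within = [f - b for f, b in zip(full, between)]
    return np.array(full), a, np.array(between), np.array(within)


class TestFullSignal:
    def test_all_g_single_record(self):
        rec = make_record([], upstream="G" * WINDOW_UP)
        rec.sequence = "G" * WINDOW_LEN
        cohort = Cohort([rec])
        assert np.all(full_gc_signal(cohort).values == 1.0)

    def test_two_records_half_gc_at_tss(self):
        r1 = make_record([(RegionLabel.FIVE_UTR, "G" + "A" * 10)], tid="a")
        r2 = make_record([(RegionLabel.FIVE_UTR, "A" + "A" * 10)], tid="b")
        sig = full_gc_signal(Cohort([r1, r2]))
        assert sig.at(0) == 0.5

    def test_flat_cohort_within_binomial_se(self):
        # CDS is codon-built, so the check runs on the upstream flank,
        # which is pure 5'end generated base-wise at probability g.
        g = 0.4
        cfg = GeneratorConfig(
            seed=31, n_transcripts=1000, gc_baseline={lab: g for lab in RegionLabel}
        )
        sig = full_gc_signal(generate_cohort(cfg))
        se = np.sqrt(g * (1 - g) / 1000)
        upstream = sig.values[:WINDOW_UP]
        assert np.all(np.abs(upstream - g) < 5 * se)

    def test_empty_cohort_raises(self):
        with pytest.raises(EmptyCohortError):
            full_gc_signal(Cohort([]))

    def test_values_in_unit_interval(self, small_cohort):
        v = full_gc_signal(small_cohort).values
        assert np.nanmin(v) >= 0 and np.nanmax(v) <= 1


class TestRegionAverage:
    def test_all_gc_cds(self):
        rec = make_record([(RegionLabel.CDS, "GGCC")])
        assert region_average_gc(Cohort([rec]), RegionLabel.CDS) == 1.0

    def test_half_gc_cds(self):
        rec = make_record([(RegionLabel.CDS, "GATC")])
        assert region_average_gc(Cohort([rec]), RegionLabel.CDS) == 0.5

    def test_absent_region_is_none(self):
        rec = make_record([(RegionLabel.CDS, "GATC")])
        assert region_average_gc(Cohort([rec]), RegionLabel.INTRON) is None

    def test_intron_recovery_within_se(self):
        g = 0.6
        cfg = GeneratorConfig(
            seed=77,
            n_transcripts=500,
            gc_baseline={**{lab: 0.45 for lab in RegionLabel}, RegionLabel.INTRON: g},
        )
        cohort = generate_cohort(cfg)
        d = decompose(cohort)
        n_intron = sum(
            e - s for rec in cohort.records for lab, s, e in rec.regions if lab is RegionLabel.INTRON
        )
        se = np.sqrt(g * (1 - g) / n_intron)
        assert abs(d.region_avg_gc[RegionLabel.INTRON] - g) < 5 * se


class TestDecompositionIdentities:
    @pytest.mark.parametrize("seed,T", [(0, 10), (1, 50), (2, 200)])
    def test_full_equals_between_plus_within(self, seed, T):
        d = decompose(generate_cohort(GeneratorConfig(seed=seed, n_transcripts=T)))
        resid = np.abs(d.full.values - d.between.values - d.within.values)
        assert np.nanmax(resid) <= 1e-12

    def test_density_partition(self, small_cohort):
        d = decompose(small_cohort)
        total = sum(d.density_by_region[lab].values for lab in RegionLabel)
        assert np.nanmax(np.abs(total - 1.0)) <= 1e-12

    def test_constituents_sum_to_signals(self, small_cohort):
        d = decompose(small_cohort)
        b = sum(d.between_by_region[lab].values for lab in RegionLabel)
        w = sum(d.within_by_region[lab].values for lab in RegionLabel)
        assert np.nanmax(np.abs(b - d.between.values)) <= 1e-12
        assert np.nanmax(np.abs(w - d.within.values)) <= 1e-12

    def test_matches_naive_oracle(self):
        cohort = generate_cohort(GeneratorConfig(seed=9, n_transcripts=8))
        full, a, between, within = naive_decompose(cohort)
        d = decompose(cohort)
        assert np.allclose(d.full.values, full, atol=1e-12)
        for r, val in a.items():
            assert d.region_avg_gc[r] == pytest.approx(val, abs=1e-12)
        assert np.allclose(d.between.values, between, atol=1e-12)
        assert np.allclose(d.within.values, within, atol=1e-12)

    def test_between_is_convex_combination(self, small_cohort):
        d = decompose(small_cohort)
        avgs = list(d.region_avg_gc.values())
        assert np.nanmin(d.between.values) >= min(avgs) - 1e-12
        assert np.nanmax(d.between.values) <= max(avgs) + 1e-12

    def test_shift_invariance(self):
        """A region-independent GC offset moves full/between, not within."""
        base = {lab: 0.40 for lab in RegionLabel}
        delta = 0.1
        shifted = {lab: 0.50 for lab in RegionLabel}
        d0 = decompose(generate_cohort(GeneratorConfig(seed=55, n_transcripts=500, gc_baseline=base)))
        d1 = decompose(
            generate_cohort(GeneratorConfig(seed=56, n_transcripts=500, gc_baseline=shifted))
        )
        # compare on the upstream flank (pure base-wise generation)
        up = slice(0, WINDOW_UP)
        se = np.sqrt(0.25 / 500)
        assert abs(np.mean(d1.full.values[up] - d0.full.values[up]) - delta) < 5 * se / np.sqrt(10)
        assert abs(np.mean(d1.within.values[up] - d0.within.values[up])) < 5 * se / np.sqrt(10)


class TestBlockToy:
    def test_between_is_block_step_function(self):
        d = decompose(generate_block_toy())
        assert d.region_avg_gc[RegionLabel.CDS] == pytest.approx(0.8, abs=1e-12)
        assert d.region_avg_gc[RegionLabel.INTRON] == pytest.approx(0.2, abs=1e-12)
        assert d.region_avg_gc[RegionLabel.FIVE_END] == pytest.approx(0.5, abs=1e-12)
        # step values inside blocks
        assert d.between.at(-500) == pytest.approx(0.5)
        assert d.between.at(50) == pytest.approx(0.8)
        assert d.between.at(150) == pytest.approx(0.2)

    def test_within_integrates_to_zero_per_block(self):
        d = decompose(generate_block_toy())
        w = d.within.values
        for block_start in range(WINDOW_UP, WINDOW_UP + 1000, 100):
            assert abs(w[block_start : block_start + 100].sum()) < 1e-9

    def test_full_equals_between_plus_within_exactly(self):
        d = decompose(generate_block_toy())
        assert np.nanmax(np.abs(d.full.values - d.between.values - d.within.values)) <= 1e-12


class TestWithinSignal:
    def test_within_is_full_minus_between(self, small_cohort):
        full = full_gc_signal(small_cohort)
        b, _ = between_region_signal(small_cohort)
        w, _ = within_region_signal(small_cohort)
        assert np.allclose(w.values, full.values - b.values, atol=1e-12)

    def test_constant_blocks_give_zero_within(self):
        """Per-position GC held at the region average everywhere => w = 0."""
        # rotate a GGAA pattern so every position has exactly 2/4 GC records
        recs = []
        for i in range(4):
            seq = "".join("G" if (i + j) % 4 < 2 else "A" for j in range(WINDOW_LEN))
            rec = make_record(
                [(RegionLabel.FIVE_UTR, "A" * 100), (RegionLabel.INTRON, "A" * 901)],
                tid=f"t{i}",
            )
            rec.sequence = seq
            recs.append(rec)
        d = decompose(Cohort(recs))
        assert np.nanmax(np.abs(d.within.values)) <= 1e-12

    def test_intron_bump_recovered_in_intron_constituent(self):
        from gcsignal import fit_gaussian_peak, intron_peak_config

        d = decompose(generate_cohort(intron_peak_config(seed=7)))
        fit = fit_gaussian_peak(d.within_by_region[RegionLabel.INTRON])
        assert 240 <= fit.center <= 260
        # other constituents stay flat within noise
        other = d.within_by_region[RegionLabel.THREE_UTR].values
        assert np.nanmax(np.abs(other)) < 0.05


class TestNormalisedWithin:
    def test_all_gc_position(self):
        rec = make_record([(RegionLabel.CDS, "GGG")])
        sig = normalised_within_region_signal(Cohort([rec]), RegionLabel.CDS)
        assert sig.at(0) == 1.0

    def test_missing_where_region_absent(self):
        rec = make_record([(RegionLabel.CDS, "GGG")])
        sig = normalised_within_region_signal(Cohort([rec]), RegionLabel.CDS)
        assert np.isnan(sig.at(500))

    def test_algebraic_relation_to_constituent(self, small_cohort):
        """w_r / density + a(r) == normalised within-region signal."""
        d = decompose(small_cohort)
        r = RegionLabel.INTRON
        norm = normalised_within_region_signal(small_cohort, r)
        dens = d.density_by_region[r].values
        mask = dens > 0
        reconstructed = d.within_by_region[r].values[mask] / dens[mask] + d.region_avg_gc[r]
        assert np.allclose(reconstructed, norm.values[mask], atol=1e-10)
        assert np.nanmin(norm.values) >= 0 and np.nanmax(norm.values) <= 1


class TestSmoothing:
    def test_constant_unchanged(self):
        s = SignalProfile(np.full(WINDOW_LEN, 0.37), 1)
        assert np.allclose(smooth_signal(s).values, 0.37)

    def test_unit_impulse_spreads_to_thirds(self):
        v = np.zeros(WINDOW_LEN)
        v[500] = 1.0
        sm = smooth_signal(SignalProfile(v, 1)).values
        assert np.allclose(sm[499:502], 1 / 3)
        assert sm[498] == 0 and sm[502] == 0

    def test_window_one_is_identity(self):
        v = np.random.default_rng(0).random(WINDOW_LEN)
        assert np.array_equal(smooth_signal(SignalProfile(v, 1), 1).values, v)

    def test_edges_shrink(self):
        v = np.arange(WINDOW_LEN, dtype=float)
        sm = smooth_signal(SignalProfile(v, 1)).values
        assert sm[0] == pytest.approx(0.5)  # mean of first two
        assert len(sm) == WINDOW_LEN

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_signal(SignalProfile(np.zeros(WINDOW_LEN), 1), 4)
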