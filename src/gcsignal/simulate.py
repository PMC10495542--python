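"""Synthetic TSS-window cohorts with controllable GC structure.

The generator emulates what the decomposition pipeline assumes about real
transcript windows: a 1000-bp upstream flank, a downstream layout of
5'UTR, coding exons interrupted by introns, 3'UTR and 3'-flank fill,
per-region GC baselines, optional position-dependent GC modulations
(Gaussian peak, sine wave or step) inside a region, and a CDS built
codon-by-codon with controllable amino-acid composition and synonymous-
codon usage.  Because every statistic in the pipeline depends only on
GC-vs-AT status, G vs C (and A vs T) are always split 50:50.

Everything is deterministic given the seed.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace

import numpy as np

from .codons import AMINO_ACIDS, STANDARD_CODE, GeneticCode
from .genome_model import (
    Cohort,
    ConfigurationError,
    CurationStatus,
    RegionLabel,
    TranscriptRecord,
    WINDOW_LEN,
    WINDOW_UP,
)

_PROB_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class Modulation:
    """A position-dependent GC perturbation applied inside one region.

    ``shape`` is one of ``gaussian_peak`` (amplitude, center, sd),
    ``sine_wave`` (amplitude, center as phase origin, period) or ``step``
    (amplitude added for p >= center).  Positions are window coordinates
    in bp relative to the TSS.
    """

    region: RegionLabel
    shape: str
    amplitude: float
    center: float = 250.0
    sd: float = 75.0
    period: float = 200.0

    def delta(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if self.shape == "gaussian_peak":
            return self.amplitude * np.exp(-((p - self.center) ** 2) / (2 * self.sd**2))
        if self.shape == "sine_wave":
            return self.amplitude * np.sin(2 * np.pi * (p - self.center) / self.period)
        if self.shape == "step":
            return self.amplitude * (p >= self.center)
        raise ConfigurationError(f"unknown modulation shape {self.shape!r}")


@dataclass(frozen=True)
class RegionGrammar:
    """Downstream layout distributions (inclusive integer ranges, bp).

    Defaults give vertebrate-flavoured windows: a compact 5'UTR and first
    coding exon, so the first intron typically begins within ~200 bp of
    the TSS, and introns long enough that they dominate the remainder of
    the +1-kb window (the 3'UTR is rarely reached).
    """

    utr5_len: tuple[int, int] = (20, 80)
    n_introns: tuple[int, int] = (1, 4)
    exon_len: tuple[int, int] = (51, 99)
    intron_len: tuple[int, int] = (300, 900)
    utr3_len: tuple[int, int] = (100, 300)

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("utr5_len", self.utr5_len),
            ("n_introns", self.n_introns),
            ("exon_len", self.exon_len),
            ("intron_len", self.intron_len),
            ("utr3_len", self.utr3_len),
        ):
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"invalid grammar range {name}={lo, hi}")
        if self.exon_len[1] < 3:
            raise ConfigurationError("exons must be able to hold at least one codon")


@dataclass(frozen=True)
class AAProfile:
    """Amino-acid composition, optionally sliding along the window.

    ``composition`` gives weights over the 20 amino acids at p = 0; when
    ``end_composition`` is set, the weights interpolate linearly to it at
    p = 1000 (a compositional gradient).  Weights need not be normalised.
    """

    composition: dict[str, float] | None = None
    end_composition: dict[str, float] | None = None

    def weights(self, p: np.ndarray) -> np.ndarray:
        """(len(p), 20) matrix of normalised amino-acid probabilities."""
        base = self._vector(self.composition)
        if self.end_composition is None:
            return np.tile(base, (len(p), 1))
        end = self._vector(self.end_composition)
        f = np.clip(np.asarray(p, dtype=float) / 1000.0, 0.0, 1.0)[:, None]
        w = (1 - f) * base[None, :] + f * end[None, :]
        return w / w.sum(axis=1, keepdims=True)

    @staticmethod
    def _vector(comp: dict[str, float] | None) -> np.ndarray:
        if comp is None:
            v = np.ones(len(AMINO_ACIDS))
        else:
            unknown = set(comp) - set(AMINO_ACIDS)
            if unknown:
                raise ConfigurationError(f"unknown amino acids in profile: {sorted(unknown)}")
            v = np.array([comp.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
        if v.sum() <= 0 or (v < 0).any():
            raise ConfigurationError("amino-acid weights must be non-negative and sum > 0")
        return v / v.sum()


@dataclass(frozen=True)
class CodonBias:
    """Position-dependent preference for GC-rich synonymous codons.

    Within each amino acid's codon set, codon probability is proportional
    to ``exp(beta(p) * gc_count(codon))`` where

        beta(p) = beta0 + slope * p/1000
                  + peak_amplitude * exp(-(p - peak_center)^2 / (2 peak_sd^2)).

    ``beta = 0`` everywhere means uniform synonymous-codon usage.
    """

    beta0: float = 0.0
    slope: float = 0.0
    peak_amplitude: float = 0.0
    peak_center: float = 250.0
    peak_sd: float = 150.0

    def beta(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        out = self.beta0 + self.slope * p / 1000.0
        if self.peak_amplitude:
            out = out + self.peak_amplitude * np.exp(
                -((p - self.peak_center) ** 2) / (2 * self.peak_sd**2)
            )
        return out


#: Vertebrate-flavoured per-region GC baselines.
DEFAULT_GC_BASELINE = {
    RegionLabel.FIVE_END: 0.45,
    RegionLabel.FIVE_UTR: 0.55,
    RegionLabel.CDS: 0.52,  # only used when a record's CDS is empty; CDS is codon-built
    RegionLabel.INTRON: 0.42,
    RegionLabel.THREE_UTR: 0.40,
    RegionLabel.THREE_END: 0.42,
}


@dataclass
class GeneratorConfig:
    seed: int
    n_transcripts: int = 500
    grammar: RegionGrammar = field(default_factory=RegionGrammar)
    gc_baseline: dict[RegionLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_GC_BASELINE)
    )
    gc_modulations: list[Modulation] = field(default_factory=list)
    aa_profile: AAProfile = field(default_factory=AAProfile)
    codon_bias: CodonBias = field(default_factory=CodonBias)
    curation_mix: dict[CurationStatus, float] = field(
        default_factory=lambda: {CurationStatus.UNLABELED: 1.0}
    )
    species: str = "synthetic"
    taxonomic_class: str = "SyntheticClass"
    kingdom: str = "vertebrate"
    intron_within_codons: bool = False
    genetic_code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be >= 1")
        self.grammar.validate()
        for lab, gprob in self.gc_baseline.items():
            if not 0.0 <= gprob <= 1.0:
                raise ConfigurationError(f"gc_baseline[{lab.value}]={gprob} outside [0,1]")
        for mod in self.gc_modulations:
            if mod.region is RegionLabel.CDS:
                raise ConfigurationError(
                    "CDS GC structure is controlled by aa_profile/codon_bias, "
                    "not base-wise modulations"
                )
        total = sum(self.curation_mix.values())
        if total <= 0:
            raise ConfigurationError("curation_mix weights must sum > 0")


_LABEL_LIST = list(RegionLabel)
_LABEL_POS = {lab: i for i, lab in enumerate(_LABEL_LIST)}


def _region_prob_matrix(cfg: GeneratorConfig) -> tuple[np.ndarray, int]:
    """(6, 2001) per-region GC probability by window position, plus clip count."""
    p = np.arange(-WINDOW_UP, WINDOW_UP + 1, dtype=float)
    mat = np.zeros((len(_LABEL_LIST), WINDOW_LEN))
    for i, lab in enumerate(_LABEL_LIST):
        prob = np.full(WINDOW_LEN, cfg.gc_baseline.get(lab, 0.5))
        for mod in cfg.gc_modulations:
            if mod.region is lab:
                prob = prob + mod.delta(p)
        mat[i] = prob
    clipped = int(((mat < _PROB_CLIP[0]) | (mat > _PROB_CLIP[1])).sum())
    return np.clip(mat, *_PROB_CLIP), clipped


def _layout_record(cfg: GeneratorConfig, rng: np.random.Generator):
    """Draw one downstream layout.

    Returns (segments, cds_complete) where segments is a list of
    (label, length) truncated to the 1001 downstream positions and
    cds_complete says whether the full intended CDS fits in the window
    (controls whether a stop codon terminates it).
    """
    g = cfg.grammar
    utr5 = int(rng.integers(g.utr5_len[0], g.utr5_len[1] + 1))
    n_int = int(rng.integers(g.n_introns[0], g.n_introns[1] + 1))
    exons = [int(rng.integers(g.exon_len[0], g.exon_len[1] + 1)) for _ in range(n_int + 1)]
    introns = [int(rng.integers(g.intron_len[0], g.intron_len[1] + 1)) for _ in range(n_int)]
    if not cfg.intron_within_codons:
        exons = [max(3, e - e % 3) for e in exons]
    utr3 = int(rng.integers(g.utr3_len[0], g.utr3_len[1] + 1))
    plan: list[tuple[RegionLabel, int]] = [(RegionLabel.FIVE_UTR, utr5)]
    for k, e in enumerate(exons):
        plan.append((RegionLabel.CDS, e))
        if k < n_int:
            plan.append((RegionLabel.INTRON, introns[k]))
    plan.append((RegionLabel.THREE_UTR, utr3))

    capacity = WINDOW_LEN - WINDOW_UP  # 1001 downstream positions
    segments: list[tuple[RegionLabel, int]] = []
    used = 0
    truncated = False
    for lab, length in plan:
        if used >= capacity:
            truncated = True
            break
        take = min(length, capacity - used)
        if take < length:
            truncated = True
        if take > 0:
            segments.append((lab, take))
            used += take
    if used < capacity:
        segments.append((RegionLabel.THREE_END, capacity - used))
    intended_cds = sum(e for e in exons)
    realized_cds = sum(n for lab, n in segments if lab is RegionLabel.CDS)
    return segments, realized_cds == intended_cds


_STOP_CODONS = ("TAA", "TAG", "TGA")


def generate_cohort_with_report(cfg: GeneratorConfig) -> tuple[Cohort, dict]:
    """Generate a cohort; also return a report (clipped-probability count)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    prob_mat, n_clipped = _region_prob_matrix(cfg)
    T, L = cfg.n_transcripts, WINDOW_LEN

    labels = np.zeros((T, L), dtype=np.int8)  # FIVE_END index is 0
    regions_per_rec: list[list[tuple[RegionLabel, int, int]]] = []
    cds_positions: list[np.ndarray] = []
    stop_terminated: list[bool] = []
    for t in range(T):
        segments, cds_complete = _layout_record(cfg, rng)
        regions = [(RegionLabel.FIVE_END, 0, WINDOW_UP)]
        cursor = WINDOW_UP
        for lab, n in segments:
            regions.append((lab, cursor, cursor + n))
            labels[t, cursor : cursor + n] = _LABEL_POS[lab]
            cursor += n
        regions_per_rec.append(regions)
        cds_idx = np.flatnonzero(labels[t] == _LABEL_POS[RegionLabel.CDS])
        cds_positions.append(cds_idx)
        stop_terminated.append(cds_complete and len(cds_idx) >= 6)

    # base-wise draw for every position; CDS positions are overwritten below
    pos_prob = prob_mat[labels, np.arange(L)[None, :]]
    is_gc = rng.random((T, L)) < pos_prob
    strand_pick = rng.random((T, L)) < 0.5
    bases = np.where(
        is_gc,
        np.where(strand_pick, "G", "C"),
        np.where(strand_pick, "A", "T"),
    ).astype("U1")

    _fill_cds(cfg, rng, bases, cds_positions, stop_terminated)

    statuses = list(cfg.curation_mix)
    weights = np.array([cfg.curation_mix[s] for s in statuses], dtype=float)
    weights = weights / weights.sum()
    status_draw = rng.choice(len(statuses), size=T, p=weights)

    records = []
    for t in range(T):
        cds_idx = cds_positions[t]
        ts = int(cds_idx[0]) if len(cds_idx) else None
        records.append(
            TranscriptRecord(
                transcript_id=f"{cfg.species}_t{t:05d}",
                species=cfg.species,
                taxonomic_class=cfg.taxonomic_class,
                sequence="".join(bases[t]),
                regions=regions_per_rec[t],
                translation_start=ts,
                curation_status=statuses[status_draw[t]],
            )
        )
    return Cohort(records=records, kingdom=cfg.kingdom), {"n_clipped_probs": n_clipped}


def generate_cohort(cfg: GeneratorConfig) -> Cohort:
    """Deterministic synthetic cohort for a single species."""
    return generate_cohort_with_report(cfg)[0]


def _fill_cds(cfg, rng, bases, cds_positions, stop_terminated) -> None:
    """Write codon-by-codon CDS bases into the base matrix, cohort-vectorized."""
    syn = cfg.genetic_code.synonymous_codons()
    codons_by_aa = [syn[aa] for aa in AMINO_ACIDS]
    gc_by_aa = [
        np.array([sum(b in "GC" for b in c) for c in codons], dtype=float)
        for codons in codons_by_aa
    ]

    # enumerate codon slots: (record, [3 array indices], window position p)
    slot_rec: list[int] = []
    slot_idx: list[np.ndarray] = []
    slot_p: list[int] = []
    fixed: list[tuple[int, np.ndarray, str]] = []  # ATG starts, stop codons
    for t, cds_idx in enumerate(cds_positions):
        n = len(cds_idx)
        if n == 0:
            continue
        # stop codon only when it would land in frame
        terminate = stop_terminated[t] and n % 3 == 0
        coding_end = n - 3 if terminate else n
        # initiator codon is always ATG
        first = cds_idx[: min(3, n)]
        fixed.append((t, first, "ATG"[: len(first)]))
        k = 3
        while k < coding_end:
            triplet = cds_idx[k : min(k + 3, coding_end)]
            slot_rec.append(t)
            slot_idx.append(triplet)  # may be truncated at the end
            slot_p.append(int(triplet[0]) - WINDOW_UP)
            k += 3
        if terminate:
            stop = _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
            fixed.append((t, cds_idx[coding_end:], stop[: n - coding_end]))

    for t, idx, s in fixed:
        bases[t, idx] = list(s)

    if not slot_rec:
        return
    p_arr = np.array(slot_p)
    aa_probs = cfg.aa_profile.weights(p_arr)
    u = rng.random(len(p_arr))
    aa_draw = (aa_probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)

    beta = cfg.codon_bias.beta(p_arr)
    for aa_i in range(len(AMINO_ACIDS)):
        sel = np.flatnonzero(aa_draw == aa_i)
        if len(sel) == 0:
            continue
        gcs = gc_by_aa[aa_i]
        w = np.exp(np.outer(beta[sel], gcs))
        w = w / w.sum(axis=1, keepdims=True)
        u2 = rng.random(len(sel))
        codon_draw = (w.cumsum(axis=1) > u2[:, None]).argmax(axis=1)
        codon_list = codons_by_aa[aa_i]
        for j, slot in enumerate(sel):
            t = slot_rec[slot]
            idx = slot_idx[slot]
            codon = codon_list[codon_draw[j]]
            bases[t, idx] = list(codon[: len(idx)])


#: Vertebrate-like layout: intron-dominated downstream windows.
VERTEBRATE_GRAMMAR = RegionGrammar()

#: Plant-like layout: long coding exons, short introns, CDS-dense windows.
PLANT_GRAMMAR = RegionGrammar(
    utr5_len=(20, 80),
    n_introns=(1, 4),
    exon_len=(120, 300),
    intron_len=(80, 200),
    utr3_len=(100, 300),
)


def intron_peak_config(
    seed: int,
    n_transcripts: int = 500,
    amplitude: float = 0.1,
    center: float = 250.0,
    sd: float = 75.0,
) -> GeneratorConfig:
    """Vertebrate-like cohort with a Gaussian GC bump on introns.

    The default bump (center +250 bp, amplitude 0.1, sd 75 bp) is the
    intron-borne within-region peak characteristic of vertebrate TSS
    windows.
    """
    return GeneratorConfig(
        seed=seed,
        n_transcripts=n_transcripts,
        gc_modulations=[
            Modulation(RegionLabel.INTRON, "gaussian_peak", amplitude, center=center, sd=sd)
        ],
        species="intron_peak",
    )


def aa_gradient_config(seed: int, n_transcripts: int = 500) -> GeneratorConfig:
    """CDS-dense cohort whose only positional CDS structure is amino-acid choice.

    Composition slides from GC-rich-codon amino acids (Gly/Ala) near the
    TSS to AT-rich-codon ones (Phe/Lys) at +1 kb, with uniform synonymous
    codon usage throughout.
    """
    return GeneratorConfig(
        seed=seed,
        n_transcripts=n_transcripts,
        grammar=PLANT_GRAMMAR,
        aa_profile=AAProfile(
            composition={"G": 1.0, "A": 1.0},
            end_composition={"F": 1.0, "K": 1.0},
        ),
        species="aa_gradient",
    )


def codon_bias_config(seed: int, n_transcripts: int = 500) -> GeneratorConfig:
    """CDS-dense cohort whose only positional CDS structure is codon bias.

    Amino-acid composition is uniform and position-independent while the
    synonymous-codon preference slides from strongly GC-favouring at the
    TSS (beta = +2) to AT-favouring at +1 kb (beta = -2).
    """
    return GeneratorConfig(
        seed=seed,
        n_transcripts=n_transcripts,
        grammar=PLANT_GRAMMAR,
        codon_bias=CodonBias(beta0=2.0, slope=-4.0),
        species="codon_bias",
    )


# ---------------------------------------------------------------------------
# Deterministic illustration cohort


def generate_block_toy() -> Cohort:
    """A deterministic toy cohort with closed-form decomposition.

    Ten transcripts share one layout: a 1000-bp upstream flank, then five
    alternating 100-bp exon/intron blocks downstream (the final intron
    absorbs the last window base).  At each position an exact number of
    transcripts carry G, following a repeating 10-bp count pattern whose
    block means are exactly 0.8 (exons) and 0.2 (introns); the upstream
    flank sits at exactly 0.5.  Hence the between-region signal is the
    two-level step function of block averages and the within-region
    signal integrates to zero over each block.
    """
    T = 10
    exon_counts = [8, 9, 10, 9, 8, 7, 6, 7, 8, 8]  # mean 8 -> GC 0.8
    intron_counts = [2, 3, 4, 3, 2, 1, 0, 1, 2, 2]  # mean 2 -> GC 0.2
    counts = np.empty(WINDOW_LEN, dtype=int)
    counts[:WINDOW_UP] = 5
    regions: list[tuple[RegionLabel, int, int]] = [(RegionLabel.FIVE_END, 0, WINDOW_UP)]
    for block in range(10):
        start = WINDOW_UP + block * 100
        end = start + 100
        label = RegionLabel.CDS if block % 2 == 0 else RegionLabel.INTRON
        if block == 9:
            end += 1  # final intron absorbs position +1000
        pattern = exon_counts if label is RegionLabel.CDS else intron_counts
        for j in range(end - start):
            counts[start + j] = pattern[j % 10]
        regions.append((label, start, end))

    records = []
    for t in range(T):
        seq = "".join("G" if t < c else "A" for c in counts)
        records.append(
            TranscriptRecord(
                transcript_id=f"toy_t{t:02d}",
                species="block_toy",
                taxonomic_class="Toy",
                sequence=seq,
                regions=list(regions),
                translation_start=None,
                curation_status=CurationStatus.UNLABELED,
            )
        )
    return Cohort(records=records, kingdom="other")


# ---------------------------------------------------------------------------
# Species panels


def default_archetypes() -> dict[str, dict]:
    """Two archetypes differing only in the intron within-region signal.

    ``intron_wave`` carries a zero-mean sine-wave GC modulation on introns
    (amplitude 0.1, period 200 bp, the decaying-wave pattern seen in some
    fish genomes); ``flat`` carries no modulation.  Because the sine
    integrates to ~0 over the intron span it leaves the pooled intron
    average — and hence the between-region signal — unchanged, so the
    intron within-region signal size is the sole systematic
    discriminator between the archetypes.
    """
    return {
        "intron_wave": {
            "gc_modulations": [
                Modulation(RegionLabel.INTRON, "sine_wave", 0.1, center=0.0, period=200.0)
            ]
        },
        "flat": {"gc_modulations": []},
    }


def archetype_feature_table(
    n_per_group: int,
    vectors: dict[str, "np.ndarray | list[float]"],
    noise_ratio: float = 0.01,
    seed: int = 0,
):
    """Synthetic organism-by-feature table drawn around archetype vectors.

    Each archetype contributes *n_per_group* organisms whose six
    signal-size features are the archetype vector plus isotropic Gaussian
    noise with sd = *noise_ratio* times the largest inter-archetype
    distance.  Returns ``(table, true_labels)`` ready for
    :func:`gcsignal.comparative.ward_cluster`.
    """
    import pandas as pd

    from .comparative import FEATURE_COLUMNS

    names = list(vectors)
    vecs = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
    for k, v in vecs.items():
        if v.shape != (len(FEATURE_COLUMNS),):
            raise ConfigurationError(
                f"archetype {k!r} must have {len(FEATURE_COLUMNS)} features"
            )
    sep = max(
        np.linalg.norm(vecs[a] - vecs[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    )
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for name in names:
        for i in range(n_per_group):
            rows.append(vecs[name] + rng.normal(0.0, noise_ratio * sep, len(FEATURE_COLUMNS)))
            labels.append(name)
            index.append(f"{name}_sp{i:02d}")
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS, index=pd.Index(index, name="organism"))
    table["taxonomic_class"] = labels
    return table, labels


def uniform_cds_gc(code: GeneticCode = STANDARD_CODE) -> float:
    """Expected per-base GC of a CDS with uniform amino-acid and codon usage."""
    syn = code.synonymous_codons()
    per_aa = [
        float(np.mean([sum(b in "GC" for b in c) / 3 for c in syn[aa]]))
        for aa in AMINO_ACIDS
    ]
    return float(np.mean(per_aa))


def intron_signal_panel(
    n_species: int = 20,
    master_seed: int = 0,
    n_transcripts: int = 300,
    amplitude: float = 0.12,
) -> list[Cohort]:
    """Panel whose only positional GC structure is intron-borne.

    All region baselines are pinned to the expected GC of an unbiased CDS
    so the between-region signal is flat, and the single archetype puts a
    sine-wave modulation on introns.  Splicing such cohorts must weaken
    the full signal: the structure lives entirely on removed bases.
    """
    flat_gc = uniform_cds_gc()
    base = GeneratorConfig(seed=0, gc_baseline={lab: flat_gc for lab in RegionLabel})
    archetypes = {
        "intron_only": {
            "gc_modulations": [
                Modulation(RegionLabel.INTRON, "sine_wave", amplitude, center=0.0, period=200.0)
            ]
        }
    }
    return generate_species_panel(
        n_species,
        archetypes=archetypes,
        master_seed=master_seed,
        n_transcripts=n_transcripts,
        base_config=base,
    )


def generate_species_panel(
    n_species: int,
    archetypes: dict[str, dict] | None = None,
    master_seed: int = 0,
    n_transcripts: int = 500,
    base_config: GeneratorConfig | None = None,
) -> list[Cohort]:
    """Generate cohorts for *n_species* species assigned round-robin to archetypes.

    Each archetype is a dict of :class:`GeneratorConfig` field overrides;
    per-species seeds are derived deterministically from *master_seed*.
    The species' taxonomic class is set to its archetype name.
    """
    if n_species < 2:
        raise ConfigurationError("a species panel needs at least 2 species")
    if archetypes is None:
        archetypes = default_archetypes()
    names = list(archetypes)
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_species)
    cohorts = []
    for i in range(n_species):
        arch = names[i % len(names)]
        base = base_config if base_config is not None else GeneratorConfig(seed=0)
        cfg = replace(
            base,
            seed=int(seeds[i]),
            n_transcripts=n_transcripts,
            species=f"{arch}_sp{i:02d}",
            taxonomic_class=arch,
            **archetypes[arch],
        )
        cohorts.append(generate_cohort(cfg))
    return cohorts
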