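"""Decompose the TSS GC profile of a vertebrate-like synthetic cohort.

Generates the default study cohort (500 transcripts, intron-borne
Gaussian GC bump at +250 bp), computes the full / between-region /
within-region decomposition with per-region constituents, and writes the
signal table plus pooled region averages.  Prints where the within-region
peak sits and which constituent carries it.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import gcsignal as g
from gcsignal.decomposition import decomposition_frame
from gcsignal.genome_model import RegionLabel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/01_decompose"))
    args = ap.parse_args()

    cohort = g.generate_cohort(g.intron_peak_config(seed=args.seed, n_transcripts=500))
    d = g.decompose(cohort)

    args.outdir.mkdir(parents=True, exist_ok=True)
    decomposition_frame(d).to_csv(args.outdir / "signals.tsv", sep="\t", index=False, na_rep="NA")
    pd.DataFrame(
        [{"region": k.value, "avg_gc": v} for k, v in d.region_avg_gc.items()]
    ).to_csv(args.outdir / "region_avg_gc.tsv", sep="\t", index=False)

    resid = np.nanmax(np.abs(d.full.values - d.between.values - d.within.values))
    fit = g.fit_gaussian_peak(d.within_by_region[RegionLabel.INTRON])
    print(f"cohort: {len(cohort)} transcripts ({cohort.species})")
    print(f"decomposition residual max |full - between - within| = {resid:.2e}")
    print("pooled region GC averages:")
    for k, v in d.region_avg_gc.items():
        print(f"  a({k.value}) = {v:.4f}")
    print(
        f"within-region intron peak: center {fit.center:.1f} bp downstream of TSS, "
        f"amplitude {fit.amplitude:.4f} GC fraction"
    )
    print(f"tables -> {args.outdir}")


if __name__ == "__main__":
    main()
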