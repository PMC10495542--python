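"""Compare GC signal sizes on pre-mRNA vs spliced mRNA windows.

Generates a 20-species panel whose positional GC structure is entirely
intron-borne, removes the introns, and compares full/between/within
signal sizes per species with a paired Wilcoxon signed-rank test.
"""

import argparse
from pathlib import Path

import numpy as np

import gcsignal as g


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/03_splice"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohorts = g.intron_signal_panel(20, master_seed=args.seed, n_transcripts=300)
    sizes, tests, pairs = g.compare_pre_post_splice(cohorts)
    sizes.to_csv(args.outdir / "splice_sizes.tsv", sep="\t", index=False)
    tests.to_csv(args.outdir / "splice_tests.tsv", sep="\t", index=False, na_rep="NA")

    pre = np.array([p.sizes_pre["full"] for p in pairs])
    post = np.array([p.sizes_post["full"] for p in pairs])
    full = tests[tests.signal == "full"].iloc[0]
    print(f"panel: {len(pairs)} species, intron-borne signal only")
    print(
        f"full-signal size pre-mRNA {pre.mean():.4f} vs mRNA {post.mean():.4f}; "
        f"pre > post in {int((pre > post).sum())}/{len(pre)} species"
    )
    print(f"Wilcoxon signed-rank (full signal): p = {full.p_value:.2e} {full.stars}")
    print(f"tables -> {args.outdir}")


if __name__ == "__main__":
    main()
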