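#!/usr/bin/env python
"""Simulate the six study cohorts (3 genotype presets x 2 sexes, n = 50).

Raw per-fly recordings (10 days x 2880 thirty-second bins each) are large,
so they go under scratch/cohorts/<genotype>_<sex>/ as arena-dialect CSVs
with metadata and ground truth; results/cohort_manifest.csv records the
design and the generative truth per fly.
"""

from pathlib import Path

import pandas as pd

from flysleep.simulate import preset, simulate_group

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

GROUPS = [
    ("wildtype-like", "wildtype"),
    ("clockless-like", "clockless"),
    ("fxs-like", "fxs"),
]
MASTER_SEED = 20240707


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    manifests = []
    for gi, (preset_name, genotype) in enumerate(GROUPS):
        for si, sex in enumerate(("female", "male")):
            cfg = preset(
                preset_name,
                n_flies=50,
                seed=MASTER_SEED + 10 * gi + si,
                genotype=genotype,
                sex=sex,
            )
            outdir = SCRATCH / f"{genotype}_{sex}"
            _, truths, manifest = simulate_group(cfg, outdir=outdir)
            n_rhy = sum(t.rhythmic for t in truths)
            print(
                f"{genotype:10s} {sex:6s}: 50 flies -> {outdir}  "
                f"(ground truth: {n_rhy}/50 rhythmic)"
            )
            manifests.append(manifest)
    pd.concat(manifests, ignore_index=True).to_csv(
        RESULTS / "cohort_manifest.csv", index=False
    )
    print(f"\nmanifest: {RESULTS / 'cohort_manifest.csv'}")


if __name__ == "__main__":
    main()
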