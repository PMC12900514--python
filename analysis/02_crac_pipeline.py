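#!/usr/bin/env python
"""Run the CRAC read-processing pipeline on the simulated read sets.

For each preset's read table from analysis/01_simulate.py: remove PCR
duplicates per replicate (key = start, end, strand, UMI), tally per-base
3'-end coverage, normalize to hits per million, and aggregate replicates
into mean / min-max envelope tracks.  Per-replicate coverage TSVs and
aggregate tracks go to scratch/; duplicate-removal statistics go to
results/02_dedup_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from polone.annotation import default_annotation, read_reads
from polone.coverage import aggregate, coverage_3p, dedup
from polone.presets import PRESET_NAMES

SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    annotation = default_annotation()
    rows = []
    for preset in PRESET_NAMES:
        reads = read_reads(SCRATCH / f"reads_{preset}.tsv")
        profiles = []
        for rep, group in reads.groupby("replicate", sort=True):
            unique, n_removed = dedup(group)
            profile = coverage_3p(unique, annotation.unit_length,
                                  condition=preset, replicate=str(rep))
            profiles.append(profile)
            profile.to_frame().to_csv(
                SCRATCH / f"cov_{preset}_{rep}.tsv", sep="\t", index=False)
            rows.append({"preset": preset, "replicate": rep,
                         "n_reads": len(group), "n_unique": len(unique),
                         "duplicate_fraction": n_removed / len(group)})
        agg = aggregate(profiles, condition=preset)
        agg.to_frame().to_csv(SCRATCH / f"agg_{preset}.tsv", sep="\t",
                              index=False, float_format="%.6g")
        print(f"{preset}: mean duplicate fraction "
              f"{sum(r['duplicate_fraction'] for r in rows[-3:]) / 3:.3f}")
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "02_dedup_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    print(f"\nwrote {RESULTS / '02_dedup_summary.tsv'}")


if __name__ == "__main__":
    main()
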