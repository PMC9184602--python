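#!/usr/bin/env python
"""Compute LOH, TAI, LST and HRDsum for every cohort tumor.

Reads the segment table written by 01_simulate_cohort.py, scores each
profile against the packaged genome build and reports the HRD-positive
fraction at the default cutpoint of 42. The planted scar counts are
checked against the recovered ones as a built-in sanity control.
"""

from pathlib import Path

import pandas as pd

from hrdkit import io
from hrdkit.config import PipelineConfig
from hrdkit.genome import default_build
from hrdkit.scars import score_profiles

COHORT = Path("results/cohort")
OUT = Path("results/scar_scores.tsv")


def main() -> None:
    profiles = io.read_segments(COHORT / "segments.tsv")
    config = PipelineConfig()
    scores = score_profiles(profiles, default_build(), config)
    scores.to_csv(OUT, sep="\t", index=False)

    truth = pd.read_csv(COHORT / "truth.tsv", sep="\t")
    merged = scores.merge(truth, on="sample")
    exact = (
        (merged["LOH"] == merged["planted_loh"])
        & (merged["TAI"] == merged["planted_tai"])
        & (merged["LST"] == merged["planted_lst"])
    )
    print(f"scored {len(scores)} tumors -> {OUT}")
    print(f"planted scar counts recovered exactly: {exact.sum()}/{len(merged)}")
    frac = scores["HRD_positive"].mean()
    print(f"HRD-positive (HRDsum >= {config.hrd_cutpoint:g}) from segments: {frac:.1%}")
    print("note: segment-level HRDsum reflects the modest planted event counts;")
    print("the per-class score distributions used for association analyses are")
    print("the emulated draws in results/cohort/scores.tsv")


if __name__ == "__main__":
    main()
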