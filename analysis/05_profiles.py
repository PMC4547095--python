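"""Composite signal profiles and global reproducibility views.

Builds the wild-type vs induced composite H4Ac profile over a 4 kb window
centered on detected decrease blocks (units: tags per bp per region, 10 bp
bins), the 5 kb / 25 bp heatmap matrix around those regions, and the
wt-vs-induced scatter correlation over background windows (a null
calibration on this generator, whose background carries no shared
structure between conditions).
"""

import os

import numpy as np
import pandas as pd

from chromcode.diffblocks import DetectorConfig, call_differential_blocks
from chromcode.profiles import composite_profile, heatmap_matrix, scatter_compare
from chromcode.simulate import CohortConfig, generate_cohort
from chromcode.trackio import GenomicInterval, normalize_track

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    cohort = generate_cohort(CohortConfig(seed=1))
    wt = normalize_track(cohort.track("H4Ac", "wt"))
    ind = normalize_track(cohort.track("H4Ac", "induced"))
    blocks = call_differential_blocks(wt, ind)
    regions = [b.interval for b in blocks if b.direction == "decrease"]

    prof_wt = composite_profile(wt, regions)
    prof_ind = composite_profile(ind, regions)
    out = pd.DataFrame(
        {"offset_bp": prof_wt.offsets, "wt": prof_wt.values, "induced": prof_ind.values}
    )
    out.to_csv(os.path.join(RESULTS, "H4Ac_composite_profile.tsv"), sep="\t", index=False)
    center = np.abs(prof_wt.offsets) < 500
    flank = np.abs(prof_wt.offsets) > 1800
    print(
        f"Composite H4Ac over {prof_wt.n_regions} decrease blocks "
        f"(tags/bp/region, 400 bins of 10 bp):\n"
        f"  wt:      center {prof_wt.values[center].mean():.2f}, flank {prof_wt.values[flank].mean():.2f}\n"
        f"  induced: center {prof_ind.values[center].mean():.2f}, flank {prof_ind.values[flank].mean():.2f}"
    )
    print("  -> signal drops inside the blocks after induction, flanks untouched")

    hm = heatmap_matrix(ind, regions)
    scratch = os.path.join(os.path.dirname(__file__), "..", "scratch")
    os.makedirs(scratch, exist_ok=True)
    pd.DataFrame(hm.matrix).to_csv(
        os.path.join(scratch, "H4Ac_induced_heatmap.tsv"), sep="\t", index=False
    )
    print(f"\nHeatmap matrix: {hm.matrix.shape[0]} regions x {hm.matrix.shape[1]} bins of 25 bp")

    rng = np.random.default_rng(1)
    chrom_len = cohort.config.chrom_length
    windows = [
        GenomicInterval("chr1", int(s), int(s) + 1000)
        for s in rng.integers(0, chrom_len - 1000, 1000)
    ]
    _, r = scatter_compare(wt, ind, windows)
    print(f"\nwt vs induced H4Ac over 1000 random 1 kb windows: Pearson r = {r:.3f}")
    print(
        "(the synthetic background is unstructured NB noise, so window totals "
        "are independent between conditions and r is a null-calibration check; "
        "real tracks share peak structure and correlate strongly)"
    )


if __name__ == "__main__":
    main()
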