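"""Call differential chromatin blocks on every mark of the benchmark cohort.

Normalizes all tracks to 10 million tags, scans 1 kb windows (500 bp step)
with the NB Wald test, keeps windows with p < 0.05 and |log2FC| > 0.4, and
merges them into direction-consistent blocks. Writes per-mark BED files and
a per-mark/direction count table; reports the H4Ac decrease width
distribution (the mark with the broadest planted domains).
"""

import os

import numpy as np
import pandas as pd

from chromcode.diffblocks import DetectorConfig, call_blocks_all_marks, write_blocks_bed
from chromcode.simulate import CohortConfig, generate_cohort
from chromcode.trackio import normalize_track

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(os.path.join(RESULTS, "blocks"), exist_ok=True)
    cohort = generate_cohort(CohortConfig(seed=1))
    normalized = {k: normalize_track(t) for k, t in cohort.tracks.items()}
    marks = [m for m in cohort.config.marks if m != "input"]
    blocks = call_blocks_all_marks(normalized, marks, DetectorConfig())

    rows = []
    for mark in marks:
        blist = blocks.get(mark, [])
        write_blocks_bed(blist, os.path.join(RESULTS, "blocks", f"{mark}.bed"))
        for direction in ("decrease", "increase"):
            sel = [b for b in blist if b.direction == direction]
            rows.append(
                {
                    "mark": mark,
                    "direction": direction,
                    "n_blocks": len(sel),
                    "mean_width_bp": round(np.mean([b.width for b in sel]), 1) if sel else 0.0,
                    "mean_abs_log2fc": round(np.mean([abs(b.log2fc) for b in sel]), 2) if sel else 0.0,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(RESULTS, "block_counts.tsv"), sep="\t", index=False)
    print("Differential blocks per mark and direction (seed 1):")
    print(table.to_string(index=False))

    h4 = [b.width for b in blocks["H4Ac"] if b.direction == "decrease"]
    print(
        f"\nH4Ac decrease blocks: n={len(h4)}, mean {np.mean(h4) / 1000:.2f} kb, "
        f"median {np.median(h4) / 1000:.2f} kb, >1 kb: {np.mean(np.array(h4) > 1000):.0%}"
    )
    print("Note the quiet H3 control: histone density itself is unchanged.")


if __name__ == "__main__":
    main()
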