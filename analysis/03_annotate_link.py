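"""Annotate blocks to genes/contexts and link them to repressor binding.

Assigns every H4Ac/H3K27Ac/H3K4me1 block to its nearest-TSS gene and a
genomic context, flags blocks whose gene carries a Hairy peak, and asks two
questions of the benchmark cohort: (1) are decrease blocks more often
Hairy-bound than increase blocks, and (2) are Hairy-bound deacetylation
blocks broader than unbound ones (two-sample KS test)?
"""

import os

import numpy as np
import pandas as pd

from chromcode.annotate import annotate_regions, link_hairy_bound
from chromcode.diffblocks import DetectorConfig, call_blocks_all_marks
from chromcode.profiles import compare_block_widths
from chromcode.simulate import CohortConfig, generate_cohort
from chromcode.trackio import normalize_track

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
MARKS = ("H4Ac", "H3K27Ac", "H3K4me1")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    cohort = generate_cohort(CohortConfig(seed=1))
    normalized = {k: normalize_track(t) for k, t in cohort.tracks.items()}
    blocks = call_blocks_all_marks(normalized, list(MARKS), DetectorConfig())

    rows = []
    for mark in MARKS:
        blist = blocks[mark]
        regions = [b.interval for b in blist]
        anns = annotate_regions(regions, cohort.genes)
        bound = link_hairy_bound(regions, cohort.peaksets["Hairy"], cohort.genes)
        for b, a, hb in zip(blist, anns, bound):
            rows.append(
                {
                    "mark": mark,
                    "direction": b.direction,
                    "width": b.width,
                    "gene_id": a.gene_id,
                    "tss_distance": a.tss_distance,
                    "context": a.context,
                    "hairy_bound": hb,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(RESULTS, "annotated_blocks.tsv"), sep="\t", index=False)

    print("Genomic context of affected regions (column %):")
    print(
        (100 * pd.crosstab(df["context"], df["mark"], normalize="columns"))
        .round(1)
        .to_string()
    )

    print("\nFraction of blocks on Hairy-bound genes, by direction:")
    frac = df.groupby(["mark", "direction"])["hairy_bound"].mean().round(2)
    print(frac.to_string())

    h4 = df[(df["mark"] == "H4Ac") & (df["direction"] == "decrease")]
    d, p, (mb, mu) = compare_block_widths(
        h4.loc[h4["hairy_bound"], "width"], h4.loc[~h4["hairy_bound"], "width"]
    )
    print(
        f"\nH4Ac decrease widths, Hairy-bound vs unbound: mean {mb:.0f} vs {mu:.0f} bp, "
        f"KS D={d:.2f}, p={p:.2e}"
    )
    print(
        "(the generator draws block widths independently of binding, so on "
        "synthetic data this comparison is expected to be flat; on real data "
        "it asks whether bound deacetylation domains spread further)"
    )


if __name__ == "__main__":
    main()
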