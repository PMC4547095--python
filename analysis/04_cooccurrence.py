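"""Co-occurrence of chromatin changes and gene-set enrichment.

Computes the pairwise signed ln-p co-occurrence matrix over all
{mark x direction} block categories (negative = enrichment), and the
hypergeometric overlap between the repressed gene set and Hairy-bound
genes — the planted analogue of "most down-regulated genes are physical
repressor targets".
"""

import os

import pandas as pd

from chromcode.annotate import peak_gene_map
from chromcode.diffblocks import DetectorConfig, call_blocks_all_marks
from chromcode.features import select_regulated_genes
from chromcode.overlap import cooccurrence_matrix, gene_set_overlap
from chromcode.simulate import CohortConfig, generate_cohort
from chromcode.trackio import normalize_track

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    cohort = generate_cohort(CohortConfig(seed=1))
    normalized = {k: normalize_track(t) for k, t in cohort.tracks.items()}
    marks = [m for m in cohort.config.marks if m not in ("input", "H3")]
    blocks = call_blocks_all_marks(normalized, marks, DetectorConfig())

    categories = {
        f"{mark}_{direction[:3]}": [
            b.interval for b in blocks[mark] if b.direction == direction
        ]
        for mark in marks
        for direction in ("decrease", "increase")
    }
    mat = cooccurrence_matrix(categories, cohort.config.genome_length)
    mat.round(1).to_csv(os.path.join(RESULTS, "cooccurrence_ln_p.tsv"), sep="\t")
    dec = [c for c in mat.columns if c.endswith("_dec")]
    print("Signed ln p co-occurrence, decrease x decrease corner (negative = enriched):")
    print(mat.loc[dec, dec].round(1).to_string())

    labelled = select_regulated_genes(cohort.expression)
    repressed = set(labelled.loc[labelled["class_label"] == "repressed", "gene_id"])
    activated = set(labelled.loc[labelled["class_label"] == "activated", "gene_id"])
    universe = set(labelled["gene_id"])
    hairy_genes = set(peak_gene_map(cohort.peaksets["Hairy"], cohort.genes))
    for name, gene_set in (("repressed", repressed), ("activated", activated)):
        res = gene_set_overlap(gene_set, hairy_genes & universe, universe)
        print(
            f"\n{name} ({res.n_a}) vs Hairy-bound ({res.n_b}) genes: "
            f"{res.n_overlap} shared ({res.n_overlap / res.n_a:.0%}), "
            f"hypergeometric ln p = {res.signed_ln_p:.1f}"
        )


if __name__ == "__main__":
    main()
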