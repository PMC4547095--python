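"""Per-gene feature table and expression-based class labels.

Each gene gets 41 numeric features: for each of the 7 differential
ChIP-seq datasets (6 histone marks + Pol II) the count, total width, max
|log2 fold change| and min |TSS distance| of its linked blocks; for each of
the 3 binding factors (Hairy, CtBP, Gro) the count, total width, max height
and min |TSS distance| of its linked peaks; plus the wild-type expression
level. 4*7 + 4*3 + 1 = 41.

A gene with no linked block/peak gets zero counts, widths and fold changes,
and the distance cap (a finite, rankable sentinel) for distances.
"""

from __future__ import annotations

import pandas as pd

from .annotate import _TssIndex, nearest_tss
from .diffblocks import DifferentialBlock
from .simulate import DIFF_MARKS, FACTORS
from .trackio import GeneModel, PeakSet

DISTANCE_CAP = 100_000  # bp
BLOCK_AGGREGATES = ("block_count", "block_width_total", "block_abs_log2fc_max", "block_tss_distance_min")
PEAK_AGGREGATES = ("peak_count", "peak_width_total", "peak_height_max", "peak_tss_distance_min")


def feature_columns(
    diff_marks: tuple[str, ...] = DIFF_MARKS,
    factors: tuple[str, ...] = FACTORS,
) -> list[str]:
    """Stable documented column order of the feature table."""
    cols = [f"{m}_{agg}" for m in diff_marks for agg in BLOCK_AGGREGATES]
    cols += [f"{f}_{agg}" for f in factors for agg in PEAK_AGGREGATES]
    cols.append("wt_expression")
    return cols


def select_regulated_genes(
    expression: pd.DataFrame, p_max: float = 0.05, fc_min: float = 2.0
) -> pd.DataFrame:
    """Label genes repressed/activated/unaffected from the expression table.

    Differential expression requires p < p_max and a fold change beyond
    fc_min in either direction (repression = fold change <= 1/fc_min, the
    reciprocal convention). Everything else is unaffected. A ``ml_label``
    column pools activated and unaffected as "nonrepressed".
    """
    required = {"gene_id", "fold_change", "p_value"}
    if required - set(expression.columns) or expression[list(required)].isna().any().any():
        raise ValueError("expression table must provide complete gene_id/fold_change/p_value")
    df = expression.copy()
    sig = df["p_value"] < p_max
    df["class_label"] = "unaffected"
    df.loc[sig & (df["fold_change"] <= 1.0 / fc_min), "class_label"] = "repressed"
    df.loc[sig & (df["fold_change"] >= fc_min), "class_label"] = "activated"
    df["ml_label"] = (df["class_label"] == "repressed").map(
        {True: "repressed", False: "nonrepressed"}
    )
    return df


def build_feature_table(
    blocks_by_mark: dict[str, list[DifferentialBlock]],
    peaks_by_factor: dict[str, PeakSet],
    expression: pd.DataFrame,
    genes: list[GeneModel],
    diff_marks: tuple[str, ...] = DIFF_MARKS,
    factors: tuple[str, ...] = FACTORS,
    distance_cap: int = DISTANCE_CAP,
) -> pd.DataFrame:
    """One row per gene, indexed by gene_id, with the documented 41 columns
    plus a ``label`` column (repressed vs nonrepressed) last.

    Blocks and peaks are linked to their nearest-TSS gene; multi-region
    genes are summarized with monotone aggregates (count / total width /
    max magnitude / min distance). Input region order never matters.
    """
    labelled = select_regulated_genes(expression).set_index("gene_id")
    missing = [g.gene_id for g in genes if g.gene_id not in labelled.index]
    if missing:
        raise ValueError(f"genes missing expression: {missing[:5]}...")
    index = _TssIndex(genes)
    cols = feature_columns(diff_marks, factors)
    table = pd.DataFrame(0.0, index=[g.gene_id for g in genes], columns=cols)
    table.index.name = "gene_id"
    for m in diff_marks:
        table[f"{m}_block_tss_distance_min"] = float(distance_cap)
    for f in factors:
        table[f"{f}_peak_tss_distance_min"] = float(distance_cap)

    for mark in diff_marks:
        for block in blocks_by_mark.get(mark, []):
            gid, dist = nearest_tss(block.interval, index)
            if gid is None:
                continue
            dist = min(abs(dist), distance_cap)
            table.loc[gid, f"{mark}_block_count"] += 1
            table.loc[gid, f"{mark}_block_width_total"] += block.width
            col = f"{mark}_block_abs_log2fc_max"
            table.loc[gid, col] = max(table.loc[gid, col], abs(block.log2fc))
            col = f"{mark}_block_tss_distance_min"
            table.loc[gid, col] = min(table.loc[gid, col], dist)

    for factor in factors:
        peakset = peaks_by_factor.get(factor)
        for peak in peakset.peaks if peakset else []:
            gid, dist = nearest_tss(peak.interval, index)
            if gid is None:
                continue
            dist = min(abs(dist), distance_cap)
            table.loc[gid, f"{factor}_peak_count"] += 1
            table.loc[gid, f"{factor}_peak_width_total"] += peak.interval.width
            col = f"{factor}_peak_height_max"
            table.loc[gid, col] = max(table.loc[gid, col], peak.height)
            col = f"{factor}_peak_tss_distance_min"
            table.loc[gid, col] = min(table.loc[gid, col], dist)

    table["wt_expression"] = labelled.loc[table.index, "wt_level"].astype(float)
    table["label"] = labelled.loc[table.index, "ml_label"]
    return table
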