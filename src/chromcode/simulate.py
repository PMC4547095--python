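"""Synthetic embryo ChIP-seq cohort generator.

Emulates the statistical structure the downstream analysis assumes, without
any sequencing data: negative-binomial replicate window counts for six
histone marks, Pol II, histone H3 and an input control in two conditions
(wild type vs. repressor-induced), differential chromatin blocks planted on
gene territories, repressor/corepressor (Hairy/Gro/CtBP) peak sets enriched
near repressed genes, and an expression table over a 241/146/196
repressed/activated/unaffected cohort of 583 genes.

Planted effects multiply the NB *mean* inside a block (replicate noise stays
NB, matching the detector's model), with block coordinates snapped to the
bin grid. A configurable fraction of non-repressed genes also receives
repression-like chromatin ("errant targeting"), which keeps chromatin state
and transcription deliberately uncoupled on part of the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trackio import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    SignalTrack,
    read_expression,
    read_genes,
    read_peaks,
    read_tracks,
    write_expression,
    write_genes_gff3,
    write_peaks,
    write_tracks,
)

DIFF_MARKS = ("H4Ac", "H3K27Ac", "H3K4me1", "H3K4me3", "H3K36me3", "H3K9me3", "PolII")
CONTROL_MARKS = ("H3", "input")
ALL_MARKS = DIFF_MARKS + CONTROL_MARKS
FACTORS = ("Hairy", "Gro", "CtBP")
CONDITIONS = ("wt", "induced")

# Per-mark direction of the planted repression signature: active marks and
# Pol II go down on repressed genes, the heterochromatic mark goes up.
MARK_DIRECTION = {
    "H4Ac": "decrease",
    "H3K27Ac": "decrease",
    "H3K4me1": "decrease",
    "H3K4me3": "decrease",
    "H3K36me3": "decrease",
    "H3K9me3": "increase",
    "PolII": "decrease",
}


def _default_block_width_mean() -> dict[str, float]:
    return {
        "H4Ac": 2500.0,
        "H3K27Ac": 2000.0,
        "H3K4me1": 2000.0,
        "H3K4me3": 1200.0,
        "H3K36me3": 2000.0,
        "H3K9me3": 1500.0,
        "PolII": 1500.0,
    }


def _default_mark_plant_prob() -> dict[str, float]:
    return {
        "H4Ac": 0.85,
        "H3K27Ac": 0.85,
        "H3K4me1": 0.85,
        "H3K4me3": 0.4,
        "H3K36me3": 0.4,
        "H3K9me3": 0.2,
        "PolII": 0.85,
    }


def _default_peak_enrichment() -> dict[str, float]:
    return {"Hairy": 0.85, "Gro": 0.7, "CtBP": 0.5}


def _default_peak_background() -> dict[str, float]:
    return {"Hairy": 0.2, "Gro": 0.15, "CtBP": 0.1}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 583
    class_counts: tuple[int, int, int] = (241, 146, 196)  # repressed/activated/unaffected
    marks: tuple[str, ...] = ALL_MARKS
    bin_size: int = 25
    nb_mean: float = 5.0  # background mean count per bin per replicate
    nb_dispersion: float = 10.0  # NB size parameter per bin
    n_replicates: int = 3
    planted_block_width_mean: dict[str, float] = field(
        default_factory=_default_block_width_mean
    )
    planted_block_width_shape: float = 4.0
    planted_effect_log2fc: float = 1.5
    p_block_given_repressed: float = 0.9  # P(repressed gene responds in chromatin)
    p_block_given_nonrepressed: float = 0.3  # P(nonrepressed gene errantly targeted)
    errant_plant_factor: float = 0.5  # per-mark plant prob multiplier on errant genes
    mark_plant_prob: dict[str, float] = field(default_factory=_default_mark_plant_prob)
    background_block_rate: float = 0.04  # per gene per mark, random direction
    peak_enrichment: dict[str, float] = field(default_factory=_default_peak_enrichment)
    peak_background: dict[str, float] = field(default_factory=_default_peak_background)
    expr_fc_repressed: tuple[float, float] = (2.0, 0.5)  # |log2 FC| ~ N(mu, sd), min 1.2
    # wild-type expression level: lognormal (log-mean, log-sd) per class;
    # repressed genes are well expressed before induction
    wt_expr_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "repressed": (2.0, 1.0),
            "activated": (1.0, 1.0),
            "unaffected": (1.2, 1.2),
        }
    )
    block_center_sd: float = 500.0  # bp around the TSS
    min_block_width: float = 200.0

    def __post_init__(self) -> None:
        if sum(self.class_counts) != self.n_genes:
            raise ValueError("class counts must sum to n_genes")
        for name in ("p_block_given_repressed", "p_block_given_nonrepressed"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(w <= 0 for w in self.planted_block_width_mean.values()):
            raise ValueError("planted block widths must be positive")
        if self.planted_effect_log2fc < 0:
            raise ValueError("planted_effect_log2fc is a magnitude, must be >= 0")

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass(frozen=True)
class PlantedBlock:
    gene_id: str
    mark_id: str
    direction: str
    interval: GenomicInterval


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    labels: dict[str, str]  # gene_id -> repressed/activated/unaffected
    responder: dict[str, bool]  # repressed genes with a planted chromatin response
    errant: dict[str, bool]  # nonrepressed genes with repression-like chromatin
    territories: dict[str, GenomicInterval]
    blocks: list[PlantedBlock]
    peak_genes: dict[str, list[str]]  # factor -> gene_ids carrying >=1 planted peak


@dataclass
class Cohort:
    config: CohortConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    tracks: dict[tuple[str, str], SignalTrack]  # (mark, condition) -> track
    peaksets: dict[str, PeakSet]
    expression: pd.DataFrame
    truth: SyntheticTruth | None = None

    def track(self, mark: str, condition: str) -> SignalTrack:
        return self.tracks[(mark, condition)]


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    # one stream per stage, sub-seeded by fixed offsets from the cohort seed
    return np.random.default_rng([int(config.seed), stage])


def generate_genome(config: CohortConfig) -> tuple[dict[str, int], list[GeneModel]]:
    """Lay out non-overlapping gene territories and gene models on the genome."""
    chrom_sizes, genes, _ = _generate_genome_full(config)
    return chrom_sizes, genes


def _generate_genome_full(
    config: CohortConfig,
) -> tuple[dict[str, int], list[GeneModel], dict[str, GenomicInterval]]:
    """As :func:`generate_genome` but also returning the gene territories.

    Territories tile each chromosome left to right with random widths; the
    gene span sits at a random offset inside its territory with a random
    strand and 1-3 disjoint exons.
    """
    rng = _rng(config, 1)
    chrom_sizes = config.chrom_sizes
    mean_territory = config.genome_length / config.n_genes
    if mean_territory < 2000:
        raise ValueError(
            f"genome too small: {config.n_genes} genes in {config.genome_length} bp"
        )
    # distribute genes over chromosomes, then tile each chromosome exactly
    # with territories whose widths vary ~ +/-20% around the chromosome mean
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    layout: list[tuple[str, GenomicInterval]] = []
    for (chrom, size), n_here in zip(chrom_sizes.items(), per_chrom):
        if n_here == 0:
            continue
        raw = rng.uniform(0.8, 1.2, int(n_here))
        edges = np.round(np.concatenate([[0.0], np.cumsum(raw)]) / raw.sum() * size)
        for j in range(int(n_here)):
            layout.append(
                (chrom, GenomicInterval(chrom, int(edges[j]), int(edges[j + 1])))
            )
    genes: list[GeneModel] = []
    territories: dict[str, GenomicInterval] = {}
    n_digits = len(str(config.n_genes))
    for i, (chrom, territory) in enumerate(layout):
        w = territory.width
        gene_id = f"g{i + 1:0{n_digits}d}"
        glen = int(w * rng.uniform(0.3, 0.6))
        gstart = territory.start + int(rng.integers(0, w - glen))
        span = GenomicInterval(chrom, gstart, gstart + glen)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 1, replace=False))
        bounds = [0, *cuts.tolist(), glen]
        exons = tuple(
            GenomicInterval(chrom, gstart + bounds[2 * j], gstart + bounds[2 * j + 1])
            for j in range(n_ex)
        )
        genes.append(GeneModel(gene_id, span, strand, exons))
        territories[gene_id] = territory
    return chrom_sizes, genes, territories


def _assign_classes(config: CohortConfig, genes: list[GeneModel]) -> dict[str, str]:
    rng = _rng(config, 2)
    n_rep, n_act, n_unaf = config.class_counts
    labels = (
        ["repressed"] * n_rep + ["activated"] * n_act + ["unaffected"] * n_unaf
    )
    order = rng.permutation(config.n_genes)
    return {genes[i].gene_id: labels[k] for k, i in enumerate(order)}


def _snap(x: float, bin_size: int) -> int:
    return int(round(x / bin_size)) * bin_size


def _plant_blocks(
    config: CohortConfig,
    genes: list[GeneModel],
    territories: dict[str, GenomicInterval],
    labels: dict[str, str],
) -> tuple[list[PlantedBlock], dict[str, bool], dict[str, bool]]:
    rng = _rng(config, 3)
    shape = config.planted_block_width_shape
    blocks: list[PlantedBlock] = []
    responder: dict[str, bool] = {}
    errant: dict[str, bool] = {}

    def plant(gene: GeneModel, mark: str, direction: str) -> None:
        mean_w = config.planted_block_width_mean[mark]
        w = rng.gamma(shape, mean_w / shape)
        w = max(w, config.min_block_width)
        center = gene.tss + rng.normal(0.0, config.block_center_sd)
        terr = territories[gene.gene_id]
        bs = config.bin_size
        lo = -(-terr.start // bs) * bs  # territory bounds pulled onto the bin grid
        hi = (terr.end // bs) * bs
        start = max(_snap(center - w / 2, bs), lo)
        end = min(_snap(center + w / 2, bs), hi)
        if end - start < bs:
            mid = min(max(_snap(center, bs), lo), hi - bs)
            start, end = mid, mid + bs
        blocks.append(
            PlantedBlock(gene.gene_id, mark, direction, GenomicInterval(gene.chrom, start, end))
        )

    for gene in genes:
        label = labels[gene.gene_id]
        if label == "repressed":
            responds = rng.random() < config.p_block_given_repressed
            responder[gene.gene_id] = bool(responds)
            factor = 1.0 if responds else 0.0
        else:
            is_errant = rng.random() < config.p_block_given_nonrepressed
            errant[gene.gene_id] = bool(is_errant)
            factor = config.errant_plant_factor if is_errant else 0.0
        for mark in DIFF_MARKS:
            if factor and rng.random() < factor * config.mark_plant_prob[mark]:
                plant(gene, mark, MARK_DIRECTION[mark])
            # class-independent background turnover, random direction
            if rng.random() < config.background_block_rate:
                direction = "decrease" if rng.random() < 0.5 else "increase"
                plant(gene, mark, direction)
    return blocks, responder, errant


def _plant_peaks(
    config: CohortConfig,
    genes: list[GeneModel],
    labels: dict[str, str],
    responder: dict[str, bool],
    errant: dict[str, bool],
) -> tuple[dict[str, PeakSet], dict[str, list[str]]]:
    rng = _rng(config, 4)
    peaksets: dict[str, PeakSet] = {}
    peak_genes: dict[str, list[str]] = {}
    for factor in FACTORS:
        peaks: list[Peak] = []
        carriers: list[str] = []
        p_hi = config.peak_enrichment[factor]
        p_bg = config.peak_background[factor]
        for gene in genes:
            label = labels[gene.gene_id]
            if label == "repressed" and responder.get(gene.gene_id, False):
                p = p_hi
            elif label != "repressed" and errant.get(gene.gene_id, False):
                p = 0.7 * p_hi
            else:
                p = p_bg
            if rng.random() >= p:
                continue
            carriers.append(gene.gene_id)
            n_peaks = 1 + rng.poisson(0.7)
            for _ in range(n_peaks):
                w = rng.uniform(300, 800)
                center = gene.tss + rng.normal(0.0, 300.0)
                start = int(max(0, center - w / 2))
                end = int(min(config.chrom_length, center + w / 2))
                if end <= start:
                    continue
                height = float(rng.lognormal(3.0, 0.5))
                peaks.append(Peak(GenomicInterval(gene.chrom, start, end), height))
        peaksets[factor] = PeakSet(factor_id=factor, peaks=peaks)
        peak_genes[factor] = carriers
    return peaksets, peak_genes


def _draw_expression(
    config: CohortConfig, genes: list[GeneModel], labels: dict[str, str]
) -> pd.DataFrame:
    rng = _rng(config, 5)
    mu, sd = config.expr_fc_repressed
    rows = []
    for gene in genes:
        label = labels[gene.gene_id]
        wt = rng.lognormal(*config.wt_expr_lognormal[label])
        if label == "repressed":
            lfc = max(rng.normal(mu, sd), 1.2)
            fc = 2.0 ** (-lfc)
            p = 10.0 ** (-rng.uniform(1.5, 8.0))
        elif label == "activated":
            lfc = max(rng.normal(mu, sd), 1.2)
            fc = 2.0**lfc
            p = 10.0 ** (-rng.uniform(1.5, 8.0))
        else:
            lfc = float(np.clip(rng.normal(0.0, 0.3), -0.85, 0.85))
            fc = 2.0**lfc
            p = rng.uniform(0.0, 1.0)
        rows.append((gene.gene_id, wt, fc, p))
    return pd.DataFrame(rows, columns=["gene_id", "wt_level", "fold_change", "p_value"])


def _simulate_tracks(
    config: CohortConfig, blocks: list[PlantedBlock]
) -> dict[tuple[str, str], SignalTrack]:
    rng = _rng(config, 6)
    chrom_sizes = config.chrom_sizes
    n_bins = {c: -(-size // config.bin_size) for c, size in chrom_sizes.items()}
    effect = 2.0**config.planted_effect_log2fc
    # per-mark per-bin NB mean multiplier in the induced condition
    induced_mult = {
        mark: {c: np.ones(n, dtype=float) for c, n in n_bins.items()}
        for mark in DIFF_MARKS
    }
    for blk in blocks:
        b0 = blk.interval.start // config.bin_size
        b1 = -(-blk.interval.end // config.bin_size)
        f = 1.0 / effect if blk.direction == "decrease" else effect
        induced_mult[blk.mark_id][blk.interval.chrom][b0:b1] *= f

    r = config.nb_dispersion
    tracks: dict[tuple[str, str], SignalTrack] = {}
    for mark in config.marks:
        for condition in CONDITIONS:
            counts = {}
            for chrom, n in n_bins.items():
                mean = np.full(n, config.nb_mean)
                if condition == "induced" and mark in DIFF_MARKS:
                    mean = mean * induced_mult[mark][chrom]
                p = r / (r + mean)
                counts[chrom] = rng.negative_binomial(
                    r, p[None, :], size=(config.n_replicates, n)
                ).astype(float)
            tracks[(mark, condition)] = SignalTrack(
                mark_id=mark,
                condition=condition,
                bin_size=config.bin_size,
                counts=counts,
                chrom_sizes=dict(chrom_sizes),
            )
    return tracks


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """A cohort with no class signal: zero planted effect, background-rate
    peaks everywhere, class-independent wild-type expression. Useful for
    type-I-error and no-signal classifier checks."""
    cfg = CohortConfig(seed=seed, **overrides)
    cfg.planted_effect_log2fc = 0.0
    cfg.peak_enrichment = dict(cfg.peak_background)
    cfg.wt_expr_lognormal = {k: (1.2, 1.0) for k in cfg.wt_expr_lognormal}
    return cfg


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort (tracks, peaks, expression, truth)."""
    config = config or CohortConfig()
    chrom_sizes, genes, territories = _generate_genome_full(config)
    labels = _assign_classes(config, genes)
    blocks, responder, errant = _plant_blocks(config, genes, territories, labels)
    peaksets, peak_genes = _plant_peaks(config, genes, labels, responder, errant)
    expression = _draw_expression(config, genes, labels)
    tracks = _simulate_tracks(config, blocks)
    truth = SyntheticTruth(
        labels=labels,
        responder=responder,
        errant=errant,
        territories=territories,
        blocks=blocks,
        peak_genes=peak_genes,
    )
    return Cohort(config, dict(chrom_sizes), genes, tracks, peaksets, expression, truth)


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------


def _track_paths(directory: str, mark: str, condition: str, n_reps: int) -> list[str]:
    return [
        os.path.join(directory, f"{mark}_{condition}_rep{i + 1}.bedGraph")
        for i in range(n_reps)
    ]


def write_dataset(cohort: Cohort, directory: str) -> dict[str, object]:
    """Write the cohort as plain-text standard formats plus a truth JSON."""
    os.makedirs(directory, exist_ok=True)
    manifest: dict[str, object] = {"bedgraphs": [], "peaks": {}, "n_replicates": None}
    for (mark, condition), track in cohort.tracks.items():
        paths = _track_paths(directory, mark, condition, track.n_replicates)
        write_tracks(track, paths)
        manifest["bedgraphs"].extend(paths)
        manifest["n_replicates"] = track.n_replicates
    for factor, peakset in cohort.peaksets.items():
        path = os.path.join(directory, f"{factor}_peaks.bed")
        write_peaks(peakset, path)
        manifest["peaks"][factor] = path
    write_genes_gff3(cohort.genes, os.path.join(directory, "genes.gff3"))
    write_expression(cohort.expression, os.path.join(directory, "expression.tsv"))
    if cohort.truth is not None:
        t = cohort.truth
        payload = {
            "labels": t.labels,
            "responder": t.responder,
            "errant": t.errant,
            "territories": {
                g: [iv.chrom, iv.start, iv.end] for g, iv in t.territories.items()
            },
            "blocks": [
                {
                    "gene_id": b.gene_id,
                    "mark_id": b.mark_id,
                    "direction": b.direction,
                    "chrom": b.interval.chrom,
                    "start": b.interval.start,
                    "end": b.interval.end,
                }
                for b in t.blocks
            ],
            "peak_genes": t.peak_genes,
        }
        with open(os.path.join(directory, "truth.json"), "w") as fh:
            json.dump(payload, fh, indent=1)
    with open(os.path.join(directory, "config.json"), "w") as fh:
        cfg = dataclasses.asdict(cohort.config)
        cfg["class_counts"] = list(cfg["class_counts"])
        cfg["marks"] = list(cfg["marks"])
        json.dump(cfg, fh, indent=1)
    return manifest


def read_dataset(directory: str) -> Cohort:
    """Load a cohort written by :func:`write_dataset` back through trackio."""
    with open(os.path.join(directory, "config.json")) as fh:
        cfg = json.load(fh)
    cfg["class_counts"] = tuple(cfg["class_counts"])
    cfg["marks"] = tuple(cfg["marks"])
    config = CohortConfig(**cfg)
    genes = read_genes(os.path.join(directory, "genes.gff3"), format="gff3")
    tracks = {}
    for mark in config.marks:
        for condition in CONDITIONS:
            paths = _track_paths(directory, mark, condition, config.n_replicates)
            tracks[(mark, condition)] = read_tracks(paths, mark, condition)
    peaksets = {
        factor: read_peaks(os.path.join(directory, f"{factor}_peaks.bed"), factor)
        for factor in FACTORS
    }
    expression = read_expression(os.path.join(directory, "expression.tsv"))
    truth = None
    truth_path = os.path.join(directory, "truth.json")
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            payload = json.load(fh)
        truth = SyntheticTruth(
            labels=payload["labels"],
            responder={k: bool(v) for k, v in payload["responder"].items()},
            errant={k: bool(v) for k, v in payload["errant"].items()},
            territories={
                g: GenomicInterval(c, s, e)
                for g, (c, s, e) in payload["territories"].items()
            },
            blocks=[
                PlantedBlock(
                    b["gene_id"],
                    b["mark_id"],
                    b["direction"],
                    GenomicInterval(b["chrom"], b["start"], b["end"]),
                )
                for b in payload["blocks"]
            ],
            peak_genes=payload["peak_genes"],
        )
    chrom_sizes = next(iter(tracks.values())).chrom_sizes
    return Cohort(config, chrom_sizes, genes, tracks, peaksets, expression, truth)
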