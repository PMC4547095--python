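"""Core genomic data model, format readers/writers, and library-size normalization.

Coordinates are 0-based, half-open everywhere inside the package (BED/bedGraph
native). GFF3 is converted on read (start − 1). The TSS of a − strand gene is
``end − 1``, the last base of the half-open span.

Signal tracks are stored pre-binned: one non-negative count vector per
chromosome per replicate, at a constant bin size (default 25 bp). Raw read
placement is out of scope; everything downstream consumes binned counts.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class TrackFormatError(ValueError):
    """A standard-format file violated the expectations of its reader."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand, derived TSS, and disjoint exons.

    The TSS is ``interval.start`` on the + strand and ``interval.end − 1``
    on the − strand.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for exon in exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError(f"exon of {self.gene_id} on wrong chromosome")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"exon of {self.gene_id} outside gene span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"exons of {self.gene_id} overlap")
            prev_end = exon.end

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class SignalTrack:
    """Binned replicate read counts for one mark in one condition.

    ``counts`` maps chromosome name to an array of shape
    ``(n_replicates, n_bins)`` with ``n_bins = ceil(chrom_length / bin_size)``.
    """

    mark_id: str
    condition: str
    bin_size: int
    counts: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        n_reps = None
        for chrom, arr in self.counts.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            self.counts[chrom] = arr
            if np.any(arr < 0):
                raise ValueError(f"negative counts on {chrom}")
            if n_reps is None:
                n_reps = arr.shape[0]
            elif arr.shape[0] != n_reps:
                raise ValueError("replicate count differs between chromosomes")
            expected = -(-self.chrom_sizes[chrom] // self.bin_size)
            if arr.shape[1] != expected:
                raise ValueError(
                    f"{chrom}: {arr.shape[1]} bins, expected {expected} "
                    f"(length {self.chrom_sizes[chrom]}, bin {self.bin_size})"
                )

    @property
    def n_replicates(self) -> int:
        return next(iter(self.counts.values())).shape[0]

    @property
    def chroms(self) -> list[str]:
        return list(self.counts)

    @property
    def total_tags(self) -> np.ndarray:
        """Sum of all counts, one value per replicate."""
        return np.sum([arr.sum(axis=1) for arr in self.counts.values()], axis=0)

    def replicate_mean(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].mean(axis=0)

    def density(self, chrom: str) -> np.ndarray:
        """Replicate-mean signal per bp, one value per bin."""
        return self.replicate_mean(chrom) / self.bin_size

    def cumulative_tags(self, chrom: str) -> np.ndarray:
        """Prefix sums of replicate-mean bin counts (length n_bins + 1)."""
        return np.concatenate([[0.0], np.cumsum(self.replicate_mean(chrom))])

    def tags_in(self, chrom: str, start: int, end: int) -> float:
        """Replicate-mean tags in ``[start, end)``, pro-rating partial bins."""
        cum = self.cumulative_tags(chrom)
        dens = self.replicate_mean(chrom) / self.bin_size
        n_bins = len(dens)
        size = self.chrom_sizes[chrom]
        start = int(np.clip(start, 0, size))
        end = int(np.clip(end, 0, size))
        if end <= start:
            return 0.0

        def cum_at(pos: int) -> float:
            b = min(pos // self.bin_size, n_bins - 1)
            return cum[b] + (pos - b * self.bin_size) * dens[b]

        return cum_at(end) - cum_at(start)


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    height: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")


@dataclass
class PeakSet:
    """Called binding peaks for one factor (Hairy, Gro, CtBP, or a mark)."""

    factor_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def _parse_bedgraph(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrackFormatError(f"{path}: cannot parse bedGraph: {exc}") from exc
    for col in ("start", "end", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise TrackFormatError(f"{path}: malformed {col} at line {line}")
    if (df["value"] < 0).any():
        line = int((df["value"] < 0).idxmax()) + 1
        raise TrackFormatError(f"{path}: negative value at line {line}")
    return df


def read_tracks(
    paths: str | list[str],
    mark_id: str = "signal",
    condition: str = "wt",
) -> SignalTrack:
    """Read one bedGraph per replicate into a :class:`SignalTrack`.

    Bins must have a single constant size; the final bin of a chromosome may
    be shorter (the chromosome tail). Replicates must agree on binning.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    per_rep: list[dict[str, np.ndarray]] = []
    bin_size = None
    chrom_sizes: dict[str, int] = {}
    for path in paths:
        df = _parse_bedgraph(os.fspath(path))
        chrom_counts: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            widths = (sub["end"] - sub["start"]).to_numpy()
            starts = sub["start"].to_numpy()
            if len(widths) > 1:
                bs = int(widths[0])
                if not (widths[:-1] == bs).all() or widths[-1] > bs:
                    raise TrackFormatError(f"{path}: inconsistent bin size on {chrom}")
            else:
                bs = int(widths[0])
            if bin_size is None:
                bin_size = bs
            elif bs != bin_size:
                raise TrackFormatError(
                    f"{path}: bin size {bs} differs from {bin_size}"
                )
            if not (starts == np.arange(len(starts)) * bin_size).all():
                raise TrackFormatError(f"{path}: non-contiguous bins on {chrom}")
            chrom_counts[chrom] = sub["value"].to_numpy(dtype=float)
            chrom_sizes.setdefault(chrom, int(sub["end"].iloc[-1]))
        per_rep.append(chrom_counts)
    chroms = list(per_rep[0])
    counts = {c: np.vstack([rep[c] for rep in per_rep]) for c in chroms}
    return SignalTrack(
        mark_id=mark_id,
        condition=condition,
        bin_size=int(bin_size),
        counts=counts,
        chrom_sizes=chrom_sizes,
    )


def write_tracks(track: SignalTrack, paths: str | list[str]) -> list[str]:
    """Write one 4-column bedGraph per replicate; inverse of :func:`read_tracks`."""
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    if len(paths) != track.n_replicates:
        raise ValueError(
            f"{track.n_replicates} replicates but {len(paths)} output paths"
        )
    out = []
    for rep, path in enumerate(paths):
        frames = []
        for chrom in track.chroms:
            vals = track.counts[chrom][rep]
            starts = np.arange(len(vals)) * track.bin_size
            ends = np.minimum(starts + track.bin_size, track.chrom_sizes[chrom])
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": vals}
                )
            )
        pd.concat(frames).to_csv(path, sep="\t", header=False, index=False)
        out.append(os.fspath(path))
    return out


def normalize_track(track: SignalTrack, target_total: float = 1e7) -> SignalTrack:
    """Scale every replicate to ``target_total`` total tags (default 10 million).

    Each replicate is multiplied by ``target_total / total_tags``, so bin
    ratios are conserved and renormalizing is a no-op.
    """
    totals = track.total_tags
    if np.any(totals <= 0):
        raise ValueError(f"{track.mark_id}/{track.condition}: zero-total replicate")
    scale = target_total / totals
    counts = {c: arr * scale[:, None] for c, arr in track.counts.items()}
    return replace(track, counts=counts)


# ---------------------------------------------------------------------------
# Gene models: GFF3 and BED12
# ---------------------------------------------------------------------------


def read_genes(path: str, format: str = "gff3") -> list[GeneModel]:
    """Read gene models (with exons) from GFF3 or BED12."""
    fmt = format.lower()
    if fmt == "gff3":
        return _read_genes_gff3(path)
    if fmt == "bed12":
        return _read_genes_bed12(path)
    raise ValueError(f"unknown gene format {format!r}")


def _read_genes_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise TrackFormatError(
                f"{path}: unknown strand {feat.strand!r} for {feat.id}"
            )
        # GFF3 is 1-based inclusive: convert to 0-based half-open.
        interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
        exons = tuple(
            GenomicInterval(ex.seqid, ex.start - 1, ex.end)
            for ex in db.children(feat, featuretype="exon", order_by="start")
        )
        genes.append(GeneModel(feat.id, interval, feat.strand, exons))
    return sorted(genes, key=lambda g: (g.chrom, g.interval.start))


def _read_genes_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise TrackFormatError(f"{path}: line {lineno}: not BED12")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            if strand not in ("+", "-"):
                raise TrackFormatError(
                    f"{path}: line {lineno}: unknown strand {strand!r}"
                )
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(name, GenomicInterval(chrom, start, end), strand, exons)
            )
    return sorted(genes, key=lambda g: (g.chrom, g.interval.start))


def write_genes_gff3(genes: list[GeneModel], path: str) -> str:
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for g in genes:
        buf.write(
            f"{g.chrom}\tchromcode\tgene\t{g.interval.start + 1}\t{g.interval.end}"
            f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
        )
        for i, ex in enumerate(g.exons, 1):
            buf.write(
                f"{ex.chrom}\tchromcode\texon\t{ex.start + 1}\t{ex.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n"
            )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return os.fspath(path)


def write_genes_bed12(genes: list[GeneModel], path: str) -> str:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or (g.interval,)
            sizes = ",".join(str(e.width) for e in exons)
            offs = ",".join(str(e.start - g.interval.start) for e in exons)
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}"
                f"\t0\t{g.strand}\t{g.interval.start}\t{g.interval.end}\t0"
                f"\t{len(exons)}\t{sizes}\t{offs}\n"
            )
    return os.fspath(path)


# ---------------------------------------------------------------------------
# Peaks (BED5) and expression tables (TSV)
# ---------------------------------------------------------------------------


def read_peaks(path: str, factor_id: str | None = None) -> PeakSet:
    """Read a BED file of peaks; column 5 carries the peak height."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score"],
        usecols=range(5),
        dtype={"chrom": str, "name": str},
    )
    peaks = [
        Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)), float(r.score))
        for r in df.itertuples()
    ]
    fid = factor_id or (df["name"].iloc[0] if len(df) else "peaks")
    return PeakSet(factor_id=fid, peaks=peaks)


def write_peaks(peakset: PeakSet, path: str) -> str:
    with open(path, "w") as fh:
        for p in peakset.peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peakset.factor_id}\t{p.height:g}\n"
            )
    return os.fspath(path)


EXPRESSION_COLUMNS = ["gene_id", "wt_level", "fold_change", "p_value"]


def read_expression(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise TrackFormatError(f"{path}: missing expression columns {sorted(missing)}")
    return df


def write_expression(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False)
    return os.fspath(path)
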