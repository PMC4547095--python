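"""End-to-end pipeline driver: simulate -> normalize -> call blocks ->
annotate -> co-occurrence -> features -> classify.

Stages communicate through files in standard formats inside the output
directory, so each intermediate is independently re-readable by the module
that owns its type. A run manifest records seeds, parameters and content
digests; reruns with the same config are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .annotate import annotate_regions, link_hairy_bound
from .diffblocks import DetectorConfig, call_blocks_all_marks, write_blocks_bed
from .features import build_feature_table
from .ml import MLConfig, prediction_report, run_grid
from .overlap import cooccurrence_matrix
from .simulate import DIFF_MARKS, Cohort, CohortConfig, generate_cohort, write_dataset
from .trackio import normalize_track

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    ml: MLConfig = field(default_factory=MLConfig)
    out_dir: str = "chromcode_run"
    write_cohort: bool = False  # also dump bedGraphs/BED/GFF3 of the cohort

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            cohort=CohortConfig(**raw.get("cohort", {})),
            detector=DetectorConfig(**raw.get("detector", {})),
            ml=MLConfig(**raw.get("ml", {})),
            out_dir=raw.get("out_dir", "chromcode_run"),
            write_cohort=bool(raw.get("write_cohort", False)),
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage, write artifacts under ``config.out_dir``, and return
    the manifest (also written as ``manifest.json``)."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    stage = "simulate"
    try:
        cohort: Cohort = generate_cohort(config.cohort)
        if config.write_cohort:
            write_dataset(cohort, os.path.join(out, "cohort"))

        stage = "normalize"
        normalized = {key: normalize_track(t) for key, t in cohort.tracks.items()}

        stage = "diffblocks"
        marks = [m for m in cohort.config.marks if m != "input"]
        blocks = call_blocks_all_marks(normalized, marks, config.detector)
        for mark, blist in blocks.items():
            write_blocks_bed(blist, os.path.join(out, f"blocks_{mark}.bed"))

        stage = "annotate"
        rows = []
        hairy = cohort.peaksets["Hairy"]
        for mark, blist in blocks.items():
            if not blist:
                continue
            anns = annotate_regions([b.interval for b in blist], cohort.genes)
            bound = link_hairy_bound([b.interval for b in blist], hairy, cohort.genes)
            for b, a, hb in zip(blist, anns, bound):
                rows.append(
                    {
                        "chrom": b.interval.chrom,
                        "start": b.interval.start,
                        "end": b.interval.end,
                        "mark": mark,
                        "direction": b.direction,
                        "log2fc": round(b.log2fc, 4),
                        "p_value": b.p_value,
                        "gene_id": a.gene_id,
                        "tss_distance": a.tss_distance,
                        "context": a.context,
                        "hairy_bound": hb,
                    }
                )
        annotated = pd.DataFrame(rows)
        annotated.to_csv(os.path.join(out, "annotated_blocks.tsv"), sep="\t", index=False)

        stage = "overlap"
        by_cat = {
            f"{mark}_{direction}": [
                b.interval for b in blist if b.direction == direction
            ]
            for mark, blist in blocks.items()
            for direction in ("decrease", "increase")
        }
        comat = cooccurrence_matrix(by_cat, cohort.config.genome_length)
        comat.to_csv(os.path.join(out, "cooccurrence_ln_p.tsv"), sep="\t")

        stage = "features"
        diff_blocks = {m: blocks.get(m, []) for m in DIFF_MARKS}
        table = build_feature_table(
            diff_blocks, cohort.peaksets, cohort.expression, cohort.genes
        )
        table.to_csv(os.path.join(out, "feature_table.tsv"), sep="\t")

        stage = "classify"
        records_by_method, report = run_grid(table, config.ml)
        report.to_csv(os.path.join(out, "evaluation.tsv"), sep="\t", index=False)
        preds = prediction_report(records_by_method, table["label"])
        preds.to_csv(os.path.join(out, "predictions.tsv"), sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.cohort.seed,
        "ml_base_seed": config.ml.base_seed,
        "cohort": _jsonable(dataclasses.asdict(config.cohort)),
        "detector": dataclasses.asdict(config.detector),
        "ml": _jsonable(dataclasses.asdict(config.ml)),
        "digests": {
            name: _sha256(os.path.join(out, name))
            for name in sorted(os.listdir(out))
            if os.path.isfile(os.path.join(out, name))
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d artifacts in %s", len(manifest["digests"]), out)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
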