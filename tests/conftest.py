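"""Shared fixtures: hand-built gene models, small cohorts, and the default
benchmark cohorts (5 seeds) reused by the slower end-to-end checks."""

import numpy as np
import pytest

from chromcode.diffblocks import DetectorConfig, call_blocks_all_marks
from chromcode.features import build_feature_table
from chromcode.ml import MLConfig, run_method
from chromcode.simulate import DIFF_MARKS, CohortConfig, generate_cohort
from chromcode.trackio import GeneModel, GenomicInterval, SignalTrack, normalize_track

BENCHMARK_SEEDS = (1, 2, 3, 4, 5)


def make_track(
    values_by_chrom: dict[str, np.ndarray],
    bin_size: int = 25,
    mark: str = "H4Ac",
    condition: str = "wt",
    chrom_sizes: dict[str, int] | None = None,
) -> SignalTrack:
    values_by_chrom = {c: np.atleast_2d(v) for c, v in values_by_chrom.items()}
    sizes = chrom_sizes or {
        c: v.shape[1] * bin_size for c, v in values_by_chrom.items()
    }
    return SignalTrack(mark, condition, bin_size, values_by_chrom, sizes)


@pytest.fixture
def two_gene_models() -> list[GeneModel]:
    fwd = GeneModel(
        "gA",
        GenomicInterval("chr1", 1000, 5000),
        "+",
        (GenomicInterval("chr1", 1000, 1500), GenomicInterval("chr1", 3000, 3600)),
    )
    rev = GeneModel(
        "gB",
        GenomicInterval("chr1", 8000, 9001),
        "-",
        (GenomicInterval("chr1", 8000, 8400),),
    )
    return [fwd, rev]


@pytest.fixture
def small_config() -> CohortConfig:
    return CohortConfig(
        seed=11,
        n_chroms=1,
        chrom_length=400_000,
        n_genes=40,
        class_counts=(16, 10, 14),
    )


@pytest.fixture
def small_cohort(small_config):
    return generate_cohort(small_config)


def _benchmark_run(seed: int) -> dict:
    cohort = generate_cohort(CohortConfig(seed=seed))
    normalized = {k: normalize_track(t) for k, t in cohort.tracks.items()}
    marks = [m for m in cohort.config.marks if m != "input"]
    blocks = call_blocks_all_marks(normalized, marks, DetectorConfig())
    table = build_feature_table(
        {m: blocks.get(m, []) for m in DIFF_MARKS},
        cohort.peaksets,
        cohort.expression,
        cohort.genes,
    )
    return {"cohort": cohort, "blocks": blocks, "table": table, "seed": seed}


@pytest.fixture(scope="session")
def benchmark_runs() -> list[dict]:
    """Default cohorts under seeds 1-5, with called blocks and feature tables."""
    return [_benchmark_run(seed) for seed in BENCHMARK_SEEDS]


@pytest.fixture(scope="session")
def rf_benchmark_records(benchmark_runs) -> list[dict]:
    """Random-forest aggregate predictions (50 iterations) for each seed."""
    out = []
    for run in benchmark_runs:
        records = run_method(
            run["table"],
            "info_gain",
            "random_forest",
            MLConfig(base_seed=run["seed"]),
        )
        out.append({**run, "records": records})
    return out
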