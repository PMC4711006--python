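"""Seeded simulation benchmark: sensitivity / specificity of the full
pipeline across junction coverages, in unguided and guided modes.

One replicate simulates a reference and a 500+500 truth junction set,
then runs the whole pipeline on reads emitted at each requested
coverage. The reference, its k-mer indexes and the truth set are shared
across coverages within a replicate; read sets are independent draws.

Under the default geometry (100 bp error-free reads, 20 bp anchors,
65 bp construct segments, exons >= 120 bp) a junction is recoverable
exactly when at least one of its reads has a donor-side length d in
[35, 65] out of the feasible [1, 99], giving the analytic detectability
law  sensitivity(c) = 1 - (1 - 31/99)^c  used as a whole-pipeline oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .align import AlignConfig
from .discovery import build_transcriptome_index
from .filters import FilterParams
from .pipeline import build_genome_index, run_pipeline
from .simulate import (
    BenchmarkMetrics,
    SimulationConfig,
    sample_truth_junctions,
    score_calls,
    simulate_reads,
    simulate_reference,
)

DETECTABLE_SPAN = 31  # feasible donor-side lengths in [35, 65]
FEASIBLE_SPAN = 99    # donor-side lengths in [1, 99]


def analytic_sensitivity(coverage: int) -> float:
    """Closed-form expected junction recovery at a given coverage."""
    return 1.0 - (1.0 - DETECTABLE_SPAN / FEASIBLE_SPAN) ** coverage


@dataclass
class ReplicateResult:
    seed: int
    metrics: dict[int, BenchmarkMetrics]          # coverage -> unguided metrics
    guided_metrics: dict[int, BenchmarkMetrics] = field(default_factory=dict)


def run_replicate(seed: int,
                  coverages: Sequence[int] = (2, 4, 6, 8, 10),
                  guided_coverages: Sequence[int] = (10,),
                  sim_config: SimulationConfig | None = None,
                  params: FilterParams = FilterParams(),
                  align_config: AlignConfig = AlignConfig()) -> ReplicateResult:
    """One seeded replicate: simulate, run pipeline at each coverage,
    score against truth. Guided mode re-runs evaluation/filtering with
    the construct library produced by the unguided run."""
    if sim_config is None:
        sim_config = SimulationConfig()
    sim_config = replace(sim_config, seed=seed % (2 ** 31))
    genome, transcriptome = simulate_reference(sim_config)
    rng = np.random.default_rng((seed * 7919 + 13) % (2 ** 31))
    truth = sample_truth_junctions(transcriptome, sim_config.n_ptes,
                                   sim_config.n_canonical, rng)
    from .reference import GenomeSource

    genome_src = GenomeSource(genome)
    txome_index = build_transcriptome_index(transcriptome, genome_src)
    genome_index = build_genome_index(genome_src)
    result = ReplicateResult(seed=seed, metrics={})
    for coverage in coverages:
        cfg = replace(sim_config, coverage=coverage)
        read_rng = np.random.default_rng((seed * 104729 + coverage) % (2 ** 31))
        reads = simulate_reads(truth, transcriptome, genome_src, cfg, read_rng)
        run = run_pipeline(reads, transcriptome, genome_src, params, align_config,
                           genome_index=genome_index, txome_index=txome_index)
        result.metrics[coverage] = score_calls(run.called_keys, truth)
        if coverage in guided_coverages:
            guided = run_pipeline(reads, transcriptome, genome_src, params,
                                  align_config, constructs=run.library,
                                  genome_index=genome_index,
                                  txome_index=txome_index)
            result.guided_metrics[coverage] = score_calls(guided.called_keys, truth)
    return result


@dataclass
class BenchmarkSummary:
    replicates: list[ReplicateResult]
    coverages: tuple[int, ...]

    def mean_sensitivity(self, coverage: int, guided: bool = False) -> float:
        vals = [(r.guided_metrics if guided else r.metrics)[coverage].sensitivity
                for r in self.replicates]
        return float(np.mean(vals))

    def mean_specificity(self) -> float:
        vals = [r.metrics[c].specificity
                for r in self.replicates for c in self.coverages]
        return float(np.mean(vals))

    def min_specificity(self) -> float:
        vals = [r.metrics[c].specificity
                for r in self.replicates for c in self.coverages]
        return float(np.min(vals))

    def total_false_positives(self) -> int:
        return sum(r.metrics[c].fp for r in self.replicates for c in self.coverages)


def run_benchmark(seed: int,
                  n_replicates: int = 10,
                  coverages: Sequence[int] = (2, 4, 6, 8, 10),
                  guided_coverages: Sequence[int] = (10,),
                  sim_config: SimulationConfig | None = None,
                  params: FilterParams = FilterParams(),
                  ) -> BenchmarkSummary:
    """Run ``n_replicates`` seeded replicates (seeds derived from
    ``seed``) and aggregate."""
    replicates = []
    for i in range(n_replicates):
        rep_seed = (seed * 1_000_003 + i * 9176 + 1) % (2 ** 31)
        replicates.append(run_replicate(rep_seed, coverages, guided_coverages,
                                        sim_config, params))
    return BenchmarkSummary(replicates=replicates, coverages=tuple(coverages))
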