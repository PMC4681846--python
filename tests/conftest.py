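"""Shared fixtures: the benchmark synthetic mixture and its pipeline run.

The benchmark mixture mirrors the standard study conditions used across
the integration tests: a GC 0.38 target genome mixed with a GC 0.62
contaminant at 10 % of bases, ~1.1 Mb of assembly, mock lineage-annotated
reference database, seed 42.  It is session-scoped because several tests
(classification quality, determinism, partition, strand invariance) probe
the same run.
"""

from __future__ import annotations

import pytest

from prodege import (
    MixtureSpec,
    RunConfig,
    SourceGenomeSpec,
    generate_mixture,
    make_lineage,
    run_prodege,
)
from prodege.pipeline import Resources


def benchmark_spec(seed: int = 42) -> MixtureSpec:
    return MixtureSpec(
        target=SourceGenomeSpec(
            lineage=make_lineage("T"), length=1_100_000, gc=0.38, seed=10
        ),
        contaminants=(
            (
                SourceGenomeSpec(
                    lineage=make_lineage("C1"), length=200_000, gc=0.62, seed=11
                ),
                0.10,
            ),
        ),
        n_contigs=220,
        contig_mu=8.4,
        contig_sigma=0.5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def benchmark_mixture():
    return generate_mixture(benchmark_spec())


@pytest.fixture(scope="session")
def benchmark_report(benchmark_mixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bench_run")
    report = run_prodege(
        benchmark_mixture.assembly,
        benchmark_mixture.target_lineage,
        Resources(ref_db=benchmark_mixture.refdb),
        RunConfig(seed=42),
        outdir=outdir,
    )
    return report, outdir


@pytest.fixture(scope="session")
def small_mixture():
    """A quick ~150 kb mixture for cheap integration tests."""
    return generate_mixture(
        MixtureSpec(
            target=SourceGenomeSpec(
                lineage=make_lineage("T"), length=250_000, gc=0.40, seed=1
            ),
            contaminants=(
                (
                    SourceGenomeSpec(
                        lineage=make_lineage("C1"), length=120_000, gc=0.60, seed=2
                    ),
                    0.15,
                ),
            ),
            n_contigs=50,
            seed=5,
        )
    )
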