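import numpy as np
import pytest

from fishimpute.data import ChromosomeTrace, GenomicAnnotation, TraceCollection
from fishimpute.simulate import SimulationConfig, apply_missingness, simulate_population


def make_annotation(K: int = 60, spacing: int = 25_000, region_id: str = "r1") -> GenomicAnnotation:
    starts = 1 + spacing * np.arange(K, dtype=np.int64)
    return GenomicAnnotation(region_id, "chr1", starts, starts + spacing - 1)


def make_trace(coords, cell="c0", allele="a", region="r1") -> ChromosomeTrace:
    return ChromosomeTrace(cell, allele, region, np.asarray(coords, dtype=float))


@pytest.fixture(scope="session")
def annotation60() -> GenomicAnnotation:
    return make_annotation(60)


@pytest.fixture(scope="session")
def small_population():
    """Complete 80-trace collection (K=30) plus its 30%-masked version."""
    cfg = SimulationConfig(K=30, n_traces=80, n_clusters=2, cluster_strength=0.7,
                           missing_rate=0.3, seed=7)
    complete, labels = simulate_population(cfg)
    masked, truth = apply_missingness(complete, cfg.missing_rate, seed=cfg.seed + 1)
    return masked, truth, labels


@pytest.fixture(scope="session")
def masked_collection(small_population) -> TraceCollection:
    return small_population[0]
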