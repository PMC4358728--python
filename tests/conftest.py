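import numpy as np
import pytest

from soysweep.genotype import GenotypeMatrix, PopulationManifest
from soysweep.simulate import SimConfig, SweepSpec, simulate_populations


def gm_from_calls(
    calls,
    chrom="chr01",
    positions=None,
    samples=None,
    ref=None,
    alt=None,
) -> GenotypeMatrix:
    """Build a matrix from a (samples × sites) call array with defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        samples=list(samples),
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object) if ref is None else np.asarray(ref, dtype=object),
        alt=np.full(n_sites, "G", dtype=object) if alt is None else np.asarray(alt, dtype=object),
        calls=calls,
    )


def two_group_manifest(samples, n_wild):
    """First n_wild samples wild, remainder split landrace/elite."""
    labels = {}
    rest = samples[n_wild:]
    half = len(rest) // 2
    for s in samples[:n_wild]:
        labels[s] = "wild"
    for s in rest[:half]:
        labels[s] = "landrace"
    for s in rest[half:]:
        labels[s] = "elite"
    return PopulationManifest(labels)


@pytest.fixture(scope="session")
def swept_sim():
    """1 Mb genome with one domestication and one improvement sweep."""
    cfg = SimConfig(
        n_chrom=1,
        chrom_length=1_000_000,
        sweep_specs=[
            SweepSpec("chr01", 300_000, 340_000, "domestication"),
            SweepSpec("chr01", 700_000, 740_000, "improvement"),
        ],
        seed=7,
    )
    return simulate_populations(cfg)


@pytest.fixture(scope="session")
def neutral_sim():
    """300 kb genome with no sweeps (pure nested bottlenecks)."""
    cfg = SimConfig(n_chrom=1, chrom_length=300_000, seed=11)
    return simulate_populations(cfg)
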