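"""Shared study configuration for the numbered analysis scripts.

One synthetic resequencing panel stands in for the published accessions:
31 wild, 15 landrace and 24 elite samples over a 2 Mb toy genome, with
two domestication sweeps on chr01 and two improvement sweeps on chr02.
Scripts are run in order; fixtures land in results/data and every stage
writes its tables under results/.
"""

from pathlib import Path

from soysweep.simulate import SimConfig, SweepSpec

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

SEED = 1

STUDY_SWEEPS = [
    SweepSpec("chr01", 300_000, 340_000, "domestication"),
    SweepSpec("chr01", 700_000, 740_000, "domestication"),
    SweepSpec("chr02", 300_000, 340_000, "improvement"),
    SweepSpec("chr02", 700_000, 740_000, "improvement"),
]


def study_config(seed: int = SEED) -> SimConfig:
    return SimConfig(
        n_chrom=2,
        chrom_length=1_000_000,
        sweep_specs=list(STUDY_SWEEPS),
        seed=seed,
    )
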