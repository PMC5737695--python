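"""Shared locations and lazy fixture construction for the analysis
drivers.  The simulated study fixture (BAMs, FASTA, GTF, ground truth)
lives under scratch/; derived tables go to results/."""

from pathlib import Path

from clipscape.pipeline import stage_simulate
from clipscape.simulate import SimConfig

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"

#: the study conditions: 12 genes / ~100 kb, 3 CLIP + 3 input replicates
#: of 50k reads, 16 planted 8-fold clusters with crosslink deletions
STUDY_CFG = SimConfig(seed=0)


def get_fixture():
    """(Re)simulate the study fixture; generation is deterministic, so
    every driver sees byte-identical inputs."""
    RESULTS.mkdir(exist_ok=True)
    FIXTURES.mkdir(parents=True, exist_ok=True)
    return stage_simulate(STUDY_CFG, FIXTURES)
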