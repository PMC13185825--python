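"""Shared paths and the default cohort used across the analysis scripts."""

from pathlib import Path

from repsv.annotate import annotate_cohort
from repsv.simulate import CohortConfig, GenomeModel, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"

#: roomy desk-scale genome: 29 autosomes of 3 Mb + X of 4.5 Mb
GENOME = GenomeModel(
    tuple((str(i), 3_000_000) for i in range(1, 30)) + (("X", 4_500_000),)
)

#: the cohort every script analyses: 30 individuals, 5000 SVs, X-biased
#: placement of large repeat SVs
CONFIG = CohortConfig(seed=17, n_svs=5000, x_bias=3.0)


def load_cohort():
    sim = simulate_cohort(CONFIG, genome=GENOME)
    ann = annotate_cohort(sim.cohort, sim.repeats, sim.genes, sim.metadata)
    return sim, ann


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
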