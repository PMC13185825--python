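#!/usr/bin/env python
"""Generate the synthetic two-subspecies cohort and write its interchange files.

Emits per-individual VCFs, the cohort VCF, repeat annotation (BED and
RepeatMasker-style .out), gene GFF3, sample metadata and the ground-truth
table under results/sim/.
"""

from _shared import CONFIG, GENOME, SIM_DIR, load_cohort
from repsv.simulate import write_cohort

sim, ann = load_cohort()
write_cohort(sim, SIM_DIR)

states = sim.truth["state"].value_counts(normalize=True).round(3)
print(f"cohort: {len(sim.cohort)} SVs, {len(sim.metadata)} individuals "
      f"({(sim.metadata['subspecies'] == 'taurine').sum()} taurine, "
      f"{(sim.metadata['subspecies'] == 'indicine').sum()} indicine, "
      f"{(sim.metadata['subspecies'] == 'hybrid').sum()} hybrid)")
print("evolutionary-state proportions:", states.to_dict())
print(f"repeat track: {len(sim.repeats)} features; genes: {len(sim.genes)} features")
print(f"wrote cohort files to {SIM_DIR}")
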