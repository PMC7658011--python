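"""Generate the synthetic study inputs for the downstream analyses.

Writes a dual-organism count matrix (13,440 host + 300 symbiont genes,
3 generations x 3 pooled replicates, ~0.3% symbiont read share) with 1% of
host genes planted on a geometric decline, plus microscopy sections for
9/10/8 genotypes, a nine-generation transmission program, and tillering
curves. Ground-truth planted gene ids go to a separate file.

Run from the repository root: python analysis/01_simulate_inputs.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from symbiotrend import (
    ColonizationSimParams,
    CountSimParams,
    ProgramSimParams,
    simulate_counts,
    simulate_maintenance_program,
    simulate_sections,
    simulate_tillering,
)
import symbiotrend.io as stio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)

cm, truth = simulate_counts(
    CountSimParams(frac_monotone_down=0.01, decline_factor=0.2,
                   dispersion=0.05, seed=SEED)
)
stio.write_counts(cm, OUT / "counts.tsv", OUT / "design.tsv", OUT / "organisms.tsv")
pd.Series(sorted(truth), name="gene_id").to_csv(OUT / "truth.tsv", sep="\t", index=False)
print(f"counts: {len(cm.gene_ids)} genes x {len(cm.sample_ids)} samples, "
      f"{len(truth)} planted decliners")

sections = simulate_sections(ColonizationSimParams(seed=SEED + 1))
stio.write_sections(sections, OUT / "sections.csv")
print(f"sections: {len(sections)} measurements")

program = simulate_maintenance_program(ProgramSimParams(seed=SEED + 2))
stio.write_transmission(program, OUT / "transmission.csv")
print("program infection rates:", [f"{r.rate:.0%}" for r in program])

tillers = []
for i, gen in enumerate(["G2", "G6", "G9"]):
    tillers += simulate_tillering(genotypes=9, days=30, rate=0.15,
                                  noise_sd=0.05, seed=SEED + 3 + i, generation=gen)
stio.write_tillering(tillers, OUT / "tillering.csv")
print(f"tillering: {len(tillers)} observations -> {OUT}")
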