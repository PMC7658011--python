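"""Seed-transmission rates and tillering phenotype of the synthetic program.

Estimates per-generation infection rates with exact binomial CIs from the
simulated maintenance program, and checks the tillering curves for
generation differences (none are planted, so the rank test should be null).

Run after 01_simulate_inputs.py: python analysis/04_transmission.py
"""

from pathlib import Path

import symbiotrend.io as stio
from symbiotrend import tillering_curve, transmission_estimate

IN = Path("results/synthetic")
OUT = Path("results/transmission")
OUT.mkdir(parents=True, exist_ok=True)

records = stio.read_transmission(IN / "transmission.csv")
rates = transmission_estimate(records)
rates.to_csv(OUT / "rates.tsv", sep="\t", index=False)
print(rates.to_string(index=False,
                      formatters={"rate": "{:.2%}".format,
                                  "ci_low": "{:.2%}".format,
                                  "ci_high": "{:.2%}".format}))

till = tillering_curve(stio.read_tillering(IN / "tillering.csv"))
till["curves"].to_csv(OUT / "tillering_curves.tsv", sep="\t")
test = till["test"]
print(f"tillering final counts across generations: KW H={test.statistic:.2f} "
      f"df={test.df} p={test.p_value:.3f}")
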