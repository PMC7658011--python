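"""Colonization phenotyping of the synthetic microscopy sections.

Summarizes hyphal counts, diameters and the biovolume index per genotype,
tests generation differences with Kruskal-Wallis on per-genotype means,
reports percent declines from the first generation, and runs the vascular
bundle chi-square on pooled hyphal counts.

Run after 01_simulate_inputs.py: python analysis/03_colonization.py
"""

import dataclasses
from pathlib import Path

import pandas as pd

import symbiotrend.io as stio
from symbiotrend import (
    generation_means,
    kruskal_wallis,
    percent_change,
    summarize_genotypes,
    vascular_chi_square,
)

IN = Path("results/synthetic")
OUT = Path("results/colonization")
OUT.mkdir(parents=True, exist_ok=True)

measurements = stio.read_sections(IN / "sections.csv")
genos = summarize_genotypes(measurements)
pd.DataFrame([dataclasses.asdict(g) for g in genos]).to_csv(
    OUT / "genotype_summaries.tsv", sep="\t", index=False
)

rows = []
for attr, label in [("mean_count", "hyphal count"),
                    ("mean_diameter_um", "hyphal diameter"),
                    ("mean_biovolume_index", "biovolume index")]:
    by_gen: dict[str, list[float]] = {}
    for g in genos:
        by_gen.setdefault(g.generation, []).append(getattr(g, attr))
    test = kruskal_wallis(list(by_gen.values()))
    means = generation_means(genos, attr)
    declines = dict(percent_change(means))
    print(f"{label}: means {({g: round(v, 1) for g, v in means.items()})}, "
          f"KW H={test.statistic:.2f} p={test.p_value:.4f}, declines "
          f"{({k: f'{v:.0f}%' for k, v in declines.items()})}")
    rows.append({"measure": label, "H": test.statistic, "df": test.df,
                 "p_value": test.p_value, **{f"decline_{k}": v for k, v in declines.items()}})
pd.DataFrame(rows).to_csv(OUT / "comparisons.tsv", sep="\t", index=False)

chi, freq = vascular_chi_square(measurements)
print(f"vascular colonization: {({g: f'{v:.2%}' for g, v in freq.items()})}, "
      f"chi2={chi.statistic:.2f} df={chi.df} p={chi.p_value:.3f}")
chi.group_summaries.to_csv(OUT / "vascular.tsv", sep="\t")
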