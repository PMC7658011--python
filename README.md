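# symbiotrend

Quantitative analyses for detecting co-adaptation in a novel grass–endophyte
association maintained by selective seed propagation. The package is aimed at
researchers working with *Epichloë*-infected grasses (or any vertically
transmitted symbiont) who track a host population across generations of a
seed maintenance program and ask: did host or symbiont gene expression drift
directionally over time, did fungal colonization change, and did seed
transmission respond to selection?

## What it computes

**Monotone-separation trend test.** For a gene measured in *k* ordered
generations with replicates (n₁,…,n_k; here 3×3), the gene is called
*declining* when every replicate value of each later generation lies strictly
below every replicate value of the preceding one (RPM scale; the statistic is
rank-based). Under exchangeability of continuous values the chance of full
separation is

  p = ∏ⱼ nⱼ! / N!  per direction,  2p for either direction,

which for (3,3,3) is 2/1680 = 1/840. With m genes tested, the expected number
of separated genes by chance is E = m/840; the observed count O is tested by
a Poisson-variance z-test, z = (O − E)/√E, one-sided upper tail, and reported
with an exact two-sided 95% CI on O (Garwood chi-square quantiles, with
Clopper–Pearson over the gene universe as a cross-check). A brute-force
permutation oracle over group labels verifies the analytic null.

**Dual-organism normalization.** Reads per million over the combined
host+symbiont library, optional TMM between-sample factors (trim 30% on M,
5% on A, precision-weighted; validated against edgeR to machine precision),
log₂ median-centering, and the per-sample/per-generation symbiont read share.

**Colonization morphometry.** Per-section hyphal counts and diameters become
a biovolume index (mean per-hypha cross-sectional area π(d/2)² × hyphal
count), averaged per genotype; generations are compared with tie-corrected
Kruskal–Wallis tests on per-genotype means, percent declines from the first
generation, and a Pearson chi-square on the vascular-bundle hyphae table.

**Transmission.** Per-generation infection rates with exact binomial CIs,
plus a generative simulator of the selective open-pollination program in
which each plant carries a heritable seed-transmission probability τ and
parents are selected on tested infection status.

All four input streams have seeded synthetic generators with ground-truth
labels, so every stage is testable without any sequencing data.

## Worked example

```
python analysis/01_simulate_inputs.py     # seeded synthetic inputs
python analysis/02_trend_test.py
python analysis/03_colonization.py
python analysis/04_transmission.py
```

With the default seed the simulator plants 134 of 13,440 host genes on a
five-fold-per-generation decline, and stage 02 prints:

```
observed 157 separated genes (144 down, 13 up) vs 16.4 expected by chance
excess 140.6, z = 34.77, p = 2.93e-265; 95% CI [133.4, 183.6] (~130-180)
symbiont read share by generation: {'G2': '0.3006%', 'G6': '0.2974%', 'G9': '0.3015%'}
recovery of 134 planted decliners: sensitivity 0.99, 12 false positives
```

157 genes fully separate down/up the generation order against ~16 expected
by chance (13,740/840); the detector recovers 99% of the planted decliners,
and the ~12 extra calls match the chance expectation. The symbiont share
stays at the simulated 0.3% of the library. Stage 03 prints the colonization
decline (biovolume means 801 → 538 → 143, i.e. 33% and 82% declines, each
Kruskal–Wallis p < 0.001; vascular frequencies 0.06% → 0.26% → 0.28%), and
stage 04 the transmission rise (80% in G1 climbing to 98% by G9 under
selection on a heritable τ).

The same stages are available as a CLI (`symbiotrend
simulate|trend|colonize|transmit|report`, each with `--out`; see `--help`).

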