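"""Colonization phenotyping: morphometry summaries and generation comparisons.

The biovolume index of a section is the mean hyphal cross-sectional area
(areas computed per hypha as pi*(d/2)^2, then averaged) multiplied by the
section's hyphal count — units um^2 x hyphae. Genotype summaries are
unweighted means over the genotype's sections; generation comparisons use
the rank-based Kruskal-Wallis test on those per-genotype means, and a
Pearson chi-square on the vascular/non-vascular hyphae table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SectionMeasurement, TillerRecord, TransmissionRecord

logger = logging.getLogger("symbiotrend")


@dataclass
class SectionSummary:
    genotype_id: str
    generation: str
    section_index: int
    hyphal_count: int
    mean_diameter_um: float  # nan when no hyphae measured
    mean_area_um2: float
    biovolume_index: float


@dataclass
class ColonizationSummary:
    genotype_id: str
    generation: str
    mean_count: float
    mean_diameter_um: float
    mean_biovolume_index: float


@dataclass
class GenerationComparison:
    statistic_name: str
    statistic: float
    df: int
    p_value: float
    group_summaries: pd.DataFrame


def summarize_section(s: SectionMeasurement, area_from_mean_diameter: bool = False) -> SectionSummary:
    """Per-section morphometry: mean diameter, mean area, biovolume index.

    Areas are computed per hypha and then averaged by default; hyphae are
    treated as circular in cross section. ``area_from_mean_diameter``
    switches to pi*(mean d/2)^2 — Jensen's inequality makes the two differ
    whenever diameters vary. Zero-count sections get biovolume 0 and a
    missing diameter.
    """
    if s.hyphal_count == 0 or not s.diameters_um:
        return SectionSummary(
            s.genotype_id, s.generation, s.section_index, s.hyphal_count,
            mean_diameter_um=float("nan"), mean_area_um2=float("nan"),
            biovolume_index=0.0,
        )
    d = np.asarray(s.diameters_um)
    mean_d = float(d.mean())
    if area_from_mean_diameter:
        mean_area = math.pi * (mean_d / 2) ** 2
    else:
        mean_area = float(np.mean(math.pi * (d / 2) ** 2))
    return SectionSummary(
        s.genotype_id, s.generation, s.section_index, s.hyphal_count,
        mean_diameter_um=mean_d, mean_area_um2=mean_area,
        biovolume_index=mean_area * s.hyphal_count,
    )


def genotype_summary(sections: list[SectionSummary]) -> ColonizationSummary:
    """Unweighted mean over a genotype's sections (normally three).

    The diameter mean skips zero-count sections (their diameter is missing);
    counts and biovolume average over all sections.
    """
    if not sections:
        raise ValueError("no sections to summarize")
    genos = {s.genotype_id for s in sections}
    if len(genos) != 1:
        raise ValueError(f"sections from multiple genotypes: {sorted(genos)}")
    if len(sections) == 1:
        logger.warning("genotype %s: only one section available", sections[0].genotype_id)
    diam = [s.mean_diameter_um for s in sections if not math.isnan(s.mean_diameter_um)]
    return ColonizationSummary(
        genotype_id=sections[0].genotype_id,
        generation=sections[0].generation,
        mean_count=float(np.mean([s.hyphal_count for s in sections])),
        mean_diameter_um=float(np.mean(diam)) if diam else float("nan"),
        mean_biovolume_index=float(np.mean([s.biovolume_index for s in sections])),
    )


def summarize_genotypes(
    measurements: list[SectionMeasurement], area_from_mean_diameter: bool = False
) -> list[ColonizationSummary]:
    """Section summaries grouped and averaged per genotype."""
    by_geno: dict[str, list[SectionSummary]] = {}
    for m in measurements:
        by_geno.setdefault(m.genotype_id, []).append(
            summarize_section(m, area_from_mean_diameter)
        )
    return [genotype_summary(v) for v in by_geno.values()]


def kruskal_wallis(groups: list[list[float]], statistic_name: str = "kruskal_wallis") -> GenerationComparison:
    """Tie-corrected Kruskal-Wallis rank test across k groups.

    All-identical values give H = 0, p = 1 rather than an error (a flat
    phenotype is a result, not a failure).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    df = len(groups) - 1
    flat = [v for g in groups for v in g]
    summaries = pd.DataFrame(
        {
            "n": [len(g) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
            "median": [float(np.median(g)) for g in groups],
            "min": [float(np.min(g)) for g in groups],
            "max": [float(np.max(g)) for g in groups],
        }
    )
    if len(set(flat)) == 1:
        return GenerationComparison(statistic_name, 0.0, df, 1.0, summaries)
    h, p = stats.kruskal(*groups)
    return GenerationComparison(statistic_name, float(h), df, float(p), summaries)


def vascular_chi_square(
    records: list[SectionMeasurement],
) -> tuple[GenerationComparison, pd.Series]:
    """Vascular-bundle colonization frequency per generation + chi-square.

    Frequency = sum(vascular hyphae) / sum(all hyphae) pooled over a
    generation's sections; the test is Pearson's chi-square (no continuity
    correction) on the k x 2 vascular/non-vascular table. Generations with
    zero hyphae are excluded with a warning; small expected cells trigger a
    warning, matching the caveat such sparse tables deserve.
    """
    totals: dict[str, int] = {}
    vasc: dict[str, int] = {}
    for r in records:
        totals[r.generation] = totals.get(r.generation, 0) + r.hyphal_count
        vasc[r.generation] = vasc.get(r.generation, 0) + r.vascular_hyphae
    gens = [g for g in totals if totals[g] > 0]
    dropped = [g for g in totals if totals[g] == 0]
    if dropped:
        logger.warning("generations with zero hyphae excluded from chi-square: %s", dropped)
    if len(gens) < 2:
        raise ValueError("need >= 2 generations with hyphae for the chi-square test")
    freq = pd.Series({g: vasc[g] / totals[g] for g in gens}, name="vascular_frequency")
    table = np.array([[vasc[g], totals[g] - vasc[g]] for g in gens])
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        logger.warning("chi-square expected cell < 5; test is approximate at these frequencies")
    summaries = pd.DataFrame(
        {"total_hyphae": [totals[g] for g in gens],
         "vascular_hyphae": [vasc[g] for g in gens],
         "frequency": freq.values},
        index=gens,
    )
    return GenerationComparison("vascular_chi_square", float(chi2), int(df), float(p), summaries), freq


def percent_change(means: dict[str, float], baseline: str | None = None) -> list[tuple[str, float]]:
    """Percent decline of each generation mean relative to the baseline.

    decline(a -> b) = (mean_a - mean_b) / mean_a * 100; negative values are
    increases. Baseline defaults to the first generation in the mapping.
    """
    gens = list(means)
    if baseline is None:
        baseline = gens[0]
    base = means[baseline]
    if base <= 0:
        raise ValueError(f"baseline mean for {baseline!r} must be > 0")
    return [
        (f"{baseline}->{g}", (base - means[g]) / base * 100.0)
        for g in gens if g != baseline
    ]


def generation_means(summaries: list[ColonizationSummary], attr: str = "mean_biovolume_index") -> dict[str, float]:
    """Generation mean of per-genotype means for a colonization attribute."""
    by_gen: dict[str, list[float]] = {}
    for s in summaries:
        by_gen.setdefault(s.generation, []).append(getattr(s, attr))
    return {g: float(np.mean(v)) for g, v in by_gen.items()}


def transmission_estimate(
    records: list[TransmissionRecord], level: float = 0.95
) -> pd.DataFrame:
    """Per-generation infection rate with exact (Clopper-Pearson) CI."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rows = []
    for r in records:
        ci = stats.binomtest(r.n_infected, r.n_tested).proportion_ci(
            confidence_level=level, method="exact"
        )
        rows.append(
            {
                "generation": r.generation, "n_tested": r.n_tested,
                "n_infected": r.n_infected, "rate": r.rate,
                "ci_low": ci.low, "ci_high": ci.high, "selected": r.selected,
            }
        )
    return pd.DataFrame(rows)


def tillering_curve(records: list[TillerRecord]) -> dict:
    """Tillering phenotype summary across generations.

    Returns per-generation mean curves (mean over genotype means per day),
    each genotype's first-daughter-tiller time (first day the count exceeds
    its day-0 value; missing if it never does), and a Kruskal-Wallis test on
    per-genotype final counts across generations.
    """
    df = pd.DataFrame(
        {
            "genotype_id": [r.genotype_id for r in records],
            "generation": [r.generation for r in records],
            "day": [r.day for r in records],
            "tiller_count": [r.tiller_count for r in records],
        }
    )
    per_geno_day = (
        df.groupby(["generation", "genotype_id", "day"])["tiller_count"].mean().reset_index()
    )
    curves = (
        per_geno_day.groupby(["generation", "day"])["tiller_count"].mean().unstack(level=0)
    )

    first_daughter = {}
    for geno, sub in per_geno_day.groupby("genotype_id"):
        sub = sub.sort_values("day")
        base = sub["tiller_count"].iloc[0]
        grew = sub[sub["tiller_count"] > base]
        first_daughter[geno] = float(grew["day"].iloc[0]) if len(grew) else float("nan")

    finals = per_geno_day.sort_values("day").groupby(["generation", "genotype_id"])["tiller_count"].last()
    groups = [list(v.values) for _, v in finals.groupby(level="generation")]
    if len(groups) >= 2:
        test = kruskal_wallis(groups, statistic_name="tillering_final_count")
    else:
        test = None
    return {"curves": curves, "first_daughter_day": first_daughter, "test": test}
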