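"""Synthetic data generators mirroring the study design.

Three generators cover the three data streams of a seed maintenance
program: pooled-replicate dual-organism RNA-seq counts with an optional
planted fraction of monotone-declining host genes, per-section hyphal
morphometry with declining colonization, and the selective open-pollination
transmission program itself. A fourth produces tiller-count growth curves.

All randomness flows through a single ``numpy.random.Generator`` seeded from
the params, so a fixed seed fixes every output bit-for-bit. Ground-truth
labels (which genes were planted) are returned separately and never written
into the data files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    HOST,
    SYMBIONT,
    CountMatrix,
    DesignTable,
    SampleDesign,
    SectionMeasurement,
    TillerRecord,
    TransmissionRecord,
)

logger = logging.getLogger("symbiotrend")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# RNA-seq counts

@dataclass
class CountSimParams:
    """Parameters of the pooled-replicate dual RNA-seq count simulator.

    Defaults emulate the study conditions: ~13,440 host genes, a small
    symbiont gene set contributing ~0.3% of reads, three generations of
    three pooled replicates, and bulk-RNA-seq-scale libraries.
    """

    n_host_genes: int = 13_440
    n_symbiont_genes: int = 300
    generations: list[tuple[str, int]] = field(
        default_factory=lambda: [("G2", 3), ("G6", 3), ("G9", 3)]
    )
    mean_log_expression: float = 5.0
    sd_log_expression: float = 1.2
    dispersion: float = 0.1
    frac_monotone_down: float = 0.0
    decline_factor: float = 0.5
    symbiont_share_target: float = 0.003
    library_size: int = 20_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_host_genes < 1 or self.n_symbiont_genes < 0:
            raise ValueError("gene counts must be positive")
        if not 0 <= self.frac_monotone_down <= 1:
            raise ValueError("frac_monotone_down must be in [0, 1]")
        if not 0 < self.decline_factor < 1:
            raise ValueError("decline_factor must be in (0, 1)")
        if not 0 < self.symbiont_share_target < 1:
            raise ValueError("symbiont_share_target must be in (0, 1)")
        if any(n < 2 for _, n in self.generations):
            raise ValueError("need >= 2 replicates per generation for separation to mean anything")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def simulate_counts(params: CountSimParams) -> tuple[CountMatrix, set[str]]:
    """Simulate a dual-organism count matrix with planted declining genes.

    Gene means are log-normal. A fraction ``frac_monotone_down`` of host
    genes declines geometrically across generations (multipliers 1, delta,
    delta^2, ...); all other genes are flat. Symbiont gene means are scaled
    so their expected read share hits ``symbiont_share_target``. Counts are
    negative binomial around per-sample expected counts derived from the
    relative expression shares and the library size.

    Returns the matrix and the set of planted (truth) gene ids.
    """
    rng = np.random.default_rng(params.seed)
    n_host, n_sym = params.n_host_genes, params.n_symbiont_genes
    host_ids = [f"host_{i:05d}" for i in range(n_host)]
    sym_ids = [f"sym_{i:04d}" for i in range(n_sym)]

    host_mu = np.exp(rng.normal(params.mean_log_expression, params.sd_log_expression, n_host))
    sym_mu = np.exp(rng.normal(params.mean_log_expression, params.sd_log_expression, n_sym))
    if n_sym > 0:
        # scale symbiont means so E[symbiont share] = target
        target = params.symbiont_share_target
        sym_mu *= (target / (1 - target)) * host_mu.sum() / sym_mu.sum()

    n_planted = int(round(params.frac_monotone_down * n_host))
    if params.frac_monotone_down > 0 and n_planted < 1:
        logger.warning("frac_monotone_down * n_host_genes < 1: no genes planted")
    planted_idx = rng.choice(n_host, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    truth = {host_ids[i] for i in planted_idx}

    designs, columns = [], {}
    for g_idx, (gen, n_rep) in enumerate(params.generations):
        mu_g = np.concatenate([host_mu, sym_mu])
        if n_planted:
            mu_g = mu_g.copy()
            mu_g[planted_idx] *= params.decline_factor ** g_idx
        rel = mu_g / mu_g.sum()
        expected = rel * params.library_size
        for rep in range(1, n_rep + 1):
            sid = f"{gen}_r{rep}"
            designs.append(SampleDesign(sid, gen, rep))
            columns[sid] = _nb_draw(rng, expected, params.dispersion)

    counts = pd.DataFrame(columns, index=host_ids + sym_ids, dtype=np.int64)
    organism = pd.Series(
        [HOST] * n_host + [SYMBIONT] * n_sym, index=host_ids + sym_ids, name="organism"
    )
    design = DesignTable(designs, [g for g, _ in params.generations])
    logger.info(
        "simulated counts: %d host + %d symbiont genes, %d samples, %d planted (seed %d)",
        n_host, n_sym, len(designs), n_planted, params.seed,
    )
    return CountMatrix(counts=counts, organism=organism, design=design), truth


# ---------------------------------------------------------------------------
# microscopy sections

@dataclass
class ColonizationSimParams:
    """Parameters of the per-section morphometry simulator.

    Genotype counts default to the study's 9/10/8 plants for G2/G6/G9 with
    three adjacent sections each. Default per-generation means encode the
    observed colonization decline: hyphal counts dropping ~75% from G2 to
    G9 and slightly thinner hyphae, so that the biovolume index declines by
    roughly a third to G6 and ~80% to G9.
    """

    genotypes_per_generation: dict[str, int] = field(
        default_factory=lambda: {"G2": 9, "G6": 10, "G9": 8}
    )
    sections_per_genotype: int = 3
    count_mean: dict[str, float] = field(
        default_factory=lambda: {"G2": 250.0, "G6": 180.0, "G9": 62.5}
    )
    count_dispersion: float = 0.01
    diameter_mean_um: dict[str, float] = field(
        default_factory=lambda: {"G2": 2.0, "G6": 1.93, "G9": 1.74}
    )
    diameter_sd_um: dict[str, float] = field(
        default_factory=lambda: {"G2": 0.25, "G6": 0.25, "G9": 0.25}
    )
    vascular_rate: dict[str, float] = field(
        default_factory=lambda: {"G2": 0.0004, "G6": 0.0023, "G9": 0.0030}
    )
    max_measured_diameters: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for gen, m in self.count_mean.items():
            if m <= 0:
                raise ValueError(f"count_mean[{gen}] must be > 0")
        for gen, r in self.vascular_rate.items():
            if not 0 <= r <= 1:
                raise ValueError(f"vascular_rate[{gen}] must be in [0, 1]")
        if self.sections_per_genotype < 1:
            raise ValueError("sections_per_genotype must be >= 1")


def simulate_sections(params: ColonizationSimParams) -> list[SectionMeasurement]:
    """Simulate per-section hyphal counts, diameters and vascular hyphae.

    Counts are negative binomial around the generation mean; diameters are
    drawn per hypha from a normal truncated at zero (at most
    ``max_measured_diameters`` per section, mirroring the measured
    subsample); vascular counts are binomial over the section's hyphae.
    """
    rng = np.random.default_rng(params.seed)
    records = []
    for gen, n_geno in params.genotypes_per_generation.items():
        cmean = params.count_mean[gen]
        dmean = params.diameter_mean_um[gen]
        dsd = params.diameter_sd_um[gen]
        vrate = params.vascular_rate[gen]
        for g in range(n_geno):
            geno = f"{gen}_p{g + 1:02d}"
            for s in range(1, params.sections_per_genotype + 1):
                count = int(_nb_draw(rng, np.array(cmean), params.count_dispersion))
                n_meas = min(count, params.max_measured_diameters)
                diam = rng.normal(dmean, dsd, n_meas) if dsd > 0 else np.full(n_meas, dmean)
                diam = np.abs(diam)
                diam[diam == 0] = dmean
                vasc = int(rng.binomial(count, vrate)) if count > 0 else 0
                records.append(
                    SectionMeasurement(
                        genotype_id=geno, generation=gen, tiller_id=f"{geno}_t1",
                        section_index=s, hyphal_count=count,
                        diameters_um=tuple(float(d) for d in diam),
                        vascular_hyphae=vasc,
                    )
                )
    logger.info("simulated %d section measurements (seed %d)", len(records), params.seed)
    return records


# ---------------------------------------------------------------------------
# maintenance program

@dataclass
class ProgramSimParams:
    """Parameters of the selective open-pollination transmission program.

    Each plant carries a seed-transmission probability tau, Beta-distributed
    across the founding population (mean ``tau_mean``, concentration
    ``tau_concentration``). Offspring inherit their parent's tau with weight
    ``heritability_of_tau`` and regress to a fresh population draw
    otherwise. Parents of each generation are the infected offspring of the
    previous one, except in ``unselected_generations`` where infection
    status is ignored.
    """

    n_generations: int = 9
    n_parents: int = 38
    tau_mean: float = 0.76
    tau_concentration: float = 1.0
    heritability_of_tau: float = 1.0
    unselected_generations: frozenset[int] = frozenset({3, 5})
    n_tested_per_generation: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tau_mean < 1:
            raise ValueError("tau_mean must be in (0, 1)")
        if not 0 <= self.heritability_of_tau <= 1:
            raise ValueError("heritability_of_tau must be in [0, 1]")
        if self.tau_concentration <= 0:
            raise ValueError("tau_concentration must be > 0")
        if self.n_parents < 1 or self.n_tested_per_generation < 1:
            raise ValueError("population sizes must be >= 1")


def simulate_maintenance_program(params: ProgramSimParams) -> list[TransmissionRecord]:
    """Simulate infection testing across the selective maintenance program.

    Each generation's offspring draw a random parent from the pool; an
    offspring is endophyte-infected with probability tau(parent). Selection
    (when on) keeps only infected offspring as the next parent pool, which
    enriches for high tau whenever tau is heritable and variable — the
    mechanism by which seed transmission climbs from ~76% toward >95%.
    """
    rng = np.random.default_rng(params.seed)
    a = params.tau_mean * params.tau_concentration
    b = (1 - params.tau_mean) * params.tau_concentration

    parent_tau = rng.beta(a, b, params.n_parents)
    records = []
    h = params.heritability_of_tau
    for gen in range(1, params.n_generations + 1):
        n = params.n_tested_per_generation
        parents = rng.integers(0, len(parent_tau), n)
        fresh = rng.beta(a, b, n)
        child_tau = h * parent_tau[parents] + (1 - h) * fresh
        infected = rng.random(n) < parent_tau[parents]
        selected = gen + 1 not in params.unselected_generations
        records.append(
            TransmissionRecord(
                generation=gen, n_tested=n, n_infected=int(infected.sum()),
                selected=gen not in params.unselected_generations,
            )
        )
        # parent pool for the NEXT generation
        if selected and infected.any():
            parent_tau = child_tau[infected]
        else:
            parent_tau = child_tau
    logger.info(
        "simulated %d-generation program: infection %s (seed %d)",
        params.n_generations,
        [f"{r.rate:.0%}" for r in records], params.seed,
    )
    return records


# ---------------------------------------------------------------------------
# tillering

def simulate_tillering(
    genotypes: int,
    days: int,
    rate: float,
    seed: int = 0,
    generation: str = "G2",
    noise_sd: float = 0.0,
    initial_tillers: int = 3,
) -> list[TillerRecord]:
    """Geometric tiller growth observed every 2 days from 3 initial tillers.

    Expected count on day d is ``initial * (1 + rate)**(d / 2)``; optional
    multiplicative log-normal noise is applied before rounding, and counts
    are made non-decreasing within a genotype (tillers do not disappear).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for g in range(genotypes):
        geno = f"{generation}_p{g + 1:02d}"
        current = float(initial_tillers)
        prev_count = initial_tillers
        for day in range(0, days + 1, 2):
            expect = initial_tillers * (1 + rate) ** (day / 2)
            noisy = expect * (np.exp(rng.normal(0, noise_sd)) if noise_sd > 0 else 1.0)
            count = max(prev_count, int(round(noisy)), 1)
            records.append(TillerRecord(geno, generation, day, count))
            prev_count = count
    return records
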