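"""Monotone-separation trend detection across ordered generations.

The statistic: a gene "declines" when every replicate value of each later
generation lies strictly below every replicate value of the preceding
generation. Under exchangeability of continuous values within a gene, the
chance of full separation in one direction is prod(n_j!) / N!; for the
(3,3,3) design used here that is 1/1680 per direction, 1/840 for either.
The observed number of separated genes is compared to m_tested * p_null with
a Poisson-variance z-test, and the count itself gets an exact confidence
interval (Garwood, with Clopper-Pearson as a cross-check).

Normalization reproduces the conventional RNA-seq chain: reads per million
over the full dual-organism library, optional TMM between-sample scaling
factors, and log2 median-centering. The detector is rank-based, so strictly
monotone transforms of the values (including RPM scaling and log) cannot
change its calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SYMBIONT, CountMatrix, DesignTable, ExpressionMatrix

logger = logging.getLogger("symbiotrend")


# ---------------------------------------------------------------------------
# group design

@dataclass
class GroupDesign:
    """Ordered sample groups (generations) with their replicate sample ids."""

    ordered_groups: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        if len(self.ordered_groups) < 2:
            raise ValueError("need at least 2 ordered groups")
        all_ids: list[str] = []
        for label, ids in self.ordered_groups:
            if len(ids) < 1:
                raise ValueError(f"group {label!r} has no samples")
            all_ids.extend(ids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("sample ids must be disjoint across groups")

    @classmethod
    def from_design(cls, design: DesignTable) -> "GroupDesign":
        by_gen = design.samples_by_generation()
        return cls([(g, ids) for g, ids in by_gen.items()])

    @property
    def group_sizes(self) -> list[int]:
        return [len(ids) for _, ids in self.ordered_groups]

    @property
    def n_total(self) -> int:
        return sum(self.group_sizes)


@dataclass(frozen=True)
class MonotoneCall:
    """Per-gene trend call; ``tied`` marks a tie that defeated separation."""

    gene_id: str
    direction: str  # down | up | none
    tied: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("down", "up", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.tied and self.direction != "none":
            raise ValueError("tied implies direction none")


@dataclass
class TrendTestResult:
    m_tested: int
    observed_down: int
    observed_up: int
    p_null_one_direction: float
    p_null_both: float
    expected: float
    excess: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float

    @property
    def observed(self) -> int:
        return self.observed_down + self.observed_up


# ---------------------------------------------------------------------------
# normalization

def normalize_rpm(cm: CountMatrix) -> ExpressionMatrix:
    """Reads per million over the whole dual-organism library.

    The library size is the column sum over ALL genes, host and symbiont
    together, so host and symbiont RPM shares are directly comparable.
    """
    lib = cm.library_sizes()
    if (lib <= 0).any():
        raise ValueError(f"zero library size: {lib.index[lib <= 0].tolist()}")
    values = cm.counts.div(lib, axis=1) * 1e6
    return ExpressionMatrix(values=values, design=cm.design, scale="rpm",
                            organism=cm.organism)


def tmm_factors(
    cm: CountMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    Each factor is 2**(precision-weighted mean of the log2 expression ratios
    to the reference sample), after trimming the most extreme 30% of
    log-ratios (M) and 5% of average log-expressions (A). Genes with a zero
    count in either member of a pair are excluded from that pair. Factors
    are renormalized to geometric mean 1. The reference defaults to the
    sample whose upper-quartile count fraction is closest to the mean.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes().to_numpy(dtype=float)
    samples = cm.sample_ids
    if len(samples) < 2:
        raise ValueError("TMM needs at least 2 samples")

    if reference is None:
        q75 = np.quantile(counts, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = samples.index(reference)
    ref = counts[:, ref_idx]
    ref_lib = lib[ref_idx]

    factors = np.ones(len(samples))
    for j in range(len(samples)):
        obs = counts[:, j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            raise ValueError(
                f"sample {samples[j]!r} shares no nonzero gene with reference {samples[ref_idx]!r}"
            )
        y, r = obs[keep], ref[keep]
        m = np.log2((y / lib[j]) / (r / ref_lib))
        a = 0.5 * np.log2((y / lib[j]) * (r / ref_lib))
        # delta-method variance of M; weights are reciprocals
        w = (lib[j] - y) / (lib[j] * y) + (ref_lib - r) / (ref_lib * r)
        if np.max(np.abs(m)) < 1e-6:  # effectively identical columns
            factors[j] = 1.0
            continue
        n = len(m)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not trimmed.any() or w[trimmed].sum() == 0:
            factors[j] = 1.0
            continue
        factors[j] = 2 ** (np.sum(m[trimmed] / w[trimmed]) / np.sum(1.0 / w[trimmed]))

    factors /= np.exp(np.mean(np.log(factors)))
    out = pd.Series(factors, index=samples, name="tmm_factor")
    logger.info("TMM reference sample: %s; factors: %s",
                samples[ref_idx], np.round(factors, 4).tolist())
    return out


def apply_tmm(cm: CountMatrix, factors: pd.Series) -> ExpressionMatrix:
    """RPM with TMM-adjusted effective library sizes (library size x factor)."""
    lib = cm.library_sizes() * factors.reindex(cm.sample_ids)
    values = cm.counts.div(lib, axis=1) * 1e6
    return ExpressionMatrix(values=values, design=cm.design, scale="rpm",
                            tmm_factors=factors, organism=cm.organism)


def log_median_center(em: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(rpm + pseudocount), centered on each sample's median.

    A per-sample strictly monotone transform: within-gene orderings across
    samples are preserved up to the per-sample median shift, and the
    detector below is invariant to it at fixed pseudocount.
    """
    if em.scale != "rpm":
        raise ValueError(f"expected rpm-scale input, got {em.scale!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    logged = np.log2(em.values + pseudocount)
    centered = logged - logged.median(axis=0)
    return ExpressionMatrix(
        values=centered, design=em.design, scale="log2_rpm_median_centered",
        pseudocount=pseudocount, tmm_factors=em.tmm_factors, organism=em.organism,
    )


# ---------------------------------------------------------------------------
# monotone separation

def _group_min_max(values: pd.DataFrame, design: GroupDesign):
    """Per-group min and max arrays, genes x groups, in group order."""
    mins, maxs = [], []
    for _, ids in design.ordered_groups:
        sub = values[ids].to_numpy()
        mins.append(sub.min(axis=1))
        maxs.append(sub.max(axis=1))
    return np.column_stack(mins), np.column_stack(maxs)


def detect_monotone(
    em: ExpressionMatrix | pd.DataFrame,
    design: GroupDesign,
    direction: str = "both",
) -> list[MonotoneCall]:
    """Call genes whose replicate values fully separate along group order.

    "down": for every adjacent pair (earlier, later) of groups,
    max(later) < min(earlier), strictly; "up" is the mirror. Equality at any
    boundary defeats both and is flagged as a tie.
    """
    if direction not in ("down", "up", "both"):
        raise ValueError(f"direction must be down/up/both, got {direction!r}")
    values = em.values if isinstance(em, ExpressionMatrix) else em
    for _, ids in design.ordered_groups:
        missing = [s for s in ids if s not in values.columns]
        if missing:
            raise ValueError(f"design samples absent from matrix: {missing}")
    mins, maxs = _group_min_max(values, design)
    # adjacent pairs: earlier j, later j+1
    down = np.all(maxs[:, 1:] < mins[:, :-1], axis=1)
    up = np.all(mins[:, 1:] > maxs[:, :-1], axis=1)
    down_tied = np.all(maxs[:, 1:] <= mins[:, :-1], axis=1) & ~down
    up_tied = np.all(mins[:, 1:] >= maxs[:, :-1], axis=1) & ~up
    tied = down_tied | up_tied

    calls = []
    for i, gene in enumerate(values.index):
        if down[i] and direction in ("down", "both"):
            calls.append(MonotoneCall(gene, "down"))
        elif up[i] and direction in ("up", "both"):
            calls.append(MonotoneCall(gene, "up"))
        else:
            calls.append(MonotoneCall(gene, "none", tied=bool(tied[i])))
    n_tied = int(tied.sum())
    if n_tied:
        logger.info("%d genes had a tie at a group boundary defeating separation", n_tied)
    return calls


def null_probability(group_sizes: list[int], directions: str = "both") -> float:
    """Chance that exchangeable continuous values fully separate by group order.

    One direction: prod(n_j!) / N!. Both: twice that (the up and down
    patterns are disjoint for k >= 2 with continuous values).
    """
    if directions not in ("one", "both"):
        raise ValueError(f"directions must be 'one' or 'both', got {directions!r}")
    if len(group_sizes) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 1 for n in group_sizes):
        raise ValueError("every group size must be >= 1")
    n_total = sum(group_sizes)
    p = math.prod(math.factorial(n) for n in group_sizes) / math.factorial(n_total)
    return 2 * p if directions == "both" else p


def permutation_null(
    em: ExpressionMatrix | pd.DataFrame,
    design: GroupDesign,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo oracle for :func:`null_probability`.

    Shuffles each gene's values across group labels independently and
    recounts full separations (either direction). Returns the empirical
    probability and its binomial standard error over genes x permutations.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    values = em.values if isinstance(em, ExpressionMatrix) else em
    sample_order = [s for _, ids in design.ordered_groups for s in ids]
    arr = values[sample_order].to_numpy(dtype=float)
    n_genes, n_samp = arr.shape
    sizes = design.group_sizes
    edges = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)

    hits = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(1, n_genes * n_samp)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = rng.permuted(
            np.broadcast_to(arr, (b, n_genes, n_samp)).copy(), axis=2
        )
        mins = np.stack([perm[:, :, edges[j]:edges[j + 1]].min(axis=2)
                         for j in range(len(sizes))], axis=2)
        maxs = np.stack([perm[:, :, edges[j]:edges[j + 1]].max(axis=2)
                         for j in range(len(sizes))], axis=2)
        down = np.all(maxs[:, :, 1:] < mins[:, :, :-1], axis=2)
        up = np.all(mins[:, :, 1:] > maxs[:, :, :-1], axis=2)
        hits += int((down | up).sum())
        done += b
    trials = n_perm * n_genes
    p_hat = hits / trials
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-300) / trials)
    logger.info("permutation null: %d/%d separations, p=%.3g (SE %.2g)",
                hits, trials, p_hat, se)
    return p_hat, se


# ---------------------------------------------------------------------------
# excess statistics

def expected_count(m_tested: int, p_null: float) -> float:
    """Number of separated genes expected by chance: m_tested * p_null."""
    if m_tested < 0:
        raise ValueError("m_tested must be >= 0")
    return m_tested * p_null


def excess_test(observed: int, expected: float) -> tuple[float, float, float]:
    """One-sided z-test for an excess of separated genes over chance.

    Rare-event count, so the null variance is Poisson: z = (obs - E)/sqrt(E);
    p is the upper tail of the standard normal.
    """
    if expected <= 0:
        raise ValueError("expected count must be > 0")
    excess = observed - expected
    z = excess / math.sqrt(expected)
    p = float(stats.norm.sf(z))
    return excess, z, p


def exact_count_ci(count: int, level: float = 0.95, method: str = "garwood",
                   m_tested: int | None = None) -> tuple[float, float]:
    """Exact two-sided confidence interval for an observed count.

    ``garwood``: exact Poisson interval via chi-square quantiles,
    low = chi2(alpha/2, 2c)/2, high = chi2(1 - alpha/2, 2c + 2)/2.
    ``clopper_pearson``: exact binomial interval on count/m_tested, scaled
    back to counts; agrees with Garwood to well under one count when the
    gene universe is large (count << m_tested).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1 - level
    if method == "garwood":
        low = 0.0 if count == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * count)
        high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * count + 2)
        return float(low), float(high)
    if method == "clopper_pearson":
        if m_tested is None or m_tested < count:
            raise ValueError("clopper_pearson needs m_tested >= count")
        ci = stats.binomtest(count, m_tested).proportion_ci(
            confidence_level=level, method="exact"
        )
        return ci.low * m_tested, ci.high * m_tested
    raise ValueError(f"unknown method {method!r}")


def round_to_ten(x: float) -> int:
    """Round to the nearest multiple of ten (for report display)."""
    return int(round(x / 10.0) * 10)


def intersect_significant(monotone_ids: set[str], significant_ids: set[str]) -> set[str]:
    """Monotone genes that also pass an external differential-expression call."""
    out = set(monotone_ids) & set(significant_ids)
    logger.info("intersect: %d monotone, %d significant, %d shared",
                len(monotone_ids), len(significant_ids), len(out))
    return out


def trend_test(
    em: ExpressionMatrix,
    design: GroupDesign,
    direction: str = "both",
    level: float = 0.95,
    m_tested: int | None = None,
) -> TrendTestResult:
    """Full trend analysis: calls, chance expectation, excess z-test, exact CI.

    The gene universe m_tested defaults to genes with nonzero total signal
    across all samples (overridable). The expectation uses the
    both-directions null even when only one direction is reported, since the
    chance baseline is for "a consistent increase or decrease".
    """
    calls = detect_monotone(em, design, direction="both")
    totals = em.values.sum(axis=1)
    if m_tested is None:
        m_tested = int((totals > 0).sum())
    observed_down = sum(1 for c in calls if c.direction == "down")
    observed_up = sum(1 for c in calls if c.direction == "up")
    p_one = null_probability(design.group_sizes, "one")
    p_both = null_probability(design.group_sizes, "both")
    expected = expected_count(m_tested, p_both)
    if direction == "down":
        observed = observed_down
    elif direction == "up":
        observed = observed_up
    else:
        observed = observed_down + observed_up
    excess, z, p = excess_test(observed, expected)
    ci_low, ci_high = exact_count_ci(observed, level)
    logger.info(
        "trend test: m=%d, down=%d, up=%d, expected=%.2f, excess=%.2f, z=%.2f, p=%.3g",
        m_tested, observed_down, observed_up, expected, excess, z, p,
    )
    return TrendTestResult(
        m_tested=m_tested, observed_down=observed_down, observed_up=observed_up,
        p_null_one_direction=p_one, p_null_both=p_both, expected=expected,
        excess=excess, z=z, p_value=p, ci_low=ci_low, ci_high=ci_high,
    )


def symbiont_share(cm: CountMatrix) -> tuple[pd.Series, pd.Series]:
    """Fraction of reads assigned to the symbiont, per sample and per generation.

    Returns (per-sample share, per-generation mean share). Host share is the
    complement; shares are computed on raw counts so they equal RPM shares.
    """
    sym = cm.subset_organism(SYMBIONT).sum(axis=0)
    total = cm.library_sizes()
    per_sample = (sym / total).rename("symbiont_share")
    gens = pd.Series({s: cm.design[s].generation for s in cm.sample_ids})
    per_gen = per_sample.groupby(gens).mean()
    per_gen = per_gen.reindex(cm.design.generation_order).rename("symbiont_share")
    return per_sample, per_gen
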