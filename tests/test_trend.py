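import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from symbiotrend import (
    CountMatrix,
    GroupDesign,
    detect_monotone,
    exact_count_ci,
    excess_test,
    expected_count,
    intersect_significant,
    log_median_center,
    normalize_rpm,
    null_probability,
    permutation_null,
    symbiont_share,
    tmm_factors,
    trend_test,
)
from symbiotrend.trend import apply_tmm, round_to_ten


# ---------------------------------------------------------------------------
# combinatorial null

def brute_force_separation_probability(group_sizes, directions="both"):
    """Enumerate all assignments of ranks 1..N into ordered groups and count
    the fully separated ones. Independent of the factorial formula."""
    n_total = sum(group_sizes)
    ranks = set(range(n_total))
    hits = total = 0

    def assignments(remaining, sizes):
        if not sizes:
            yield []
            return
        for combo in itertools.combinations(sorted(remaining), sizes[0]):
            for rest in assignments(remaining - set(combo), sizes[1:]):
                yield [set(combo)] + rest

    for groups in assignments(ranks, list(group_sizes)):
        total += 1
        down = all(max(groups[j + 1]) < min(groups[j]) for j in range(len(groups) - 1))
        up = all(min(groups[j + 1]) > max(groups[j]) for j in range(len(groups) - 1))
        if directions == "both":
            hits += down or up
        else:
            hits += down
    return hits / total, hits, total


@pytest.mark.parametrize(
    "sizes,directions",
    [((3, 3, 3), "both"), ((2, 2), "both"), ((1, 1), "one"), ((2, 3, 4), "both"),
     ((3, 3, 3), "one")],
)
def test_null_probability_matches_enumeration(sizes, directions):
    oracle, hits, total = brute_force_separation_probability(sizes, directions)
    assert null_probability(list(sizes), directions) == pytest.approx(oracle, rel=1e-12)


def test_null_probability_3x3_closed_form():
    """1680 rank partitions of a (3,3,3) design, exactly 2 fully separated."""
    p, hits, total = brute_force_separation_probability((3, 3, 3), "both")
    assert (hits, total) == (2, 1680)
    assert null_probability([3, 3, 3], "both") == pytest.approx(1 / 840)
    assert null_probability([2, 2], "both") == pytest.approx(1 / 3)
    assert null_probability([1, 1], "one") == pytest.approx(0.5)


def test_null_probability_both_is_twice_one_direction():
    for sizes in ([3, 3, 3], [2, 2], [2, 3, 4]):
        assert null_probability(sizes, "both") == pytest.approx(
            2 * null_probability(sizes, "one")
        )


def test_null_probability_rejects_bad_groups():
    with pytest.raises(ValueError):
        null_probability([3], "both")
    with pytest.raises(ValueError):
        null_probability([3, 0], "both")


# ---------------------------------------------------------------------------
# monotone detection

def _em(values, group_design):
    samples = [s for _, ids in group_design.ordered_groups for s in ids]
    return pd.DataFrame([values], index=["g"], columns=samples)


def test_detect_monotone_down_up_and_ties(group_design_3x3):
    down = _em([10, 11, 12, 7, 8, 9, 1, 2, 3], group_design_3x3)
    assert detect_monotone(down, group_design_3x3)[0].direction == "down"
    up = _em([1, 2, 3, 7, 8, 9, 10, 11, 12], group_design_3x3)
    assert detect_monotone(up, group_design_3x3)[0].direction == "up"
    tied = _em([5, 5, 5, 5, 4, 4, 1, 1, 1], group_design_3x3)
    call = detect_monotone(tied, group_design_3x3)[0]
    assert call.direction == "none" and call.tied


def test_detect_monotone_direction_filter(group_design_3x3):
    up = _em([1, 2, 3, 7, 8, 9, 10, 11, 12], group_design_3x3)
    assert detect_monotone(up, group_design_3x3, direction="down")[0].direction == "none"


def test_detect_monotone_null_rate_matches_formula(group_design_3x3):
    """Continuous exchangeable values separate at the analytic rate 1/840."""
    rng = np.random.default_rng(11)
    n = 200_000
    samples = [s for _, ids in group_design_3x3.ordered_groups for s in ids]
    values = pd.DataFrame(rng.normal(size=(n, 9)), columns=samples,
                          index=[f"g{i}" for i in range(n)])
    calls = detect_monotone(values, group_design_3x3)
    hits = sum(1 for c in calls if c.direction != "none")
    p_hat = hits / n
    se = math.sqrt((1 / 840) * (1 - 1 / 840) / n)
    assert abs(p_hat - 1 / 840) < 4 * se


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_detect_monotone_rank_invariant_under_monotone_transform(seed):
    """The detector is a rank statistic: strictly increasing transforms of
    the values leave every call unchanged."""
    rng = np.random.default_rng(seed)
    gd = GroupDesign([("G2", ["a", "b"]), ("G6", ["c", "d"]), ("G9", ["e", "f"])])
    values = pd.DataFrame(rng.integers(0, 6, size=(30, 6)).astype(float),
                          columns=list("abcdef"), index=[f"g{i}" for i in range(30)])
    base = detect_monotone(values, gd)
    for transform in (lambda x: np.exp(x), lambda x: 3 * x + 7, lambda x: x ** 3):
        assert detect_monotone(transform(values), gd) == base


def test_permutation_null_agrees_with_formula(group_design_3x3):
    rng = np.random.default_rng(2)
    samples = [s for _, ids in group_design_3x3.ordered_groups for s in ids]
    values = pd.DataFrame(rng.normal(size=(20, 9)), columns=samples,
                          index=[f"g{i}" for i in range(20)])
    p_hat, se = permutation_null(values, group_design_3x3, n_perm=20_000, seed=3)
    assert abs(p_hat - 1 / 840) < 3 * se


def test_permutation_null_2x2_design():
    gd = GroupDesign([("A", ["a", "b"]), ("B", ["c", "d"])])
    rng = np.random.default_rng(4)
    values = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"),
                          index=[f"g{i}" for i in range(50)])
    p_hat, se = permutation_null(values, gd, n_perm=5_000, seed=5)
    assert abs(p_hat - 1 / 3) < 3 * se


def test_permutation_null_identical_values_never_separate(group_design_3x3):
    samples = [s for _, ids in group_design_3x3.ordered_groups for s in ids]
    values = pd.DataFrame(np.ones((5, 9)), columns=samples,
                          index=[f"g{i}" for i in range(5)])
    p_hat, _ = permutation_null(values, group_design_3x3, n_perm=1_000, seed=0)
    assert p_hat == 0.0


# ---------------------------------------------------------------------------
# normalization

def test_normalize_rpm_scaling_and_conservation(small_counts):
    em = normalize_rpm(small_counts)
    lib = small_counts.library_sizes()
    assert em.values.iloc[0, 0] == pytest.approx(
        small_counts.counts.iloc[0, 0] / lib.iloc[0] * 1e6
    )
    assert np.allclose(em.values.sum(axis=0), 1e6)
    assert em.scale == "rpm"


def test_rpm_closed_form():
    """10 reads in a 1M library is 10 RPM; in a 2M library, 5 RPM."""
    from symbiotrend import DesignTable, SampleDesign

    design = DesignTable(
        [SampleDesign("s1", "G2", 1), SampleDesign("s2", "G2", 2)], ["G2"]
    )
    counts = pd.DataFrame(
        {"s1": [10, 999_990], "s2": [10, 1_999_990]}, index=["gA", "filler"]
    )
    cm = CountMatrix(counts=counts, organism=pd.Series(["host", "host"], index=counts.index),
                     design=design)
    em = normalize_rpm(cm)
    assert em.values.loc["gA", "s1"] == pytest.approx(10.0)
    assert em.values.loc["gA", "s2"] == pytest.approx(5.0)


def test_log_median_center_properties(small_counts):
    em = normalize_rpm(small_counts)
    centered = log_median_center(em, pseudocount=1.0)
    assert centered.scale == "log2_rpm_median_centered"
    assert np.allclose(centered.values.median(axis=0), 0.0)
    with pytest.raises(ValueError):
        log_median_center(em, pseudocount=-0.5)
    # constant matrix centers to all zeros
    const = em.values * 0 + 5.0
    from symbiotrend import ExpressionMatrix
    flat = ExpressionMatrix(values=const, design=em.design, scale="rpm")
    assert np.allclose(log_median_center(flat, 1.0).values, 0.0)


def test_tmm_identical_columns_give_unit_factors(design_3x3):
    rng = np.random.default_rng(0)
    col = rng.integers(1, 1000, 500)
    counts = pd.DataFrame({s: col for s in design_3x3.sample_ids},
                          index=[f"g{i}" for i in range(500)])
    cm = CountMatrix(counts=counts, organism=pd.Series("host", index=counts.index),
                     design=design_3x3)
    f = tmm_factors(cm)
    assert np.allclose(f.values, 1.0)


def test_tmm_pure_depth_difference_absorbed_by_library_size(design_3x3):
    """Doubling every count of a sample changes its library size, not its
    composition, so all M-values to the reference are 0 and factors stay 1."""
    rng = np.random.default_rng(1)
    col = rng.integers(1, 1000, 400)
    cols = {s: col for s in design_3x3.sample_ids}
    cols["G9_r3"] = col * 2
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(400)])
    cm = CountMatrix(counts=counts, organism=pd.Series("host", index=counts.index),
                     design=design_3x3)
    assert np.allclose(tmm_factors(cm).values, 1.0)


def test_tmm_factors_bounded_and_geomean_one(design_3x3):
    rng = np.random.default_rng(2)
    base = np.exp(rng.normal(4, 1, 800))
    cols = {
        s: rng.poisson(base * rng.uniform(0.7, 1.4)) + 1
        for s in design_3x3.sample_ids
    }
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(800)])
    cm = CountMatrix(counts=counts, organism=pd.Series("host", index=counts.index),
                     design=design_3x3)
    f = tmm_factors(cm)
    assert np.all((f.values > 0.5) & (f.values < 2.0))
    assert np.exp(np.mean(np.log(f.values))) == pytest.approx(1.0)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_tmm_matches_edger_oracle(tmp_path, design_3x3):
    """Independent cross-check of the TMM factors against edgeR's
    calcNormFactors on the same matrix."""
    rng = np.random.default_rng(9)
    base = np.exp(rng.normal(4, 1.5, 600))
    cols = {s: rng.poisson(base * rng.uniform(0.6, 1.6)) for s in design_3x3.sample_ids}
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(600)])
    cm = CountMatrix(counts=counts, organism=pd.Series("host", index=counts.index),
                     design=design_3x3)
    ours = tmm_factors(cm)
    counts.to_csv(tmp_path / "c.tsv", sep="\t")
    script = (
        f'x <- as.matrix(read.delim("{tmp_path / "c.tsv"}", row.names=1));'
        'suppressMessages(library(edgeR));'
        'cat(paste(calcNormFactors(x, method="TMM"), collapse=","))'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                         timeout=300)
    assert out.returncode == 0, out.stderr
    edger = np.array([float(v) for v in out.stdout.strip().split(",")])
    np.testing.assert_allclose(ours.values, edger, rtol=1e-8)


def test_apply_tmm_rescales_library(small_counts):
    f = tmm_factors(small_counts)
    em = apply_tmm(small_counts, f)
    assert em.tmm_factors is not None
    lib = small_counts.library_sizes()
    expected = small_counts.counts.iloc[0, 0] / (lib.iloc[0] * f.iloc[0]) * 1e6
    assert em.values.iloc[0, 0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# excess statistics

def test_expected_count_closed_forms():
    assert expected_count(13_440, 1 / 840) == pytest.approx(16.0)
    assert expected_count(840, 1 / 840) == pytest.approx(1.0)
    assert expected_count(0, 1 / 840) == 0.0


def test_excess_test_closed_forms():
    excess, z, p = excess_test(53, 16.0)
    assert excess == pytest.approx(37.0)
    assert z == pytest.approx(37 / 4)
    assert p < 1e-19
    _, z0, p0 = excess_test(16, 16.0)
    assert (z0, p0) == (0.0, pytest.approx(0.5))
    _, z1, p1 = excess_test(20, 16.0)
    assert z1 == pytest.approx(1.0)
    assert p1 == pytest.approx(0.1587, abs=1e-4)
    with pytest.raises(ValueError):
        excess_test(5, 0.0)


def test_excess_test_p_strictly_decreasing_in_observed():
    ps = [excess_test(obs, 16.0)[2] for obs in range(0, 60, 5)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_exact_count_ci_closed_forms():
    low, high = exact_count_ci(53, 0.95)
    assert low == pytest.approx(39.70, abs=0.01)
    assert high == pytest.approx(69.33, abs=0.01)
    low0, high0 = exact_count_ci(0, 0.95)
    assert low0 == 0.0
    assert high0 == pytest.approx(3.689, abs=0.001)
    with pytest.raises(ValueError):
        exact_count_ci(53, 1.2)


def test_exact_count_ci_agrees_with_clopper_pearson_at_large_m():
    g = exact_count_ci(53, 0.95, method="garwood")
    cp = exact_count_ci(53, 0.95, method="clopper_pearson", m_tested=13_440)
    assert abs(g[0] - cp[0]) < 1.0
    assert abs(g[1] - cp[1]) < 1.0


def test_exact_count_ci_coverage_at_poisson_16():
    rng = np.random.default_rng(12)
    lam = 16.0
    draws = rng.poisson(lam, 2000)
    covered = sum(
        1 for c in draws
        if exact_count_ci(int(c))[0] <= lam <= exact_count_ci(int(c))[1]
    )
    assert covered / 2000 >= 0.95


def test_round_to_ten():
    assert round_to_ten(39.70) == 40
    assert round_to_ten(69.33) == 70
    assert round_to_ten(14.9) == 10


def test_intersect_significant():
    assert intersect_significant({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
    assert intersect_significant({"a"}, {"b"}) == set()
    assert intersect_significant({"a", "b"}, {"a", "b", "c"}) == {"a", "b"}


# ---------------------------------------------------------------------------
# integration

def test_trend_test_on_toy_matrix(small_counts, group_design_3x3):
    em = normalize_rpm(small_counts)
    res = trend_test(em, group_design_3x3)
    assert res.m_tested == 4
    assert res.observed_down == 1 and res.observed_up == 1
    assert res.expected == pytest.approx(4 / 840)
    assert res.ci_low <= res.observed <= res.ci_high
    assert res.p_null_both == pytest.approx(2 * res.p_null_one_direction)


def test_symbiont_share_printed_ratio(design_3x3):
    """A sample with 49,404 symbiont and 16,270,827 host reads has a symbiont
    share of ~0.303% of the dual-organism library."""
    counts = pd.DataFrame(
        {s: [16_270_827, 49_404] for s in design_3x3.sample_ids},
        index=["host_all", "sym_all"],
    )
    cm = CountMatrix(
        counts=counts,
        organism=pd.Series(["host", "symbiont"], index=counts.index),
        design=design_3x3,
    )
    per_sample, per_gen = symbiont_share(cm)
    expected = 49_404 / (16_270_827 + 49_404)
    assert np.allclose(per_sample.values, expected)
    assert per_sample.iloc[0] == pytest.approx(0.00303, abs=2e-5)
    assert list(per_gen.index) == ["G2", "G6", "G9"]
    # complement: host share + symbiont share is 1 by construction
    host_share = cm.subset_organism("host").sum() / cm.library_sizes()
    assert np.allclose(host_share + per_sample, 1.0)


def test_symbiont_share_zero_when_all_host(small_counts):
    cm = small_counts
    cm2 = CountMatrix(
        counts=cm.counts,
        organism=pd.Series("host", index=cm.counts.index),
        design=cm.design,
    )
    per_sample, _ = symbiont_share(cm2)
    assert (per_sample == 0).all()
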