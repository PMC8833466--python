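import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from pancdwi import (
    dunn_bonferroni,
    fleiss_kappa,
    friedman,
    kappa_band,
    ks_normality,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------- Wilcoxon

def _brute_force_wilcoxon_p(d):
    """Exhaustive enumeration over all 2^n sign assignments (oracle)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


def test_identical_pairs_degenerate():
    x = np.arange(8.0)
    res = wilcoxon_signed_rank(x, x)
    assert res.p_value == 1.0 and res.n == 0


def test_all_positive_differences_exact_tail():
    """Differences +1..+5: one-sided tail 1/32, two-sided p = 0.0625."""
    res = wilcoxon_signed_rank(np.arange(1.0, 6.0), np.zeros(5), mode="exact")
    assert res.statistic == 15.0
    assert res.p_value == pytest.approx(2 / 32)
    assert res.exact


@given(st.integers(0, 99))
def test_exact_p_equals_exhaustive_enumeration(seed):
    """Exact p equals the brute-force 2^n sign-flip oracle for n <= 10,
    including ties and zero differences."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    x = rng.integers(0, 5, n).astype(float)
    y = rng.integers(0, 5, n).astype(float)
    if np.all(x == y):
        return
    res = wilcoxon_signed_rank(x, y, mode="exact")
    assert res.p_value == pytest.approx(_brute_force_wilcoxon_p(x - y))


def test_asymptotic_matches_scipy_reference():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=60), rng.normal(size=60)
    res = wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(x, y, correction=False, method="approx")
    assert not res.exact
    assert res.p_value == pytest.approx(ref.pvalue)


def test_zero_handling_conventions():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 0.0, 0.0, 0.0])
    drop = wilcoxon_signed_rank(x, y, mode="exact")
    assert drop.n == 3  # the zero difference is discarded
    pratt = wilcoxon_signed_rank(x, y, mode="exact", zero_method="pratt")
    assert pratt.statistic > drop.statistic  # zeros push surviving ranks up


# ---------------------------------------------------------------- Friedman

def _naive_friedman(r):
    """Rank-by-hand oracle with the tie-corrected chi-square formula."""
    r = np.asarray(r, float)
    n, k = r.shape
    ranks = np.array([sps.rankdata(row) for row in r])
    stat = 12.0 / (n * k * (k + 1)) * (ranks.sum(0) ** 2).sum() - 3 * n * (k + 1)
    ties = sum(
        (np.unique(row, return_counts=True)[1] ** 3 - np.unique(row, return_counts=True)[1]).sum()
        for row in r
    )
    corr = 1 - ties / (n * k * (k * k - 1))
    return stat / corr


def test_identical_conditions_give_zero_statistic():
    r = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
    res = friedman(r)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_perfect_ordering_attains_maximum_for_3x3():
    r = np.array([[1, 2, 3], [1, 2, 3], [1, 2, 3]], dtype=float)
    assert friedman(r).statistic == pytest.approx(6.0)


@given(st.integers(0, 49))
def test_friedman_matches_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    r = rng.integers(1, 5, size=(10, 5)).astype(float)
    if all(len(np.unique(row)) == 1 for row in r):
        return
    res = friedman(r)
    assert res.statistic == pytest.approx(_naive_friedman(r))


def test_friedman_matches_scipy_without_ties():
    rng = np.random.default_rng(1)
    r = rng.normal(size=(12, 4))  # continuous -> no ties -> correction = 1
    res = friedman(r)
    ref = sps.friedmanchisquare(*r.T)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


@given(st.integers(0, 19))
def test_friedman_invariant_under_row_monotone_transforms(seed):
    """Rank-based: any strictly monotone per-row transform leaves it fixed."""
    rng = np.random.default_rng(seed)
    r = rng.normal(size=(8, 4))
    transformed = np.vstack([np.exp(row) if i % 2 else row**3 + 5 for i, row in enumerate(r)])
    assert friedman(r).statistic == pytest.approx(friedman(transformed).statistic)


def test_single_condition_rejected():
    with pytest.raises(ValueError):
        friedman(np.ones((5, 1)))


# ---------------------------------------------------------------- Dunn

def test_identical_columns_nothing_significant():
    r = np.tile(np.arange(6.0)[:, None], (1, 4))
    out = dunn_bonferroni(r + np.zeros((6, 4)))
    assert all(x.p_adjusted == 1.0 and not x.significant for x in out)


def test_five_conditions_give_ten_pairs():
    rng = np.random.default_rng(0)
    out = dunn_bonferroni(rng.normal(size=(12, 5)))
    assert len(out) == 10


def test_adjusted_p_bounded_and_alpha_monotone():
    rng = np.random.default_rng(5)
    r = rng.normal(size=(20, 4))
    r[:, 0] += 1.5
    out05 = dunn_bonferroni(r, alpha=0.05)
    out01 = dunn_bonferroni(r, alpha=0.01)
    for a, b in zip(out05, out01):
        raw = 2 * sps.norm.sf(abs(a.z))
        assert raw <= a.p_adjusted <= 1.0
        assert b.significant <= a.significant  # shrinking alpha can only drop pairs


def test_shifted_condition_has_smallest_adjusted_p_matching_permutation_oracle():
    """One shifted condition of five: its pairs carry the smallest adjusted
    p-values, and the z ordering matches a label-permutation oracle."""
    rng = np.random.default_rng(11)
    r = rng.normal(size=(46, 5))
    r[:, 2] += 1.2
    out = dunn_bonferroni(r)
    shifted = sorted(x.p_adjusted for x in out if 2 in x.pair)
    others = sorted(x.p_adjusted for x in out if 2 not in x.pair)
    assert max(shifted) <= min(others)

    # permutation oracle: within-row label shuffles give the null of |z|
    ranks = np.array([sps.rankdata(row) for row in r])
    obs = {x.pair: abs(x.z) for x in out}
    n_perm = 5000
    exceed = {pair: 0 for pair in obs}
    se = np.sqrt(5 * 6 / (6.0 * 46))
    for _ in range(n_perm):
        perm = np.array([rng.permutation(row) for row in ranks])
        mr = perm.mean(0)
        for (i, j), o in obs.items():
            if abs(mr[i] - mr[j]) / se >= o:
                exceed[(i, j)] += 1
    perm_p = {k: v / n_perm for k, v in exceed.items()}
    shifted_perm = max(perm_p[k] for k in perm_p if 2 in k)
    others_perm = min(perm_p[k] for k in perm_p if 2 not in k)
    assert shifted_perm <= others_perm


def test_dunn_needs_three_conditions():
    with pytest.raises(ValueError):
        dunn_bonferroni(np.ones((5, 2)))


# ---------------------------------------------------------------- Fleiss

def test_perfect_agreement_kappa_one():
    counts = np.array([[3, 0], [0, 3], [3, 0], [0, 3]])
    res = fleiss_kappa(counts)
    assert res.kappa == pytest.approx(1.0)
    assert res.band == "almost perfect" and not res.degenerate


def test_toy_tally_matches_hand_computed_value():
    """4 subjects x 3 raters x 2 categories; P-bar = 2/3, Pe = 1/2,
    kappa = (2/3 - 1/2)/(1 - 1/2) = 1/3 (worked by hand)."""
    counts = np.array([[3, 0], [2, 1], [0, 3], [1, 2]])
    assert fleiss_kappa(counts).kappa == pytest.approx(1 / 3)


def test_band_assignment_follows_cutpoints():
    assert kappa_band(0.85) == "almost perfect"
    assert kappa_band(0.80) == "substantial"
    assert kappa_band(0.41) == "moderate"
    assert kappa_band(0.21) == "fair"
    assert kappa_band(0.10) == "slight"
    with pytest.warns(UserWarning):
        assert kappa_band(-0.2) == "slight"


def test_single_category_everywhere_flagged_degenerate():
    counts = np.array([[3, 0], [3, 0], [3, 0]])
    res = fleiss_kappa(counts)
    assert res.kappa == 1.0 and res.degenerate


def test_unequal_rater_counts_rejected():
    with pytest.raises(ValueError):
        fleiss_kappa(np.array([[2, 1], [3, 1]]))


@given(st.integers(0, 19))
def test_kappa_invariant_under_category_relabeling(seed):
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(3, [0.4, 0.3, 0.2, 0.1], size=9)
    perm = rng.permutation(4)
    k1 = fleiss_kappa(counts)
    k2 = fleiss_kappa(counts[:, perm])
    assert k1.kappa == pytest.approx(k2.kappa)


def test_kappa_below_one_when_any_disagreement():
    counts = np.array([[3, 0], [2, 1], [0, 3]])
    assert fleiss_kappa(counts).kappa < 1.0


# ---------------------------------------------------------------- KS

def test_normal_sample_passes_normality():
    rng = np.random.default_rng(12)
    res = ks_normality(rng.normal(3.0, 2.0, 10_000))
    assert res.p_value > 0.05


def test_exponential_sample_fails_normality():
    rng = np.random.default_rng(12)
    x = rng.exponential(1.0, 200)
    assert ks_normality(x).p_value <= 0.001  # Lilliefors table floor
    assert ks_normality(x, variant="ks").p_value < 0.001


def test_ks_distance_equals_hand_enumeration():
    """On 5 points the KS distance is max |ECDF - CDF| at the jumps."""
    x = np.array([-1.2, -0.3, 0.1, 0.8, 2.0])
    res = ks_normality(x, variant="ks")
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    n = len(x)
    d = max(max(np.abs(np.arange(1, n + 1) / n - cdf)), max(np.abs(np.arange(n) / n - cdf)))
    assert res.statistic == pytest.approx(d)


def test_ks_input_validation():
    with pytest.raises(ValueError):
        ks_normality(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        ks_normality(np.ones(10))


def test_wilcoxon_type_one_error_on_exchangeable_null():
    """Null simulations (no effect, n = 46): rejection near the nominal 5%."""
    rng = np.random.default_rng(2024)
    rejections = sum(
        wilcoxon_signed_rank(rng.normal(size=46), rng.normal(size=46)).significant
        for _ in range(1000)
    )
    assert 30 <= rejections <= 75  # generous binomial envelope around 5%
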