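"""Nonparametric statistical battery for paired reader-study comparisons.

Wilcoxon signed-rank (exact sign-flip null or tie-corrected normal
approximation), Friedman with tie correction, Dunn–Bonferroni post hoc on
within-subject ranks, Fleiss' kappa with the conventional interpretation
bands, and normality screening (Lilliefors / plain Kolmogorov–Smirnov).

Conventions (documented, switchable where noted): zero differences are
dropped before ranking (Wilcoxon's original treatment); tied absolute
differences receive mid-ranks; all tests are two-sided; significance is
declared at p <= 0.05 inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

ALPHA = 0.05

KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    band: str
    n_subjects: int
    n_raters: int
    n_categories: int
    degenerate: bool = False  # chance agreement = 1 (single category everywhere)


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple
    z: float
    p_adjusted: float
    significant: bool


def kappa_band(kappa: float) -> str:
    """Map kappa to its agreement band; negative values report 'slight'."""
    if kappa < 0:
        warnings.warn(
            f"kappa = {kappa:.3f} < 0 (worse than chance); reported in the "
            "'slight' band whose scale starts at 0.00",
            stacklevel=2,
        )
        return "slight"
    for cut, name in KAPPA_BANDS:
        if kappa <= cut + 1e-12:
            return name
    return "almost perfect"


def _signflip_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Exact null distribution of the positive-rank sum over all sign flips.

    ``ranks2`` are doubled mid-ranks (integers).  Returns counts over
    W+ ∈ {0 .. sum(ranks2)} computed by dynamic programming, equivalent to
    enumerating all 2**n sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(x, y, mode: str = "auto", zero_method: str = "drop") -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (``zero_method="drop"``) or kept and
    signed-ranked with the others Pratt-style (``"pratt"``).  The exact null
    (all sign flips of the observed mid-ranks) is used when the effective n
    is <= 25 in ``auto`` mode; otherwise the tie-corrected normal
    approximation.  All differences zero yields the degenerate p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    if mode not in ("exact", "asymptotic", "auto"):
        raise ValueError(f"invalid mode {mode!r}")
    d = x - y
    if zero_method == "drop":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValueError(f"invalid zero_method {zero_method!r}")
    n = len(d)
    if n == 0 or np.all(d == 0):
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="wilcoxon", exact=True)

    ranks = sps.rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        ranks, d = ranks[keep], d[keep]
        n = len(d)
    w_plus = float(ranks[d > 0].sum())

    use_exact = mode == "exact" or (mode == "auto" and n <= 25)
    if use_exact:
        ranks2 = np.round(2 * ranks).astype(int)
        dist = _signflip_distribution(ranks2)
        total = dist.sum()
        w2 = int(round(2 * w_plus))
        p_low = dist[: w2 + 1].sum() / total
        p_high = dist[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(statistic=w_plus, p_value=p, n=n, method="wilcoxon", exact=True)

    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestResult(statistic=w_plus, p_value=1.0, n=n, method="wilcoxon", exact=False)
    z = (w_plus - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=w_plus, p_value=p, n=n, method="wilcoxon", exact=False)


def _row_ranks(ratings: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, ratings)


def friedman(ratings) -> TestResult:
    """Friedman chi-square test across >= 2 repeated conditions.

    Within-subject mid-ranks with the tie-corrected chi-square statistic;
    identical columns give statistic 0, p = 1.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("ratings must be a subjects x conditions matrix with >= 2 conditions")
    n, k = r.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    ranks = _row_ranks(r)
    col_sums = ranks.sum(axis=0)
    stat_un = 12.0 / (n * k * (k + 1)) * (col_sums**2).sum() - 3.0 * n * (k + 1)
    ties = 0.0
    for row in r:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:  # every row fully tied -> no information
        return TestResult(statistic=0.0, p_value=1.0, n=n, method="friedman", exact=False)
    stat = stat_un / correction
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df=k - 1))
    return TestResult(statistic=float(stat), p_value=p, n=n, method="friedman", exact=False)


def dunn_bonferroni(ratings, alpha: float = ALPHA) -> list[PosthocResult]:
    """All-pairs Dunn post hoc on Friedman ranks with Bonferroni adjustment.

    z_ij = (mean-rank difference) / sqrt(k(k+1)/(6n)); two-sided p times the
    number of pairs, capped at 1.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 3:
        raise ValueError("post hoc requires >= 3 conditions")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    n, k = r.shape
    mean_ranks = _row_ranks(r).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    out = []
    for i, j in combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
        out.append(PosthocResult(pair=(i, j), z=float(z), p_adjusted=float(p), significant=p <= alpha))
    return out


def fleiss_kappa(counts) -> KappaResult:
    """Fleiss' kappa from a subjects x categories tally matrix.

    Every subject must be rated by the same number of raters m >= 2.  If all
    raters choose a single category for every subject, chance agreement is 1
    and kappa is reported as 1 with the ``degenerate`` flag set.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] < 1:
        raise ValueError("counts must be a subjects x categories matrix")
    if np.any(c < 0) or np.any(c != np.round(c)):
        raise ValueError("counts must be non-negative integers")
    row_sums = c.sum(axis=1)
    m = row_sums[0]
    if m < 2 or np.any(row_sums != m):
        raise ValueError("every subject must have the same rater count m >= 2")
    n_subjects, n_categories = c.shape

    p_cat = c.sum(axis=0) / (n_subjects * m)
    pe = float((p_cat**2).sum())
    if pe >= 1.0 - 1e-12:
        return KappaResult(
            kappa=1.0, band="almost perfect", n_subjects=n_subjects,
            n_raters=int(m), n_categories=n_categories, degenerate=True,
        )
    kappa = float(_sm_fleiss(c, method="fleiss"))
    return KappaResult(
        kappa=kappa, band=kappa_band(kappa), n_subjects=n_subjects,
        n_raters=int(m), n_categories=n_categories,
    )


def ks_normality(x, variant: str = "lilliefors") -> TestResult:
    """Kolmogorov–Smirnov screen against a normal distribution.

    ``lilliefors`` (default) estimates mean/SD from the sample and uses the
    Lilliefors small-sample null; ``ks`` is the plain KS test against the
    normal with sample-estimated moments (anti-conservative, provided for
    completeness).  Lilliefors table p-values are clipped to [0.001, 0.2].
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    if x.std(ddof=0) == 0:
        raise ValueError("sample has zero variance; normality test undefined")
    if variant == "lilliefors":
        stat, p = _lilliefors(x, dist="norm")
        return TestResult(statistic=float(stat), p_value=float(min(p, 1.0)), n=len(x),
                          method="lilliefors", exact=False)
    if variant == "ks":
        res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n=len(x), method="ks", exact=False)
    raise ValueError(f"variant must be 'lilliefors' or 'ks', got {variant!r}")
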