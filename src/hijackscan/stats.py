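"""Statistical tests for viral-vs-metazoan comparisons.

Thin, uniformly-shaped wrappers around scipy.stats: the two-sample
Kolmogorov–Smirnov test (asymptotic p-values — the screens this package
serves compare thousands of linker lengths), upper-tail hypergeometric and
binomial probabilities, the classical paired t test, and ECDF tables for
cumulative-fraction plots of linker lengths.

The "families in which the viral mean is shorter" enrichment is offered in
two parametrizations: a binomial sign test against p0 = 0.5 (the default —
under the null a viral mean is shorter in half the families) and a
hypergeometric draw from a finite pool for users who prefer an urn model.
Both are reported explicitly; neither is silently substituted for the
other. No multiple-testing correction is applied by default; a
Benjamini–Hochberg column is available as opt-in output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DegenerateInputError",
    "ks_two_sample",
    "hypergeometric_tail",
    "sign_enrichment",
    "paired_t",
    "ecdf_table",
    "benjamini_hochberg",
]


class DegenerateInputError(ValueError):
    """The requested statistic is undefined on this input."""


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if not math.isfinite(self.statistic):
            raise ValueError(f"non-finite statistic {self.statistic}")


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample KS test: D is the maximum ECDF distance.

    The p-value uses the asymptotic two-sample Kolmogorov distribution with
    effective size n_a*n_b/(n_a+n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires two nonempty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    p = float(res.pvalue)
    if not math.isfinite(p):  # scipy's asymp mode yields nan at n=1
        en = a.size * b.size / (a.size + b.size)
        p = float(sps.kstwobign.sf(math.sqrt(en) * float(res.statistic)))
    return TestResult(
        "ks_two_sample",
        float(res.statistic),
        min(max(p, 0.0), 1.0),
        int(a.size),
        int(b.size),
    )


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of marked items, n the sample
    size, k the observed number of marked items in the sample.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N:
        raise ValueError(f"inconsistent hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf in log space guards against underflow at extreme tails
    return float(min(1.0, math.exp(sps.hypergeom.logsf(k - 1, N, K, n))))


def sign_enrichment(
    n_families: int,
    n_shorter: int,
    p0: float = 0.5,
    mode: str = "binomial",
    pool: Optional[tuple[int, int]] = None,
) -> TestResult:
    """One-sided enrichment of "viral shorter" outcomes over families.

    Default: binomial sign test, P[X >= n_shorter | Binomial(n_families, p0)].
    With ``mode="hypergeometric"`` the outcomes are drawn without
    replacement from a pool of (K marked, N total) given via ``pool``.
    """
    if not (0 <= n_shorter <= n_families):
        raise ValueError(f"need 0 <= n_shorter <= n_families, got {n_shorter}/{n_families}")
    if mode == "binomial":
        if not (0 < p0 < 1):
            raise ValueError("p0 must be in (0, 1)")
        p = 1.0 if n_shorter == 0 else float(sps.binom.sf(n_shorter - 1, n_families, p0))
        details = {"mode": "binomial", "p0": p0}
    elif mode == "hypergeometric":
        if pool is None:
            raise ValueError("hypergeometric mode requires pool=(K, N)")
        K, N = pool
        p = hypergeometric_tail(n_shorter, K, n_families, N)
        details = {"mode": "hypergeometric", "pool_marked": K, "pool_total": N}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fraction = n_shorter / n_families if n_families else 0.0
    return TestResult(
        "sign_enrichment", fraction, min(max(p, 0.0), 1.0), n_families, n_shorter, details
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Classical paired t test on a - b, two-sided p with n-1 df.

    Identical samples give t = 0, p = 1; constant nonzero differences have
    zero variance and raise :class:`DegenerateInputError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t requires two 1-d samples of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired_t requires at least 2 pairs")
    d = a - b
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if float(d[0]) == 0.0:
            return TestResult("paired_t", 0.0, 1.0, n, n, {"mean_difference": 0.0})
        raise DegenerateInputError(
            "all pairwise differences are identical and nonzero; t is undefined"
        )
    t = float(d.mean()) / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TestResult("paired_t", t, min(p, 1.0), n, n, {"mean_difference": float(d.mean())})


def ecdf_table(values: Sequence[float], grid_max: int) -> list[tuple[int, float]]:
    """Cumulative fraction P[V <= x] on the integer grid 0..grid_max."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("ecdf_table requires a nonempty sample")
    xs = np.arange(grid_max + 1)
    fracs = np.searchsorted(v, xs, side="right") / v.size
    return [(int(x), float(f)) for x, f in zip(xs, fracs)]


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (opt-in output column; not applied by default)."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    _, adjusted, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(q) for q in adjusted]
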