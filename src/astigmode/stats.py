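"""Paired comparison of absolute prediction errors and sample-size planning.

Median absolute errors are compared with the paired Wilcoxon signed-rank
test and mean absolute errors with the paired t-test; Shapiro–Wilk on the
paired differences gates which test a normality-based policy reports.

The a-priori sample size for a paired comparison uses the Guenther-
corrected normal approximation for the paired t,

    n_t = (z_{1−α/2} + z_{power})² · (σ/δ)² + z_{1−α/2}² / 2,

rounded up; for the Wilcoxon signed-rank test n_t is divided by the Pitman
asymptotic relative efficiency 3/π of the signed-rank test against the t
under a normal shift alternative.  For δ = 0.20 D, σ = 0.50 D, α = 0.05,
power = 0.80 this gives 51 (paired t) and 54 (Wilcoxon) eyes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "compare_modes",
    "required_sample_size",
    "PITMAN_ARE_WILCOXON",
]

#: Pitman ARE of the Wilcoxon signed-rank test vs the paired t (normal shift).
PITMAN_ARE_WILCOXON = 3.0 / math.pi

NORMALITY_ALPHA = 0.05
MIN_PAIRS = 6


@dataclass(frozen=True)
class PairedComparison:
    """Result of one paired mode-vs-mode comparison of absolute errors."""

    n: int
    test_used: str              #: "wilcoxon" or "paired_t" (the reported test)
    statistic: float
    p_value: float
    normality_p: float          #: Shapiro–Wilk p on the paired differences
    wilcoxon_statistic: float
    wilcoxon_p: float
    t_statistic: float
    t_p: float
    mean_difference: float
    degenerate: bool = False    #: all paired differences zero


def compare_modes(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    policy: str = "wilcoxon",
) -> PairedComparison:
    """Paired comparison of two per-eye absolute-error vectors.

    ``policy`` selects the reported test: ``"wilcoxon"`` (median
    comparison), ``"paired_t"`` (mean comparison), or ``"normality"``
    (paired t if Shapiro–Wilk does not reject at 0.05, else Wilcoxon).
    Both tests are always computed and carried in the result.  When every
    paired difference is zero the signed-rank statistic is undefined; the
    comparison is flagged degenerate and reported with p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("errors_a and errors_b must be 1-D arrays of equal length")
    n = a.size
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} pairs, got {n}")
    diff = a - b

    if np.all(diff == 0.0):
        return PairedComparison(
            n=n, test_used="wilcoxon", statistic=float("nan"), p_value=1.0,
            normality_p=float("nan"), wilcoxon_statistic=float("nan"),
            wilcoxon_p=1.0, t_statistic=float("nan"), t_p=1.0,
            mean_difference=0.0, degenerate=True,
        )

    # exact signed-rank null for small samples; normal approximation beyond
    method = "exact" if np.count_nonzero(diff) <= 25 else "auto"
    w_stat, w_p = sps.wilcoxon(a, b, alternative="two-sided", method=method)
    near_constant = np.ptp(diff) <= 1e-9 * max(1.0, float(np.abs(diff).max()))
    if near_constant:
        # a constant nonzero shift: normality untestable, t degenerate at ±inf
        shapiro_p = float("nan")
        t_stat, t_p = math.copysign(math.inf, float(diff.mean())), 0.0
    else:
        shapiro_p = float(sps.shapiro(diff).pvalue)
        t_stat, t_p = sps.ttest_rel(a, b)

    if policy == "wilcoxon":
        used, stat, p = "wilcoxon", float(w_stat), float(w_p)
    elif policy == "paired_t":
        used, stat, p = "paired_t", float(t_stat), float(t_p)
    elif policy == "normality":
        if shapiro_p > NORMALITY_ALPHA:
            used, stat, p = "paired_t", float(t_stat), float(t_p)
        else:
            used, stat, p = "wilcoxon", float(w_stat), float(w_p)
    else:
        raise ValueError(f"unknown policy {policy!r}")

    return PairedComparison(
        n=n, test_used=used, statistic=stat, p_value=p, normality_p=shapiro_p,
        wilcoxon_statistic=float(w_stat), wilcoxon_p=float(w_p),
        t_statistic=float(t_stat), t_p=float(t_p),
        mean_difference=float(diff.mean()),
    )


def _paired_t_n(delta: float, sd: float, alpha: float, power: float, method: str) -> float:
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    n_normal = (z_a + z_b) ** 2 * (sd / delta) ** 2
    if method == "normal":
        return n_normal
    if method == "guenther":
        return n_normal + z_a**2 / 2.0
    if method == "noncentral_t":
        # smallest n whose noncentral-t power reaches the target
        n = 2
        while n < 10**7:
            nc = delta / sd * math.sqrt(n)
            crit = sps.t.ppf(1.0 - alpha / 2.0, n - 1)
            achieved = sps.nct.sf(crit, n - 1, nc) + sps.nct.cdf(-crit, n - 1, nc)
            if achieved >= power:
                return float(n)
            n += 1
        raise RuntimeError("sample-size search did not converge")
    raise ValueError(f"unknown sample-size method {method!r}")


def required_sample_size(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    test: str = "paired_t",
    method: str = "guenther",
) -> int:
    """Eyes needed for a paired comparison detecting a shift ``delta`` (D).

    ``test="paired_t"`` rounds the (by default Guenther-corrected) normal
    approximation up; ``test="wilcoxon"`` first divides by the Pitman ARE
    3/π.  ``method`` exposes the uncorrected ``"normal"`` and exact
    ``"noncentral_t"`` variants of the t-based count.
    """
    if not (delta > 0):
        raise ValueError("delta must be > 0 (a zero difference needs infinite n)")
    if not (sd > 0):
        raise ValueError("sd must be > 0")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    n_t = _paired_t_n(delta, sd, alpha, power, method)
    if test == "paired_t":
        return math.ceil(n_t)
    if test == "wilcoxon":
        return math.ceil(n_t / PITMAN_ARE_WILCOXON)
    raise ValueError(f"unknown test {test!r}")
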