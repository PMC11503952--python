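"""Frequentist and default-Bayesian inference for group comparisons.

This module provides the inferential layer used around the oculomotor
pipeline: independent-samples t-tests computed either from raw vectors or
from published summary statistics (n, mean, SD), Jeffreys-Zellner-Siow (JZS)
default Bayes factors for one- and two-sample t designs, and Pearson
correlations with Benjamini-Hochberg false-discovery-rate adjustment within
declared families of comparisons.

The JZS Bayes factor places a zero-centred Cauchy prior with scale ``r``
(default ``sqrt(2)/2``) on the standardized effect size under the
alternative.  Using the scale-mixture representation of the Cauchy — a
normal prior on the effect with variance ``g`` and an inverse-gamma(1/2,
r^2/2) prior on ``g`` — the marginal likelihood of the observed t statistic
under the alternative is a one-dimensional integral over ``g`` which we
evaluate by adaptive quadrature on the log scale.  BF10 > 1 favours the
alternative; by convention BF10 > 3 is "positive" evidence for an effect
and BF10 < 1/3 positive evidence for the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0

__all__ = [
    "GroupSummary",
    "TTestResult",
    "BFResult",
    "CorrelationResult",
    "t_from_summary",
    "t_one_sample",
    "jzs_bf_t",
    "bf_from_summaries",
    "pearson_fdr",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_sided: float
    variant: Literal["welch", "pooled", "one-sample"]


@dataclass(frozen=True)
class BFResult:
    bf10: float
    prior_scale: float
    design: Literal["one-sample", "two-sample"]
    error_estimate: float


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    r: float
    n: int
    p: float
    p_adjusted: float
    family: str = ""


def t_from_summary(
    a: GroupSummary,
    b: GroupSummary,
    variant: Literal["welch", "pooled"] = "welch",
) -> TTestResult:
    """Independent-samples t-test from two (n, mean, SD) summaries.

    ``pooled`` assumes equal variances (df = n1 + n2 - 2); ``welch`` uses
    the Welch-Satterthwaite approximation for the degrees of freedom.
    """
    v1, v2 = a.sd**2, b.sd**2
    if v1 == 0 and v2 == 0:
        if a.mean == b.mean:
            raise ValueError("t undefined: zero variance in both groups with equal means")
        return TTestResult(math.copysign(math.inf, a.mean - b.mean), float("nan"), 0.0, variant)
    if variant == "pooled":
        sp2 = ((a.n - 1) * v1 + (b.n - 1) * v2) / (a.n + b.n - 2)
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = float(a.n + b.n - 2)
    elif variant == "welch":
        se = math.sqrt(v1 / a.n + v2 / b.n)
        df = (v1 / a.n + v2 / b.n) ** 2 / (
            (v1 / a.n) ** 2 / (a.n - 1) + (v2 / b.n) ** 2 / (b.n - 1)
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t, df, p, variant)


def t_one_sample(x: Sequence[float], popmean: float = 0.0) -> TTestResult:
    """One-sample t-test of a vector against ``popmean``."""
    x = np.asarray(x, dtype=float)
    res = stats.ttest_1samp(x, popmean)
    return TTestResult(float(res.statistic), float(len(x) - 1), float(res.pvalue), "one-sample")


def _jzs_log_integrand(u: float, t: float, n_eff: float, df: float, r: float) -> float:
    # g = exp(u); the Jacobian dg = g du contributes +u.  log(1+N*g) and
    # r^2/(2g) are computed without forming exp(u), so the integrand stays
    # finite over the whole (-inf, inf) range the quadrature probes.
    if u < -700.0:  # exp(-u) would overflow; the prior term has killed the mass
        return -math.inf
    log_ng1 = float(np.logaddexp(0.0, u + math.log(n_eff)))
    inv_2g = 0.5 * r * r * math.exp(-u)
    log_prior = math.log(r) - 0.5 * math.log(2.0 * math.pi) - 1.5 * u - inv_2g
    log_lik = -0.5 * log_ng1 - (df + 1.0) / 2.0 * math.log1p(
        t * t / df * math.exp(-log_ng1)
    )
    return log_prior + log_lik + u


def jzs_bf_t(
    t: float,
    n1: int,
    n2: int | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BFResult:
    """Default JZS Bayes factor BF10 from a t statistic.

    One-sample design (``n2 is None``): effective sample size N = n1 and
    df = n1 - 1.  Two-sample design: N = n1*n2/(n1+n2), df = n1 + n2 - 2.
    The marginal likelihood under the alternative is integrated over the
    inverse-gamma mixing distribution of the Cauchy prior; the null marginal
    is the central t density term, so their ratio is the Bayes factor.
    """
    if not math.isfinite(t):
        raise ValueError(f"t must be finite, got {t}")
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("each group needs n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    if n2 is None:
        n_eff, df, design = float(n1), float(n1 - 1), "one-sample"
    else:
        n_eff, df, design = n1 * n2 / (n1 + n2), float(n1 + n2 - 2), "two-sample"

    log_m0 = -(df + 1.0) / 2.0 * math.log1p(t * t / df)
    # Factor the null marginal out of the integrand so the quadrature
    # directly returns the Bayes factor, keeping large BFs in range.
    val, err = integrate.quad(
        lambda u: math.exp(_jzs_log_integrand(u, t, n_eff, df, prior_scale) - log_m0),
        -np.inf,
        np.inf,
        epsabs=1e-10,
        epsrel=1e-10,
        limit=200,
    )
    if val <= 0:
        raise ArithmeticError("quadrature failed: non-positive marginal likelihood")
    return BFResult(bf10=val, prior_scale=prior_scale, design=design, error_estimate=err / val)


def bf_from_summaries(
    a: GroupSummary,
    b: GroupSummary,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BFResult:
    """Two-sample JZS BF10 from summary statistics.

    The t statistic is reconstructed with the pooled-variance formula, the
    convention of default Bayes-factor t-tests on raw data.
    """
    tt = t_from_summary(a, b, variant="pooled")
    return jzs_bf_t(tt.t, a.n, b.n, prior_scale=prior_scale)


def pearson_fdr(
    pairs: Sequence[tuple[Sequence[float], Sequence[float], str]],
    families: Sequence[str] | None = None,
) -> list[CorrelationResult]:
    """Pearson correlations with BH-FDR adjustment within families.

    ``pairs`` is a list of (x, y, label); ``families`` assigns each pair to
    an adjustment family (default: one family for all pairs).  Raw two-sided
    p-values are adjusted by the Benjamini-Hochberg step-up procedure
    separately within each family.
    """
    if families is None:
        families = [""] * len(pairs)
    if len(families) != len(pairs):
        raise ValueError("families must match pairs in length")
    raw: list[CorrelationResult] = []
    for (x, y, label), fam in zip(pairs, families):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.size < 3:
            raise ValueError(f"pair {label!r}: vectors must be equal length >= 3")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"pair {label!r}: zero variance, correlation undefined")
        r, p = stats.pearsonr(x, y)
        raw.append(CorrelationResult(label, float(r), int(x.size), float(p), float("nan"), fam))
    out = list(raw)
    for fam in set(families):
        idx = [i for i, f in enumerate(families) if f == fam]
        _, p_adj, _, _ = multipletests([raw[i].p for i in idx], method="fdr_bh")
        for i, pa in zip(idx, p_adj):
            c = out[i]
            out[i] = CorrelationResult(c.label, c.r, c.n, c.p, float(pa), c.family)
    return out
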