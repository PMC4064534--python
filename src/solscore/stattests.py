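"""Exact and closed-form statistical primitives.

Fisher's exact test for 2x2 contingency tables, the Pearson
product-moment correlation coefficient, and the one-tailed p-value of a
correlation coefficient via the Student t transform

    t = r * sqrt((n - 2) / (1 - r^2)),   df = n - 2.

The t tail is evaluated with a continued-fraction regularised incomplete
beta function, so the core needs no statistical library.

The two-sided Fisher p follows the minimum-likelihood rule: the sum of
hypergeometric probabilities of all tables sharing the observed margins
whose probability does not exceed that of the observed table.  For grand
totals up to 500 the rule is applied with exact integer weights
(rational-arithmetic enumeration); for larger tables probabilities are
computed in log space with a 1e-7 relative tie tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "FisherResult",
    "fisher_exact",
    "pearson_r",
    "one_tailed_p",
    "t_sf",
]

_EXACT_TOTAL_LIMIT = 500
_LOG_TIE_TOL = 1e-7


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher exact p and the sample odds ratio (a*d)/(b*c)."""

    p_two_sided: float
    odds_ratio: float


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact(
    table: tuple[int, int, int, int] | "np.ndarray | list",
    alternative: str = "two-sided",
) -> FisherResult:
    """Fisher's exact test on a 2x2 table ``[[a, b], [c, d]]`` or ``(a,b,c,d)``.

    ``alternative`` is ``two-sided`` (minimum-likelihood rule), ``greater``
    (P of a table at least as extreme towards larger ``a``) or ``less``.
    Any zero row or column margin leaves a single attainable table and
    p = 1.
    """
    flat = np.asarray(table).ravel()
    if flat.size != 4:
        raise ValueError("Fisher test needs a 2x2 table")
    if np.any(flat < 0):
        raise ValueError("counts must be non-negative")
    a, b, c, d = (int(v) for v in flat)
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be >= 1")
    r1, c1 = a + b, a + c
    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    odds = _odds_ratio(a, b, c, d)
    if k_min == k_max:  # degenerate margins: one attainable table
        return FisherResult(p_two_sided=1.0, odds_ratio=odds)

    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    if n <= _EXACT_TOTAL_LIMIT:
        weights = {
            k: math.comb(r1, k) * math.comb(n - r1, c1 - k)
            for k in range(k_min, k_max + 1)
        }
        w_obs = weights[a]
        if alternative == "two-sided":
            num = sum(w for w in weights.values() if w <= w_obs)
        elif alternative == "greater":
            num = sum(w for k, w in weights.items() if k >= a)
        else:
            num = sum(w for k, w in weights.items() if k <= a)
        p = float(Fraction(num, math.comb(n, c1)))
    else:
        ks = np.arange(k_min, k_max + 1)
        from scipy.special import gammaln

        def lchoose(nn, kk):
            return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

        logw = lchoose(r1, ks) + lchoose(n - r1, c1 - ks) - lchoose(n, c1)
        log_obs = float(logw[a - k_min])
        if alternative == "two-sided":
            sel = logw <= log_obs + _LOG_TIE_TOL
        elif alternative == "greater":
            sel = ks >= a
        else:
            sel = ks <= a
        p = float(np.exp(logw[sel]).sum())
    return FisherResult(p_two_sided=min(p, 1.0), odds_ratio=odds)


def pearson_r(xs, ys) -> float:
    """Product-moment correlation coefficient.

    Raises ``ValueError`` on length mismatch, fewer than 3 points, or zero
    variance in either argument (mapped to an ND result upstream).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("undefined correlation: zero variance")
    r = float(xc @ yc) / denom
    return max(-1.0, min(1.0, r))


def _betacf(a: float, b: float, x: float, max_iter: int = 200, eps: float = 3e-14) -> float:
    """Continued fraction for the incomplete beta function (Lentz method)."""
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < 1e-300:
        d = 1e-300
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            return h
    raise ArithmeticError("incomplete beta continued fraction did not converge")


def _betainc(a: float, b: float, x: float) -> float:
    """Regularised incomplete beta function I_x(a, b)."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_front = (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + a * math.log(x)
        + b * math.log1p(-x)
    )
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def t_sf(t: float, df: float) -> float:
    """Upper tail P(T >= t) of Student's t with *df* degrees of freedom."""
    if df <= 0:
        raise ValueError("df must be positive")
    if t == 0.0:
        return 0.5
    x = df / (df + t * t)
    tail = 0.5 * _betainc(0.5 * df, 0.5, x)
    return tail if t > 0 else 1.0 - tail


def one_tailed_p(r: float, n: int) -> float:
    """One-tailed p-value of a correlation coefficient.

    Refers ``t = r * sqrt((n-2)/(1-r^2))`` to the t distribution with
    ``n - 2`` degrees of freedom and returns the tail beyond ``t`` in the
    direction of positive association (so ``r = 0`` gives 0.5 and
    ``one_tailed_p(-r, n) = 1 - one_tailed_p(r, n)``).  The |r| = 1 limit
    returns 0.0 (or 1.0 for r = -1).
    """
    if n < 3:
        raise ValueError("need n >= 3 for a defined p-value")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if r == 1.0:
        return 0.0
    if r == -1.0:
        return 1.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return t_sf(t, n - 2)
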