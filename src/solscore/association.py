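"""Per-category association of features with expression outcome.

Three variable types are handled the way the categorical workflow
prescribes:

* yes/no (binary) features — one 2x2 contingency table per category
  (feature present/absent x in-category/rest) with a Fisher exact test;
* discrete features — one bin per observed value, sparse adjacent values
  merged to a minimum occupancy, then Pearson correlation of the per-bin
  category percentages against bin values;
* continuous features — quantile bins, otherwise as discrete.

Percentages of A, C and N within each bin always form a partition (sum to
100).  Smoothing (centred moving average) is a presentation aid; by
default the correlation runs on unsmoothed percentages.

Sign calls summarise each feature x category pair as ``+`` (significant
positive), ``-`` (significant negative), ``+/-`` (the lower- and
upper-half correlations are individually significant with opposite signs
— a non-monotone, e.g. U-shaped, relationship) or ``ND``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .stattests import fisher_exact, one_tailed_p, pearson_r

__all__ = [
    "CATEGORIES",
    "SIGNS",
    "BinaryAssociation",
    "ProfileBin",
    "CategoryProfile",
    "CorrelationResult",
    "binary_association",
    "profile_feature",
    "smooth_profile",
    "correlate_profile",
    "sign_from_profile",
    "sign_from_binary",
]

CATEGORIES = ("A", "C", "N")
SIGNS = ("+", "-", "+/-", "ND")


@dataclass(frozen=True)
class BinaryAssociation:
    """Fisher-exact association of a yes/no feature with one category."""

    category: str
    table: tuple[int, int, int, int]  # (present&cat, present&rest, absent&cat, absent&rest)
    p: float
    odds_ratio: float
    direction: int  # sign of (odds ratio - 1); 0 when undefined
    significant: bool
    nd: bool = False

    @property
    def n(self) -> int:
        return sum(self.table)


def binary_association(
    categories: Sequence[str],
    present: Sequence[bool] | np.ndarray,
    alpha: float = 0.05,
) -> dict[str, BinaryAssociation]:
    """Per-category 2x2 Fisher tests for a binary feature.

    A feature that is constant (all present or all absent) cannot be
    tested and yields ND results for every category.
    """
    cats = np.asarray(categories)
    pres = np.asarray(present, dtype=bool)
    if cats.shape != pres.shape:
        raise ValueError("categories and feature must be equally long")
    results: dict[str, BinaryAssociation] = {}
    degenerate = pres.all() or (~pres).all()
    for cat in CATEGORIES:
        in_cat = cats == cat
        a = int(np.sum(pres & in_cat))
        b = int(np.sum(pres & ~in_cat))
        c = int(np.sum(~pres & in_cat))
        d = int(np.sum(~pres & ~in_cat))
        if degenerate:
            results[cat] = BinaryAssociation(
                category=cat,
                table=(a, b, c, d),
                p=math.nan,
                odds_ratio=math.nan,
                direction=0,
                significant=False,
                nd=True,
            )
            continue
        fisher = fisher_exact((a, b, c, d))
        odds = fisher.odds_ratio
        if math.isnan(odds) or odds == 1.0:
            direction = 0
        else:
            direction = 1 if odds > 1.0 else -1
        results[cat] = BinaryAssociation(
            category=cat,
            table=(a, b, c, d),
            p=fisher.p_two_sided,
            odds_ratio=odds,
            direction=direction,
            significant=fisher.p_two_sided < alpha,
        )
    return results


@dataclass(frozen=True)
class ProfileBin:
    """One bin of a category profile."""

    label: str
    representative: float
    count: int
    percentages: dict[str, float]  # category -> percentage within bin


@dataclass(frozen=True)
class CategoryProfile:
    """Per-bin A/C/N percentages plus the dataset distribution over bins."""

    feature: str
    kind: str  # discrete | continuous
    bins: tuple[ProfileBin, ...]
    usable: bool
    n_excluded: int = 0  # records with missing feature values

    @property
    def representatives(self) -> np.ndarray:
        return np.array([b.representative for b in self.bins])

    @property
    def counts(self) -> np.ndarray:
        return np.array([b.count for b in self.bins])

    def percentages(self, category: str) -> np.ndarray:
        return np.array([b.percentages[category] for b in self.bins])


def _bin_stats(
    cats: np.ndarray, members: np.ndarray, values: np.ndarray, label: str
) -> ProfileBin:
    count = int(members.sum())
    pct = {
        cat: 100.0 * float(np.sum(cats[members] == cat)) / count
        for cat in CATEGORIES
    }
    return ProfileBin(
        label=label,
        representative=float(values[members].mean()),
        count=count,
        percentages=pct,
    )


def profile_feature(
    categories: Sequence[str],
    values,
    kind: str,
    feature: str = "",
    n_bins: int = 10,
    min_bin: int = 20,
) -> CategoryProfile:
    """Bin a feature over its full range and profile A/C/N percentages.

    Discrete features get one bin per observed value with sparse adjacent
    values merged until every bin holds at least *min_bin* records (a
    trailing sparse bin is merged backwards).  Continuous features use
    quantile bins (*n_bins* by default; ties collapse into one bin).
    Records with missing (NaN) values are excluded and counted.  Profiles
    with fewer than 3 bins are flagged unusable for correlation (ND).
    """
    if kind not in ("discrete", "continuous"):
        raise ValueError(f"kind must be discrete or continuous, got {kind!r}")
    cats_all = np.asarray(categories)
    vals_all = np.asarray(values, dtype=float)
    if cats_all.shape != vals_all.shape:
        raise ValueError("categories and values must be equally long")
    keep = ~np.isnan(vals_all)
    cats, vals = cats_all[keep], vals_all[keep]
    n_excluded = int((~keep).sum())
    if vals.size == 0:
        return CategoryProfile(feature, kind, (), usable=False, n_excluded=n_excluded)

    bins: list[ProfileBin] = []
    if kind == "discrete":
        uniq, counts = np.unique(vals, return_counts=True)
        groups: list[list[int]] = []
        current: list[int] = []
        current_count = 0
        for i, cnt in enumerate(counts):
            current.append(i)
            current_count += int(cnt)
            if current_count >= min_bin:
                groups.append(current)
                current, current_count = [], 0
        if current:
            if groups:
                groups[-1].extend(current)
            else:
                groups.append(current)
        for group in groups:
            members = np.isin(vals, uniq[group])
            lo, hi = uniq[group[0]], uniq[group[-1]]
            label = f"{lo:g}" if lo == hi else f"{lo:g}-{hi:g}"
            bins.append(_bin_stats(cats, members, vals, label))
    else:
        edges = np.unique(np.quantile(vals, np.linspace(0.0, 1.0, n_bins + 1)))
        if edges.size < 2:  # constant feature
            members = np.ones_like(vals, dtype=bool)
            bins.append(_bin_stats(cats, members, vals, f"{edges[0]:g}"))
        else:
            idx = np.clip(
                np.searchsorted(edges, vals, side="right") - 1, 0, edges.size - 2
            )
            for b in range(edges.size - 1):
                members = idx == b
                if not members.any():
                    continue
                label = f"[{edges[b]:.4g},{edges[b + 1]:.4g}]"
                bins.append(_bin_stats(cats, members, vals, label))
    return CategoryProfile(
        feature=feature,
        kind=kind,
        bins=tuple(bins),
        usable=len(bins) >= 3,
        n_excluded=n_excluded,
    )


def smooth_profile(profile: CategoryProfile, window: int = 3) -> CategoryProfile:
    """Centred moving average of the percentage curves (edge-shrunk).

    The window must be odd; ``window=1`` is the identity.  Counts and bin
    definitions are untouched, and because the same weights apply to all
    three curves the per-bin percentages still sum to 100.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1 or len(profile.bins) == 0:
        return profile
    half = window // 2
    n = len(profile.bins)
    smoothed: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        y = profile.percentages(cat)
        out = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            out[i] = y[lo:hi].mean()
        smoothed[cat] = out
    new_bins = tuple(
        replace(b, percentages={cat: float(smoothed[cat][i]) for cat in CATEGORIES})
        for i, b in enumerate(profile.bins)
    )
    return replace(profile, bins=new_bins)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one category's percentage curve."""

    category: str
    r: float
    n: int
    p_one_tailed: float
    significant: bool
    nd: bool = False


def _correlate(x: np.ndarray, y: np.ndarray, category: str, alpha: float) -> CorrelationResult:
    try:
        r = pearson_r(x, y)
    except ValueError:
        return CorrelationResult(category, math.nan, x.size, math.nan, False, nd=True)
    p = one_tailed_p(abs(r), x.size)
    return CorrelationResult(category, r, x.size, p, significant=p < alpha)


def correlate_profile(
    profile: CategoryProfile, alpha: float = 0.05
) -> dict[str, CorrelationResult]:
    """Pearson r of category percentage vs. bin value, per category.

    x is the bin representative (the value itself for discrete bins, the
    within-bin mean for continuous bins); the one-tailed p is taken in the
    direction of the observed sign, with n = number of bins.
    """
    if not profile.usable:
        return {
            cat: CorrelationResult(cat, math.nan, len(profile.bins), math.nan, False, nd=True)
            for cat in CATEGORIES
        }
    x = profile.representatives
    return {
        cat: _correlate(x, profile.percentages(cat), cat, alpha)
        for cat in CATEGORIES
    }


def _half_signs(
    profile: CategoryProfile, category: str, alpha: float
) -> Optional[tuple[int, int]]:
    """Signs of individually significant half-profile correlations, if both."""
    n = len(profile.bins)
    if n < 5:
        return None
    x = profile.representatives
    y = profile.percentages(category)
    split_hi = (n + 1) // 2  # middle bin shared when n is odd
    split_lo = n // 2
    halves = ((x[:split_hi], y[:split_hi]), (x[split_lo:], y[split_lo:]))
    signs = []
    for hx, hy in halves:
        res = _correlate(hx, hy, category, alpha)
        if res.nd or not res.significant:
            return None
        signs.append(1 if res.r > 0 else -1)
    return signs[0], signs[1]


def sign_from_profile(
    profile: CategoryProfile,
    results: dict[str, CorrelationResult] | None = None,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Table-style sign call per category for a profiled feature.

    The non-monotone ``+/-`` rule is checked first: if the lower- and
    upper-half correlations are individually significant with opposite
    signs the call is ``+/-`` regardless of the overall correlation.
    Otherwise a significant overall correlation yields ``+``/``-`` and
    anything else is ``ND``.
    """
    if results is None:
        results = correlate_profile(profile, alpha)
    signs: dict[str, str] = {}
    for cat in CATEGORIES:
        res = results[cat]
        if res.nd:
            signs[cat] = "ND"
            continue
        halves = _half_signs(profile, cat, alpha)
        if halves is not None and halves[0] * halves[1] < 0:
            signs[cat] = "+/-"
        elif res.significant:
            signs[cat] = "+" if res.r > 0 else "-"
        else:
            signs[cat] = "ND"
    return signs


def sign_from_binary(results: dict[str, BinaryAssociation]) -> dict[str, str]:
    """Sign call per category for a yes/no feature."""
    signs: dict[str, str] = {}
    for cat in CATEGORIES:
        res = results[cat]
        if res.nd or not res.significant or res.direction == 0:
            signs[cat] = "ND"
        else:
            signs[cat] = "+" if res.direction > 0 else "-"
    return signs
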