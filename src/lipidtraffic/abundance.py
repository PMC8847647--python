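"""Quantitative group comparisons: rank tests, Bonferroni, ratios, ENFC.

Lipidomics signal intensities are treated as unequally distributed and
heteroscedastic, so group location comparisons use the two-sided
Mann-Whitney rank-sum test (exact null distribution at small sample sizes,
normal approximation with tie correction otherwise) with a Bonferroni
family-wise threshold.

The error-normalised fold change (ENFC) expresses a case/control fold
change in units of its own uncertainty:

    ENFC = log2(mean_case / mean_control) / SE[log2 FC]

with the standard error propagated by the delta method,

    SE = sqrt( sd_case^2 / (n_case * mean_case^2)
             + sd_control^2 / (n_control * mean_control^2) ) / ln 2.

It is dimensionless, zero exactly when the fold change is 1, and exactly
antisymmetric under swapping case and control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import mannwhitneyu

from .io import LipidomicsDataset
from .nomenclature import LipidSpecies

__all__ = [
    "relative_abundance",
    "GroupComparison",
    "compare_groups",
    "bonferroni_threshold",
    "FaRatio",
    "fa_ratio",
    "EnfcResult",
    "enfc",
]


def relative_abundance(profile) -> np.ndarray:
    """Normalise a non-negative signal profile to proportions summing to 1."""
    arr = np.asarray(profile, dtype=float)
    if (arr < 0).any():
        raise ValueError("signals must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero profile has no relative abundances")
    return arr / total


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided rank-sum comparison of one variable between two groups."""

    statistic: float
    p_raw: float
    method: str  # "exact" | "asymptotic"
    n_g1: int
    n_g2: int
    p_threshold_bonferroni: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.p_threshold_bonferroni is None:
            return None
        return self.p_raw < self.p_threshold_bonferroni

    def with_bonferroni(self, alpha: float, m: int) -> "GroupComparison":
        return replace(self, p_threshold_bonferroni=bonferroni_threshold(alpha, m))


# Below this per-group size (and absent ties) the exact Mann-Whitney null
# distribution is enumerated rather than approximated.
EXACT_RANKSUM_MAX_N = 8


def compare_groups(values_g1, values_g2) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum test between two groups.

    Exact when both groups have at most 8 observations and no ties occur;
    otherwise the normal approximation with tie correction.  Each group
    needs at least 3 observations.
    """
    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise ValueError("compare_groups needs >= 3 observations per group")
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (
        g1.size <= EXACT_RANKSUM_MAX_N
        and g2.size <= EXACT_RANKSUM_MAX_N
        and not has_ties
    )
    method = "exact" if use_exact else "asymptotic"
    res = mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return GroupComparison(
        statistic=float(res.statistic),
        p_raw=float(min(1.0, res.pvalue)),
        method=method,
        n_g1=int(g1.size),
        n_g2=int(g2.size),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m`` for m variables.

    >>> round(bonferroni_threshold(0.05, 33), 5)
    0.00152
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    return alpha / m


@dataclass(frozen=True)
class FaRatio:
    """Per-sample ratio of two variables within one group and compartment."""

    numerator: str
    denominator: str
    group: str
    compartment: str
    ratios: np.ndarray
    n_excluded: int

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())


def fa_ratio(
    dataset: LipidomicsDataset,
    numerator: LipidSpecies | str,
    denominator: LipidSpecies | str,
    group: str,
    compartment: str,
    *,
    per_sample: bool = True,
) -> FaRatio:
    """Diagnostic ratio of two variables, e.g. FA(15:0)/FA(17:0).

    By default the ratio is formed per sample and then summarised by the
    group mean, which supports a per-sample rank test between groups.
    ``per_sample=False`` instead returns the single ratio of group means.
    Samples with a zero denominator are excluded with a warning; if all are
    excluded the ratio is undefined.
    """
    num_name = numerator if isinstance(numerator, str) else numerator.raw_name
    den_name = denominator if isinstance(denominator, str) else denominator.raw_name
    num = dataset.values(group, compartment, num_name)
    den = dataset.values(group, compartment, den_name)
    if num.size == 0:
        raise ValueError(f"no samples for group {group!r} in {compartment!r}")
    ok = den > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} sample(s) excluded from {num_name}/{den_name} "
            f"({group}, {compartment}): zero denominator",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError(
            f"ratio {num_name}/{den_name} undefined: denominator zero in "
            f"every sample of ({group}, {compartment})"
        )
    if per_sample:
        ratios = num[ok] / den[ok]
    else:
        ratios = np.array([num[ok].mean() / den[ok].mean()])
    return FaRatio(
        numerator=num_name,
        denominator=den_name,
        group=group,
        compartment=compartment,
        ratios=ratios,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class EnfcResult:
    """Error-normalised fold change of one variable (case vs control)."""

    fold_change: float
    enfc: float
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    n_case: int
    n_control: int


def enfc(case, control) -> EnfcResult:
    """Error-normalised fold change, case over control.

    ``fold_change = mean(case) / mean(control)``;
    ``enfc = log2(fold_change) / SE`` with the delta-method standard error
    of the log2 fold change (see module docstring).  Exactly antisymmetric:
    ``enfc(a, b) == -enfc(b, a)``.  Both means must be positive; if both
    groups have zero variance the ENFC is 0 for equal means and signed
    infinity otherwise.
    """
    a = np.asarray(case, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("enfc needs >= 3 observations per group")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("enfc undefined: both group means must be positive")
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    # log(mean_a) - log(mean_b) negates exactly under swap, unlike
    # log(mean_a / mean_b), whose rounding is not antisymmetric.
    log2_fc = (math.log(mean_a) - math.log(mean_b)) / math.log(2)
    se = math.sqrt(
        sd_a**2 / (a.size * mean_a**2) + sd_b**2 / (b.size * mean_b**2)
    ) / math.log(2)
    if se == 0.0:
        value = 0.0 if log2_fc == 0.0 else math.copysign(math.inf, log2_fc)
    else:
        value = log2_fc / se
    return EnfcResult(
        fold_change=mean_a / mean_b,
        enfc=value,
        mean_case=mean_a,
        mean_control=mean_b,
        sd_case=sd_a,
        sd_control=sd_b,
        n_case=int(a.size),
        n_control=int(b.size),
    )
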