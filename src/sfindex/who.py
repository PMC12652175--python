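"""WHO semen-analysis categorization and the high-quality subgroup filter.

Samples are tallied against lower reference limits for three parameters —
concentration, progressive motility and normal morphology — giving four
categories: normospermic (0 abnormal), one or two altered parameters, and
oligo-astheno-teratospermia (OAT, all three concurrently abnormal).
A value exactly at a limit is normal (limits are lower reference limits,
inclusive). Total motility is carried and used by the high-quality gate
but is not part of the abnormality tally.

Defaults are the 6th-edition WHO manual limits (16 × 10^6/mL, 30%
progressive motility, 4% normal morphology, 42% total motility); all are
configurable. The "very high-quality" subgroup is normospermic samples in
the upper quartile of every parameter: >= 50 × 10^6/mL, >= 50% total
motility, >= 40% progressive motility and >= 14% normal forms (Kruger's
strict criteria).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

WHO_CATEGORIES = ("normospermic", "one_abnormal", "two_abnormal", "oat")


@dataclass(frozen=True)
class SemenParams:
    concentration: float  # 10^6 sperm/mL
    total_motility: float  # %
    progressive_motility: float  # %
    normal_morphology: float  # %

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration cannot be negative")
        for name in ("total_motility", "progressive_motility", "normal_morphology"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")


@dataclass(frozen=True)
class WhoReferenceLimits:
    """Lower reference limits; at-limit values count as normal."""

    min_concentration: float = 16.0
    min_progressive_motility: float = 30.0
    min_morphology: float = 4.0
    min_total_motility: float = 42.0  # carried, not tallied

    def __post_init__(self) -> None:
        for f in (
            "min_concentration",
            "min_progressive_motility",
            "min_morphology",
            "min_total_motility",
        ):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class HighQualityCriteria:
    """Upper-quartile gate for the very-high-quality subgroup (all inclusive >=)."""

    min_concentration: float = 50.0
    min_total_motility: float = 50.0
    min_progressive_motility: float = 40.0
    min_morphology: float = 14.0


@dataclass(frozen=True)
class WhoCategory:
    category: str  # one of WHO_CATEGORIES
    n_abnormal: int  # 0..3


DEFAULT_LIMITS = WhoReferenceLimits()
DEFAULT_HQ_CRITERIA = HighQualityCriteria()


def classify_who(
    params: SemenParams, limits: WhoReferenceLimits = DEFAULT_LIMITS
) -> WhoCategory:
    """Count tallied parameters strictly below their lower reference limits."""
    n_abnormal = sum(
        [
            params.concentration < limits.min_concentration,
            params.progressive_motility < limits.min_progressive_motility,
            params.normal_morphology < limits.min_morphology,
        ]
    )
    category = WHO_CATEGORIES[n_abnormal]
    return WhoCategory(category=category, n_abnormal=n_abnormal)


def is_high_quality(
    params: SemenParams,
    who: WhoCategory,
    criteria: HighQualityCriteria = DEFAULT_HQ_CRITERIA,
) -> bool:
    """Normospermic AND at/above every high-quality minimum."""
    if who.category != "normospermic":
        return False
    return (
        params.concentration >= criteria.min_concentration
        and params.total_motility >= criteria.min_total_motility
        and params.progressive_motility >= criteria.min_progressive_motility
        and params.normal_morphology >= criteria.min_morphology
    )


class WhoClassifier(BaseEstimator, TransformerMixin):
    """Transformer appending ``who_category``, ``n_abnormal``, ``high_quality``.

    Expects columns ``concentration_mpml, total_motility_pct,
    progressive_motility_pct, morphology_pct``.
    """

    def __init__(
        self,
        limits: WhoReferenceLimits = DEFAULT_LIMITS,
        hq_criteria: HighQualityCriteria = DEFAULT_HQ_CRITERIA,
    ) -> None:
        self.limits = limits
        self.hq_criteria = hq_criteria

    def fit(self, X: pd.DataFrame, y=None) -> "WhoClassifier":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        cats, tallies, hq = [], [], []
        for row in X.itertuples():
            params = SemenParams(
                concentration=row.concentration_mpml,
                total_motility=row.total_motility_pct,
                progressive_motility=row.progressive_motility_pct,
                normal_morphology=row.morphology_pct,
            )
            who = classify_who(params, self.limits)
            cats.append(who.category)
            tallies.append(who.n_abnormal)
            hq.append(is_high_quality(params, who, self.hq_criteria))
        out["who_category"] = cats
        out["n_abnormal"] = tallies
        out["high_quality"] = hq
        return out
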