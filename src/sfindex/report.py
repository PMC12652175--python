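"""Cohort orchestration and cross-tabulated reporting.

Runs every sample of a cohort sheet through WHO categorization, the
high-quality gate, SFI computation and tier assignment, then assembles
count-plus-percentage distributions: the overall WHO breakdown, the
overall SFI-tier breakdown, and the tier breakdowns within the
normospermic and high-quality strata.

Counts are the source of truth; percentages are always re-derived from
counts with round-half-up at a configurable precision (1 decimal by
default). Per-sample failures never abort a whole batch by default —
they are collected per sample_id and the run only fails when the error
fraction exceeds a configurable ceiling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import AlignmentError, PipelineError
from .sfi import (
    ALIQUOT_SCALE,
    DEFAULT_THRESHOLDS,
    DEFAULT_WEIGHTS,
    MotileSpermInput,
    SfiThresholds,
    SfiWeights,
    TIERS,
    classify_sfi,
    compute_sfi,
)
from .who import (
    DEFAULT_HQ_CRITERIA,
    DEFAULT_LIMITS,
    HighQualityCriteria,
    SemenParams,
    WHO_CATEGORIES,
    WhoReferenceLimits,
    classify_who,
    is_high_quality,
)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 decimal → 0.1, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentages(counts: Mapping[str, int], decimals: int = 1) -> dict[str, float | None]:
    """Counts → round-half-up percentages of their own total (None if total 0)."""
    total = sum(counts.values())
    if total == 0:
        return {k: None for k in counts}
    return {k: round_half_up(100.0 * v / total, decimals) for k, v in counts.items()}


@dataclass(frozen=True)
class Distribution:
    """One categorical breakdown: counts plus derived percentages."""

    counts: dict[str, int]
    pct: dict[str, float | None]
    denominator: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], decimals: int = 1) -> "Distribution":
        counts = dict(counts)
        return cls(
            counts=counts,
            pct=percentages(counts, decimals),
            denominator=sum(counts.values()),
        )

    def to_dict(self) -> dict:
        return {"counts": self.counts, "pct": self.pct, "n": self.denominator}


@dataclass(frozen=True)
class CrossTab:
    """WHO-category × SFI-tier contingency table with row percentages."""

    counts: pd.DataFrame
    row_pct: pd.DataFrame


def crosstab(
    categories: Sequence[str], tiers: Sequence[str], decimals: int = 1
) -> CrossTab:
    """Cell counts and row percentages for paired category/tier labels."""
    if len(categories) != len(tiers):
        raise AlignmentError(
            f"{len(categories)} categories vs {len(tiers)} tiers"
        )
    cats = [c for c in WHO_CATEGORIES if c in set(categories)] or sorted(set(categories))
    counts = pd.DataFrame(0, index=cats, columns=list(TIERS), dtype=int)
    for c, t in zip(categories, tiers):
        counts.loc[c, t] += 1
    row_pct = counts.apply(
        lambda row: pd.Series(percentages(row.to_dict(), decimals)), axis=1
    )
    return CrossTab(counts=counts, row_pct=row_pct)


@dataclass
class PipelineConfig:
    """All tunables of a cohort run, JSON-round-trippable."""

    weights: SfiWeights = field(default_factory=SfiWeights)
    thresholds: SfiThresholds = field(default_factory=SfiThresholds)
    limits: WhoReferenceLimits = field(default_factory=WhoReferenceLimits)
    hq_criteria: HighQualityCriteria = field(default_factory=HighQualityCriteria)
    aliquot_scale: float = ALIQUOT_SCALE
    pct_decimals: int = 1
    max_error_fraction: float = 0.1

    def to_dict(self) -> dict:
        return {
            "weights": vars(self.weights),
            "thresholds": vars(self.thresholds),
            "limits": vars(self.limits),
            "hq_criteria": vars(self.hq_criteria),
            "aliquot_scale": self.aliquot_scale,
            "pct_decimals": self.pct_decimals,
            "max_error_fraction": self.max_error_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(
            weights=SfiWeights(**d.get("weights", {})),
            thresholds=SfiThresholds(**d.get("thresholds", {})),
            limits=WhoReferenceLimits(**d.get("limits", {})),
            hq_criteria=HighQualityCriteria(**d.get("hq_criteria", {})),
            aliquot_scale=d.get("aliquot_scale", ALIQUOT_SCALE),
            pct_decimals=d.get("pct_decimals", 1),
            max_error_fraction=d.get("max_error_fraction", 0.1),
        )


@dataclass
class CohortReport:
    who: Distribution
    sfi: Distribution
    sfi_within_normospermic: Distribution
    sfi_within_high_quality: Distribution
    per_sample: pd.DataFrame
    errors: dict[str, str]
    flags: list[str]

    def to_dict(self) -> dict:
        return {
            "n": int(len(self.per_sample)),
            "who": self.who.to_dict(),
            "sfi": self.sfi.to_dict(),
            "sfi_within_normospermic": self.sfi_within_normospermic.to_dict(),
            "sfi_within_high_quality": self.sfi_within_high_quality.to_dict(),
            "errors": dict(sorted(self.errors.items())),
            "flags": list(self.flags),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


COHORT_COLUMNS = (
    "sample_id",
    "concentration_mpml",
    "total_motility_pct",
    "progressive_motility_pct",
    "morphology_pct",
    "delta_aurka",
    "delta_hdac4",
    "delta_carhsp1",
    "motile_millions_in_aliquot",
    "extract_volume_ml",
)


def run_pipeline(
    cohort: pd.DataFrame, config: PipelineConfig | None = None
) -> CohortReport:
    """Score and classify every record; assemble the cohort report.

    Deterministic: the report is a pure function of the cohort table and
    the config. Records that fail any stage are skipped and logged into
    ``report.errors``; the run raises :class:`PipelineError` only when
    more than ``config.max_error_fraction`` of records fail.
    """
    config = config or PipelineConfig()
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort sheet missing columns: {sorted(missing)}")
    ids = cohort["sample_id"]
    if ids.duplicated().any():
        raise ValueError(
            f"duplicate sample_id(s): {sorted(ids[ids.duplicated()].unique())}"
        )

    rows: list[dict] = []
    errors: dict[str, str] = {}
    for row in cohort.itertuples():
        try:
            params = SemenParams(
                concentration=row.concentration_mpml,
                total_motility=row.total_motility_pct,
                progressive_motility=row.progressive_motility_pct,
                normal_morphology=row.morphology_pct,
            )
            who = classify_who(params, config.limits)
            hq = is_high_quality(params, who, config.hq_criteria)
            delta = {
                "AURKA": row.delta_aurka,
                "HDAC4": row.delta_hdac4,
                "CARHSP1": row.delta_carhsp1,
            }
            motile = MotileSpermInput(
                motile_millions=row.motile_millions_in_aliquot,
                volume_ml=row.extract_volume_ml,
            )
            value = compute_sfi(delta, motile, config.weights, config.aliquot_scale)
            tier = classify_sfi(value, config.thresholds)
        except Exception as exc:  # per-record isolation, batch realism
            errors[str(row.sample_id)] = f"{type(exc).__name__}: {exc}"
            continue
        rows.append(
            {
                "sample_id": row.sample_id,
                "who_category": who.category,
                "n_abnormal": who.n_abnormal,
                "high_quality": hq,
                "sfi_value": value,
                "sfi_tier": tier,
            }
        )

    n_input = len(cohort)
    if n_input > 0 and len(errors) / n_input > config.max_error_fraction:
        raise PipelineError(
            f"{len(errors)}/{n_input} records failed "
            f"(> {config.max_error_fraction:.0%} allowed): {errors}"
        )
    per_sample = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "who_category",
            "n_abnormal",
            "high_quality",
            "sfi_value",
            "sfi_tier",
        ],
    )

    d = config.pct_decimals

    def tier_dist(frame: pd.DataFrame) -> Distribution:
        counts = {t: int((frame["sfi_tier"] == t).sum()) for t in TIERS}
        return Distribution.from_counts(counts, d)

    who_counts = {
        c: int((per_sample["who_category"] == c).sum()) for c in WHO_CATEGORIES
    }
    flags = []
    if len(per_sample) == 0:
        flags.append("empty")
    if errors:
        flags.append("has_errors")
    return CohortReport(
        who=Distribution.from_counts(who_counts, d),
        sfi=tier_dist(per_sample),
        sfi_within_normospermic=tier_dist(
            per_sample[per_sample["who_category"] == "normospermic"]
        ),
        sfi_within_high_quality=tier_dist(
            per_sample[per_sample["high_quality"].astype(bool)]
        ),
        per_sample=per_sample,
        errors=errors,
        flags=flags,
    )
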