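"""Seeded synthetic-data generators.

Two generators make every pipeline stage testable without patient data:

* :func:`simulate_training` draws training-style datasets — correlated,
  strictly positive Δ[RNA] triples for two latent quality classes
  (score 0 vs score 6). Expression ratios are modelled as multivariate
  lognormal with class-shifted log-means; defaults give all three genes
  strongly positive pairwise correlation and HDAC4 the largest
  standardized class separation.
* :func:`build_count_matched_fixture` emits validation-style cohorts
  whose WHO categories, SFI tiers and high-quality flags land exactly on
  a requested count specification: parameter values are placed on
  prescribed sides of each decision boundary with a safety margin, with
  seeded jitter inside the safe region, so raw values vary by seed but
  classification counts never do.
* :func:`simulate_run_sheet` renders Δ[RNA] targets back into a raw qPCR
  run sheet (standards + unknown wells) through per-channel true curves,
  for end-to-end quantification tests.

All generator parameters are explicit configuration — none are estimates
of any real study population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .qpcr import CHANNELS, GENES, HOUSEKEEPING
from .sfi import (
    ALIQUOT_SCALE,
    DEFAULT_THRESHOLDS,
    DEFAULT_WEIGHTS,
    SfiThresholds,
    SfiWeights,
    TIERS,
)
from .training import FEATURE_COLUMNS, TrainingDataset
from .who import (
    DEFAULT_HQ_CRITERIA,
    DEFAULT_LIMITS,
    HighQualityCriteria,
    WHO_CATEGORIES,
    WhoReferenceLimits,
)

_GENE_TO_COLUMN = {"AURKA": "delta_aurka", "HDAC4": "delta_hdac4", "CARHSP1": "delta_carhsp1"}


# ---------------------------------------------------------------------------
# training-style datasets
# ---------------------------------------------------------------------------

def _default_correlation() -> np.ndarray:
    r = 0.6
    m = np.full((3, 3), r)
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class TrainingSimConfig:
    """Lognormal two-class generation model for Δ[RNA] triples.

    Log-scale means per class and gene (order AURKA, HDAC4, CARHSP1),
    shared log-scale standard deviations, and one latent correlation
    matrix. Defaults: sd 0.5 for every gene, class shifts of 1.0 / 1.5 /
    1.0 log units, i.e. standardized log-scale separations of 2.0 / 3.0 /
    2.0 — HDAC4 carries the strongest signal, at 53 samples per class
    every gene separates decisively, and two classes of 53 are nearly
    separable by the three-gene logistic model.
    """

    n_per_class: int = 53
    log_means_score0: Mapping[str, float] = field(
        default_factory=lambda: {"AURKA": -2.12, "HDAC4": -1.90, "CARHSP1": -1.61}
    )
    log_means_score6: Mapping[str, float] = field(
        default_factory=lambda: {"AURKA": -1.12, "HDAC4": -0.40, "CARHSP1": -0.61}
    )
    log_sds: Mapping[str, float] = field(
        default_factory=lambda: {"AURKA": 0.5, "HDAC4": 0.5, "CARHSP1": 0.5}
    )
    correlation: np.ndarray = field(default_factory=_default_correlation)
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ConfigError("correlation must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ConfigError("correlation matrix must have unit diagonal")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ConfigError("correlation matrix must be positive definite") from None
        self.correlation = corr
        if self.n_per_class < 0:
            raise ConfigError("n_per_class cannot be negative")
        for g in GENES:
            if self.log_means_score6[g] < self.log_means_score0[g]:
                raise ConfigError(f"score-6 log-mean below score-0 log-mean for {g}")
            if not self.log_sds[g] > 0:
                raise ConfigError(f"log-sd for {g} must be positive")


def simulate_training(config: TrainingSimConfig | None = None) -> TrainingDataset:
    """Draw a two-class multivariate-lognormal Δ[RNA] dataset.

    Deterministic per config seed; labels are 0 for the low-quality class
    and 1 for the high-quality class.
    """
    config = config or TrainingSimConfig()
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(config.correlation)
    sds = np.array([config.log_sds[g] for g in GENES])
    blocks, labels = [], []
    for label, means in ((0, config.log_means_score0), (1, config.log_means_score6)):
        mu = np.array([means[g] for g in GENES])
        z = rng.standard_normal((config.n_per_class, 3)) @ chol.T
        blocks.append(np.exp(mu + sds * z))
        labels.append(np.full(config.n_per_class, label))
    values = np.vstack(blocks)
    features = pd.DataFrame(
        {_GENE_TO_COLUMN[g]: values[:, i] for i, g in enumerate(GENES)},
        columns=list(FEATURE_COLUMNS),
    )
    return TrainingDataset(features=features, target=np.concatenate(labels))


# ---------------------------------------------------------------------------
# count-matched validation cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortCountSpec:
    """Target classification counts for a fixture cohort.

    ``who``: records per WHO category. ``tiers``: SFI-tier counts, either
    overall (assigned across records in deterministic order) or per WHO
    category via ``tiers_by_category`` (which overrides ``tiers``).
    ``high_quality``: how many normospermic records must additionally pass
    the high-quality gate.
    """

    who: Mapping[str, int]
    tiers: Mapping[str, int] | None = None
    tiers_by_category: Mapping[str, Mapping[str, int]] | None = None
    high_quality: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.who) - set(WHO_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown WHO categories: {sorted(unknown)}")
        if any(v < 0 for v in self.who.values()):
            raise ConfigError("WHO counts cannot be negative")
        n = self.total
        if self.tiers_by_category is not None:
            for cat, tiers in self.tiers_by_category.items():
                if sum(tiers.values()) != self.who.get(cat, 0):
                    raise ConfigError(
                        f"tier counts for {cat!r} do not sum to its WHO count"
                    )
                if set(tiers) - set(TIERS):
                    raise ConfigError(f"unknown tiers for {cat!r}")
        elif self.tiers is not None:
            if set(self.tiers) - set(TIERS):
                raise ConfigError(f"unknown tiers: {sorted(set(self.tiers) - set(TIERS))}")
            if sum(self.tiers.values()) != n:
                raise ConfigError(
                    f"tier counts sum to {sum(self.tiers.values())}, expected {n}"
                )
        else:
            raise ConfigError("either tiers or tiers_by_category must be given")
        if not 0 <= self.high_quality <= self.who.get("normospermic", 0):
            raise ConfigError("high_quality exceeds the normospermic count")

    @property
    def total(self) -> int:
        return sum(self.who.values())


def _tier_sequence(spec: CohortCountSpec) -> dict[str, list[str]]:
    """Tier label stream per category (or one shared stream under '*')."""
    if spec.tiers_by_category is not None:
        return {
            cat: [t for t in TIERS for _ in range(tiers.get(t, 0))]
            for cat, tiers in spec.tiers_by_category.items()
        }
    stream = [t for t in TIERS for _ in range(spec.tiers.get(t, 0))]
    return {"*": stream}


def _normal_value(rng, limit: float, cap: float, gap_frac: float) -> float:
    lo = limit * (1.0 + gap_frac)
    if cap <= lo:
        raise ConfigError(f"no room above limit {limit} with gap {gap_frac} and cap {cap}")
    return float(rng.uniform(lo, cap))


def _abnormal_value(rng, limit: float, floor: float, gap_frac: float) -> float:
    hi = limit * (1.0 - gap_frac)
    if hi <= floor:
        raise ConfigError(f"no room below limit {limit} with gap {gap_frac}")
    return float(rng.uniform(floor, hi))


def _semen_params(
    rng,
    category: str,
    index: int,
    hq: bool,
    limits: WhoReferenceLimits,
    criteria: HighQualityCriteria,
    gap_frac: float,
) -> dict[str, float]:
    abnormal = {
        "normospermic": (),
        "one_abnormal": (("conc",), ("prog",), ("morph",))[index % 3],
        "two_abnormal": (("conc", "prog"), ("conc", "morph"), ("prog", "morph"))[index % 3],
        "oat": ("conc", "prog", "morph"),
    }[category]

    if "conc" in abnormal:
        conc = _abnormal_value(rng, limits.min_concentration, 0.6, gap_frac)
    elif hq:
        conc = _normal_value(rng, criteria.min_concentration, 120.0, gap_frac)
    else:
        # stays strictly below the high-quality concentration gate
        conc = float(
            rng.uniform(
                limits.min_concentration * (1 + gap_frac),
                criteria.min_concentration * (1 - gap_frac),
            )
        )
    if "prog" in abnormal:
        prog = _abnormal_value(rng, limits.min_progressive_motility, 1.0, gap_frac)
    elif hq:
        prog = _normal_value(rng, criteria.min_progressive_motility, 70.0, gap_frac)
    else:
        prog = _normal_value(rng, limits.min_progressive_motility, 65.0, gap_frac)
    if "morph" in abnormal:
        morph = _abnormal_value(rng, limits.min_morphology, 0.1, gap_frac)
    elif hq:
        morph = _normal_value(rng, criteria.min_morphology, 25.0, gap_frac)
    else:
        morph = _normal_value(rng, limits.min_morphology, 13.0, gap_frac)

    if hq:
        total = min(prog + float(rng.uniform(12.0, 20.0)), 95.0)
        total = max(total, criteria.min_total_motility * (1 + gap_frac))
    else:
        total = min(prog + float(rng.uniform(5.0, 15.0)), 95.0)
    return {
        "concentration_mpml": conc,
        "total_motility_pct": total,
        "progressive_motility_pct": prog,
        "morphology_pct": morph,
    }


def _tier_target(rng, tier: str, thresholds: SfiThresholds, margin: float) -> float:
    lo, hi = thresholds.low, thresholds.high
    if tier == "low":
        upper = lo - margin
        if upper <= 0:
            raise ConfigError("SFI margin leaves no room in the low tier")
        return float(rng.uniform(0.3 * upper, upper))
    if tier == "intermediate":
        if lo + margin >= hi - margin:
            raise ConfigError("SFI margin too wide for the intermediate band")
        return float(rng.uniform(lo + margin, hi - margin))
    return float(rng.uniform(hi + margin, 2.0 * hi))


def build_count_matched_fixture(
    spec: CohortCountSpec,
    seed: int = 0,
    limits: WhoReferenceLimits = DEFAULT_LIMITS,
    hq_criteria: HighQualityCriteria = DEFAULT_HQ_CRITERIA,
    thresholds: SfiThresholds = DEFAULT_THRESHOLDS,
    weights: SfiWeights = DEFAULT_WEIGHTS,
    gap_frac: float = 0.05,
    sfi_margin: float = 5.0,
) -> pd.DataFrame:
    """Cohort table whose downstream classification reproduces ``spec`` exactly.

    Semen parameters sit at least ``gap_frac`` (relative) away from every
    WHO limit on the prescribed side; SFI values sit at least
    ``sfi_margin`` (absolute, SFI units) inside the prescribed tier — the
    relative rule cannot apply there, as 5% of the lower threshold is
    wider than half the intermediate band. Raw values carry seeded jitter
    within the safe regions, so two seeds give different tables with
    identical classification tallies.
    """
    rng = np.random.default_rng(seed)
    tier_streams = _tier_sequence(spec)
    shared = tier_streams.get("*")
    cursor = {cat: 0 for cat in tier_streams}
    shared_cursor = 0

    rows = []
    counter = 0
    for category in WHO_CATEGORIES:
        n_cat = spec.who.get(category, 0)
        for i in range(n_cat):
            hq = category == "normospermic" and i < spec.high_quality
            params = _semen_params(rng, category, i, hq, limits, hq_criteria, gap_frac)
            if shared is not None:
                tier = shared[shared_cursor]
                shared_cursor += 1
            else:
                tier = tier_streams[category][cursor[category]]
                cursor[category] += 1
            target_sfi = _tier_target(rng, tier, thresholds, sfi_margin)

            s = float(rng.uniform(2.0, 6.0))  # millions motile in the aliquot
            v = float(rng.uniform(0.8, 3.0))  # total extract volume, mL
            factor = s * v * ALIQUOT_SCALE
            budget = target_sfi / factor  # required weighted Δ[RNA] sum
            frac_a = float(rng.uniform(0.02, 0.08))
            frac_c = float(rng.uniform(0.02, 0.08))
            delta_a = frac_a * budget / weights.aurka
            delta_c = frac_c * budget / weights.carhsp1
            delta_h = (1.0 - frac_a - frac_c) * budget / weights.hdac4

            counter += 1
            rows.append(
                {
                    "sample_id": f"S{counter:04d}",
                    **params,
                    "delta_aurka": delta_a,
                    "delta_hdac4": delta_h,
                    "delta_carhsp1": delta_c,
                    "motile_millions_in_aliquot": s,
                    "extract_volume_ml": v,
                }
            )
    columns = [
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
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# raw qPCR run sheets
# ---------------------------------------------------------------------------

def simulate_run_sheet(
    deltas: pd.DataFrame,
    seed: int = 0,
    housekeeping_copies: float = 1000.0,
    dilutions: tuple[float, ...] = (1e5, 1e4, 1e3, 1e2),
    noise_sd: float = 0.0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Render Δ[RNA] targets into a raw run sheet through true standard curves.

    Each channel gets a true line with doubling slope (−1/log10 2) and a
    channel-specific intercept; standards and unknowns are emitted as Cq
    values with optional Gaussian cycle noise. A Δ[RNA] of exactly 0
    becomes an empty Cq cell (no amplification). ``deltas`` needs columns
    ``sample_id, delta_aurka, delta_hdac4, delta_carhsp1``.
    """
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(2.0)
    intercepts = {c: 38.0 + 0.5 * i for i, c in enumerate(CHANNELS)}

    def cq_of(channel: str, copies: float) -> float:
        if copies <= 0:
            return float("nan")
        cq = intercepts[channel] + slope * np.log10(copies)
        if noise_sd > 0:
            cq += rng.normal(0.0, noise_sd)
        return float(cq)

    rows = []
    for channel in CHANNELS:
        for known in dilutions:
            for _ in range(n_replicates):
                rows.append(
                    {
                        "sample_id": f"std_{channel}",
                        "channel": channel,
                        "well_role": "standard",
                        "known_copies_per_ul": known,
                        "cq": cq_of(channel, known),
                    }
                )
    for row in deltas.itertuples():
        copies = {
            "AURKA": row.delta_aurka * housekeeping_copies,
            "HDAC4": row.delta_hdac4 * housekeeping_copies,
            "CARHSP1": row.delta_carhsp1 * housekeeping_copies,
            HOUSEKEEPING: housekeeping_copies,
        }
        for channel in CHANNELS:
            for _ in range(n_replicates):
                rows.append(
                    {
                        "sample_id": row.sample_id,
                        "channel": channel,
                        "well_role": "unknown",
                        "known_copies_per_ul": np.nan,
                        "cq": cq_of(channel, copies[channel]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "channel", "well_role", "known_copies_per_ul", "cq"]
    )
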