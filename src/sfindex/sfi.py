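"""The Spermatozoa Function Index (SFI).

The SFI combines housekeeping-normalized expression of three genes with
the quantity of motile sperm assayed:

    SFI = (w_C · Δ[RNA](CARHSP1) + w_A · Δ[RNA](AURKA) + w_H · Δ[RNA](HDAC4))
          · (s · v · 1000/300)

where s is the number of motile spermatozoa (in millions) in the 0.3 mL
aliquot taken for RNA extraction, v is the total volume (mL) of the
extracted sample, and 1000/300 converts the aliquot count to a per-mL
scale. The published weights are w_C = 3.14, w_A = 4.51, w_H = 18.91;
HDAC4 dominates, reflecting its strongest association with sperm quality.

Values map onto three functionality tiers: low (< 290), intermediate
(290–320 inclusive on both ends) and normal (> 320). The shipped
thresholds are the published constants; :func:`derive_thresholds`
re-derives a cutoff from labelled training scores via the Youden-J ROC
operating point, with a symmetric grey-zone margin around it.

Note on units: the source formula does not state whether s is an
absolute count or in millions; this package carries s in millions and
exposes the whole aliquot conversion as one configurable multiplier
(``aliquot_scale``) so an alternative unit reading is a config change,
not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import IncompleteExpressionError, UndefinedRocError
from .qpcr import GENES

#: aliquot count (0.3 mL) to per-mL conversion, the "1000/300" of the formula
ALIQUOT_SCALE = 1000.0 / 300.0

TIERS = ("low", "intermediate", "normal")


@dataclass(frozen=True)
class SfiWeights:
    """Per-gene weights of the composite index (published constants)."""

    carhsp1: float = 3.14
    aurka: float = 4.51
    hdac4: float = 18.91

    def __post_init__(self) -> None:
        for name in ("carhsp1", "aurka", "hdac4"):
            if not getattr(self, name) > 0:
                raise ValueError(f"weight {name} must be positive")


@dataclass(frozen=True)
class MotileSpermInput:
    """Motile-sperm scaling inputs for one ejaculate.

    ``motile_millions``: motile sperm (millions) counted in the 0.3 mL
    assayed aliquot (the s of the formula). ``volume_ml``: total volume
    of the extracted sample in mL (the v).
    """

    motile_millions: float
    volume_ml: float

    def __post_init__(self) -> None:
        if self.motile_millions < 0:
            raise ValueError("motile sperm count cannot be negative")
        if not self.volume_ml > 0:
            raise ValueError("extract volume must be positive")

    def scaling_factor(self, aliquot_scale: float = ALIQUOT_SCALE) -> float:
        return self.motile_millions * self.volume_ml * aliquot_scale


@dataclass(frozen=True)
class SfiThresholds:
    """Tier boundaries in SFI units; both boundaries belong to the intermediate tier."""

    low: float = 290.0
    high: float = 320.0

    def __post_init__(self) -> None:
        if self.low < 0 or self.low > self.high:
            raise ValueError(f"need 0 <= low <= high, got {self.low}, {self.high}")


DEFAULT_WEIGHTS = SfiWeights()
DEFAULT_THRESHOLDS = SfiThresholds()


def compute_sfi(
    delta: Mapping[str, float],
    motile: MotileSpermInput,
    weights: SfiWeights = DEFAULT_WEIGHTS,
    aliquot_scale: float = ALIQUOT_SCALE,
) -> float:
    """Weighted Δ[RNA] sum times the motile-sperm scaling factor.

    ``delta`` must provide all three genes (keys AURKA, HDAC4, CARHSP1);
    a missing gene raises :class:`IncompleteExpressionError` rather than
    silently scoring a partial profile.
    """
    missing = [g for g in GENES if g not in delta]
    if missing:
        raise IncompleteExpressionError(f"missing Δ[RNA] for gene(s): {missing}")
    for g in GENES:
        if delta[g] < 0:
            raise ValueError(f"Δ[RNA]({g}) cannot be negative: {delta[g]}")
    weighted = (
        weights.carhsp1 * delta["CARHSP1"]
        + weights.aurka * delta["AURKA"]
        + weights.hdac4 * delta["HDAC4"]
    )
    return weighted * motile.scaling_factor(aliquot_scale)


def classify_sfi(value: float, thresholds: SfiThresholds = DEFAULT_THRESHOLDS) -> str:
    """Tier of one SFI value: low (< low), normal (> high), else intermediate."""
    if value < 0:
        raise ValueError(f"SFI cannot be negative: {value}")
    if value < thresholds.low:
        return "low"
    if value > thresholds.high:
        return "normal"
    return "intermediate"


def derive_thresholds(
    sfi_values: Sequence[float],
    labels: Sequence[int],
    margin: float = 15.0,
) -> SfiThresholds:
    """Re-derive tier thresholds from labelled SFI values via ROC analysis.

    The center cutoff maximizes Youden's J = sensitivity + specificity − 1
    over the candidate grid (midpoints between consecutive sorted unique
    values, plus the extreme values themselves); a sample is called
    positive when its SFI >= cutoff. Ties go to the lowest candidate,
    which favors sensitivity. The intermediate band is the center ±
    ``margin``; margin 0 collapses the band to a single cutoff.
    """
    values = np.asarray(sfi_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if values.shape != y.shape:
        raise ValueError("sfi_values and labels must have equal length")
    if margin < 0:
        raise ValueError("margin cannot be negative")
    if len(np.unique(y)) < 2:
        raise UndefinedRocError("both classes required to derive a ROC cutoff")

    uniq = np.unique(values)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]])
    candidates = np.unique(candidates)

    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best_j, center = -np.inf, None
    for c in candidates:  # ascending, so first max is the lowest tied candidate
        pred = values >= c
        sens = float((pred & (y == 1)).sum()) / n_pos
        spec = float((~pred & (y == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, center = j, float(c)
    return SfiThresholds(low=center - margin, high=center + margin)


class SfiScorer(BaseEstimator, TransformerMixin):
    """Stateless transformer appending ``sfi_value`` and ``sfi_tier`` columns.

    Expects a DataFrame with columns ``delta_carhsp1, delta_aurka,
    delta_hdac4, motile_millions_in_aliquot, extract_volume_ml``.
    """

    def __init__(
        self,
        weights: SfiWeights = DEFAULT_WEIGHTS,
        thresholds: SfiThresholds = DEFAULT_THRESHOLDS,
        aliquot_scale: float = ALIQUOT_SCALE,
    ) -> None:
        self.weights = weights
        self.thresholds = thresholds
        self.aliquot_scale = aliquot_scale

    def fit(self, X: pd.DataFrame, y=None) -> "SfiScorer":
        return self  # nothing to learn; published constants

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        values = []
        for row in X.itertuples():
            delta = {
                "CARHSP1": row.delta_carhsp1,
                "AURKA": row.delta_aurka,
                "HDAC4": row.delta_hdac4,
            }
            motile = MotileSpermInput(
                motile_millions=row.motile_millions_in_aliquot,
                volume_ml=row.extract_volume_ml,
            )
            values.append(
                compute_sfi(delta, motile, self.weights, self.aliquot_scale)
            )
        out["sfi_value"] = values
        out["sfi_tier"] = [classify_sfi(v, self.thresholds) for v in values]
        return out
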