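"""Absolute qPCR quantification via plasmid standard curves.

One fluorophore channel per gene: the three targets (AURKA, HDAC4,
CARHSP1) plus one housekeeping channel. Each run carries a 10-fold
dilution series (1e5 down to 1e2 copies/µL by default) from which a
Cq-vs-log10(copies) line is fitted per channel. Runs are gated on
amplification efficiency E = 10^(-1/slope) - 1, accepted when
90% <= E <= 110% (inclusive). Unknown wells are back-calculated from
the channel's curve and targets are normalized to the housekeeping
channel as Δ[RNA] = copies(target) / copies(housekeeping).

Curve fits are strictly per-run, per-channel: efficiency is a run-level
QC statistic and pooling across runs would mask a failed run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CurveUnderdeterminedError,
    DegenerateCurveError,
    InvalidSampleError,
    QcFailedError,
)

logger = logging.getLogger(__name__)

GENES = ("AURKA", "HDAC4", "CARHSP1")
HOUSEKEEPING = "housekeeping"
CHANNELS = GENES + (HOUSEKEEPING,)

#: inclusive amplification-efficiency acceptance window, in percent
EFFICIENCY_WINDOW = (90.0, 110.0)

#: default warn-only threshold for the standard-curve coefficient of determination
R_SQUARED_WARN = 0.98


@dataclass(frozen=True)
class DilutionPoint:
    """One standard well: known template amount and observed Cq."""

    known_copies: float  # copies/µL, > 0
    cq: float  # cycles, > 0

    def __post_init__(self) -> None:
        if not self.known_copies > 0:
            raise ValueError(f"known_copies must be positive, got {self.known_copies}")
        if not self.cq > 0:
            raise ValueError(f"cq must be positive, got {self.cq}")


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope.

    E = (10^(-1/slope) - 1) * 100. A slope of -1/log10(2) ≈ -3.3219
    corresponds to exact per-cycle doubling, i.e. 100%.
    """
    if not slope < 0:
        raise DegenerateCurveError(
            f"standard-curve slope must be negative, got {slope}"
        )
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Cq = intercept + slope * log10(copies/µL) line for one channel."""

    channel: str
    slope: float  # cycles per log10(copies), < 0
    intercept: float  # cycles at 1 copy/µL
    efficiency_pct: float
    r_squared: float

    @property
    def passes_qc(self) -> bool:
        lo, hi = EFFICIENCY_WINDOW
        return lo <= self.efficiency_pct <= hi


@dataclass(frozen=True)
class QuantResult:
    """Back-calculated absolute quantity for one sample/channel."""

    channel: str
    copies_per_ul: float  # >= 0; exactly 0 marks no amplification


def fit_standard_curve(
    points: Iterable[DilutionPoint],
    channel: str,
    r2_warn: float = R_SQUARED_WARN,
) -> StandardCurve:
    """OLS fit of Cq on log10(known copies) for one channel's dilution series.

    Requires at least three wells at three distinct template amounts.
    Raises :class:`DegenerateCurveError` when the fitted slope is not
    negative (an inverted or corrupt series). ``r_squared`` is reported
    and logged but never gated; only efficiency is a hard QC criterion.
    """
    pts = list(points)
    if len(pts) < 3 or len({p.known_copies for p in pts}) < 3:
        raise CurveUnderdeterminedError(
            f"channel {channel!r}: need >= 3 wells at >= 3 distinct copy numbers, "
            f"got {len(pts)} wells at {len({p.known_copies for p in pts})} levels"
        )
    x = np.log10([p.known_copies for p in pts])
    y = np.array([p.cq for p in pts], dtype=float)
    fit = stats.linregress(x, y)
    if not fit.slope < 0:
        raise DegenerateCurveError(
            f"channel {channel!r}: non-negative slope {fit.slope:.4g}; "
            "dilution series appears inverted or flat"
        )
    r2 = float(fit.rvalue) ** 2
    curve = StandardCurve(
        channel=channel,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency_pct=efficiency_from_slope(float(fit.slope)),
        r_squared=r2,
    )
    if r2 < r2_warn:
        logger.warning(
            "channel %s: standard curve r^2 = %.4f below warn threshold %.2f",
            channel, r2, r2_warn,
        )
    if not curve.passes_qc:
        logger.warning(
            "channel %s: efficiency %.1f%% outside [%.0f, %.0f]",
            channel, curve.efficiency_pct, *EFFICIENCY_WINDOW,
        )
    return curve


def quantify(cq: float | None, curve: StandardCurve) -> QuantResult:
    """Invert a passing standard curve: copies/µL = 10^((cq - intercept)/slope).

    ``cq`` of None/NaN is the no-amplification sentinel and maps to zero
    copies (treated as true non-expression, not missing data). A curve
    that failed the efficiency gate cannot quantify anything: the run
    must be repeated, so this raises :class:`QcFailedError`.
    """
    if not curve.passes_qc:
        raise QcFailedError(
            f"channel {curve.channel!r}: efficiency {curve.efficiency_pct:.1f}% "
            f"outside [{EFFICIENCY_WINDOW[0]:.0f}, {EFFICIENCY_WINDOW[1]:.0f}]; repeat the run"
        )
    if cq is None or (isinstance(cq, float) and math.isnan(cq)):
        return QuantResult(channel=curve.channel, copies_per_ul=0.0)
    if not cq > 0:
        raise ValueError(f"cq must be positive or absent, got {cq}")
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return QuantResult(channel=curve.channel, copies_per_ul=float(copies))


def normalize(
    targets: Mapping[str, QuantResult | float],
    housekeeping: QuantResult | float,
) -> dict[str, float]:
    """Housekeeping-normalized expression: Δ[RNA] per target gene.

    Δ[RNA](g) = copies(g) / copies(housekeeping). Undefined when the
    housekeeping gene did not amplify; such samples are flagged
    (:class:`InvalidSampleError`), never silently scored.
    """
    hk = housekeeping.copies_per_ul if isinstance(housekeeping, QuantResult) else float(housekeeping)
    if not hk > 0:
        raise InvalidSampleError(
            "housekeeping gene yielded 0 copies/µL; normalization undefined"
        )
    out: dict[str, float] = {}
    for gene, q in targets.items():
        copies = q.copies_per_ul if isinstance(q, QuantResult) else float(q)
        if copies < 0:
            raise ValueError(f"negative copy number for {gene}: {copies}")
        out[gene] = copies / hk
    return out


# ---------------------------------------------------------------------------
# run-sheet processing
# ---------------------------------------------------------------------------

RUN_SHEET_COLUMNS = ("sample_id", "channel", "well_role", "known_copies_per_ul", "cq")


def read_run_sheet(path) -> pd.DataFrame:
    """Read a qPCR run sheet (CSV or TSV by extension); empty cq = no amplification."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(RUN_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"run sheet missing columns: {sorted(missing)}")
    return df


def process_run_sheet(
    sheet: pd.DataFrame,
    r2_warn: float = R_SQUARED_WARN,
    strict: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full run workflow: fit per-channel curves, gate, quantify, normalize.

    Replicate unknown wells for the same (sample, channel) are averaged on
    the Cq scale before quantification; wells with an empty Cq cell count
    as no amplification, and a sample/channel whose wells are all empty
    quantifies to zero copies.

    Returns ``(deltas, qc_report)`` where ``deltas`` has one row per valid
    sample with columns ``sample_id, delta_aurka, delta_hdac4,
    delta_carhsp1`` and ``qc_report`` records per-channel slope,
    efficiency, r² and pass/fail plus the list of invalid samples
    (housekeeping failure). With ``strict=True`` (default) any channel
    failing the efficiency gate raises :class:`QcFailedError`.
    """
    sheet = sheet.copy()
    sheet["cq"] = pd.to_numeric(sheet["cq"], errors="coerce")

    curves: dict[str, StandardCurve] = {}
    qc: dict = {"channels": {}, "invalid_samples": []}
    for channel in CHANNELS:
        std = sheet[(sheet["channel"] == channel) & (sheet["well_role"] == "standard")]
        if std.empty:
            raise CurveUnderdeterminedError(f"no standard wells for channel {channel!r}")
        pts = [
            DilutionPoint(known_copies=row.known_copies_per_ul, cq=row.cq)
            for row in std.itertuples()
        ]
        curve = fit_standard_curve(pts, channel, r2_warn=r2_warn)
        curves[channel] = curve
        qc["channels"][channel] = {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "efficiency_pct": curve.efficiency_pct,
            "r_squared": curve.r_squared,
            "qc_pass": curve.passes_qc,
        }
    failed = [c for c, curve in curves.items() if not curve.passes_qc]
    if failed and strict:
        raise QcFailedError(
            f"efficiency gate failed for channel(s) {failed}; repeat the run"
        )

    unknowns = sheet[sheet["well_role"] == "unknown"]
    rows = []
    for sample_id, grp in unknowns.groupby("sample_id", sort=True):
        quants: dict[str, QuantResult] = {}
        for channel in CHANNELS:
            if failed and channel in failed:
                continue
            wells = grp[grp["channel"] == channel]["cq"]
            mean_cq = float(wells.mean()) if wells.notna().any() else float("nan")
            quants[channel] = quantify(mean_cq, curves[channel])
        try:
            delta = normalize(
                {g: quants[g] for g in GENES if g in quants}, quants[HOUSEKEEPING]
            )
        except InvalidSampleError:
            qc["invalid_samples"].append(sample_id)
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "delta_aurka": delta.get("AURKA"),
                "delta_hdac4": delta.get("HDAC4"),
                "delta_carhsp1": delta.get("CARHSP1"),
            }
        )
    deltas = pd.DataFrame(
        rows, columns=["sample_id", "delta_aurka", "delta_hdac4", "delta_carhsp1"]
    )
    return deltas, qc
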