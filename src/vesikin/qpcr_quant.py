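"""Absolute qPCR quantification against a serial-dilution standard curve.

A standard curve is an ordinary least-squares fit of Cq on log10(quantity)
over a 10-fold dilution series (canonically 100 ng down to 0.0001 ng).
Unknown Cq values are interpolated back to nanograms and converted to copy
numbers through the construct molecular weight.  The curve carries a strict
quality gate (R^2 > 0.975 by default); interpolation against a failing
curve requires an explicit override and warns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stoichiometry import CopyCount, mass_to_copies

__all__ = [
    "StandardPoint",
    "StandardCurve",
    "InterpolatedQuantity",
    "QcError",
    "build_standard_curve",
    "interpolate_quantity",
    "quantity_to_copies",
    "quantify_samples",
    "amplification_efficiency",
    "mean_cq",
    "DEFAULT_R2_THRESHOLD",
    "PERFECT_EFFICIENCY_SLOPE",
]

DEFAULT_R2_THRESHOLD = 0.975

#: Slope of a 100%-efficient amplification, -log2(10) Cq per decade.
PERFECT_EFFICIENCY_SLOPE = -math.log2(10.0)


class QcError(RuntimeError):
    """Standard curve failed its quality gate."""


@dataclass(frozen=True)
class StandardPoint:
    """One dilution-series point: known quantity (ng) and measured Cq."""

    quantity_ng: float
    cq: float

    def __post_init__(self) -> None:
        if self.quantity_ng <= 0:
            raise ValueError(f"standard quantity must be positive, got {self.quantity_ng}")
        if not math.isfinite(self.cq):
            raise ValueError(f"Cq must be finite, got {self.cq}")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Cq = intercept + slope * log10(quantity_ng) line."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[StandardPoint, ...]
    qc_pass: bool
    r2_threshold: float = DEFAULT_R2_THRESHOLD

    @property
    def quantity_span_ng(self) -> tuple[float, float]:
        qs = [p.quantity_ng for p in self.points]
        return (min(qs), max(qs))


class InterpolatedQuantity(NamedTuple):
    """Interpolated quantity with an extrapolation flag."""

    quantity_ng: float
    extrapolated: bool


def mean_cq(cqs: Sequence[float]) -> float:
    """Average technical-replicate Cq values on the Cq scale."""
    arr = np.asarray(cqs, dtype=float)
    if arr.size == 0:
        raise ValueError("no Cq values to average")
    return float(arr.mean())


def build_standard_curve(
    points: Sequence[StandardPoint],
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> StandardCurve:
    """OLS fit of Cq on log10(quantity) with an R^2 quality gate.

    Requires at least three distinct quantities.  R^2 is the squared
    Pearson correlation of the fit; ``qc_pass`` is strict
    (``r_squared > r2_threshold``).
    """
    pts = tuple(points)
    if len(pts) < 3:
        raise ValueError(f"need at least 3 standard points, got {len(pts)}")
    qs = np.array([p.quantity_ng for p in pts])
    if np.unique(qs).size < 3:
        raise ValueError("need at least 3 distinct standard quantities")
    cqs = np.array([p.cq for p in pts])
    fit = stats.linregress(np.log10(qs), cqs)
    r2 = float(fit.rvalue**2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        points=pts,
        qc_pass=r2 > r2_threshold,
        r2_threshold=r2_threshold,
    )


def interpolate_quantity(
    curve: StandardCurve, cq: float, allow_qc_fail: bool = False
) -> InterpolatedQuantity:
    """Invert the standard curve: quantity = 10**((cq - intercept) / slope).

    Raises :class:`QcError` if the curve failed QC (unless overridden with a
    warning) and flags results outside the fitted dilution span as
    extrapolated rather than refusing them.
    """
    if curve.slope >= 0:
        raise ValueError(f"invalid standard curve: slope must be negative, got {curve.slope}")
    if not curve.qc_pass:
        if not allow_qc_fail:
            raise QcError(
                f"standard curve failed QC (R^2 = {curve.r_squared:.4f} "
                f"<= {curve.r2_threshold})"
            )
        warnings.warn(
            f"interpolating against a curve that failed QC (R^2 = {curve.r_squared:.4f})",
            stacklevel=2,
        )
    quantity = 10.0 ** ((cq - curve.intercept) / curve.slope)
    lo, hi = curve.quantity_span_ng
    return InterpolatedQuantity(quantity_ng=quantity, extrapolated=not lo <= quantity <= hi)


def quantity_to_copies(
    quantity_ng: float, mw_g_per_mol: float, entity: str = "mRNA"
) -> CopyCount:
    """Convert an interpolated quantity in ng to a molecule count."""
    if quantity_ng < 0:
        raise ValueError(f"quantity must be non-negative, got {quantity_ng}")
    return mass_to_copies(quantity_ng * 1e-9, mw_g_per_mol, entity=entity)


def quantify_samples(
    standards: pd.DataFrame,
    unknowns: pd.DataFrame,
    mw_g_per_mol: float,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    allow_qc_fail: bool = False,
) -> tuple[StandardCurve, pd.DataFrame]:
    """Batch absolute quantification of a table of unknown Cq values.

    ``standards`` needs columns quantity_ng and cq (replicate rows are fit
    together); ``unknowns`` needs sample_id and cq.  Technical-replicate Cq
    values are averaged per sample before interpolation.  Returns the
    fitted curve and a per-sample table with quantity (ng) and copies.
    """
    points = [
        StandardPoint(quantity_ng=row.quantity_ng, cq=row.cq)
        for row in standards.itertuples()
    ]
    curve = build_standard_curve(points, r2_threshold=r2_threshold)
    rows = []
    for sample_id, group in unknowns.groupby("sample_id", sort=False):
        cq = mean_cq(group["cq"].to_numpy())
        quantity = interpolate_quantity(curve, cq, allow_qc_fail=allow_qc_fail)
        rows.append(
            {
                "sample_id": sample_id,
                "mean_cq": cq,
                "quantity_ng": quantity.quantity_ng,
                "extrapolated": quantity.extrapolated,
                "copies": quantity_to_copies(quantity.quantity_ng, mw_g_per_mol).copies,
            }
        )
    return curve, pd.DataFrame(rows)


def amplification_efficiency(slope: float) -> float:
    """PCR efficiency in percent from the standard-curve slope.

    100% corresponds to perfect doubling (slope -log2(10) ~ -3.3219).
    """
    if slope >= 0:
        raise ValueError(f"slope must be negative, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0
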