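"""Per-well quantification of the four multiplexed assay readouts.

Raw plate-reader measurements are converted to interpretable phenotype
values: Griess optical density -> nitrite concentration (uM) via a sodium
nitrite standard curve; LDH absorbance -> percent cytotoxicity relative to
a lysis-control maximum; wound width time series -> migration velocity
(um/h); phagocytosis fluorescence -> fold over the nontargeting-siRNA
control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CurveError, FitError


class QuantificationWarning(UserWarning):
    """A readout was clamped or flagged during quantification."""


@dataclass
class StandardCurve:
    """Ordinary least-squares calibration line OD = slope * conc + intercept."""

    slope: float  # OD per uM
    intercept: float  # OD
    r_squared: float
    standards: list[tuple[float, float]] = field(default_factory=list)
    low_r2: bool = False


def fit_nitrite_standard_curve(
    standards: Sequence[tuple[float, float]], r2_warn: float = 0.95
) -> StandardCurve:
    """Fit the Griess calibration line to (concentration uM, OD) standards.

    Raises :class:`FitError` with fewer than two distinct concentrations and
    :class:`CurveError` when the fitted slope is not positive (OD must grow
    with nitrite for a valid Griess curve).
    """
    conc = np.asarray([s[0] for s in standards], dtype=float)
    od = np.asarray([s[1] for s in standards], dtype=float)
    if len(np.unique(conc)) < 2:
        raise FitError("need >= 2 distinct standard concentrations")
    res = stats.linregress(conc, od)
    r2 = float(res.rvalue**2)
    if res.slope <= 0:
        raise CurveError(f"non-positive Griess slope ({res.slope:.4g} OD/uM)")
    curve = StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        standards=[(float(c), float(o)) for c, o in standards],
        low_r2=r2 < r2_warn,
    )
    if curve.low_r2:
        warnings.warn(
            f"standard curve r^2 = {r2:.3f} < {r2_warn}", QuantificationWarning, stacklevel=2
        )
    return curve


def nitrite_concentration(od, curve: StandardCurve):
    """Invert the standard curve: conc = (OD - intercept) / slope, clamped at 0.

    Accepts a scalar or array.  Below-blank optical densities (OD below the
    intercept) are clamped to 0 uM and flagged with a warning rather than
    rejected; they are ordinary reader noise around the blank.
    """
    if curve.slope <= 0:
        raise CurveError("invalid standard curve (slope <= 0)")
    od = np.asarray(od, dtype=float)
    conc = (od - curve.intercept) / curve.slope
    if np.any(conc < 0):
        warnings.warn(
            "optical density below blank; clamping to 0 uM",
            QuantificationWarning,
            stacklevel=2,
        )
    conc = np.maximum(conc, 0.0)
    return float(conc) if conc.ndim == 0 else conc


def percent_cytotoxicity(experimental, maximum):
    """% cytotoxicity = 100 x experimental / maximum LDH release.

    ``maximum`` is the same-plate lysis-control (full kill) signal.  Values
    outside [0, 100] are clamped with a warning.
    """
    maximum = float(maximum)
    if maximum <= 0:
        raise ValueError("maximum LDH release must be positive")
    pct = 100.0 * np.asarray(experimental, dtype=float) / maximum
    if np.any((pct < 0) | (pct > 100)):
        warnings.warn(
            "% cytotoxicity outside [0, 100]; clamping", QuantificationWarning, stacklevel=2
        )
    pct = np.clip(pct, 0.0, 100.0)
    return float(pct) if pct.ndim == 0 else pct


def migration_velocity(width_series: Sequence[tuple[float, float]]) -> float:
    """Migration velocity (um/h) from a wound-width time series.

    Uses the two-edge convention: both wound edges advance, so the per-edge
    velocity is (W_first - W_last) / (2 * (t_last - t_first)).  Negative
    velocities (wound widening) are allowed and flagged.
    """
    if len(width_series) < 2:
        raise ValueError("need >= 2 timepoints")
    t = np.asarray([p[0] for p in width_series], dtype=float)
    w = np.asarray([p[1] for p in width_series], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if np.any(w < 0):
        raise ValueError("wound widths must be nonnegative")
    v = (w[0] - w[-1]) / (2.0 * (t[-1] - t[0]))
    if v < 0:
        warnings.warn("wound widened over time (negative velocity)", QuantificationWarning,
                      stacklevel=2)
    return float(v)


def confluence_to_width(relative_confluence, initial_width: float):
    """Convert relative wound confluence (0..1) to an equivalent wound width.

    width = initial_width * (1 - relative wound confluence); provided for
    live-imaging exports that report confluence instead of width.
    """
    if initial_width <= 0:
        raise ValueError("initial_width must be positive")
    rc = np.asarray(relative_confluence, dtype=float)
    if np.any((rc < 0) | (rc > 1)):
        raise ValueError("relative confluence must lie in [0, 1]")
    w = initial_width * (1.0 - rc)
    return float(w) if w.ndim == 0 else w


def phagocytosis_signal(well_fluorescence, neg_control_mean: float, background: float = 0.0):
    """Phagocytosis fold change over the nontargeting control.

    fold = (well - background) / (neg_control_mean - background); the
    denominator must be positive.
    """
    denom = float(neg_control_mean) - float(background)
    if denom <= 0:
        raise ValueError("control mean must exceed background")
    fold = (np.asarray(well_fluorescence, dtype=float) - background) / denom
    return float(fold) if fold.ndim == 0 else fold
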