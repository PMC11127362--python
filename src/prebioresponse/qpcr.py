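"""Absolute quantification of target genes by qPCR.

Standard curves relate cycle-threshold (CT) values linearly to log10
template copies over the curve's dynamic range.  Unknowns are quantified
by inverting a fitted curve; *Bifidobacterium* cell counts use the same
machinery with log10 CFU/ml on the abscissa.

Non-detect wells are represented by ``None``/``NaN`` CT values and
propagate to a copy number of 0 in downstream feature matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

# Molar mass of one base pair of double-stranded DNA, g/mol.
BP_MOLAR_MASS = 660.0
# Avogadro's number as used in the copy-number formula.
AVOGADRO = 6.023e23

#: slope band (CT per log10 copies) corresponding to amplification
#: efficiencies roughly between 90% and 110%
EFFICIENCY_SLOPE_BAND = (-3.6, -3.1)


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of CT against log10 quantity.

    ``slope`` is in CT per log10(copies) and must be negative (more
    template -> earlier amplification).  ``dynamic_range`` is the
    (min, max) log10 quantity spanned by the calibration series.
    """

    slope: float
    intercept: float
    r2: float
    dynamic_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")


def copies_from_concentration(
    conc_ng_per_ul: float, product_size_bp: float, volume_ul: float
) -> float:
    """Gene copies in a purified PCR product aliquot.

    copies = conc[ng/ul] * 1e-9[g/ng] * (1/660)[mol bp/g] * 6.023e23[bp/mol]
             * (1/size)[copy/bp] * volume[ul]
    """
    if product_size_bp <= 0:
        raise ValueError("product_size_bp must be > 0")
    if conc_ng_per_ul < 0 or volume_ul < 0:
        raise ValueError("concentration and volume must be >= 0")
    return (
        conc_ng_per_ul
        * 1e-9
        / BP_MOLAR_MASS
        * AVOGADRO
        / product_size_bp
        * volume_ul
    )


def fit_standard_curve(copies, ct) -> StandardCurve:
    """OLS fit of CT on log10(copies) from a dilution series.

    Requires at least three distinct dilution levels.  Emits a warning
    when the slope falls outside the amplification-efficiency sanity
    band of [-3.6, -3.1] CT per decade.
    """
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.shape != ct.shape:
        raise ValueError("copies and ct must have equal length")
    if np.any(copies <= 0):
        raise ValueError("standard copies must be > 0")
    log10c = np.log10(copies)
    if np.unique(np.round(log10c, 9)).size < 3:
        raise ValueError("need >= 3 distinct dilution levels to fit a curve")
    res = stats.linregress(log10c, ct)
    lo, hi = EFFICIENCY_SLOPE_BAND
    if not (lo <= res.slope <= hi):
        warnings.warn(
            f"standard-curve slope {res.slope:.3f} outside efficiency band "
            f"[{lo}, {hi}]",
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        dynamic_range=(float(log10c.min()), float(log10c.max())),
    )


def quantify_unknown(curve: StandardCurve, ct):
    """Invert a standard curve: CT -> copies.

    ``ct`` may be a scalar or array; non-detect (None/NaN) maps to NaN
    copies (downstream feature construction encodes these as 0).
    Returns ``(copies, extrapolated)`` where ``extrapolated`` flags
    results outside the curve's dynamic range.
    """
    ct_arr = np.asarray(ct, dtype=float)
    log10q = (ct_arr - curve.intercept) / curve.slope
    copies = np.power(10.0, log10q)
    lo, hi = curve.dynamic_range
    with np.errstate(invalid="ignore"):
        extrapolated = (log10q < lo) | (log10q > hi)
    copies = np.where(np.isnan(ct_arr), np.nan, copies)
    if np.ndim(ct) == 0:
        return float(copies), bool(extrapolated)
    return copies, extrapolated


def bifido_cfu(curve_cfu: StandardCurve, ct):
    """Quantify *Bifidobacterium* in CFU/ml from a CT-vs-log10(CFU/ml) curve."""
    return quantify_unknown(curve_cfu, ct)


def is_nondetect(ct) -> bool:
    """True when a CT value encodes a non-detect well."""
    return ct is None or (isinstance(ct, float) and math.isnan(ct))
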