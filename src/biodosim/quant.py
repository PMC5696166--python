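"""Direct quantification formulas for gamma-counting and imaging data.

These are the small, dimensionally exact conversions every biodistribution
study rests on: counts → %ID/g against a standard, target-to-background
contrast, receptor-blocking remaining-uptake percentage, in-vitro cell-bound
fraction, caliper tumor volume and PET standardized uptake value.
"""
from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

from .errors import InvalidInputError

log = logging.getLogger(__name__)


def percent_id_per_gram(sample_counts: float, standard_counts: float, mass_g: float) -> float:
    """Percent injected dose per gram from gamma-counter counts.

    ``standard_counts`` is the count rate of a standard representing 100 %
    of the injected dose, measured with the same geometry/efficiency as the
    sample, so counter efficiency cancels.
    """
    if standard_counts <= 0:
        raise InvalidInputError(f"standard_counts must be > 0, got {standard_counts}")
    if mass_g <= 0:
        raise InvalidInputError(f"mass_g must be > 0, got {mass_g}")
    if sample_counts < 0:
        raise InvalidInputError(f"sample_counts must be >= 0, got {sample_counts}")
    return sample_counts / standard_counts * 100.0 / mass_g


def tumor_to_background(tumor_pidg: float, background_pidg: float) -> float:
    """Target-to-background contrast ratio (e.g. tumor/blood, tumor/muscle)."""
    if background_pidg <= 0:
        raise InvalidInputError(f"background must be > 0, got {background_pidg}")
    if tumor_pidg < 0:
        raise InvalidInputError(f"tumor uptake must be >= 0, got {tumor_pidg}")
    return tumor_pidg / background_pidg


def blocking_fraction(unblocked_pidg: float, blocked_pidg: float) -> float:
    """Remaining uptake (%) after receptor blocking with excess cold antibody.

    Reported as ``blocked / unblocked × 100``: "reduced to X %" phrasing,
    so complete blocking → 0 and no blocking → 100.
    """
    if unblocked_pidg <= 0:
        raise InvalidInputError(f"unblocked uptake must be > 0, got {unblocked_pidg}")
    if blocked_pidg < 0:
        raise InvalidInputError(f"blocked uptake must be >= 0, got {blocked_pidg}")
    return blocked_pidg / unblocked_pidg * 100.0


def cell_bound_percent(total_bound: float, nonspecific: float, applied: float) -> float:
    """Specific cell-bound radioactivity (%) from an in-vitro binding assay.

    ``(total bound − nonspecific) / applied × 100``.  A negative result
    (nonspecific exceeding total) is evidence of an assay problem; it is
    returned as-is with a logged warning rather than clamped.
    """
    if applied <= 0:
        raise InvalidInputError(f"applied activity must be > 0, got {applied}")
    result = (total_bound - nonspecific) / applied * 100.0
    if result < 0:
        log.warning(
            "negative specific binding (%.3g%%): nonspecific %.3g exceeds total bound %.3g",
            result, nonspecific, total_bound,
        )
    return result


def tumor_volume_mm3(long_diameter_mm: float, short_diameter_mm: float) -> float:
    """Caliper tumor volume: ``long × short² / 2`` (mm³)."""
    if long_diameter_mm <= 0 or short_diameter_mm <= 0:
        raise InvalidInputError("tumor diameters must be > 0")
    if long_diameter_mm < short_diameter_mm:
        log.warning(
            "long diameter %.3g mm < short diameter %.3g mm; check caliper axes",
            long_diameter_mm, short_diameter_mm,
        )
    return long_diameter_mm * short_diameter_mm**2 / 2.0


def suv(tissue_concentration: float, injected_activity: float, body_weight_g: float) -> float:
    """Standardized uptake value (dimensionless).

    ``tissue activity concentration (per gram) × body weight / injected
    activity``; equivalently ``%ID/g / 100 × body weight``.
    """
    if injected_activity <= 0:
        raise InvalidInputError(f"injected_activity must be > 0, got {injected_activity}")
    if body_weight_g <= 0:
        raise InvalidInputError(f"body_weight_g must be > 0, got {body_weight_g}")
    return tissue_concentration * body_weight_g / injected_activity


def suv_from_pidg(pidg: float, body_weight_g: float) -> float:
    """SUV from %ID/g: ``pidg / 100 × body weight (g)``."""
    if body_weight_g <= 0:
        raise InvalidInputError(f"body_weight_g must be > 0, got {body_weight_g}")
    return pidg / 100.0 * body_weight_g


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding used for report tables (12.85 → 12.9)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
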