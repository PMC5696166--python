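"""Organ time-activity kinetics: mono-exponential fits and cumulated activity.

The dosimetry chain needs, per source region, the cumulated activity
Ã = ∫ A(t) dt — the total number of decays occurring there — per unit
injected activity (the residence time τ).  Curves are fitted to the
per-timepoint *means* of the biodistribution data.  Two integration schemes
are provided:

* ``monoexp``: closed-form integral of a fitted A0·exp(−λ_bio·t) curve with
  physical decay re-applied, Ã = (A0/100)·injected / (λ_bio + λ_phys).
  Appropriate for washout-only organs.
* ``hybrid``: trapezoidal integration of the measured, decay-inclusive curve
  over the sampled interval plus an analytic tail beyond the last timepoint.
  A single falling exponential cannot represent an organ that is still
  accumulating (a tumor peaking days after injection); the hybrid scheme
  handles any curve shape and is the default whenever the fitted biological
  rate is negative.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, FitError, InvalidInputError
from .nuclides import LN2, NuclideSpec, decay_factor

log = logging.getLogger(__name__)


@dataclass
class TimeActivityCurve:
    """Mean uptake of one organ over time.

    ``values`` are %ID/g (``units="%ID/g"``, per-gram concentration) or %ID
    (``units="%ID"``, whole-organ content, as produced by human
    extrapolation).  ``decay_corrected=True`` means values are corrected to
    injection time; integration re-applies physical decay.
    """

    organ: str
    times_h: np.ndarray
    values: np.ndarray
    nuclide: NuclideSpec
    decay_corrected: bool = True
    units: str = "%ID/g"
    sd: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.shape != self.values.shape:
            raise InvalidInputError("times and values must have equal length")
        if len(self.times_h) < 2:
            raise InvalidInputError("a time-activity curve needs >= 2 points")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.times_h < 0) or np.any(self.values < 0):
            raise InvalidInputError("negative time or uptake in curve")
        if self.units not in ("%ID/g", "%ID"):
            raise InvalidInputError(f"units must be %ID/g or %ID, got {self.units!r}")

    def decay_inclusive_values(self) -> np.ndarray:
        """Curve with physical decay applied (what a detector would see)."""
        if self.decay_corrected:
            return self.values * decay_factor(self.nuclide, self.times_h)
        return self.values


@dataclass
class MonoExpFit:
    """Fitted A(t) = a0 · exp(−λ_bio · t) for one decay-corrected curve.

    ``lambda_bio_raw`` keeps the unclamped estimate as a diagnostic; a
    negative raw rate flags an accumulating organ, for which ``lambda_bio``
    is clamped to 0 before integration (the fitted washout would otherwise
    diverge).  ``lambda_eff = lambda_bio + ln2/T_half`` governs the in-vivo
    activity decline.  ``rss`` is the residual sum of squares in the log
    domain the fit was performed in.
    """

    organ: str
    a0: float
    lambda_bio_raw: float
    nuclide: NuclideSpec
    rss: float = 0.0
    method: str = "loglinear"
    units: str = "%ID/g"

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise FitError(f"fitted a0 must be > 0, got {self.a0}")

    @property
    def lambda_bio(self) -> float:
        """Biological rate used for integration (raw value floored at 0)."""
        return max(self.lambda_bio_raw, 0.0)

    @property
    def lambda_eff(self) -> float:
        return self.lambda_bio + self.nuclide.lambda_phys

    @property
    def accumulating(self) -> bool:
        return self.lambda_bio_raw < 0

    def predict(self, t_h) -> np.ndarray:
        """Decay-corrected model value at ``t_h``."""
        return self.a0 * np.exp(-self.lambda_bio * np.asarray(t_h, dtype=float))


@dataclass
class CumulatedActivity:
    """Cumulated activity of one source region and its residence time.

    ``value`` is MBq·h — per gram of tissue when ``per="gram"`` (curve in
    %ID/g) or per whole organ when ``per="organ"`` (curve in %ID).
    ``residence_time_h`` is value / injected activity, the quantity a MIRD
    dose engine consumes.
    """

    organ: str
    value_mbq_h: float
    residence_time_h: float
    per: str
    scheme: str

    def __post_init__(self) -> None:
        if self.value_mbq_h < 0 or self.residence_time_h < 0:
            raise InvalidInputError("cumulated activity must be >= 0")


def fit_monoexp(tac: TimeActivityCurve, weighting: str = "none",
                method: str = "loglinear") -> MonoExpFit:
    """Fit a single falling exponential to a decay-corrected mean curve.

    Default is ordinary least squares on log-transformed means (the classic
    linearization: reproducible, no starting-value sensitivity).
    ``method="nlls"`` refines it by nonlinear least squares on the natural
    scale.  Zero/non-positive means are excluded with a warning; at least two
    positive points are required.  A constant curve yields ``lambda_bio = 0``.
    """
    if weighting not in ("none",):
        raise ConfigError(f"unknown weighting {weighting!r}")
    if method not in ("loglinear", "nlls"):
        raise ConfigError(f"unknown fit method {method!r}")
    if not tac.decay_corrected:
        raise FitError("fit_monoexp expects a decay-corrected curve")
    mask = tac.values > 0
    if np.count_nonzero(~mask):
        log.warning("%s: excluding %d non-positive points from fit",
                    tac.organ, int(np.count_nonzero(~mask)))
    t, y = tac.times_h[mask], tac.values[mask]
    if len(t) < 2:
        raise FitError(f"{tac.organ}: fewer than 2 positive points to fit")
    logy = np.log(y)
    slope, intercept = np.polyfit(t, logy, 1)
    a0, lam = math.exp(intercept), -slope
    if abs(lam) < 1e-12:  # flat curve up to round-off
        lam = 0.0
    if method == "nlls":
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(lambda tt, a, l: a * np.exp(-l * tt), t, y,
                            p0=[a0, lam], maxfev=10000)
        a0, lam = float(popt[0]), float(popt[1])
    rss = float(np.sum((np.log(a0) - lam * t - logy) ** 2))
    fit = MonoExpFit(organ=tac.organ, a0=a0, lambda_bio_raw=lam,
                     nuclide=tac.nuclide, rss=rss, method=method, units=tac.units)
    if fit.accumulating:
        log.info("%s: fitted lambda_bio %.4g/h < 0 (accumulating); clamped to 0 "
                 "for integration", tac.organ, lam)
    return fit


def cumulated_activity_monoexp(fit: MonoExpFit, injected_mbq: float) -> CumulatedActivity:
    """Closed-form Ã of a fitted mono-exponential with physical decay.

    Ã = (a0/100) · injected / λ_eff, the integral of
    a0·e^(−λ_bio t)·e^(−λ_phys t) from 0 to ∞.
    """
    if injected_mbq <= 0:
        raise InvalidInputError(f"injected_mbq must be > 0, got {injected_mbq}")
    lam_eff = fit.lambda_eff
    if lam_eff <= 0:
        raise FitError("lambda_eff must be > 0 (physical decay guarantees this)")
    value = fit.a0 / 100.0 * injected_mbq / lam_eff
    return CumulatedActivity(
        organ=fit.organ, value_mbq_h=value,
        residence_time_h=value / injected_mbq,
        per="gram" if fit.units == "%ID/g" else "organ",
        scheme="monoexp",
    )


def cumulated_activity_hybrid(tac: TimeActivityCurve, injected_mbq: float,
                              tail: str = "physical",
                              t0_mode: str = "zero") -> CumulatedActivity:
    """Trapezoid-plus-analytic-tail Ã for arbitrary curve shapes.

    The decay-inclusive curve is integrated by the trapezoidal rule from
    t = 0 to the last timepoint, then an analytic tail is added from the
    last measured value y_end:

    * ``tail="physical"``: y_end / λ_phys — the organ retains its activity
      and only physical decay removes it (conservative for dose).
    * ``tail="fitted"``: y_end / λ_term with λ_term the effective terminal
      slope estimated from the last two decay-inclusive points, floored at
      λ_phys (biological clearance cannot be negative in the tail).

    ``t0_mode="zero"`` anchors the curve at (0, 0) — tissues fill from blood
    after injection; ``t0_mode="extrapolate"`` back-extrapolates the first
    two decay-inclusive points log-linearly to t = 0 (blood itself starts at
    its distribution-volume concentration).  If the curve already samples
    t = 0 the anchor is not added.
    """
    if tail not in ("physical", "fitted"):
        raise ConfigError(f"unknown tail {tail!r}; use physical|fitted")
    if t0_mode not in ("zero", "extrapolate"):
        raise ConfigError(f"unknown t0_mode {t0_mode!r}; use zero|extrapolate")
    if injected_mbq <= 0:
        raise InvalidInputError(f"injected_mbq must be > 0, got {injected_mbq}")

    t = tac.times_h
    y = tac.decay_inclusive_values()
    if t[0] > 0:
        if t0_mode == "zero":
            y0 = 0.0
        else:
            if y[0] > 0 and y[1] > 0:
                slope = (math.log(y[1]) - math.log(y[0])) / (t[1] - t[0])
                y0 = y[0] * math.exp(-slope * t[0])
            else:
                y0 = y[0]
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[y0], y])

    area = float(np.trapezoid(y, t))
    y_end = float(y[-1])
    lam_phys = tac.nuclide.lambda_phys
    if y_end > 0:
        if tail == "physical":
            lam_tail = lam_phys
        else:
            if y[-2] > 0:
                lam_term = (math.log(y[-2]) - math.log(y_end)) / (t[-1] - t[-2])
            else:
                lam_term = lam_phys
            lam_tail = max(lam_term, lam_phys)
        area += y_end / lam_tail
    value = area / 100.0 * injected_mbq
    return CumulatedActivity(
        organ=tac.organ, value_mbq_h=value,
        residence_time_h=value / injected_mbq,
        per="gram" if tac.units == "%ID/g" else "organ",
        scheme=f"hybrid-{tail}",
    )


def cumulated_activity_auto(tac: TimeActivityCurve, injected_mbq: float,
                            tail: str = "physical") -> tuple[CumulatedActivity, MonoExpFit]:
    """Default pipeline scheme selection.

    Fits a mono-exponential; if the raw biological rate is non-negative the
    closed-form integral is used, otherwise (accumulating organ) the hybrid
    trapezoid-plus-tail scheme.  Returns the cumulated activity and the fit
    (kept for reporting either way).
    """
    fit = fit_monoexp(tac)
    if fit.accumulating:
        return cumulated_activity_hybrid(tac, injected_mbq, tail=tail), fit
    return cumulated_activity_monoexp(fit, injected_mbq), fit


def residence_time_bound_h(nuclide: NuclideSpec) -> float:
    """Upper bound τ = T½/ln2: all injected activity decays in place."""
    return nuclide.half_life_h / LN2


def tac_from_study(study, organ: str) -> TimeActivityCurve:
    """Mean time-activity curve of one organ from a biodistribution study."""
    means = study.organ_means(organ)
    return TimeActivityCurve(
        organ=organ,
        times_h=means["time_h"].to_numpy(),
        values=means["mean"].to_numpy(),
        nuclide=study.nuclide,
        decay_corrected=study.decay_corrected,
        units="%ID/g",
        sd=means["sd"].to_numpy(),
        n=means["n"].to_numpy(),
    )
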