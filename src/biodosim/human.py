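"""Mouse-to-human extrapolation of organ kinetics.

Murine %ID/g curves are converted to human whole-organ %ID curves with the
percent-kg/g (relative organ mass) method,

    %ID_human,organ(t) = %ID/g_mouse(t) · M_mouse(kg) · m_organ,human(g) / M_human(kg),

applied timepoint-wise, assuming pharmacokinetics are species-invariant on
that relative scale.  The scaled curves then follow the same fitting and
integration path as mouse curves, yielding human source-organ residence
times for the MIRD dose engine.  A ``direct`` mode (no mass adjustment,
%ID_human = %ID/g_mouse · m_organ,human) is available for sensitivity
analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, MappingError
from .pk import (CumulatedActivity, TimeActivityCurve, cumulated_activity_auto,
                 residence_time_bound_h, tac_from_study)
from .study import BiodistributionStudy

log = logging.getLogger(__name__)

REMAINDER_LABEL = "remainder of body"
WHOLE_BODY_LABEL = "whole body"


@dataclass
class HumanPhantom:
    """Reference-human organ masses.

    ``organ_masses_g`` maps lower-case organ labels to grams; their sum must
    not exceed the body mass (the difference is the remainder of body).
    """

    body_mass_kg: float = 70.0
    organ_masses_g: dict[str, float] = field(default_factory=dict)
    name: str = "adult"

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise InvalidInputError("phantom body mass must be > 0")
        self.organ_masses_g = {k.strip().lower(): float(v)
                               for k, v in self.organ_masses_g.items()}
        for organ, mass in self.organ_masses_g.items():
            if mass <= 0:
                raise InvalidInputError(f"phantom organ {organ!r} mass must be > 0")
        total = sum(self.organ_masses_g.values())
        if total > self.body_mass_kg * 1000.0:
            raise InvalidInputError(
                f"phantom organ masses sum to {total:.0f} g > body mass "
                f"{self.body_mass_kg * 1000:.0f} g")

    def mass_g(self, organ: str) -> float:
        key = organ.strip().lower()
        if key not in self.organ_masses_g:
            raise MappingError(
                f"organ {organ!r} not in phantom {self.name!r}; known organs: "
                + ", ".join(sorted(self.organ_masses_g)))
        return self.organ_masses_g[key]


@dataclass
class ResidenceTimeSet:
    """Per-source-organ residence times (h), mouse- or human-scale.

    Includes a remainder-of-body entry when total-body accounting was
    possible.  The physical bound Σ τ ≤ T½/ln2 holds whenever recovered
    activity never exceeds 100 %ID.
    """

    residence_h: dict[str, float]
    scale: str
    nuclide_name: str = ""
    schemes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("mouse", "human"):
            raise InvalidInputError(f"scale must be mouse|human, got {self.scale!r}")
        for organ, tau in self.residence_h.items():
            if tau < 0:
                raise InvalidInputError(f"negative residence time for {organ!r}")

    @property
    def total_h(self) -> float:
        return float(sum(self.residence_h.values()))


def human_percent_id(pidg_mouse: float, mouse_body_kg: float,
                     organ_mass_human_g: float, human_body_kg: float) -> float:
    """Percent-kg/g scaling of one %ID/g value to a human whole-organ %ID."""
    if min(mouse_body_kg, organ_mass_human_g, human_body_kg) <= 0:
        raise InvalidInputError("all masses must be > 0")
    if pidg_mouse < 0:
        raise InvalidInputError("%ID/g must be >= 0")
    return pidg_mouse * mouse_body_kg * organ_mass_human_g / human_body_kg


def load_aliases(path=None) -> dict[str, str]:
    """Organ alias map (lower-cased); packaged defaults unless ``path`` given."""
    import csv
    from importlib import resources

    if path is None:
        src = resources.files("biodosim.data").joinpath("organ_aliases.csv").open()
    else:
        src = open(path)
    aliases: dict[str, str] = {}
    with src as fh:
        for row in csv.reader(line for line in fh if not line.startswith("#")):
            if len(row) != 2 or row[0] == "alias":
                continue
            aliases[row[0].strip().lower()] = row[1].strip().lower()
    return aliases


def _canonical(organ: str, aliases: dict[str, str]) -> str:
    key = organ.strip().lower().rstrip(".")
    for candidate in (organ.strip().lower(), key, key.replace(" ", "")):
        if candidate in aliases:
            return aliases[candidate]
    return key


def map_organ(organ: str, phantom: HumanPhantom,
              aliases: dict[str, str] | None = None) -> str | None:
    """Phantom organ name for a study label, or None if unmappable."""
    aliases = aliases if aliases is not None else load_aliases()
    name = _canonical(organ, aliases)
    if name in phantom.organ_masses_g or name == WHOLE_BODY_LABEL:
        return name
    return None


def extrapolate_residence_times(
    study: BiodistributionStudy,
    phantom: HumanPhantom,
    mouse_body_kg: float = 0.020,
    method: str = "percent_kg_per_g",
    tail: str = "physical",
    aliases: dict[str, str] | None = None,
    exclude: tuple[str, ...] = ("tumor",),
) -> ResidenceTimeSet:
    """Human source-organ residence times from a mouse biodistribution study.

    Each mappable organ's mean %ID/g curve is scaled to a human %ID curve,
    fitted and integrated (closed-form mono-exponential, or hybrid trapezoid
    for accumulating organs).  The remainder-of-body residence time is the
    total-body residence time minus the organ sum, floored at 0; total-body
    retention comes from a whole-body curve when the study has one, else
    from the physical-decay bound T½/ln2 with a logged warning.  Organs in
    ``exclude`` (the xenograft tumor by default — humans have no implanted
    tumor source) and unmappable organs are skipped with a warning.
    """
    if method not in ("percent_kg_per_g", "direct"):
        raise InvalidInputError(f"unknown extrapolation method {method!r}")
    if mouse_body_kg <= 0:
        raise InvalidInputError("mouse_body_kg must be > 0")
    aliases = aliases if aliases is not None else load_aliases()

    residence: dict[str, float] = {}
    schemes: dict[str, str] = {}
    whole_body_tau: float | None = None
    mapped_any = False
    for organ in study.organs:
        target = map_organ(organ, phantom, aliases)
        if target is None:
            if organ.strip().lower() not in exclude:
                log.warning("organ %r not mappable to phantom %r; skipped",
                            organ, phantom.name)
            continue
        tac = tac_from_study(study, organ)
        if target == WHOLE_BODY_LABEL:
            # whole-body %ID/g × mouse body mass (g) = retained fraction (%ID),
            # assumed species-invariant
            if not np.any(tac.values > 0):
                whole_body_tau = 0.0
                schemes[WHOLE_BODY_LABEL] = "zero"
                mapped_any = True
                continue
            human_values = tac.values * mouse_body_kg * 1000.0
            human_tac = TimeActivityCurve(
                organ=WHOLE_BODY_LABEL, times_h=tac.times_h, values=human_values,
                nuclide=tac.nuclide, decay_corrected=tac.decay_corrected, units="%ID")
            ca, _ = cumulated_activity_auto(human_tac, injected_mbq=1.0, tail=tail)
            whole_body_tau = ca.residence_time_h
            schemes[WHOLE_BODY_LABEL] = ca.scheme
            mapped_any = True
            continue
        if organ.strip().lower() in exclude:
            continue
        mass_h = phantom.mass_g(target)
        if not np.any(tac.values > 0):
            residence[target] = 0.0
            schemes[target] = "zero"
            mapped_any = True
            continue
        if method == "percent_kg_per_g":
            values = human_percent_id(1.0, mouse_body_kg, mass_h,
                                      phantom.body_mass_kg) * tac.values
        else:
            values = tac.values * mass_h / 1000.0  # direct: g→kg bookkeeping only
        human_tac = TimeActivityCurve(
            organ=target, times_h=tac.times_h, values=values,
            nuclide=tac.nuclide, decay_corrected=tac.decay_corrected, units="%ID",
            sd=None, n=None)
        t0_mode = "extrapolate" if target == "blood" else "zero"
        fit_scheme_ca, fit = cumulated_activity_auto(human_tac, injected_mbq=1.0, tail=tail)
        if fit.accumulating and t0_mode == "extrapolate":
            from .pk import cumulated_activity_hybrid

            fit_scheme_ca = cumulated_activity_hybrid(human_tac, 1.0, tail=tail,
                                                      t0_mode=t0_mode)
        residence[target] = fit_scheme_ca.residence_time_h
        schemes[target] = fit_scheme_ca.scheme
        mapped_any = True
    if not mapped_any:
        raise MappingError(
            "no study organ maps onto the phantom; study organs: "
            + ", ".join(study.organs))

    bound = residence_time_bound_h(study.nuclide)
    if whole_body_tau is None:
        if any(tau > 0 for tau in residence.values()):
            log.warning("no whole-body curve in study; remainder of body computed "
                        "from the physical-decay bound T1/2/ln2 = %.3g h", bound)
            whole_body_tau = bound
        else:
            whole_body_tau = 0.0  # nothing retained anywhere
    organ_sum = sum(residence.values())
    residence[REMAINDER_LABEL] = max(whole_body_tau - organ_sum, 0.0)
    schemes[REMAINDER_LABEL] = "difference"
    return ResidenceTimeSet(residence_h=residence, scale="human",
                            nuclide_name=study.nuclide.name, schemes=schemes)
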