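"""MIRD-schema absorbed-dose calculation from residence times.

The MIRD formalism writes the absorbed dose to a target region as
D(target) = Σ_source τ(source) · S(target ← source), with τ the residence
time (MBq·h per MBq injected) and S the absorbed dose per unit cumulated
activity for the nuclide/phantom pair.

Without a user-supplied S-value file the engine runs in *self-dose-only*
mode: each source irradiates itself through local deposition of its
non-penetrating (electron) emissions, S_self = Δ_np / m.  For a low-energy
beta emitter such as Lu-177 this is the dominant dose term; cross-organ
photon dose is omitted and every report says so.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import DosimetryError, InvalidInputError
from .human import REMAINDER_LABEL, HumanPhantom, ResidenceTimeSet
from .nuclides import NuclideSpec

log = logging.getLogger(__name__)

#: decays per MBq·h
DECAYS_PER_MBQ_H = 3.6e9
#: joule per keV
J_PER_KEV = 1.602176634e-16
#: unit identity: 1 mGy/MBq = 3.7 rad/mCi
RAD_PER_MCI_PER_MGY_PER_MBQ = 3.7


def self_dose_factor(nuclide: NuclideSpec, mass_g: float) -> float:
    """Self-dose S value under local energy deposition, mGy/(MBq·h).

    All non-penetrating (electron) energy is absorbed in the source mass;
    photons escape and are ignored (absorbed-fraction hooks live in the
    sphere model).  S = 3.6e9 decays · E_np(keV) · 1.602e−16 J/keV / m(kg).
    """
    if mass_g <= 0:
        raise InvalidInputError(f"mass_g must be > 0, got {mass_g}")
    joules_per_mbq_h = DECAYS_PER_MBQ_H * nuclide.mean_nonpenetrating_energy_kev * J_PER_KEV
    gy_per_mbq_h = joules_per_mbq_h / (mass_g * 1e-3)
    return gy_per_mbq_h * 1e3  # Gy → mGy


@dataclass
class SMatrix:
    """S values, mGy/(MBq·h), keyed by (target, source) organ pairs."""

    values: dict[tuple[str, str], float]
    phantom_name: str = ""
    nuclide_name: str = ""

    def __post_init__(self) -> None:
        self.values = {(t.strip().lower(), s.strip().lower()): float(v)
                       for (t, s), v in self.values.items()}
        for key, v in self.values.items():
            if v < 0:
                raise InvalidInputError(f"negative S value for {key}")

    def sources(self) -> set[str]:
        return {s for _, s in self.values}

    def targets(self) -> set[str]:
        return {t for t, _ in self.values}

    @classmethod
    def self_dose_only(cls, nuclide: NuclideSpec, phantom: HumanPhantom,
                       extra_masses_g: dict[str, float] | None = None) -> "SMatrix":
        """Diagonal S matrix from local electron deposition in phantom organs."""
        masses = dict(phantom.organ_masses_g)
        masses[REMAINDER_LABEL] = max(
            phantom.body_mass_kg * 1000.0 - sum(phantom.organ_masses_g.values()), 1.0)
        if extra_masses_g:
            masses.update({k.strip().lower(): v for k, v in extra_masses_g.items()})
        values = {(organ, organ): self_dose_factor(nuclide, m)
                  for organ, m in masses.items()}
        return cls(values=values, phantom_name=phantom.name, nuclide_name=nuclide.name)


@dataclass
class DoseReport:
    """Absorbed dose per unit injected activity, per target organ.

    ``doses_mgy_per_mbq`` maps organ → mGy/MBq; ``rad_per_mci`` is the same
    column in the customary US unit (× 3.7 exactly).
    """

    doses_mgy_per_mbq: dict[str, float]
    whole_body_mgy_per_mbq: float | None = None
    mode: str = "self-dose-only"
    nuclide_name: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for organ, d in self.doses_mgy_per_mbq.items():
            if d < 0:
                raise InvalidInputError(f"negative dose for {organ!r}")

    @property
    def rad_per_mci(self) -> dict[str, float]:
        return {o: d * RAD_PER_MCI_PER_MGY_PER_MBQ
                for o, d in self.doses_mgy_per_mbq.items()}

    def ranked(self) -> list[tuple[str, float]]:
        """(organ, mGy/MBq) sorted by descending dose."""
        return sorted(self.doses_mgy_per_mbq.items(), key=lambda kv: -kv[1])


def organ_doses(residence: ResidenceTimeSet, s: SMatrix,
                drop_missing: bool = False) -> DoseReport:
    """MIRD sum D(target) = Σ_source τ(source) × S(target ← source)."""
    sources = s.sources()
    tau = dict(residence.residence_h)
    for organ in list(tau):
        if organ not in sources:
            if not drop_missing:
                raise DosimetryError(
                    f"source {organ!r} has no S entries (known sources: "
                    + ", ".join(sorted(sources)) + "); pass drop_missing=True to skip")
            log.warning("source %r has no S entries; dropped from dose sum", organ)
            tau.pop(organ)
    for organ in tau:
        if (organ, organ) not in s.values:
            raise DosimetryError(f"missing self-dose S entry for source {organ!r}")
    doses: dict[str, float] = {}
    for target in sorted(s.targets()):
        d = sum(t * s.values.get((target, source), 0.0) for source, t in tau.items())
        doses[target] = d
    mode = "self-dose-only" if all(t == s_ for t, s_ in s.values) else "s-matrix"
    notes = []
    if mode == "self-dose-only":
        notes.append("self-dose-only engine: local electron deposition; "
                     "cross-organ photon dose omitted")
    return DoseReport(doses_mgy_per_mbq=doses, mode=mode,
                      nuclide_name=s.nuclide_name or residence.nuclide_name,
                      notes=notes)


def whole_body_dose(residence: ResidenceTimeSet, nuclide: NuclideSpec,
                    body_mass_kg: float = 70.0) -> float:
    """Whole-body absorbed dose, mGy/MBq.

    Total residence time (all sources including remainder of body) times the
    self-dose factor of the whole body mass: the non-penetrating energy of
    every decay in the body is deposited in the body.
    """
    if body_mass_kg <= 0:
        raise InvalidInputError("body_mass_kg must be > 0")
    if REMAINDER_LABEL not in residence.residence_h:
        log.warning("no remainder-of-body entry; whole-body dose computed over "
                    "listed sources only")
    return residence.total_h * self_dose_factor(nuclide, body_mass_kg * 1000.0)
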