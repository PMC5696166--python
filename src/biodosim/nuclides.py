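"""Nuclide physical constants and radioactive-decay helpers.

Constants live in ``data/nuclides.yaml`` (half-life, mean non-penetrating
energy per decay, principal photon lines) so that adding a nuclide never
requires a code change.  Non-penetrating means electrons — beta spectrum
mean plus conversion and Auger electrons — which for a therapeutic
beta emitter like Lu-177 carry the locally absorbed dose.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigError, InvalidInputError

LN2 = math.log(2.0)


@dataclass(frozen=True)
class NuclideSpec:
    """Physical constants of one radionuclide.

    Parameters
    ----------
    name : str
        Display label, e.g. ``"Lu-177"``.
    half_life_h : float
        Physical half-life in hours; must be positive.
    mean_nonpenetrating_energy_kev : float
        Mean energy emitted per decay as electrons (keV).
    photon_emissions : tuple of (float, float)
        Principal photon lines as ``(energy_kev, yield_per_decay)``;
        may be empty.  Yields must lie in [0, 1].
    """

    name: str
    half_life_h: float
    mean_nonpenetrating_energy_kev: float
    photon_emissions: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise InvalidInputError(f"half_life_h must be > 0, got {self.half_life_h}")
        if self.mean_nonpenetrating_energy_kev < 0:
            raise InvalidInputError("mean_nonpenetrating_energy_kev must be >= 0")
        for energy, yld in self.photon_emissions:
            if not 0.0 <= yld <= 1.0:
                raise InvalidInputError(f"photon yield {yld} outside [0, 1]")
            if energy <= 0:
                raise InvalidInputError(f"photon energy {energy} must be > 0")

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant, 1/h."""
        return LN2 / self.half_life_h


def decay_factor(nuclide: NuclideSpec, t_h) -> float | np.ndarray:
    """Fraction of activity remaining after ``t_h`` hours of physical decay.

    ``exp(-ln2 * t / T_half)``.  Decay-correcting a raw measurement back to
    injection time divides by this factor; applying decay multiplies by it.
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("decay time must be >= 0")
    out = np.exp(-LN2 * t / nuclide.half_life_h)
    return float(out) if np.ndim(t_h) == 0 else out


def _load_table() -> dict:
    with resources.files("biodosim.data").joinpath("nuclides.yaml").open() as fh:
        return yaml.safe_load(fh)


def available_nuclides() -> list[str]:
    """Keys accepted by :func:`get_nuclide`."""
    return sorted(_load_table())


def get_nuclide(key: str) -> NuclideSpec:
    """Look up a packaged nuclide by key (``"lu177"``, ``"cu64"``, ...)."""
    table = _load_table()
    norm = key.strip().lower().replace("-", "")
    if norm not in table:
        raise ConfigError(f"unknown nuclide {key!r}; available: {', '.join(sorted(table))}")
    entry = table[norm]
    return NuclideSpec(
        name=entry["name"],
        half_life_h=float(entry["half_life_h"]),
        mean_nonpenetrating_energy_kev=float(entry["mean_nonpenetrating_energy_kev"]),
        photon_emissions=tuple((float(e), float(y)) for e, y in entry.get("photon_emissions", [])),
    )
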