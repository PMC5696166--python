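"""Biodistribution study container and summary statistics.

A study is a tidy table of excised-tissue measurements — one row per
(organ, animal, timepoint) — with nuclide and injected-activity metadata.
%ID/g values are stored decay-corrected to injection time (gamma-counting
practice); downstream dosimetry reintroduces physical decay explicitly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError
from .nuclides import NuclideSpec
from .quant import tumor_to_background

log = logging.getLogger(__name__)

#: Canonical sample-table columns.
SAMPLE_COLUMNS = ["organ", "animal_id", "time_h", "mass_g", "pidg"]

#: Default contrast ratios reported by summaries, when both organs exist.
DEFAULT_RATIO_PAIRS = [("Tumor", "Blood"), ("Tumor", "Muscle")]


@dataclass(frozen=True)
class TissueSample:
    """One excised-tissue measurement from one animal at one timepoint."""

    organ: str
    animal_id: str
    time_h: float
    mass_g: float
    pidg: float

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise InvalidInputError(f"sample mass must be > 0, got {self.mass_g}")
        if self.time_h < 0:
            raise InvalidInputError(f"time_h must be >= 0, got {self.time_h}")
        if self.pidg < 0:
            raise InvalidInputError(f"%ID/g must be >= 0, got {self.pidg}")


@dataclass
class BiodistributionStudy:
    """Multi-animal, multi-organ, multi-timepoint %ID/g table with metadata.

    Parameters
    ----------
    nuclide : NuclideSpec
    injected_mbq : float
        Injected activity per animal, MBq.
    samples : pandas.DataFrame
        Tidy table with columns ``organ, animal_id, time_h, mass_g, pidg``.
    decay_corrected : bool
        True when %ID/g values are corrected to injection time (the stored
        convention; readers and the generator both produce it).
    arm : str
        ``"baseline"`` or ``"blocking"``.
    injected_mass_ug : float, optional
        Injected antibody mass, µg (metadata only).
    """

    nuclide: NuclideSpec
    injected_mbq: float
    samples: pd.DataFrame
    decay_corrected: bool = True
    arm: str = "baseline"
    injected_mass_ug: float | None = None

    def __post_init__(self) -> None:
        if self.injected_mbq <= 0:
            raise InvalidInputError(f"injected_mbq must be > 0, got {self.injected_mbq}")
        if self.arm not in ("baseline", "blocking"):
            raise InvalidInputError(f"arm must be baseline|blocking, got {self.arm!r}")
        df = self.samples
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"sample table missing columns: {missing}")
        if len(df) == 0:
            raise SchemaError("study contains no samples")
        dup = df.duplicated(subset=["organ", "animal_id", "time_h"])
        if dup.any():
            row = df[dup].iloc[0]
            raise SchemaError(
                f"duplicate sample for organ={row['organ']!r} animal={row['animal_id']!r} "
                f"time_h={row['time_h']}"
            )
        if (df["mass_g"] <= 0).any():
            bad = df[df["mass_g"] <= 0].iloc[0]
            raise SchemaError(f"non-positive mass for organ={bad['organ']!r} row")
        if (df["time_h"] < 0).any() or (df["pidg"] < 0).any():
            raise SchemaError("negative time_h or %ID/g in sample table")
        self.samples = df[SAMPLE_COLUMNS].reset_index(drop=True)

    @property
    def organs(self) -> list[str]:
        return sorted(self.samples["organ"].unique())

    @property
    def timepoints_h(self) -> np.ndarray:
        return np.sort(self.samples["time_h"].unique())

    def organ_means(self, organ: str) -> pd.DataFrame:
        """Per-timepoint mean ± SD (sample SD, n−1) for one organ."""
        sub = self.samples[self.samples["organ"] == organ]
        if len(sub) == 0:
            raise SchemaError(f"organ {organ!r} not in study (has: {self.organs})")
        g = sub.groupby("time_h")["pidg"]
        out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
        return out.reset_index()

    def summarize(self, ratio_pairs: list[tuple[str, str]] | None = None) -> "SummaryTable":
        """Mean ± SD per organ × timepoint plus contrast-ratio rows."""
        g = self.samples.groupby(["organ", "time_h"])["pidg"]
        uptake = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()}).reset_index()

        if ratio_pairs is None:
            ratio_pairs = [
                (a, b) for a, b in DEFAULT_RATIO_PAIRS
                if a in self.organs and b in self.organs
            ]
        rows = []
        for num, den in ratio_pairs:
            for t in self.timepoints_h:
                sel = self.samples["time_h"] == t
                num_s = self.samples[sel & (self.samples["organ"] == num)]
                den_s = self.samples[sel & (self.samples["organ"] == den)]
                num_mean = num_s["pidg"].mean()
                den_mean = den_s["pidg"].mean()
                rom = tumor_to_background(num_mean, den_mean) if den_mean > 0 else np.nan
                # per-animal ratios need animals present in both organ groups
                merged = num_s.merge(den_s, on="animal_id", suffixes=("_num", "_den"))
                merged = merged[merged["pidg_den"] > 0]
                if len(merged) > 0:
                    per = merged["pidg_num"] / merged["pidg_den"]
                    mor, mor_sd, n = per.mean(), per.std(ddof=1), len(per)
                else:
                    mor, mor_sd, n = np.nan, np.nan, 0
                rows.append({
                    "pair": f"{num}/{den}", "time_h": t,
                    "ratio_of_means": rom, "mean_of_ratios": mor,
                    "sd_of_ratios": mor_sd, "n": n,
                })
        ratios = pd.DataFrame(rows, columns=["pair", "time_h", "ratio_of_means",
                                             "mean_of_ratios", "sd_of_ratios", "n"])
        return SummaryTable(uptake=uptake, ratios=ratios)

    def peak_uptake(self, organ: str) -> tuple[float, float]:
        """(time_h, mean %ID/g) of the maximum mean uptake for ``organ``."""
        means = self.organ_means(organ)
        idx = means["mean"].idxmax()
        return float(means.loc[idx, "time_h"]), float(means.loc[idx, "mean"])


@dataclass
class SummaryTable:
    """Mean ± SD uptake per organ × timepoint and contrast-ratio summary.

    ``ratios`` carries both conventions: ``ratio_of_means`` (ratio of group
    means — what published tables computed from printed means reproduce) and
    ``mean_of_ratios`` (mean of per-animal ratios with its SD — the default
    displayed statistic, since group tables are per-animal means).
    """

    uptake: pd.DataFrame
    ratios: pd.DataFrame
    displayed_ratio: str = field(default="mean_of_ratios")

    def uptake_cell(self, organ: str, time_h: float) -> tuple[float, float, int]:
        """(mean, sd, n) for one organ × timepoint cell."""
        sel = (self.uptake["organ"] == organ) & np.isclose(self.uptake["time_h"], time_h)
        if not sel.any():
            raise SchemaError(f"no summary cell for {organ!r} at {time_h} h")
        row = self.uptake[sel].iloc[0]
        return float(row["mean"]), float(row["sd"]), int(row["n"])

    def ratio_cell(self, pair: str, time_h: float, statistic: str | None = None) -> float:
        statistic = statistic or self.displayed_ratio
        if statistic not in ("ratio_of_means", "mean_of_ratios"):
            raise InvalidInputError(f"unknown ratio statistic {statistic!r}")
        sel = (self.ratios["pair"] == pair) & np.isclose(self.ratios["time_h"], time_h)
        if not sel.any():
            raise SchemaError(f"no ratio cell for {pair!r} at {time_h} h")
        return float(self.ratios[sel].iloc[0][statistic])
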