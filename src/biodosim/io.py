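"""Delimited-text I/O for studies, phantoms, S matrices and reports.

Study files are comma- or tab-delimited with a required header row and
``# key: value`` metadata comments::

    # nuclide: lu177
    # injected_MBq: 3.7
    # decay_corrected: true
    # arm: baseline
    organ,animal_id,time,time_unit,mass_g,pidg
    Tumor,m1,2,h,0.12,2.5

``time_unit`` is ``h`` or ``d`` per row; activity comes either as ``pidg``
(%ID/g) or as raw ``counts`` with a ``# standard_counts:`` metadata line
giving the counts of a 100 %-injected-dose standard.
"""
from __future__ import annotations

import io as _io
import logging
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .human import HumanPhantom
from .mird import DoseReport, SMatrix
from .nuclides import NuclideSpec, get_nuclide
from .pk import TimeActivityCurve
from .quant import percent_id_per_gram, round_half_up
from .sphere import SphereDoseGrid
from .study import BiodistributionStudy, SummaryTable

log = logging.getLogger(__name__)

_TIME_UNIT_H = {"h": 1.0, "hr": 1.0, "hour": 1.0, "hours": 1.0,
                "d": 24.0, "day": 24.0, "days": 24.0}


def _read_metadata(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                if key.strip() and value.strip():
                    meta[key.strip().lower()] = value.strip()
    return meta


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#") and ln.strip()]
    if not lines:
        raise SchemaError(f"{path}: empty file (no header row)")
    sep = "\t" if "\t" in lines[0] else ","
    try:
        return pd.read_csv(_io.StringIO("".join(lines)), sep=sep,
                           skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"{path}: cannot parse table: {exc}") from exc


def read_study(path, nuclide: NuclideSpec | None = None) -> BiodistributionStudy:
    """Read a biodistribution study file (see module docstring for schema)."""
    meta = _read_metadata(path)
    df = _read_table(path)
    required = {"organ", "animal_id", "time", "time_unit", "mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns: {sorted(missing)}")
    if "pidg" not in df.columns and "counts" not in df.columns:
        raise SchemaError(f"{path}: need a 'pidg' or 'counts' column")

    if nuclide is None:
        if "nuclide" not in meta:
            raise SchemaError(f"{path}: no '# nuclide:' metadata line and no "
                              "nuclide argument")
        nuclide = get_nuclide(meta["nuclide"])
    injected = float(meta.get("injected_mbq", "nan"))
    if math.isnan(injected):
        raise SchemaError(f"{path}: missing '# injected_MBq:' metadata line")
    decay_corrected = meta.get("decay_corrected", "true").lower() in ("true", "1", "yes")
    arm = meta.get("arm", "baseline")

    bad_units = set(df["time_unit"].str.strip().str.lower()) - set(_TIME_UNIT_H)
    if bad_units:
        raise SchemaError(f"{path}: unknown time units {sorted(bad_units)}")
    time_h = df["time"].astype(float) * df["time_unit"].str.strip().str.lower().map(_TIME_UNIT_H)

    if "pidg" in df.columns:
        pidg = df["pidg"].astype(float)
    else:
        std = float(meta.get("standard_counts", "nan"))
        if math.isnan(std) or std <= 0:
            raise SchemaError(f"{path}: 'counts' column needs a positive "
                              "'# standard_counts:' metadata line")
        pidg = pd.Series([
            percent_id_per_gram(c, std, m)
            for c, m in zip(df["counts"].astype(float), df["mass_g"].astype(float))
        ], index=df.index)

    samples = pd.DataFrame({
        "organ": df["organ"].astype(str).str.strip(),
        "animal_id": df["animal_id"].astype(str).str.strip(),
        "time_h": time_h.astype(float),
        "mass_g": df["mass_g"].astype(float),
        "pidg": pidg.astype(float),
    })
    if samples.isna().any().any():
        row = samples[samples.isna().any(axis=1)].index[0]
        raise SchemaError(f"{path}: non-numeric value in data row {row}")
    kwargs = {}
    if "injected_mass_ug" in meta:
        kwargs["injected_mass_ug"] = float(meta["injected_mass_ug"])
    return BiodistributionStudy(nuclide=nuclide, injected_mbq=injected,
                                samples=samples, decay_corrected=decay_corrected,
                                arm=arm, **kwargs)


def write_study(study: BiodistributionStudy, path, nuclide_key: str | None = None) -> None:
    """Write a study back to the canonical file format (times in hours)."""
    with open(path, "w") as fh:
        key = nuclide_key or study.nuclide.name.replace("-", "").lower()
        fh.write(f"# nuclide: {key}\n")
        fh.write(f"# injected_MBq: {study.injected_mbq!r}\n")
        if study.injected_mass_ug is not None:
            fh.write(f"# injected_mass_ug: {study.injected_mass_ug!r}\n")
        fh.write(f"# decay_corrected: {str(study.decay_corrected).lower()}\n")
        fh.write(f"# arm: {study.arm}\n")
        out = study.samples.copy()
        out.insert(2, "time", out.pop("time_h"))
        out.insert(3, "time_unit", "h")
        out.to_csv(fh, index=False, float_format="%.10g")


def write_summary(summary: SummaryTable, path, style: str = "split",
                  ratio_statistic: str | None = None) -> None:
    """Write a summary as organ rows × timepoint columns.

    ``style="split"`` emits separate ``<t>h_mean`` / ``<t>h_sd`` columns;
    ``style="pm"`` emits single ``mean ± SD`` text cells (report layout,
    values half-up rounded to 1 decimal place).  Ratio rows follow the
    uptake rows, labelled with the pair name.
    """
    if style not in ("split", "pm"):
        raise ConfigError(f"unknown summary style {style!r}")
    stat = ratio_statistic or summary.displayed_ratio
    times = sorted(summary.uptake["time_h"].unique())
    rows = []
    for organ in summary.uptake["organ"].unique():
        row: dict[str, object] = {"row": organ}
        for t in times:
            try:
                mean, sd, _ = summary.uptake_cell(organ, t)
            except SchemaError:
                continue
            _fill(row, t, mean, sd, style)
        rows.append(row)
    for pair in summary.ratios["pair"].unique():
        row = {"row": pair}
        sub = summary.ratios[summary.ratios["pair"] == pair]
        for t in times:
            cell = sub[np.isclose(sub["time_h"], t)]
            if len(cell) == 0:
                continue
            mean = float(cell.iloc[0][stat])
            sd = float(cell.iloc[0]["sd_of_ratios"]) if stat == "mean_of_ratios" else float("nan")
            _fill(row, t, mean, sd, style)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _fill(row: dict, t: float, mean: float, sd: float, style: str) -> None:
    label = f"{t:g}h"
    if style == "split":
        row[f"{label}_mean"] = mean
        row[f"{label}_sd"] = sd
    else:
        sd_txt = "" if math.isnan(sd) else f" ± {round_half_up(sd, 1)}"
        row[label] = f"{round_half_up(mean, 1)}{sd_txt}"


def read_phantom(path=None) -> HumanPhantom:
    """Reference-human phantom from ``organ,mass_g`` text.

    Default is the packaged 70-kg adult table.  A ``# body_mass_kg:`` header
    line sets the body mass (default 70).
    """
    if path is None:
        path = resources.files("biodosim.data").joinpath("phantom_adult_70kg.csv")
        name = "adult-70kg"
    else:
        name = Path(path).stem
    meta = _read_metadata(path)
    df = _read_table(path)
    if not {"organ", "mass_g"} <= set(df.columns):
        raise SchemaError(f"{path}: phantom file needs organ,mass_g columns")
    return HumanPhantom(
        body_mass_kg=float(meta.get("body_mass_kg", 70.0)),
        organ_masses_g=dict(zip(df["organ"].astype(str), df["mass_g"].astype(float))),
        name=name,
    )


def read_smatrix(path) -> SMatrix:
    """S-value file: ``target,source,s_mgy_per_mbq_h`` with metadata header."""
    meta = _read_metadata(path)
    df = _read_table(path)
    required = {"target", "source", "s_mgy_per_mbq_h"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: S-matrix file needs columns {sorted(required)}")
    values = {(str(r["target"]), str(r["source"])): float(r["s_mgy_per_mbq_h"])
              for _, r in df.iterrows()}
    return SMatrix(values=values, phantom_name=meta.get("phantom", ""),
                   nuclide_name=meta.get("nuclide", ""))


def read_sphere_grid(path, nuclide: NuclideSpec) -> SphereDoseGrid:
    """Sphere dose-factor grid from ``mass_g,dose_factor`` text."""
    df = _read_table(path)
    if not {"mass_g", "dose_factor"} <= set(df.columns):
        raise SchemaError(f"{path}: grid file needs mass_g,dose_factor columns")
    order = np.argsort(df["mass_g"].to_numpy())
    return SphereDoseGrid(nuclide=nuclide,
                          masses_g=df["mass_g"].to_numpy()[order],
                          factors_mgy_per_mbq_h=df["dose_factor"].to_numpy()[order])


def write_dose_report(report: DoseReport, path) -> None:
    """Dose report as ``organ, mGy/MBq, rad/mCi`` delimited text."""
    with open(path, "w") as fh:
        fh.write(f"# dose engine: {report.mode}\n")
        for note in report.notes:
            fh.write(f"# note: {note}\n")
        if report.nuclide_name:
            fh.write(f"# nuclide: {report.nuclide_name}\n")
        rad = report.rad_per_mci
        df = pd.DataFrame({
            "organ": list(report.doses_mgy_per_mbq),
            "mGy_per_MBq": list(report.doses_mgy_per_mbq.values()),
            "rad_per_mCi": [rad[o] for o in report.doses_mgy_per_mbq],
        })
        if report.whole_body_mgy_per_mbq is not None:
            df.loc[len(df)] = ["whole body", report.whole_body_mgy_per_mbq,
                               report.whole_body_mgy_per_mbq * 3.7]
        df.to_csv(fh, index=False, float_format="%.8g")


def load_reference_summary(key: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Packaged reference biodistribution summary (printed study means).

    ``key`` is ``"lu177"`` or ``"cu64"``.  Returns the tidy summary table
    (organ, time_h, mean_pidg, sd, n) and its metadata.
    """
    names = {"lu177": "lu177_cetuximab_reference.csv",
             "cu64": "cu64_cetuximab_reference.csv"}
    norm = key.strip().lower().replace("-", "")
    if norm not in names:
        raise ConfigError(f"unknown reference dataset {key!r}; use lu177|cu64")
    path = resources.files("biodosim.data").joinpath(names[norm])
    return _read_table(path), _read_metadata(path)


def reference_study(key: str) -> BiodistributionStudy:
    """Reference summary expanded to a single-pseudo-animal study.

    Each organ × timepoint mean becomes one sample (animal ``"mean"``,
    nominal 1 g mass), so summary-level published data can flow through the
    same pipeline as raw per-animal tables.
    """
    df, meta = load_reference_summary(key)
    samples = pd.DataFrame({
        "organ": df["organ"], "animal_id": "mean",
        "time_h": df["time_h"].astype(float),
        "mass_g": 1.0, "pidg": df["mean_pidg"].astype(float),
    })
    return BiodistributionStudy(
        nuclide=get_nuclide(meta["nuclide"]),
        injected_mbq=float(meta.get("injected_mbq", 3.7)),
        samples=samples,
        decay_corrected=meta.get("decay_corrected", "true").lower() == "true",
    )


def reference_tac(key: str, organ: str) -> TimeActivityCurve:
    """Mean time-activity curve of one organ from a packaged reference set."""
    df, meta = load_reference_summary(key)
    sub = df[df["organ"].str.lower() == organ.strip().lower()].sort_values("time_h")
    if len(sub) == 0:
        raise SchemaError(f"organ {organ!r} not in reference set {key!r}")
    return TimeActivityCurve(
        organ=organ, times_h=sub["time_h"].to_numpy(dtype=float),
        values=sub["mean_pidg"].to_numpy(dtype=float),
        nuclide=get_nuclide(meta["nuclide"]),
        decay_corrected=meta.get("decay_corrected", "true").lower() == "true",
        sd=sub["sd"].to_numpy(dtype=float), n=sub["n"].to_numpy(dtype=float),
    )
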