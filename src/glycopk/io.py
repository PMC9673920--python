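"""Readers and writers for the tidy delimited tables the pipeline exchanges.

All tables are comma-separated UTF-8 text with a header row:

profiles
    sample_id (optional), animal_id, group, route, time_h, glycoform, fraction
concentrations
    animal_id, group, time_h, conc_ug_ml, bloq (optional)
doses
    group, nominal_dose_mg_per_kg, route
standards
    profile-shaped table of spiked-standard measurements, keyed by group
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .model import AnalysisConfig, ConcentrationSeries, DoseSpec, SampleProfile, SchemaError
from .registry import GlycoformRegistry

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["animal_id", "group", "route", "time_h", "glycoform", "fraction"]
CONC_COLUMNS = ["animal_id", "group", "time_h", "conc_ug_ml"]
DOSE_COLUMNS = ["group", "nominal_dose_mg_per_kg", "route"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def profiles_from_frame(df: pd.DataFrame, registry: GlycoformRegistry) -> list[SampleProfile]:
    """Build normalized :class:`SampleProfile` objects from a tidy long frame."""
    registry.require(df["glycoform"].unique())
    has_sample_id = "sample_id" in df.columns and df["sample_id"].notna().all()
    keys = ["sample_id"] if has_sample_id else ["animal_id", "group", "route", "time_h"]
    profiles = []
    for _, sample in df.groupby(keys, sort=False):
        first = sample.iloc[0]
        dupes = sample["glycoform"].duplicated()
        if dupes.any():
            raise SchemaError(
                f"sample {first.get('sample_id', first['animal_id'])}: duplicate glycoform "
                f"{sample['glycoform'][dupes].iloc[0]!r}"
            )
        profile = SampleProfile(
            animal_id=str(first["animal_id"]),
            group=str(first["group"]),
            route=str(first["route"]),
            time_h=float(first["time_h"]),
            fractions=dict(zip(sample["glycoform"], sample["fraction"].astype(float))),
            sample_id=str(first["sample_id"]) if has_sample_id else None,
        )
        profiles.append(profile.normalized())
    return profiles


def read_profiles(path: str | Path, registry: GlycoformRegistry) -> list[SampleProfile]:
    """Read glycosylation profiles; percent-scale fractions are rescaled.

    Each sample is renormalized to sum exactly 1; raw sums outside
    [0.95, 1.05] (or [95, 105] on percent scale) raise, flagging the sample.
    """
    df = pd.read_csv(path)
    _require_columns(df, PROFILE_COLUMNS, path)
    return profiles_from_frame(df, registry)


def profiles_to_frame(profiles: Iterable[SampleProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for g, f in p.fractions.items():
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "animal_id": p.animal_id,
                    "group": p.group,
                    "route": p.route,
                    "time_h": p.time_h,
                    "glycoform": g,
                    "fraction": f,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id"] + PROFILE_COLUMNS)


def write_profiles(profiles: Iterable[SampleProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def concentrations_from_frame(
    df: pd.DataFrame, lloq_ng_ml: float = 7.0
) -> list[ConcentrationSeries]:
    """Build :class:`ConcentrationSeries` per (animal, group) from a tidy frame."""
    lloq_ug_ml = lloq_ng_ml / 1000.0
    series = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=False):
        conc = sub["conc_ug_ml"].astype(float).to_numpy()
        bloq = conc < lloq_ug_ml
        if "bloq" in sub.columns:
            bloq |= sub["bloq"].fillna(False).astype(bool).to_numpy()
        series.append(
            ConcentrationSeries(
                animal_id=str(animal),
                group=str(group),
                times_h=sub["time_h"].astype(float).to_numpy(),
                conc_ug_ml=conc,
                bloq=bloq,
            )
        )
    return series


def read_concentrations(
    path: str | Path, lloq_ng_ml: float = 7.0
) -> list[ConcentrationSeries]:
    """Read total-concentration series; values below the LLOQ are flagged BLOQ.

    An explicit ``bloq`` column is honored in addition to the LLOQ rule.
    """
    df = pd.read_csv(path)
    _require_columns(df, CONC_COLUMNS, path)
    return concentrations_from_frame(df, lloq_ng_ml)


def concentrations_to_frame(series: Iterable[ConcentrationSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, c, b in zip(s.times_h, s.conc_ug_ml, s.bloq):
            rows.append(
                {"animal_id": s.animal_id, "group": s.group, "time_h": t, "conc_ug_ml": c, "bloq": b}
            )
    return pd.DataFrame(rows, columns=CONC_COLUMNS + ["bloq"])


def write_concentrations(series: Iterable[ConcentrationSeries], path: str | Path) -> None:
    concentrations_to_frame(series).to_csv(path, index=False)


def mean_profile(profiles: list[SampleProfile]) -> SampleProfile:
    """Average replicate profiles glycoform-wise and renormalize."""
    if not profiles:
        raise SchemaError("cannot average an empty set of profiles")
    names: list[str] = []
    for p in profiles:
        for g in p.fractions:
            if g not in names:
                names.append(g)
    fractions = {g: float(np.mean([p.fractions.get(g, 0.0) for p in profiles])) for g in names}
    first = profiles[0]
    return SampleProfile(
        animal_id=first.animal_id,
        group=first.group,
        route=first.route,
        time_h=first.time_h,
        fractions=fractions,
    ).normalized()


def read_doses(
    path: str | Path,
    standards: Iterable[SampleProfile],
) -> dict[str, DoseSpec]:
    """Read the dose table and attach per-group spiked-standard profiles.

    Replicate standard measurements of a group are averaged into one
    standard profile.
    """
    df = pd.read_csv(path)
    _require_columns(df, DOSE_COLUMNS, path)
    by_group: dict[str, list[SampleProfile]] = {}
    for p in standards:
        by_group.setdefault(p.group, []).append(p)
    doses = {}
    for _, row in df.iterrows():
        group = str(row["group"])
        if group in doses:
            raise SchemaError(f"{path}: duplicate dose row for group {group!r}")
        if group not in by_group:
            raise SchemaError(f"no spiked-standard profile available for group {group!r}")
        doses[group] = DoseSpec(
            group=group,
            nominal_dose_mg_per_kg=float(row["nominal_dose_mg_per_kg"]),
            route=str(row["route"]),
            standard_profile=mean_profile(by_group[group]),
        )
    return doses


def write_doses(doses: Mapping[str, DoseSpec], path: str | Path) -> None:
    rows = [
        {"group": d.group, "nominal_dose_mg_per_kg": d.nominal_dose_mg_per_kg, "route": d.route}
        for d in doses.values()
    ]
    pd.DataFrame(rows, columns=DOSE_COLUMNS).to_csv(path, index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file (``analysis:`` section
    or top-level keys); unknown keys raise."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "analysis" in data:
        data = data["analysis"] or {}
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**data)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"analysis": config.__dict__}, fh, sort_keys=False)
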