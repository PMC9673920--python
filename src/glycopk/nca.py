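"""Glycoform-resolved non-compartmental analysis.

Per-glycoform concentration-time series are constructed by multiplying each
animal's total serum concentration with the glycoform's relative abundance
at the same time point. Non-compartmental evaluation then yields Cmax, the
terminal rate constant λz (log-linear best fit over candidate terminal
windows), AUC to the last point and to infinity, and clearance

    CL_g = dose_g / AUC∞_g            (CL/F after subcutaneous dosing),

where dose_g distributes the nominal protein dose over glycoforms according
to the spiked-standard profile. Clearances are normalized within each
animal to a reference glycoform, cancelling inter-animal variability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .model import AnalysisConfig, ConcentrationSeries, DoseSpec, SampleProfile, SchemaError
from .stats import summarize

logger = logging.getLogger(__name__)

#: Adjusted-R² margin within which a larger terminal window wins the λz fit.
R2_TIE_TOL = 1e-4
#: Extrapolated AUC share above which a quality warning is emitted.
EXTRAP_WARN_PERCENT = 20.0

NCA_COLUMNS = [
    "animal_id",
    "group",
    "glycoform",
    "route",
    "cmax_ug_ml",
    "tmax_h",
    "lambda_z_per_h",
    "half_life_h",
    "auc_last_ug_h_ml",
    "auc_inf_ug_h_ml",
    "extrap_percent",
    "dose_ug_kg",
    "clearance_ml_day_kg",
    "cl_label",
    "n_lambda_points",
    "fit_r2adj",
    "estimable",
]


@dataclass
class GlycoformConcSeries:
    """Per-glycoform concentration-time series for one animal."""

    animal_id: str
    group: str
    glycoform: str
    times_h: np.ndarray
    conc_ug_ml: np.ndarray
    route: str = "IV"

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_ug_ml = np.asarray(self.conc_ug_ml, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise SchemaError(f"{self.animal_id}/{self.glycoform}: times must be strictly increasing")
        if np.any(self.conc_ug_ml < 0):
            raise SchemaError(f"{self.animal_id}/{self.glycoform}: negative concentration")


class LambdaZFit(NamedTuple):
    lambda_z_per_h: float
    n_points: int
    r2adj: float
    estimable: bool

    @property
    def half_life_h(self) -> float:
        return np.log(2) / self.lambda_z_per_h if self.estimable else np.nan


class AUCResult(NamedTuple):
    auc_last: float
    auc_inf: float
    extrap_percent: float


def split_concentrations(
    profiles: Sequence[SampleProfile],
    conc_series: Sequence[ConcentrationSeries],
    config: AnalysisConfig | None = None,
) -> list[GlycoformConcSeries]:
    """Combine glycosylation profiles with total concentrations into
    per-glycoform series: C_g(t) = f_g(t) · C_total(t), per animal and time
    point.

    Retains only points inside the analysis window that have a non-BLOQ
    total and a matching profile; an animal with no usable point raises.
    """
    config = config or AnalysisConfig()
    profile_index: dict[tuple[str, str, float], SampleProfile] = {}
    for p in profiles:
        key = (p.animal_id, p.group, float(p.time_h))
        if key in profile_index:
            raise SchemaError(f"duplicate profile for animal {p.animal_id} at {p.time_h} h")
        profile_index[key] = p

    out: list[GlycoformConcSeries] = []
    for series in conc_series:
        times, concs, route, point_profiles = [], [], None, []
        for t, c, bloq in zip(series.times_h, series.conc_ug_ml, series.bloq):
            if bloq or t > config.analysis_window_h:
                continue
            profile = profile_index.get((series.animal_id, series.group, float(t)))
            if profile is None:
                continue
            times.append(t)
            concs.append(c)
            point_profiles.append(profile)
            route = profile.route
        if not times:
            raise SchemaError(
                f"animal {series.animal_id} ({series.group}): no time point has both a "
                "usable glycosylation profile and a quantifiable total concentration"
            )
        glycoforms: list[str] = []
        for p in point_profiles:
            for g in p.fractions:
                if g not in glycoforms:
                    glycoforms.append(g)
        times_arr = np.array(times)
        concs_arr = np.array(concs)
        for g in glycoforms:
            cg = np.array([p.fractions.get(g, 0.0) for p in point_profiles]) * concs_arr
            out.append(
                GlycoformConcSeries(
                    animal_id=series.animal_id,
                    group=series.group,
                    glycoform=g,
                    times_h=times_arr,
                    conc_ug_ml=cg,
                    route=route or "IV",
                )
            )
        # total over the same retained grid, so glycoform AUCs add up exactly
        out.append(
            GlycoformConcSeries(
                animal_id=series.animal_id,
                group=series.group,
                glycoform="Total",
                times_h=times_arr,
                conc_ug_ml=concs_arr,
                route=route or "IV",
            )
        )
    return out


def _loglinear_fit(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of ln(c) on t and the adjusted R²."""
    logc = np.log(c)
    n = len(t)
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    if ss_tot == 0:
        return slope, -np.inf  # flat series carries no elimination information
    r2 = 1.0 - ss_res / ss_tot
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, r2adj


def estimate_lambda_z(
    series: GlycoformConcSeries, config: AnalysisConfig | None = None
) -> LambdaZFit:
    """Terminal rate constant by log-linear best fit.

    Candidate windows are the last k points for k from
    ``lambda_z_min_points`` up to all points after Cmax (for SC, Tmax itself
    is excluded from candidates; for IV the curve is terminal from the first
    sample). Non-positive concentrations are excluded before fitting. The
    window with the highest adjusted R² wins; ties go to the window with
    more points.
    """
    config = config or AnalysisConfig()
    positive = series.conc_ug_ml > 0
    t = series.times_h[positive]
    c = series.conc_ug_ml[positive]
    if len(t) == 0:
        return LambdaZFit(np.nan, 0, np.nan, False)
    imax = int(np.argmax(c))
    start = imax + 1 if series.route == "SC" else imax
    t, c = t[start:], c[start:]
    n = len(t)
    if n < config.lambda_z_min_points:
        return LambdaZFit(np.nan, n, np.nan, False)

    best: LambdaZFit | None = None
    for k in range(config.lambda_z_min_points, n + 1):
        slope, r2adj = _loglinear_fit(t[-k:], c[-k:])
        if slope >= 0:
            continue
        candidate = LambdaZFit(-slope, k, r2adj, True)
        if best is None or candidate.r2adj > best.r2adj + R2_TIE_TOL or (
            candidate.r2adj >= best.r2adj - R2_TIE_TOL and candidate.n_points > best.n_points
        ):
            best = candidate
    return best if best is not None else LambdaZFit(np.nan, n, np.nan, False)


def auc_trapezoid(
    series: GlycoformConcSeries,
    lambda_z: LambdaZFit | float | None = None,
    config: AnalysisConfig | None = None,
) -> AUCResult:
    """AUC to the last observation and, given λz, to infinity.

    The default linear trapezoid preserves exact additivity across
    glycoforms; the lin-up/log-down variant uses the logarithmic mean on
    strictly decreasing positive intervals. AUC∞ = AUC_last + C_last/λz;
    the observed curve is not back-extrapolated before the first sample.
    """
    config = config or AnalysisConfig()
    t = series.times_h
    c = series.conc_ug_ml
    if len(t) < 2:
        raise SchemaError(f"{series.animal_id}/{series.glycoform}: AUC needs at least 2 points")
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    linear = 0.5 * (c1 + c2) * dt
    if config.trapezoid_rule == "lin-up-log-down":
        down = (c2 < c1) & (c2 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logmean = (c1 - c2) / np.log(c1 / c2)
        segments = np.where(down, logmean * dt, linear)
    else:
        segments = linear
    auc_last = float(np.sum(segments))

    lz = lambda_z.lambda_z_per_h if isinstance(lambda_z, LambdaZFit) else lambda_z
    estimable = (
        lambda_z.estimable if isinstance(lambda_z, LambdaZFit) else lz is not None and np.isfinite(lz)
    )
    if not estimable:
        return AUCResult(auc_last, np.nan, np.nan)
    c_last = c[c > 0][-1] if np.any(c > 0) else 0.0
    auc_inf = auc_last + float(c_last) / float(lz)
    extrap = 100.0 * (auc_inf - auc_last) / auc_inf if auc_inf > 0 else np.nan
    if extrap > EXTRAP_WARN_PERCENT:
        warnings.warn(
            f"{series.animal_id}/{series.glycoform}: {extrap:.1f}% of AUC∞ is extrapolated",
            stacklevel=2,
        )
    return AUCResult(auc_last, auc_inf, extrap)


def nca_series(series: GlycoformConcSeries, config: AnalysisConfig | None = None) -> dict:
    """Full NCA of one series: Cmax/Tmax, λz, half-life, AUCs, extrapolation."""
    config = config or AnalysisConfig()
    imax = int(np.argmax(series.conc_ug_ml))
    fit = estimate_lambda_z(series, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # high extrapolation is reported, not re-warned here
        auc = auc_trapezoid(series, fit, config)
    return {
        "animal_id": series.animal_id,
        "group": series.group,
        "glycoform": series.glycoform,
        "route": series.route,
        "cmax_ug_ml": float(series.conc_ug_ml[imax]),
        "tmax_h": float(series.times_h[imax]),
        "lambda_z_per_h": fit.lambda_z_per_h,
        "half_life_h": fit.half_life_h,
        "auc_last_ug_h_ml": auc.auc_last,
        "auc_inf_ug_h_ml": auc.auc_inf,
        "extrap_percent": auc.extrap_percent,
        "n_lambda_points": fit.n_points,
        "fit_r2adj": fit.r2adj,
        "estimable": fit.estimable,
    }


def nca_study(
    profiles: Sequence[SampleProfile],
    concentrations: Sequence[ConcentrationSeries],
    dose: DoseSpec,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Glycoform-resolved NCA of one experimental group.

    Splits totals into per-glycoform series, runs NCA per animal and
    glycoform, and converts AUC∞ to clearance with the spiked-standard dose
    adjustment: dose_g = nominal dose × f_g(standard), CL = dose_g /
    (AUC∞/24) in mL/day/kg. The ``Total`` row uses the unsplit
    concentrations with the full nominal dose. After SC dosing the column
    holds apparent clearance CL/F (``cl_label``).
    """
    config = config or AnalysisConfig()
    split = split_concentrations(profiles, concentrations, config)
    rows = []
    for series in split:
        row = nca_series(series, config)
        if series.glycoform == "Total":
            dose_ug_kg = dose.nominal_dose_mg_per_kg * 1000.0
        else:
            dose_ug_kg = dose.dose_ug_per_kg(series.glycoform)
        row["dose_ug_kg"] = dose_ug_kg
        auc_inf = row["auc_inf_ug_h_ml"]
        row["clearance_ml_day_kg"] = (
            dose_ug_kg / (auc_inf / 24.0) if np.isfinite(auc_inf) and auc_inf > 0 else np.nan
        )
        row["cl_label"] = "CL" if series.route == "IV" else "CL/F"
        rows.append(row)
    return pd.DataFrame(rows, columns=NCA_COLUMNS)


def normalize_to_reference(
    results: pd.DataFrame, reference: str = "G0F"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-animal clearance ratios CL_g / CL_reference and their summary.

    Animals in which the reference is not estimable are excluded with a
    warning. Returns ``(ratios, summary)``: per-animal ratios and a
    per-glycoform table with n, mean, SD and t-based 95% CI.
    """
    wide = results[results["glycoform"] != "Total"].pivot_table(
        index="animal_id", columns="glycoform", values="clearance_ml_day_kg"
    )
    if reference not in wide.columns:
        raise SchemaError(f"reference glycoform {reference!r} absent from results")
    missing = wide.index[wide[reference].isna()]
    for animal in missing:
        logger.warning("animal %s: reference %s not estimable; excluded", animal, reference)
    wide = wide.drop(index=missing)
    if wide.empty:
        raise SchemaError(f"reference {reference!r} not estimable in any animal")
    ratios = wide.div(wide[reference], axis=0)
    tidy = (
        ratios.reset_index()
        .melt(id_vars="animal_id", var_name="glycoform", value_name="ratio")
        .dropna(subset=["ratio"])
        .reset_index(drop=True)
    )
    summary_rows = []
    for g, sub in tidy.groupby("glycoform", sort=False):
        values = sub["ratio"].to_numpy()
        if len(values) >= 2:
            s = summarize(values)
            summary_rows.append(
                {
                    "glycoform": g,
                    "n": len(values),
                    "mean": s.mean,
                    "sd": s.sd,
                    "ci95_low": s.ci95_low,
                    "ci95_high": s.ci95_high,
                }
            )
    return tidy, pd.DataFrame(
        summary_rows, columns=["glycoform", "n", "mean", "sd", "ci95_low", "ci95_high"]
    )
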