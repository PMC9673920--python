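"""Core domain types: sample profiles, concentration series, doses, config."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

FRACTION_SUM_TOL = 1e-9
#: Acceptable raw profile sums before renormalization (unit or percent scale).
RAW_SUM_WINDOW = (0.95, 1.05)


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema or invariants."""


@dataclass(frozen=True)
class SampleProfile:
    """Compositional glycoform fractions for one animal at one time point.

    ``fractions`` maps glycoform name to its relative abundance; after
    :meth:`normalized` the values are non-negative and sum to 1.
    """

    animal_id: str
    group: str
    route: str
    time_h: float
    fractions: Mapping[str, float]
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.route not in ("IV", "SC", "STD"):
            raise SchemaError(f"route must be IV, SC or STD, got {self.route!r}")
        if self.time_h < 0:
            raise SchemaError(f"time_h must be >= 0, got {self.time_h}")
        for g, f in self.fractions.items():
            if f < 0:
                raise SchemaError(f"negative fraction {f} for glycoform {g!r}")

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))

    def normalized(self) -> "SampleProfile":
        """Return a copy whose fractions sum to exactly 1.

        Percent-scale profiles (sum near 100) are rescaled first; raw sums
        outside [0.95, 1.05] on either scale are rejected.
        """
        total = self.total
        if abs(total - 1.0) <= FRACTION_SUM_TOL:
            return self  # already normalized; keep values bit-identical
        lo, hi = RAW_SUM_WINDOW
        if lo * 100 <= total <= hi * 100:
            total_scale = total
        elif lo <= total <= hi:
            total_scale = total
        else:
            raise SchemaError(
                f"sample {self.sample_id or self.animal_id}@{self.time_h}h: fractions sum to "
                f"{total:.4g}, outside [{lo}, {hi}] (or percent-scale [{lo*100}, {hi*100}])"
            )
        fractions = {g: f / total_scale for g, f in self.fractions.items()}
        return replace(self, fractions=fractions)

    def is_normalized(self) -> bool:
        return abs(self.total - 1.0) <= FRACTION_SUM_TOL


@dataclass
class ConcentrationSeries:
    """Total mAb serum concentration vs time for one animal.

    Times are hours, concentrations µg/mL; ``bloq`` flags points below the
    lower limit of quantitation, which are retained in storage but excluded
    from NCA and profile joins downstream.
    """

    animal_id: str
    group: str
    times_h: np.ndarray
    conc_ug_ml: np.ndarray
    bloq: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_ug_ml = np.asarray(self.conc_ug_ml, dtype=float)
        self.bloq = np.asarray(self.bloq, dtype=bool)
        if not (len(self.times_h) == len(self.conc_ug_ml) == len(self.bloq)):
            raise SchemaError(f"animal {self.animal_id}: misaligned series columns")
        order = np.argsort(self.times_h, kind="stable")
        self.times_h = self.times_h[order]
        self.conc_ug_ml = self.conc_ug_ml[order]
        self.bloq = self.bloq[order]
        if np.any(np.diff(self.times_h) <= 0):
            dup = self.times_h[np.where(np.diff(self.times_h) <= 0)[0][0]]
            raise SchemaError(f"animal {self.animal_id}: duplicate time point {dup} h")
        if np.any(self.conc_ug_ml < 0):
            raise SchemaError(f"animal {self.animal_id}: negative concentration")

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations with BLOQ points removed."""
        keep = ~self.bloq
        return self.times_h[keep], self.conc_ug_ml[keep]


@dataclass
class DoseSpec:
    """Nominal dose and the spiked-standard profile used for dose adjustment.

    The standard profile is the glycosylation profile measured in drug-free
    serum spiked with 10 mg/L mAb; its fraction of each glycoform converts
    the nominal protein dose into per-glycoform doses.
    """

    group: str
    nominal_dose_mg_per_kg: float
    route: str
    standard_profile: SampleProfile

    def __post_init__(self) -> None:
        if self.nominal_dose_mg_per_kg <= 0:
            raise SchemaError(f"group {self.group}: dose must be positive")
        if self.route not in ("IV", "SC"):
            raise SchemaError(f"group {self.group}: route must be IV or SC")
        if not self.standard_profile.is_normalized():
            self.standard_profile = self.standard_profile.normalized()

    def dose_ug_per_kg(self, glycoform: str) -> float:
        """Glycoform dose in µg/kg: nominal dose × standard-profile fraction."""
        try:
            f = self.standard_profile.fractions[glycoform]
        except KeyError:
            raise SchemaError(
                f"group {self.group}: glycoform {glycoform!r} absent from the standard profile"
            ) from None
        return self.nominal_dose_mg_per_kg * 1000.0 * f


@dataclass
class AnalysisConfig:
    """Tunable parameters of the glycoform-resolved PK analysis.

    Attributes
    ----------
    reference_glycoform:
        Glycoform whose clearance normalizes the others (G0F by default).
    analysis_window_h:
        Upper time bound in hours; later samples are excluded to avoid
        anti-drug-antibody interference (10 days by default).
    background_fraction:
        Fraction of the reported spectral background additionally subtracted
        from analyte signals before normalization.
    fdr:
        Benjamini-Hochberg false discovery rate per comparison family.
    lloq_ng_ml:
        ELISA lower limit of quantitation (ng/mL).
    profile_loq_ug_ml:
        Total concentration below which glycosylation profiles are not
        considered quantifiable (µg/mL).
    trapezoid_rule:
        "linear" or "lin-up-log-down" AUC rule.
    lambda_z_min_points:
        Minimum number of terminal points for the log-linear λz fit.
    """

    reference_glycoform: str = "G0F"
    analysis_window_h: float = 240.0
    background_fraction: float = 0.3
    fdr: float = 0.05
    lloq_ng_ml: float = 7.0
    profile_loq_ug_ml: float = 1.0
    trapezoid_rule: str = "linear"
    lambda_z_min_points: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.background_fraction < 1:
            raise SchemaError("background_fraction must be in [0, 1)")
        if not 0 < self.fdr < 1:
            raise SchemaError("fdr must be in (0, 1)")
        if self.analysis_window_h <= 0:
            raise SchemaError("analysis_window_h must be positive")
        if self.trapezoid_rule not in ("linear", "lin-up-log-down"):
            raise SchemaError(f"unknown trapezoid_rule {self.trapezoid_rule!r}")
        if self.lambda_z_min_points < 3:
            raise SchemaError("lambda_z_min_points must be at least 3")

    @property
    def lloq_ug_ml(self) -> float:
        return self.lloq_ng_ml / 1000.0
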