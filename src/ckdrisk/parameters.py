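"""Baseline eGFR-decline parameter tables, risk modifiers and patient profiles.

The decline model is stratified: for each sex, 10-year age band and
10-unit eGFR band the table stores the mean (``mu_base``, signed, negative =
decline) and standard deviation (``sd_base``) of the annual eGFR change in
mL/min/1.73 m^2 per year.  Covariate effects enter as dimensionless
multiplicative factors on the mean (alpha) and SD (beta).

Band conventions
----------------
All bands are half-open ``[lower, upper)``.  Ages outside the tabulated
range are clamped to the nearest band.  Individuals with eGFR below
30 mL/min/1.73 m^2 are assigned the parameters of the stratum containing
eGFR 30 (the 30-39 band in the default layout), because decline estimates
below 30 are not separately tabulated.  eGFR above the top band is clamped
to the top band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "BandEntry",
    "ParameterTable",
    "RiskModifiers",
    "PatientProfile",
    "read_parameter_table",
    "write_parameter_table",
    "lookup_base",
    "modifier_factors",
    "effective_params",
]

SEXES = ("male", "female")
SMOKING_STATUSES = ("never", "current", "ceased")
BP_CATEGORIES = ("normal", "high")

#: eGFR below this value is mapped to the stratum containing it (the
#: "same parameters as the 30-39 band" rule).
EGFR_LOWER_RULE = 30.0


class FormatError(ValueError):
    """A parameter file is missing required columns/keys or is malformed."""


class ValidationError(ValueError):
    """A parameter table violates a structural invariant."""


@dataclass(frozen=True)
class BandEntry:
    """One stratum: half-open age and eGFR bands with slope mean and SD."""

    age_lo: float
    age_hi: float
    egfr_lo: float
    egfr_hi: float
    mu_base: float  # mL/min/1.73 m^2 per year, signed (negative = decline)
    sd_base: float  # mL/min/1.73 m^2 per year, >= 0


class ParameterTable:
    """Sex-stratified grid of annual eGFR-change means and SDs.

    Entries for each sex must tile a full (age band) x (eGFR band) grid:
    bands are half-open, non-overlapping and jointly cover the declared
    ranges.  Both sexes must be present.
    """

    def __init__(self, entries: Mapping[str, Iterable[BandEntry]]):
        self.entries: dict[str, tuple[BandEntry, ...]] = {
            sex: tuple(rows) for sex, rows in entries.items()
        }
        for sex in SEXES:
            if sex not in self.entries or not self.entries[sex]:
                raise ValidationError(f"table must contain entries for {sex!r}")
        unknown = set(self.entries) - set(SEXES)
        if unknown:
            raise ValidationError(f"unknown sex values {sorted(unknown)}")
        self._grids: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for sex, rows in self.entries.items():
            self._grids[sex] = self._build_grid(sex, rows)

    @staticmethod
    def _build_grid(sex, rows):
        for r in rows:
            if r.sd_base < 0:
                raise ValidationError(
                    f"sd_base must be >= 0, got {r.sd_base} for {sex} "
                    f"age [{r.age_lo},{r.age_hi}) eGFR [{r.egfr_lo},{r.egfr_hi})"
                )
            if not (r.age_lo < r.age_hi and r.egfr_lo < r.egfr_hi):
                raise ValidationError(f"empty band in entry {r}")
        age_edges = np.unique([r.age_lo for r in rows] + [r.age_hi for r in rows])
        egfr_edges = np.unique([r.egfr_lo for r in rows] + [r.egfr_hi for r in rows])
        na, ng = len(age_edges) - 1, len(egfr_edges) - 1
        if len(rows) != na * ng:
            raise ValidationError(
                f"{sex}: {len(rows)} entries do not tile a {na}x{ng} band grid "
                "(overlapping or missing bands)"
            )
        mu = np.full((na, ng), np.nan)
        sd = np.full((na, ng), np.nan)
        for r in rows:
            ia = int(np.searchsorted(age_edges, r.age_lo))
            ig = int(np.searchsorted(egfr_edges, r.egfr_lo))
            if (
                ia >= na
                or ig >= ng
                or age_edges[ia + 1] != r.age_hi
                or egfr_edges[ig + 1] != r.egfr_hi
            ):
                raise ValidationError(f"{sex}: band {r} overlaps a neighbouring band")
            if not np.isnan(mu[ia, ig]):
                raise ValidationError(f"{sex}: duplicate band at {r}")
            mu[ia, ig] = r.mu_base
            sd[ia, ig] = r.sd_base
        return age_edges.astype(float), egfr_edges.astype(float), mu, sd

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def n_entries(self) -> int:
        return sum(len(rows) for rows in self.entries.values())

    def grid(self, sex: str):
        """Return (age_edges, egfr_edges, mu, sd) arrays for one sex."""
        if sex not in self._grids:
            raise KeyError(f"sex {sex!r} not in table")
        return self._grids[sex]

    def lookup_vec(self, sex: str, age, egfr):
        """Vectorised stratum lookup with clamping and the eGFR<30 rule."""
        age_edges, egfr_edges, mu, sd = self.grid(sex)
        age = np.asarray(age, dtype=float)
        g = np.maximum(np.asarray(egfr, dtype=float), EGFR_LOWER_RULE)
        ia = np.clip(np.searchsorted(age_edges, age, side="right") - 1, 0, mu.shape[0] - 1)
        ig = np.clip(np.searchsorted(egfr_edges, g, side="right") - 1, 0, mu.shape[1] - 1)
        return mu[ia, ig], sd[ia, ig]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sex": sex,
                "age_lo": r.age_lo,
                "age_hi": r.age_hi,
                "egfr_lo": r.egfr_lo,
                "egfr_hi": r.egfr_hi,
                "mu_base": r.mu_base,
                "sd_base": r.sd_base,
            }
            for sex, entries in self.entries.items()
            for r in entries
        ]
        return pd.DataFrame(rows)

    def __eq__(self, other):
        if not isinstance(other, ParameterTable):
            return NotImplemented
        if set(self.entries) != set(other.entries):
            return False
        return all(
            sorted(self.entries[s], key=lambda r: (r.age_lo, r.egfr_lo))
            == sorted(other.entries[s], key=lambda r: (r.age_lo, r.egfr_lo))
            for s in self.entries
        )


@dataclass(frozen=True)
class RiskModifiers:
    """Multiplicative covariate effects on the annual decline mean and SD.

    alpha_* scale the mean change, beta_* scale the SD.  With the signed
    convention (negative mean = decline), a therapy that slows decline by
    30% is alpha = 0.7.  Defaults: RASi 0.7, SGLT2i 0.5, current smoking
    1.2, ceased smoking 1.0 (full attenuation of the smoking excess),
    blood-pressure factors 1.0.  The proteinuria factors are synthetic
    defaults (the source stratification is not published): alpha 2.0 on the
    mean, beta 1.3 on the SD.
    """

    alpha_prot: float = 2.0
    alpha_bp: float = 1.0
    alpha_sglt2: float = 0.5
    alpha_arb: float = 0.7
    alpha_smoke: float = 1.2
    alpha_smoke_ceased: float = 1.0
    beta_prot: float = 1.3
    beta_bp: float = 1.0

    def __post_init__(self):
        for name in (
            "alpha_prot",
            "alpha_bp",
            "alpha_sglt2",
            "alpha_arb",
            "alpha_smoke",
            "alpha_smoke_ceased",
            "beta_prot",
            "beta_bp",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")

    def replace(self, **kwargs) -> "RiskModifiers":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PatientProfile:
    """One individual's baseline state and covariate flags."""

    sex: str
    age: float  # years
    egfr: float  # mL/min/1.73 m^2
    proteinuria: bool = False
    bp_category: str = "normal"
    on_rasi: bool = False
    on_sglt2i: bool = False
    smoking: str = "never"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age >= 0:
            raise ValidationError("age must be >= 0")
        if not self.egfr > 0:
            raise ValidationError("egfr must be > 0")
        if self.bp_category not in BP_CATEGORIES:
            raise ValidationError(f"bp_category must be one of {BP_CATEGORIES}")
        if self.smoking not in SMOKING_STATUSES:
            raise ValidationError(f"smoking must be one of {SMOKING_STATUSES}")

    def replace(self, **kwargs) -> "PatientProfile":
        return replace(self, **kwargs)


_COLUMNS = ["sex", "age_lo", "age_hi", "egfr_lo", "egfr_hi", "mu_base", "sd_base"]


def read_parameter_table(path, format: str | None = None) -> ParameterTable:
    """Read a parameter table from CSV or JSON and validate it.

    CSV schema: columns ``sex, age_lo, age_hi, egfr_lo, egfr_hi, mu_base,
    sd_base`` (half-open bands).  JSON schema: a list of records with the
    same keys.  The format is inferred from the file extension when not
    given.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif format == "json":
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame(records)
    else:
        raise FormatError(f"unknown format {format!r}")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"parameter table missing columns {missing}")
    entries: dict[str, list[BandEntry]] = {}
    for _, row in df.iterrows():
        entries.setdefault(str(row["sex"]), []).append(
            BandEntry(
                age_lo=float(row["age_lo"]),
                age_hi=float(row["age_hi"]),
                egfr_lo=float(row["egfr_lo"]),
                egfr_hi=float(row["egfr_hi"]),
                mu_base=float(row["mu_base"]),
                sd_base=float(row["sd_base"]),
            )
        )
    return ParameterTable(entries)


def write_parameter_table(table: ParameterTable, path, format: str | None = None) -> None:
    """Write a table in the CSV/JSON schema accepted by `read_parameter_table`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    df = table.to_frame()[_COLUMNS]
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        raise FormatError(f"unknown format {format!r}")


def lookup_base(table: ParameterTable, sex: str, age: float, egfr: float):
    """Return (mu_base, sd_base) for the stratum containing (age, egfr).

    Applies the half-open band convention, age clamping and the eGFR<30
    rule (parameters of the stratum containing eGFR 30).

    Raises
    ------
    KeyError
        If ``sex`` is not in the table.
    ValueError
        If ``egfr`` <= 0.
    """
    if not egfr > 0:
        raise ValueError("egfr must be > 0")
    mu, sd = table.lookup_vec(sex, [age], [egfr])
    return float(mu[0]), float(sd[0])


def modifier_factors(profile: PatientProfile, mods: RiskModifiers):
    """Overall (alpha, beta) multipliers for one individual.

    alpha multiplies the stratum mean, beta the stratum SD.  Treatment
    factors apply only when the corresponding flag is set; the smoking
    factor is chosen by smoking status; proteinuria and blood-pressure
    factors apply to both mean and SD per their alpha/beta values.
    """
    alpha = 1.0
    beta = 1.0
    if profile.proteinuria:
        alpha *= mods.alpha_prot
        beta *= mods.beta_prot
    if profile.bp_category == "high":
        alpha *= mods.alpha_bp
        beta *= mods.beta_bp
    if profile.on_sglt2i:
        alpha *= mods.alpha_sglt2
    if profile.on_rasi:
        alpha *= mods.alpha_arb
    if profile.smoking == "current":
        alpha *= mods.alpha_smoke
    elif profile.smoking == "ceased":
        alpha *= mods.alpha_smoke_ceased
    return alpha, beta


def effective_params(
    mu_base: float, sd_base: float, profile: PatientProfile, mods: RiskModifiers
):
    """Apply covariate multipliers: mu = mu_base * alpha, sigma = sd_base * beta."""
    alpha, beta = modifier_factors(profile, mods)
    return mu_base * alpha, sd_base * beta
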