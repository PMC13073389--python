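"""Deterministic eGFR trajectory projection for a fixed latent effect z.

Each individual carries a single standard-normal random effect ``z`` fixed
over the whole projection.  The annual change at age *a* and current eGFR
*g* is ``delta = mu(a, g) + z * sigma(a, g)`` with ``mu``/``sigma`` taken
from the current stratum after covariate modifiers; eGFR is floored at 0.
The time step is one integer year (slopes are annual; fractional starting
ages are truncated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterTable, PatientProfile, RiskModifiers, modifier_factors

__all__ = ["Trajectory", "project", "first_passage_age"]


@dataclass(frozen=True)
class Trajectory:
    """A projected yearly (age, eGFR) path for one fixed z."""

    ages: np.ndarray  # integer years, strictly increasing by 1
    egfrs: np.ndarray  # mL/min/1.73 m^2, floored at 0
    z: float

    @property
    def points(self):
        return list(zip(self.ages.tolist(), self.egfrs.tolist()))

    def __len__(self):
        return len(self.ages)


def project(
    profile: PatientProfile,
    z: float,
    target_age: float,
    table: ParameterTable,
    mods: RiskModifiers | None = None,
) -> Trajectory:
    """Project the yearly eGFR path from the profile's age to target_age.

    Starting from ``(age, egfr)``, each year applies
    ``e <- max(0, e + mu + z * sigma)`` with the stratum parameters looked
    up at the *current* age and eGFR (clamped bands, eGFR<30 rule) and
    scaled by the profile's covariate multipliers.  Returns the full path
    up to ``target_age`` inclusive.
    """
    if mods is None:
        mods = RiskModifiers()
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    start_age = int(profile.age)
    end_age = int(target_age)
    if end_age <= start_age:
        raise ValueError("target_age must exceed the starting age")
    alpha, beta = modifier_factors(profile, mods)
    ages = np.arange(start_age, end_age + 1)
    egfrs = np.empty(len(ages))
    e = float(profile.egfr)
    egfrs[0] = e
    for k, a in enumerate(ages[:-1]):
        mu_b, sd_b = table.lookup_vec(profile.sex, [a], [max(e, 1e-12)])
        e = max(0.0, e + alpha * float(mu_b[0]) + z * beta * float(sd_b[0]))
        egfrs[k + 1] = e
    return Trajectory(ages=ages, egfrs=egfrs, z=float(z))


def first_passage_age(traj: Trajectory, threshold: float):
    """Smallest age in the path with eGFR strictly below threshold, or None."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    below = np.flatnonzero(traj.egfrs < threshold)
    if below.size == 0:
        return None
    return int(traj.ages[below[0]])
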