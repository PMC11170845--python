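"""One-compartment intravenous-infusion concentration model.

The disposition model is a single well-stirred compartment with first-order
elimination (rate constant ``k = CL / V``).  During a zero-order infusion at
rate ``R0`` started at ``t0`` the above-baseline concentration is

    C(t) = (R0 / CL) * (1 - exp(-k * (t - t0)))          t0 <= t <= te

and after the infusion ends at ``te`` the end-of-infusion value decays
mono-exponentially,

    C(t) = C(te) * exp(-k * (t - te))                    t > te.

The model is linear, so contributions from an arbitrary multi-day dosing
schedule add (superposition).  Total serum concentration is the drug
contribution plus the endogenous baseline.

Amounts in :class:`DoseEvent` are mg of elemental magnesium; the helper
constructors convert labeled grams of MgSO4 via the regimen's salt factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .units import DEFAULT_SALT_FACTOR


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order infusion.

    Parameters
    ----------
    start_time : float
        Hours since study start (t = 0 at the start of the first dose).
    amount : float
        mg of elemental magnesium delivered over the whole infusion.
    duration : float
        Infusion length in hours; must be strictly positive (bolus dosing
        is not used for magnesium seizure prophylaxis).
    """

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.amount < 0:
            raise ValueError(f"amount must be >= 0, got {self.amount}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not np.isfinite(self.amount / self.duration):
            raise ValueError("infusion rate amount/duration must be finite")

    @property
    def rate(self) -> float:
        """Infusion rate, mg elemental Mg per hour."""
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of infusions plus the dose-unit convention."""

    events: tuple[DoseEvent, ...]
    salt_factor: float = DEFAULT_SALT_FACTOR

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if self.salt_factor <= 0:
            raise ValueError("salt_factor must be > 0")
        starts = [e.start_time for e in events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("events must be sorted by start_time")

    @classmethod
    def from_grams(
        cls,
        doses: Iterable[tuple[float, float, float]],
        salt_factor: float = DEFAULT_SALT_FACTOR,
    ) -> "Regimen":
        """Build a regimen from ``(start_h, labeled_grams, duration_h)`` triples."""
        events = tuple(
            DoseEvent(start, grams * salt_factor, dur)
            for start, grams, dur in sorted(doses, key=lambda d: d[0])
        )
        return cls(events=events, salt_factor=salt_factor)

    @property
    def total_grams(self) -> float:
        """Total labeled grams of MgSO4 in the regimen."""
        return sum(e.amount for e in self.events) / self.salt_factor

    @property
    def end_of_last_infusion(self) -> float:
        return max((e.end_time for e in self.events), default=0.0)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, durations, rates) as float arrays, one entry per event."""
        starts = np.array([e.start_time for e in self.events], dtype=float)
        durs = np.array([e.duration for e in self.events], dtype=float)
        rates = np.array([e.rate for e in self.events], dtype=float)
        return starts, durs, rates


@dataclass(frozen=True)
class PKParameters:
    """Individual disposition parameters.

    CL is clearance in L/h, V the apparent volume in L, and ``baseline`` the
    endogenous serum magnesium in the same unit as model predictions
    (mg/L internally).
    """

    CL: float
    V: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.CL > 0:
            raise ValueError(f"CL must be > 0, got {self.CL}")
        if not self.V > 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        if self.baseline < 0:
            raise ValueError(f"baseline must be >= 0, got {self.baseline}")

    @property
    def k(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return self.CL / self.V


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration--time profile; ``total = above_baseline + baseline``."""

    times: np.ndarray
    above_baseline: np.ndarray
    baseline: float

    @property
    def total(self) -> np.ndarray:
        return self.above_baseline + self.baseline


def infusion_superposition(t, starts, durations, rates, CL, V):
    """Above-baseline concentration under superposed zero-order infusions.

    Fully vectorized kernel shared by the scalar API and the estimation /
    simulation engines.  ``t`` may be any shape; ``starts``/``durations``/
    ``rates`` are 1-d over events (events with rate 0 contribute nothing, so
    padding is harmless).  ``CL`` and ``V`` are scalars here.
    """
    t = np.asarray(t, dtype=float)
    k = CL / V
    dt = t[..., None] - np.asarray(starts, dtype=float)
    tau1 = np.clip(dt, 0.0, np.asarray(durations, dtype=float))
    tau2 = np.clip(dt - np.asarray(durations, dtype=float), 0.0, None)
    contrib = (np.asarray(rates, dtype=float) / CL) * (
        -np.expm1(-k * tau1)
    ) * np.exp(-k * tau2)
    return contrib.sum(axis=-1)


def conc_at(regimen: Regimen, params: PKParameters, t):
    """Total concentration (baseline + drug) at time(s) ``t`` in hours.

    Continuous and non-negative in ``t``; negative times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    if len(regimen.events) == 0:
        return params.baseline + np.zeros_like(t_arr) if t_arr.ndim else params.baseline
    starts, durs, rates = regimen.arrays()
    above = infusion_superposition(t_arr, starts, durs, rates, params.CL, params.V)
    out = params.baseline + above
    return float(out) if np.ndim(t) == 0 else out


def conc_profile(regimen: Regimen, params: PKParameters, times) -> ConcentrationProfile:
    """Vectorized :func:`conc_at` over a non-decreasing time grid."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    if np.any(times < 0):
        raise ValueError("time must be >= 0")
    if len(regimen.events) == 0:
        above = np.zeros_like(times)
    else:
        starts, durs, rates = regimen.arrays()
        above = infusion_superposition(times, starts, durs, rates, params.CL, params.V)
    return ConcentrationProfile(times=times, above_baseline=above, baseline=params.baseline)
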