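"""Blood-alcohol input profiles and concentration <-> partial-pressure maps.

The model is driven by an imposed blood alcohol concentration (BAC) history.
Profiles are triangular — linear absorption from zero to a peak, then linear
metabolic elimination back to zero — or arbitrary tabulated series read from
CSV.  Because the balance equations are written in ethanol partial pressures,
the profile is converted to an arterial partial pressure ``P_a(t)`` through
the blood:gas equilibrium relationship; the same linear map converts the
simulated gas-compartment pressure back into an equivalent BAC for reporting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ModelParameters

__all__ = [
    "BACProfile",
    "bac_conversion_factor",
    "bac_to_pressure",
    "pressure_to_bac_eq",
]


def bac_conversion_factor(p: ModelParameters) -> float:
    """Equivalent BAC per Torr of gas-phase ethanol partial pressure, g/dL.

    The gas-compartment pressure ``P_g`` maps to the blood concentration that
    would be in equilibrium with it:

        BAC_EQ = (beta_b / beta_g) * P_g * M_etoh / (R * T) * 100

    ``beta_b/beta_g`` is the dimensionless blood:gas partition coefficient,
    ``P_g*M/(R*T)`` is the gas-phase mass concentration in g/cm^3, and the
    factor 100 converts per-cm^3 to per-dL.  The molar mass does not appear in
    the usual compact statement of this relationship but is required for the
    result to carry g/dL; with the default parameters the factor is
    ~0.4187 g/dL per Torr, giving ~0.19 Torr at 0.08 g/dL, consistent with
    ethanol blood:gas partition physiology.
    """
    return (p.beta_b / p.beta_g) * p.M_etoh * 100.0 / (p.R_gas * p.T)


def pressure_to_bac_eq(P_g: float | np.ndarray, p: ModelParameters) -> float | np.ndarray:
    """Convert gas-phase ethanol partial pressure (Torr) to equivalent BAC (g/dL)."""
    if np.any(np.asarray(P_g) < 0):
        raise ValueError("partial pressure must be non-negative")
    return bac_conversion_factor(p) * P_g


def bac_to_pressure(bac: float | np.ndarray, p: ModelParameters) -> float | np.ndarray:
    """Convert a blood alcohol concentration (g/dL) to its equilibrium ethanol
    partial pressure (Torr); exact inverse of :func:`pressure_to_bac_eq`."""
    if np.any(np.asarray(bac) < 0):
        raise ValueError("concentration must be non-negative")
    return np.asarray(bac) / bac_conversion_factor(p) if isinstance(bac, np.ndarray) \
        else bac / bac_conversion_factor(p)


@dataclass(frozen=True)
class BACProfile:
    """An imposed blood alcohol concentration history.

    Triangular mode: BAC rises linearly from 0 at ``start_time`` to
    ``bac_max`` over ``absorption_time``, then falls linearly at
    ``elimination_rate`` and is floored at zero.  Tabulated mode wraps an
    arbitrary (time, concentration) series interpolated linearly and zero
    outside its range.  All times are hours, concentrations g/dL.
    """

    absorption_time: float
    bac_max: float
    elimination_rate: float
    start_time: float = 0.0
    mode: str = "triangular"
    times: np.ndarray | None = field(default=None, repr=False)
    values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("triangular", "tabulated"):
            raise ValueError(f"unknown profile mode {self.mode!r}")
        if self.mode == "triangular" and (
                self.absorption_time <= 0 or self.bac_max <= 0 or self.elimination_rate <= 0):
            raise ValueError("absorption_time, bac_max and elimination_rate must be > 0")
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if self.mode == "tabulated":
            t = np.asarray(self.times, dtype=float)
            v = np.asarray(self.values, dtype=float)
            if t.ndim != 1 or t.shape != v.shape or t.size < 2:
                raise ValueError("tabulated profile needs matching 1-D time/value arrays")
            if np.any(np.diff(t) <= 0):
                raise ValueError("tabulated times must be strictly increasing")
            if np.any(v < 0):
                raise ValueError("tabulated concentrations must be non-negative")
            object.__setattr__(self, "times", t)
            object.__setattr__(self, "values", v)

    # -- constructors -----------------------------------------------------

    @classmethod
    def triangular(cls, absorption_time: float, bac_max: float,
                   elimination_rate: float = 0.018, start_time: float = 0.0) -> "BACProfile":
        return cls(absorption_time, bac_max, elimination_rate, start_time)

    @classmethod
    def tabulated(cls, times_h: np.ndarray, bac_g_per_dL: np.ndarray) -> "BACProfile":
        """Wrap a tabulated (hours, g/dL) series.

        The nominal triangular fields are filled with summary values of the
        series (peak and mean decline) so that downstream code that reports
        them stays meaningful.
        """
        t = np.asarray(times_h, dtype=float)
        v = np.asarray(bac_g_per_dL, dtype=float)
        ipk = int(np.argmax(v))
        peak_t = float(t[ipk])
        bmax = float(v[ipk])
        post = v[ipk:]
        # mean decline rate over the falling limb, as a stand-in elimination rate
        fall = (bmax - float(post[-1])) / max(float(t[-1]) - peak_t, 1e-9)
        return cls(
            absorption_time=max(peak_t - float(t[0]), 1e-9),
            bac_max=bmax,  # zero for an all-zero series (zero-input limit)
            elimination_rate=max(fall, 1e-9),
            start_time=float(t[0]),
            mode="tabulated",
            times=t,
            values=v,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "BACProfile":
        """Read a tabulated profile from CSV with header ``time_h,bac_g_per_dL``."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or \
                    [c.strip() for c in reader.fieldnames[:2]] != ["time_h", "bac_g_per_dL"]:
                raise ValueError(
                    f"{path}: expected CSV header 'time_h,bac_g_per_dL', got {reader.fieldnames}"
                )
            rows = [(float(r["time_h"]), float(r["bac_g_per_dL"])) for r in reader]
        if not rows:
            raise ValueError(f"{path}: empty profile")
        t, v = zip(*rows)
        return cls.tabulated(np.asarray(t), np.asarray(v))

    # -- evaluation -------------------------------------------------------

    def bac_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """BAC at time ``t`` (hours), g/dL."""
        tt = np.asarray(t, dtype=float)
        if np.any(tt < 0):
            raise ValueError("time must be non-negative")
        if self.mode == "tabulated":
            out = np.interp(tt, self.times, self.values, left=0.0, right=0.0)
        else:
            rise = self.bac_max * (tt - self.start_time) / self.absorption_time
            peak_t = self.start_time + self.absorption_time
            fall = self.bac_max - self.elimination_rate * (tt - peak_t)
            out = np.where(tt < self.start_time, 0.0, np.where(tt <= peak_t, rise, fall))
            out = np.maximum(out, 0.0)
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out

    @property
    def peak_time(self) -> float:
        """Time of the BAC maximum, hours."""
        if self.mode == "tabulated":
            return float(self.times[int(np.argmax(self.values))])
        return self.start_time + self.absorption_time

    def zero_time(self) -> float:
        """Time at which BAC returns to zero, hours."""
        if self.mode == "triangular":
            return self.start_time + self.absorption_time + self.bac_max / self.elimination_rate
        v, t = self.values, self.times
        pos = v > 0
        if not pos.any() or pos[-1]:
            raise ValueError("tabulated profile never returns to zero")
        last = int(np.max(np.nonzero(pos)[0]))  # last strictly positive sample
        t0, t1 = t[last], t[last + 1]
        v0, v1 = v[last], v[last + 1]
        return float(t0 + v0 * (t1 - t0) / (v0 - v1))

    def breakpoints(self) -> np.ndarray:
        """Times (hours) at which the profile has slope discontinuities."""
        if self.mode == "triangular":
            return np.array([self.start_time, self.peak_time, self.zero_time()])
        return np.asarray(self.times, dtype=float)

    def pressure_at(self, t: float | np.ndarray, p: ModelParameters) -> float | np.ndarray:
        """Arterial ethanol partial pressure P_a at time ``t`` (hours), Torr."""
        return self.bac_at(t) / bac_conversion_factor(p)
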