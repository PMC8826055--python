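"""Methane oxidation potential (MOP) and depletion endpoints.

MOP converts a headspace CH4 drawdown (ppmv) into a mass rate per gram of dry
soil, assuming linear kinetics over the chosen window:

    MOP [μg CH4 g⁻¹ h⁻¹] =
        Δppmv · 10⁻⁶ · V_headspace(L) · (16 g mol⁻¹ / 22.4 L mol⁻¹)
        · (273 / (273 + T_°C)) · 10⁶ / (soil_mass(g) · elapsed_hours)

i.e. the drawn-down CH4 volume at incubation temperature is converted to moles
via the ideal-gas molar volume at STP with a temperature correction, then to
micrograms.  Every constant comes from the :class:`~mobkit.io_core.DepletionSeries`
(headspace volume, soil mass, temperature), so alternative microcosm setups
need no code change.

A ``verbatim`` mode reproduces the commonly printed constant set for the
120-ml serum-bottle protocol (0.120 L nominal bottle volume, 301 K reference
temperature) for comparison with legacy spreadsheets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import DepletionSeries

__all__ = ["MopResult", "methane_oxidation_potential", "time_to_fraction_consumed"]

MOLAR_MASS_CH4 = 16.0  # g/mol
MOLAR_VOLUME_STP = 22.4  # L/mol at 273 K, 1 atm


@dataclass(frozen=True)
class MopResult:
    microcosm_id: str
    mop: float  # μg CH4 g⁻¹ dry soil h⁻¹; negative = net production
    c_start: float  # ppmv
    c_end: float  # ppmv
    elapsed_hours: float


def methane_oxidation_potential(
    series: DepletionSeries,
    start_index: int = 0,
    end_index: int = -1,
    mode: str = "ideal_gas",
) -> MopResult:
    """Compute MOP between two observations of a depletion series.

    Consumption is reported positive; a rising concentration yields a negative
    MOP with a warning.  ``mode='verbatim'`` uses the fixed 0.120 L / 301 K
    constants instead of the series' own headspace volume and temperature.
    """
    times, conc = series.times, series.concentrations
    n = len(times)
    start_index = range(n)[start_index]
    end_index = range(n)[end_index]
    if end_index <= start_index:
        raise ValueError("end_index must come after start_index")
    c_start, c_end = conc[start_index], conc[end_index]
    elapsed = times[end_index] - times[start_index]
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    if series.soil_mass <= 0:
        raise ValueError("soil_mass must be positive")

    delta = c_start - c_end  # ppmv consumed
    if mode == "ideal_gas":
        v_l = series.headspace_volume / 1000.0
        temp_factor = 273.0 / (273.0 + series.temperature)
    elif mode == "verbatim":
        v_l = 0.120
        temp_factor = 273.0 / 301.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mop = (
        abs(delta)
        * 1e-6
        * v_l
        * (MOLAR_MASS_CH4 / MOLAR_VOLUME_STP)
        * temp_factor
        * 1e6
        / (series.soil_mass * elapsed)
    )
    if delta < 0:
        warnings.warn(
            f"{series.microcosm_id}: CH4 increased over the window; "
            "reporting net production as negative MOP",
            stacklevel=2,
        )
        mop = -mop
    return MopResult(
        microcosm_id=series.microcosm_id,
        mop=float(mop),
        c_start=float(c_start),
        c_end=float(c_end),
        elapsed_hours=float(elapsed),
    )


def time_to_fraction_consumed(
    series: DepletionSeries, fraction: float
) -> float | None:
    """First time (hours) at which ``fraction`` of the initial CH4 is gone.

    The threshold concentration is ``(1 - fraction) * initial``; the crossing
    is located by linear interpolation between the bracketing observations.
    Returns ``None`` if the series never reaches the threshold.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    times, conc = series.times, series.concentrations
    threshold = (1.0 - fraction) * conc[0]
    if conc[0] <= threshold:
        return float(times[0])
    below = np.nonzero(conc <= threshold)[0]
    if len(below) == 0:
        return None
    j = below[0]
    i = j - 1
    if conc[i] == conc[j]:
        return float(times[j])
    frac = (conc[i] - threshold) / (conc[i] - conc[j])
    return float(times[i] + frac * (times[j] - times[i]))
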