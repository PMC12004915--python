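"""Thermodynamic decomposition of micellization.

From the fitted CMC and demicellization enthalpy:

    ΔH°_mic  = −ΔH°_demicellization
    ΔG°_mic  = R·T·ln(CMC/c°)             (zwitterionic: no counterion term)
    −TΔS°    = ΔG° − ΔH°_mic
    ΔC_p,mic = slope of the linear ΔH°_mic(T) fit;  T_H its zero crossing.

c° defaults to 1 mol L⁻¹; the mole-fraction convention (55.5 M) only
shifts ΔG° by an additive constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .constants import GAS_CONSTANT, STANDARD_CONCENTRATION
from .protocol import ValidationError

__all__ = ["ThermoRecord", "HeatCapacityResult", "micellization_enthalpy",
           "gibbs_energy", "entropy_terms", "heat_capacity",
           "build_thermo_record"]


@dataclass(frozen=True)
class ThermoRecord:
    """Per-condition, per-temperature thermodynamic state (J mol⁻¹)."""

    condition_label: str
    temperature: float
    cmc: float
    dg: float
    dh_mic: float
    minus_tds: float
    ds: float

    def __post_init__(self) -> None:
        closure = self.dg - self.dh_mic - self.minus_tds
        scale = max(abs(self.dg), abs(self.dh_mic), abs(self.minus_tds), 1.0)
        if abs(closure) > 1e-9 * scale:
            raise ValidationError(
                f"decomposition identity violated: dG - dH - (-TdS) = {closure}")


@dataclass(frozen=True)
class HeatCapacityResult:
    """Linear ΔH°_mic(T) fit: slope ΔC_p, zero crossing T_H."""

    dcp: float
    t_h: float
    slope_stderr: float
    n_points: int
    extrapolated: bool


def micellization_enthalpy(dh_demic: float) -> float:
    """Micellization enthalpy from the demicellization enthalpy (sign flip)."""
    return -dh_demic


def gibbs_energy(cmc: float, temperature: float,
                 c_std: float = STANDARD_CONCENTRATION) -> float:
    """Standard Gibbs energy of micellization, R·T·ln(CMC/c°), J mol⁻¹.

    Valid for nonionic and zwitterionic surfactants, where counterion
    association is negligible.  Strictly increasing in the CMC; negative
    whenever CMC < c°.
    """
    if not cmc > 0:
        raise ValidationError("cmc must be positive")
    if not temperature > 0:
        raise ValidationError("temperature must be positive")
    if not c_std > 0:
        raise ValidationError("c_std must be positive")
    return GAS_CONSTANT * temperature * float(np.log(cmc / c_std))


def entropy_terms(dg: float, dh_mic: float,
                  temperature: float) -> Tuple[float, float]:
    """(ΔS°, −TΔS°) from ΔG° = ΔH° − TΔS°.

    Returns ``ds`` in J mol⁻¹ K⁻¹ and ``minus_tds`` in J mol⁻¹; the
    identity ΔG° = ΔH° + (−TΔS°) holds exactly.
    """
    if not temperature > 0:
        raise ValidationError("temperature must be positive")
    minus_tds = dg - dh_mic
    ds = (dh_mic - dg) / temperature
    return ds, minus_tds


def heat_capacity(series: Sequence[Tuple[float, float]]) -> HeatCapacityResult:
    """ΔC_p,mic and T_H from an ordinary least-squares line ΔH(T).

    ``series`` is (temperature K, ΔH°_mic J mol⁻¹) pairs at ≥ 2 distinct
    temperatures.  The slope is ΔC_p,mic; T_H = −intercept/slope is the
    temperature where micellization is athermal (NaN when the slope is
    zero: T_H undefined, not an error).  ``extrapolated`` flags a T_H
    further than 50 K outside the measured range.
    """
    pts = [(float(t), float(h)) for t, h in series]
    if len(pts) < 2:
        raise ValidationError("need at least two (T, dH) points")
    temps = np.array([p[0] for p in pts])
    dh = np.array([p[1] for p in pts])
    if np.unique(temps).size < 2:
        raise ValidationError("all temperatures identical")
    if len(pts) == 2:
        slope = (dh[1] - dh[0]) / (temps[1] - temps[0])
        intercept = dh[0] - slope * temps[0]
        stderr = 0.0
    else:
        fit = stats.linregress(temps, dh)
        slope, intercept, stderr = fit.slope, fit.intercept, fit.stderr
    if slope == 0.0:
        return HeatCapacityResult(0.0, float("nan"), float(stderr),
                                  len(pts), False)
    t_h = -intercept / slope
    extrapolated = not (temps.min() - 50.0 <= t_h <= temps.max() + 50.0)
    return HeatCapacityResult(float(slope), float(t_h), float(stderr),
                              len(pts), bool(extrapolated))


def build_thermo_record(condition_label: str, temperature: float, cmc: float,
                        dh_demic: float,
                        c_std: float = STANDARD_CONCENTRATION) -> ThermoRecord:
    """Assemble the full decomposition from pipeline outputs."""
    dh_mic = micellization_enthalpy(dh_demic)
    dg = gibbs_energy(cmc, temperature, c_std)
    ds, minus_tds = entropy_terms(dg, dh_mic, temperature)
    return ThermoRecord(condition_label, temperature, cmc, dg, dh_mic,
                        minus_tds, ds)
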