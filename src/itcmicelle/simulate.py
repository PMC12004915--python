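"""Forward simulator of the ITC demicellization experiment.

The simulator reproduces the standard protocol — a perfusion-type
(overfilled) cell of fixed active volume receiving a sequence of equal
injections of micellar stock — under either a pseudophase or a
mass-action aggregation model, and can render the integrated heats as a
raw differential-power trace for testing the peak-integration stage.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .containers import Enthalpogram, Thermogram
from .protocol import (MicellizationModel, NoiseSpec, TitrationProtocol,
                       ValidationError)


class SimulationWarning(UserWarning):
    pass


class NumericalError(RuntimeError):
    """Raised when an equilibrium solve fails to converge."""


# ---------------------------------------------------------------------------
# concentration bookkeeping
# ---------------------------------------------------------------------------

def cell_concentration(protocol: TitrationProtocol, i: int,
                       dilution: str = "displacement") -> float:
    """Total surfactant concentration in the cell after injection ``i``.

    The default ``displacement`` model describes an overfilled cell of
    constant active volume V₀: each injection of volume v expels an equal
    volume of the (mixed) cell content, giving

        C_i = C_syr · [1 − (1 − v/V₀)^i].

    ``additive`` is the naive bookkeeping C_i = C_syr·i·v/(V₀+i·v); the two
    differ by <1% at v/V₀ ≈ 0.006.  ``i = 0`` returns 0 (nothing injected).
    """
    if not 0 <= i <= protocol.n_injections:
        raise IndexError(
            f"injection index {i} out of range 0..{protocol.n_injections}")
    v, v0, cs = (protocol.injection_volume, protocol.cell_volume,
                 protocol.syringe_conc)
    if dilution == "displacement":
        return cs * (1.0 - (1.0 - v / v0) ** i)
    if dilution == "additive":
        return cs * (i * v) / (v0 + i * v)
    raise ValueError(f"unknown dilution model {dilution!r}")


def concentration_profile(protocol: TitrationProtocol,
                          dilution: str = "displacement") -> np.ndarray:
    """Cell concentration after injections 0..n (length n+1)."""
    return np.array([cell_concentration(protocol, i, dilution)
                     for i in range(protocol.n_injections + 1)])


# ---------------------------------------------------------------------------
# mass-action equilibrium
# ---------------------------------------------------------------------------

def _solve_reduced(r: float, k_red: float, n: int) -> float:
    """Solve y + k_red·yⁿ = r for y ≥ 0 (reduced monomer concentration)."""
    if r == 0.0:
        return 0.0
    if k_red == 0.0:
        return r
    f = lambda y: y + k_red * y ** n - r
    try:
        return brentq(f, 0.0, r, xtol=1e-300, rtol=4 * np.finfo(float).eps,
                      maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise NumericalError(
            f"monomer solve failed (r={r}, k_red={k_red}, n={n}): {exc}")


def solve_monomer(c_total: float, k_assoc: float, n: int) -> float:
    """Free-monomer concentration of the n-mer equilibrium n·S ⇌ Mₙ.

    Returns the unique x ≥ 0 with x + n·K·xⁿ = c_total.  For K = 0 the
    solution is x = c_total (no aggregation).  Internally the equation is
    solved in reduced units, so very sharp equilibria (large n) are safe.
    """
    if c_total < 0:
        raise ValidationError("c_total must be >= 0")
    if n < 2 or int(n) != n:
        raise ValidationError("aggregation number must be an integer >= 2")
    if k_assoc < 0:
        raise ValidationError("k_assoc must be >= 0")
    if k_assoc == 0.0 or c_total == 0.0:
        return float(c_total)
    # scale by the textbook CMC (nK)^(-1/(n-1)) so k_red = 1
    scale = (n * k_assoc) ** (-1.0 / (n - 1))
    return _solve_reduced(c_total / scale, 1.0, int(n)) * scale


def _monomer_curve(conc: np.ndarray, model: MicellizationModel) -> np.ndarray:
    """Free-monomer concentration at each total concentration."""
    conc = np.asarray(conc, dtype=float)
    if model.kind == "pseudophase":
        return np.minimum(conc, model.cmc_true)
    k_red = model.k_reduced
    if k_red is None:
        raise ValidationError(
            "mass_action model has no k_reduced; call calibrate_mass_action "
            "or set k_reduced explicitly (1.0 = textbook convention)")
    cmc, n = model.cmc_true, int(model.agg_number)
    return np.array([_solve_reduced(c / cmc, k_red, n) * cmc for c in conc])


# ---------------------------------------------------------------------------
# enthalpogram forward model
# ---------------------------------------------------------------------------

def simulate_enthalpogram(protocol: TitrationProtocol,
                          model: MicellizationModel,
                          noise: Optional[NoiseSpec] = None,
                          *,
                          assignment: str = "midpoint",
                          dilution: str = "displacement",
                          condition_label: str = "") -> Enthalpogram:
    """Integrated molar heats of a demicellization titration.

    For each injection the syringe delivers C_syr·v moles, partitioned as
    ``cmc_true`` monomer and ``C_syr − cmc_true`` micellar (the stock is
    micelle-dominated by design).  The heat is the demicellized amount
    across the injection times ``dh_demic``, normalized per mole injected,
    plus the dilution offset and the pre/post linear baseline terms:

        qᵢ = dh_demic · Δn_demic,i / (C_syr·v) + offset + baseline(Cᵢ)

    Δn_demic,i is computed from the micellar amount in the hypothetical
    mixed-but-unequilibrated cell minus the equilibrium micellar amount
    after the injection.  ``assignment`` places each heat at the
    ``midpoint`` of the pre/post cell concentrations (default; unbiased
    for a step-average quantity) or at the ``post`` concentration (the
    instrument-vendor convention).
    """
    if noise is None:
        noise = NoiseSpec(0.0, 0)
    cs, v, v0 = (protocol.syringe_conc, protocol.injection_volume,
                 protocol.cell_volume)
    cmc = model.cmc_true
    if cs <= cmc:
        raise ValidationError(
            "demicellization design requires syringe_conc > cmc_true")

    model = calibrate_mass_action(model, protocol) \
        if (model.kind == "mass_action" and model.k_reduced is None) else model

    conc = concentration_profile(protocol, dilution)  # length n+1
    if conc[-1] <= cmc:
        warnings.warn("final cell concentration never exceeds the CMC; "
                      "no transition will be observed", SimulationWarning)

    monomer = _monomer_curve(conc, model)
    micellar = conc - monomer
    mic_injected_conc = cs - cmc          # micellar content of the stock
    n_inj = cs * v                        # moles per injection

    f = v / v0
    # micellar conc of the mixed, not-yet-re-equilibrated cell
    mixed = micellar[:-1] * (1.0 - f) + mic_injected_conc * f
    dn_demic = (mixed - micellar[1:]) * v0          # moles demicellized
    q = model.dh_demic * dn_demic / n_inj + model.dilution_offset

    # demicellized fraction of the injected micelles weights the baselines
    frac = np.clip(dn_demic / (mic_injected_conc * v), 0.0, 1.0) \
        if mic_injected_conc > 0 else np.zeros_like(dn_demic)
    s_pre, s_post = model.baseline_slopes
    c_assigned = 0.5 * (conc[:-1] + conc[1:]) if assignment == "midpoint" \
        else conc[1:]
    if assignment not in ("midpoint", "post"):
        raise ValueError(f"unknown assignment {assignment!r}")
    q = q + (s_pre * frac + s_post * (1.0 - frac)) * c_assigned

    if noise.sigma_heat > 0:
        q = q + noise.rng().normal(
            0.0, noise.sigma_heat * abs(model.dh_demic), size=q.size)

    return Enthalpogram(c_assigned, q, protocol.temperature, condition_label)


# ---------------------------------------------------------------------------
# operational calibration of the mass-action constant
# ---------------------------------------------------------------------------

def _continuum_heats(conc: np.ndarray, model: MicellizationModel,
                     protocol: TitrationProtocol) -> np.ndarray:
    """Ideal (infinitesimal-injection) molar heat curve q(C).

    Differential limit of the per-injection balance:
    q(C) = dh·[(C_syr − cmc − M(C)) − M'(C)·(C_syr − C)]/C_syr + offset.
    """
    cs, cmc = protocol.syringe_conc, model.cmc_true
    m = _monomer_curve(conc, model)
    big_m = conc - m
    h = 1e-7 * cmc
    mp = (_monomer_curve(conc + h, model) - _monomer_curve(conc - h, model)) \
        / (2 * h)
    big_mp = 1.0 - mp
    q = model.dh_demic * ((cs - cmc - big_m) - big_mp * (cs - conc)) / cs
    return q + model.dilution_offset


def calibrate_mass_action(model: MicellizationModel,
                          protocol: TitrationProtocol,
                          n_grid: int = 256) -> MicellizationModel:
    """Fix ``k_reduced`` so the model's operational CMC equals ``cmc_true``.

    The operational CMC of a smooth-transition model is what the analysis
    pipeline measures: the first-derivative extremum of the six-parameter
    sigmoid fitted to the ideal noise-free continuum heat curve over the
    protocol's concentration range.  ``k_reduced`` is root-found (in log
    space) so that this operational CMC coincides with the nominal one,
    making parameter recovery well-posed.  Models that already carry a
    ``k_reduced`` are returned unchanged.
    """
    from dataclasses import replace

    from .fitting import cmc_from_fit, fit_sigmoid

    if model.kind != "mass_action":
        return model
    if model.k_reduced is not None:
        return model
    base = replace(model, k_reduced=1.0,
                   dh_demic=model.dh_demic if model.dh_demic != 0 else 1.0,
                   dilution_offset=0.0, baseline_slopes=(0.0, 0.0))
    c_lo = cell_concentration(protocol, 1)
    c_hi = cell_concentration(protocol, protocol.n_injections)
    grid = np.linspace(c_lo, c_hi, n_grid)

    def operational_cmc(log_k: float) -> float:
        trial = replace(base, k_reduced=10.0 ** log_k)
        q = _continuum_heats(grid, trial, protocol)
        fit = fit_sigmoid(Enthalpogram(grid, q, protocol.temperature),
                          n_starts=1)
        return cmc_from_fit(fit)

    try:
        log_k = brentq(lambda lk: operational_cmc(lk) - model.cmc_true,
                       -5.0, 2.0, xtol=1e-9)
    except ValueError as exc:
        raise NumericalError(
            f"mass-action calibration failed for cmc={model.cmc_true}, "
            f"n={model.agg_number}: {exc}")
    return replace(model, k_reduced=10.0 ** log_k)


# ---------------------------------------------------------------------------
# raw power trace
# ---------------------------------------------------------------------------

def simulate_power_trace(enthalpogram: Enthalpogram,
                         protocol: TitrationProtocol,
                         peak_width: float = 20.0,
                         baseline_drift: float = 0.0,
                         *,
                         baseline_power: float = 0.0,
                         lead_in: Optional[float] = None,
                         dt: float = 1.0,
                         noise_power: float = 0.0,
                         seed: int = 0) -> Thermogram:
    """Render integrated heats as a differential-power time series.

    Each injection's heat appears as a Gaussian pulse of standard
    deviation ``peak_width/4`` centred ``peak_width`` seconds after the
    injection mark, whose time-integral equals that injection's heat
    (J = molar heat × moles injected), on a linear baseline
    ``baseline_power + baseline_drift·t``.  The pulse must decay back to
    baseline before the next injection, hence ``peak_width < spacing``.
    """
    if peak_width >= protocol.spacing:
        raise ValidationError("peak_width must be < injection spacing")
    if lead_in is None:
        lead_in = protocol.spacing
    n = len(enthalpogram)
    t_end = lead_in + n * protocol.spacing
    times = np.arange(0.0, t_end + dt / 2, dt)
    power = baseline_power + baseline_drift * times

    sigma = peak_width / 4.0
    heats_joule = enthalpogram.heats * protocol.moles_per_injection
    markers = []
    for i in range(n):
        t_inj = lead_in + i * protocol.spacing
        markers.append((i + 1, t_inj, protocol.injection_volume))
        centre = t_inj + peak_width
        pulse = np.exp(-0.5 * ((times - centre) / sigma) ** 2) \
            / (sigma * np.sqrt(2.0 * np.pi))
        power = power + heats_joule[i] * pulse
    if noise_power > 0:
        power = power + np.random.default_rng(seed).normal(
            0.0, noise_power, size=power.size)
    return Thermogram(times, power, markers)


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------

def simulate_temperature_series(dcp: float, t_h: float,
                                temperatures: Sequence[float]
                                ) -> List[Tuple[float, float]]:
    """Micellization enthalpies on a linear ΔH(T) = ΔC_p·(T − T_H) law.

    ΔC_p in J mol⁻¹ K⁻¹, temperatures in K.  Duplicate temperatures are
    collapsed to the unique set with a warning.  The returned enthalpies
    are micellization enthalpies (zero at T_H, endothermic below it for
    negative ΔC_p, exothermic above — the hydrophobic-effect signature).
    """
    temps = list(temperatures)
    if len(temps) < 2:
        raise ValidationError("need at least two temperatures")
    unique = sorted(set(float(t) for t in temps))
    if len(unique) < len(temps):
        warnings.warn("duplicate temperatures collapsed", SimulationWarning)
    if len(unique) < 2:
        raise ValidationError("need at least two distinct temperatures")
    return [(t, dcp * (t - t_h)) for t in unique]


def model_at_temperature(base: MicellizationModel, dcp: float, t_h: float,
                         temperature: float) -> MicellizationModel:
    """Model whose demicellization enthalpy follows the linear ΔH(T) law."""
    from dataclasses import replace

    dh_mic = dcp * (temperature - t_h)
    return replace(base, dh_demic=-dh_mic)
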