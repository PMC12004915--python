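"""Experiment descriptors: titration geometry, micellization model, noise.

A demicellization experiment titrates a concentrated (micellar) surfactant
stock into the calorimeter cell.  While the cell is below the critical
micelle concentration (CMC) the injected micelles dissolve and their
demicellization heat is recorded; once the cell passes the CMC the heats
collapse to the dilution baseline.  These dataclasses carry everything the
forward simulator needs to reproduce that design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Tuple


class ValidationError(ValueError):
    """Raised when an experiment descriptor violates its invariants."""


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument geometry and injection schedule.

    Parameters
    ----------
    cell_volume : float
        Active cell volume in L (reference instrument: 1.4 mL).
    injection_volume : float
        Volume of a single injection in L.
    n_injections : int
        Number of injections (≥ 2).
    syringe_conc : float
        Total surfactant concentration in the syringe, mol L⁻¹.  For a
        demicellization design this is well above the CMC (~12×).
    spacing : float
        Time between injections, s.  Long enough for the thermal signal
        to return to baseline.
    temperature : float
        Cell temperature, K.
    """

    cell_volume: float
    injection_volume: float
    n_injections: int
    syringe_conc: float
    spacing: float = 300.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("cell_volume", "injection_volume", "syringe_conc",
                     "spacing", "temperature"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.injection_volume >= self.cell_volume:
            raise ValidationError("injection_volume must be < cell_volume")
        if int(self.n_injections) != self.n_injections or self.n_injections < 2:
            raise ValidationError("n_injections must be an integer >= 2")

    @property
    def moles_per_injection(self) -> float:
        """Moles of surfactant delivered per injection (C_syr · v)."""
        return self.syringe_conc * self.injection_volume

    @property
    def injection_times(self):
        """Nominal injection times (s), first injection at t = spacing."""
        import numpy as np

        return self.spacing * np.arange(1, self.n_injections + 1)


ModelKind = Literal["pseudophase", "mass_action"]


@dataclass(frozen=True)
class MicellizationModel:
    """Aggregation model generating the demicellization heat curve.

    ``pseudophase`` treats micelles as a separate phase appearing sharply at
    ``cmc_true`` (monomer capped at the CMC); ``mass_action`` uses the n-mer
    equilibrium n·S ⇌ Mₙ, which produces the smooth sigmoidal transition
    seen in real enthalpograms.

    The mass-action equilibrium constant is stored in reduced form
    ``k_reduced = n · K · cmc_true**(n-1)`` (dimensionless), which is
    numerically safe for large aggregation numbers.  ``k_reduced = 1``
    is the textbook convention CMC = (nK)^(−1/(n−1)); leave it ``None``
    to have the simulator calibrate it so the model's operational CMC
    (sigmoid-fit derivative extremum of the ideal curve) equals
    ``cmc_true`` — see :func:`itcmicelle.simulate.calibrate_mass_action`.

    ``dh_demic`` is the demicellization enthalpy in J mol⁻¹ (positive for
    an endothermic micelle dissolution); the micellization enthalpy is its
    negative.  ``baseline_slopes`` are the pre-/post-transition linear
    baseline slopes in (J mol⁻¹)/(mol L⁻¹).
    """

    kind: ModelKind
    cmc_true: float
    dh_demic: float
    agg_number: Optional[int] = None
    k_reduced: Optional[float] = None
    dilution_offset: float = 0.0
    baseline_slopes: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("pseudophase", "mass_action"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        if not self.cmc_true > 0:
            raise ValidationError("cmc_true must be positive")
        if self.kind == "mass_action":
            if self.agg_number is None or self.agg_number < 2:
                raise ValidationError(
                    "mass_action model requires agg_number >= 2")
            if self.k_reduced is not None and not self.k_reduced > 0:
                raise ValidationError("k_reduced must be positive")
        if len(self.baseline_slopes) != 2:
            raise ValidationError("baseline_slopes must be a (pre, post) pair")

    @property
    def k_assoc(self) -> Optional[float]:
        """Equilibrium constant K in (mol L⁻¹)^(1-n); may overflow for
        very large aggregation numbers — prefer ``k_reduced``."""
        if self.kind != "mass_action" or self.k_reduced is None:
            return None
        n = self.agg_number
        return self.k_reduced / (n * self.cmc_true ** (n - 1))

    def with_enthalpy(self, dh_demic: float) -> "MicellizationModel":
        """Copy of this model with a different demicellization enthalpy."""
        return replace(self, dh_demic=dh_demic)


@dataclass(frozen=True)
class NoiseSpec:
    """IID Gaussian noise on integrated heats.

    ``sigma_heat`` is expressed as a fraction of |dh_demic| so that noise
    levels are comparable across conditions.  The seed is mandatory: the
    simulator never touches global random state.
    """

    sigma_heat: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_heat < 0:
            raise ValidationError("sigma_heat must be >= 0")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")

    def rng(self):
        import numpy as np

        return np.random.default_rng(int(self.seed))


# sentinel noise-free configuration
NOISELESS = NoiseSpec(sigma_heat=0.0, seed=0)
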