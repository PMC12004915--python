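"""In-memory containers for raw and integrated titration data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .protocol import ValidationError


@dataclass
class Thermogram:
    """Raw differential-power record with injection markers.

    ``times`` (s, strictly increasing), ``powers`` (W), and ``injections``
    as (index, time_s, volume_L) tuples sorted by time.
    """

    times: np.ndarray
    powers: np.ndarray
    injections: List[Tuple[int, float, float]]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.powers.shape:
            raise ValidationError("times and powers must be 1-D and equal length")
        if self.times.size < 2:
            raise ValidationError("thermogram needs at least two samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValidationError(f"times not strictly increasing at row {row}")
        self.injections = sorted(self.injections, key=lambda m: m[1])
        for _, t, _ in self.injections:
            if not (self.times[0] <= t <= self.times[-1]):
                raise ValidationError(
                    f"injection time {t} outside the recorded interval")

    @property
    def n_injections(self) -> int:
        return len(self.injections)


@dataclass
class Enthalpogram:
    """Per-injection molar heats vs cell surfactant concentration.

    ``concentrations`` in mol L⁻¹ (strictly increasing), ``heats`` in
    J per mole of injectant, plus the run temperature (K) and a free-text
    condition label (salt identity/concentration).
    """

    concentrations: np.ndarray
    heats: np.ndarray
    temperature: float = 298.15
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.concentrations.ndim != 1 or \
                self.concentrations.shape != self.heats.shape:
            raise ValidationError(
                "concentrations and heats must be 1-D and equal length")
        if self.concentrations.size == 0:
            raise ValidationError("enthalpogram is empty")
        dc = np.diff(self.concentrations)
        if np.any(dc <= 0):
            row = int(np.argmax(dc <= 0)) + 2  # 1-based row of the offender
            raise ValidationError(
                f"concentrations not strictly increasing at data row {row}")
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive")

    def __len__(self) -> int:
        return self.concentrations.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "injection": np.arange(1, len(self) + 1),
            "conc_mol_per_L": self.concentrations,
            "q_J_per_mol": self.heats,
        })

    def scaled(self, heat_factor: float = 1.0,
               conc_factor: float = 1.0) -> "Enthalpogram":
        """Unit-scaled copy (e.g. mol→mmol with ``conc_factor=1e3``)."""
        return Enthalpogram(self.concentrations * conc_factor,
                            self.heats * heat_factor,
                            self.temperature, self.condition_label)
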