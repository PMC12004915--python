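"""Plain-text I/O: enthalpogram / thermogram CSV dialects and TOML configs.

CSV dialects (header rows mandatory, decimal point, no thousands
separators):

* enthalpogram: ``injection,conc_mol_per_L,q_J_per_mol``
* thermogram:   ``time_s,power_W``
* injection schedule: ``injection,time_s,volume_L``

Round trips are lossless to 12 significant digits.
"""

from __future__ import annotations

import sys
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

from .containers import Enthalpogram, Thermogram
from .protocol import (MicellizationModel, NoiseSpec, TitrationProtocol,
                       ValidationError)

_FLOAT_FMT = "%.15g"

PathLike = Union[str, Path]


def _read_csv(path: PathLike, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty data section")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2  # header is row 1
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = vals
    return df


def read_enthalpogram(path: PathLike, temperature: float = 298.15,
                      condition_label: str = "") -> Enthalpogram:
    df = _read_csv(path, ("injection", "conc_mol_per_L", "q_J_per_mol"))
    conc = df["conc_mol_per_L"].to_numpy()
    dup = np.flatnonzero(np.diff(conc) <= 0)
    if dup.size:
        raise ValidationError(
            f"{path}: concentration not strictly increasing at data row "
            f"{int(dup[0]) + 3}")
    return Enthalpogram(conc, df["q_J_per_mol"].to_numpy(),
                        temperature, condition_label)


def write_enthalpogram(e: Enthalpogram, path: PathLike) -> None:
    e.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_thermogram(path: PathLike, schedule_path: PathLike) -> Thermogram:
    df = _read_csv(path, ("time_s", "power_W"))
    sched = _read_csv(schedule_path, ("injection", "time_s", "volume_L"))
    markers = [(int(r.injection), float(r.time_s), float(r.volume_L))
               for r in sched.itertuples()]
    return Thermogram(df["time_s"].to_numpy(), df["power_W"].to_numpy(),
                      markers)


def write_thermogram(t: Thermogram, path: PathLike,
                     schedule_path: PathLike) -> None:
    pd.DataFrame({"time_s": t.times, "power_W": t.powers}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(t.injections,
                 columns=["injection", "time_s", "volume_L"]).to_csv(
        schedule_path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# TOML configuration
# ---------------------------------------------------------------------------

def load_toml(path: PathLike) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def protocol_from_dict(d: dict) -> TitrationProtocol:
    return TitrationProtocol(
        cell_volume=float(d["cell_volume"]),
        injection_volume=float(d["injection_volume"]),
        n_injections=int(d["n_injections"]),
        syringe_conc=float(d["syringe_conc"]),
        spacing=float(d.get("spacing", 300.0)),
        temperature=float(d.get("temperature", 298.15)),
    )


def model_from_dict(d: dict) -> MicellizationModel:
    slopes = d.get("baseline_slopes", (0.0, 0.0))
    return MicellizationModel(
        kind=d.get("kind", "mass_action"),
        cmc_true=float(d["cmc_true"]),
        dh_demic=float(d["dh_demic"]),
        agg_number=(int(d["agg_number"]) if "agg_number" in d else None),
        k_reduced=(float(d["k_reduced"]) if "k_reduced" in d else None),
        dilution_offset=float(d.get("dilution_offset", 0.0)),
        baseline_slopes=(float(slopes[0]), float(slopes[1])),
    )


def noise_from_dict(d: dict) -> NoiseSpec:
    return NoiseSpec(sigma_heat=float(d.get("sigma_heat", 0.0)),
                     seed=int(d.get("seed", 0)))


def read_simulation_config(path: PathLike):
    """(protocol, model, noise) from a TOML file with those three tables."""
    cfg = load_toml(path)
    for key in ("protocol", "model"):
        if key not in cfg:
            raise ValidationError(f"{path}: missing [{key}] table")
    return (protocol_from_dict(cfg["protocol"]),
            model_from_dict(cfg["model"]),
            noise_from_dict(cfg.get("noise", {})))
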