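"""Batch driver: salt × temperature study → consolidated tables.

A study is a list of conditions (e.g. "DPS water", "DPS NaClO4"), each
with one protocol, one micellization model (optionally a linear ΔH(T)
law via ``dcp``/``t_h``) or per-temperature input files, and a list of
temperatures.  The driver runs simulate/ingest → fit → thermodynamic
decomposition per (condition, temperature), a heat-capacity fit per
condition, and writes tidy CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import Enthalpogram
from .fitting import SigmoidFit, fit_sigmoid
from .io import (load_toml, model_from_dict, noise_from_dict,
                 protocol_from_dict, read_enthalpogram)
from .protocol import (MicellizationModel, NoiseSpec, TitrationProtocol,
                       ValidationError)
from .simulate import model_at_temperature, simulate_enthalpogram
from .thermo import (HeatCapacityResult, ThermoRecord, build_thermo_record,
                     heat_capacity)

log = logging.getLogger("itcmicelle.study")

THERMO_COLUMNS = ["condition", "T_K", "cmc_mol_per_L", "dG_J_per_mol",
                  "dH_mic_J_per_mol", "minus_TdS_J_per_mol",
                  "dS_J_per_mol_K"]
HEATCAP_COLUMNS = ["condition", "dCp_J_per_mol_K", "T_H_K",
                   "slope_stderr_J_per_mol_K", "n_points", "extrapolated"]


@dataclass
class ConditionSpec:
    """One experimental condition of a study."""

    label: str
    temperatures: List[float]
    protocol: Optional[TitrationProtocol] = None
    model: Optional[MicellizationModel] = None
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(0.0, 0))
    dcp: Optional[float] = None          # J mol⁻¹ K⁻¹, linear ΔH(T) law
    t_h: Optional[float] = None          # K, zero crossing of ΔH_mic
    inputs: Dict[float, str] = field(default_factory=dict)  # T -> csv path

    def __post_init__(self) -> None:
        if not self.temperatures:
            raise ValidationError(
                f"condition {self.label!r} has no temperatures")
        if not self.inputs and (self.protocol is None or self.model is None):
            raise ValidationError(
                f"condition {self.label!r} needs either input files or a "
                "protocol+model to simulate")


@dataclass
class StudyConfig:
    conditions: List[ConditionSpec]
    output_dir: Path
    plot: bool = False
    seed: int = 0
    c_std: float = 1.0

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValidationError("condition labels must be unique")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_toml(cls, path) -> "StudyConfig":
        cfg = load_toml(path)
        conditions = []
        for cd in cfg.get("condition", []):
            protocol = protocol_from_dict(cd["protocol"]) \
                if "protocol" in cd else None
            model = model_from_dict(cd["model"]) if "model" in cd else None
            inputs = {float(inp["temperature"]): inp["enthalpogram"]
                      for inp in cd.get("input", [])}
            conditions.append(ConditionSpec(
                label=cd["label"],
                temperatures=[float(t) for t in cd["temperatures"]],
                protocol=protocol, model=model,
                noise=noise_from_dict(cd.get("noise", {})),
                dcp=cd.get("dcp"), t_h=cd.get("t_h"),
                inputs=inputs))
        return cls(conditions=conditions,
                   output_dir=Path(cfg.get("output_dir", "itc_study_out")),
                   plot=bool(cfg.get("plot", False)),
                   seed=int(cfg.get("seed", 0)),
                   c_std=float(cfg.get("c_std", 1.0)))


@dataclass
class StudyReport:
    records: List[ThermoRecord]
    heat_capacities: Dict[str, HeatCapacityResult]
    fits: Dict[Tuple[str, float], SigmoidFit]
    enthalpograms: Dict[Tuple[str, float], Enthalpogram]
    failures: List[Tuple[str, float, str]]

    @property
    def ok(self) -> bool:
        return not self.failures

    def thermo_frame(self) -> pd.DataFrame:
        rows = [[r.condition_label, r.temperature, r.cmc, r.dg, r.dh_mic,
                 r.minus_tds, r.ds] for r in self.records]
        return pd.DataFrame(rows, columns=THERMO_COLUMNS)

    def heatcap_frame(self) -> pd.DataFrame:
        rows = [[label, hc.dcp, hc.t_h, hc.slope_stderr, hc.n_points,
                 hc.extrapolated]
                for label, hc in self.heat_capacities.items()]
        return pd.DataFrame(rows, columns=HEATCAP_COLUMNS)


def _condition_seed(base: int, ci: int, ti: int) -> int:
    """Stable per-(condition, temperature) seed below 2**31."""
    return int(np.random.SeedSequence([int(base), ci, ti])
               .generate_state(1)[0] % (2 ** 31))


def _obtain_enthalpogram(cond: ConditionSpec, temperature: float,
                         seed: int) -> Enthalpogram:
    if temperature in cond.inputs:
        return read_enthalpogram(cond.inputs[temperature], temperature,
                                 cond.label)
    model = cond.model
    if cond.dcp is not None and cond.t_h is not None:
        model = model_at_temperature(model, cond.dcp, cond.t_h, temperature)
    protocol = replace(cond.protocol, temperature=temperature)
    noise = NoiseSpec(cond.noise.sigma_heat, seed)
    return simulate_enthalpogram(protocol, model, noise,
                                 condition_label=cond.label)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline for every (condition, temperature).

    Failures (e.g. a non-converging fit) are isolated per condition and
    collected in ``report.failures``; the remaining conditions are
    unaffected.  Identical seeds give bit-identical outputs.
    """
    records: List[ThermoRecord] = []
    fits, enths, failures = {}, {}, []
    heat_caps: Dict[str, HeatCapacityResult] = {}
    for ci, cond in enumerate(config.conditions):
        series = []
        for ti, temp in enumerate(cond.temperatures):
            seed = _condition_seed(config.seed, ci, ti)
            try:
                e = _obtain_enthalpogram(cond, temp, seed)
                fit = fit_sigmoid(e, jitter_seed=seed)
                rec = build_thermo_record(cond.label, temp, fit.cmc,
                                          fit.dh_demic, config.c_std)
            except Exception as exc:
                log.warning("condition %r at %.2f K failed: %s",
                            cond.label, temp, exc)
                failures.append((cond.label, temp, str(exc)))
                continue
            log.debug("fit %r T=%.2f K: cmc=%.4g M dH=%.4g J/mol rss=%.3g",
                      cond.label, temp, fit.cmc, fit.dh_demic, fit.rss)
            records.append(rec)
            fits[(cond.label, temp)] = fit
            enths[(cond.label, temp)] = e
            series.append((temp, rec.dh_mic))
        if len(series) >= 2:
            heat_caps[cond.label] = heat_capacity(series)
    return StudyReport(records, heat_caps, fits, enths, failures)


def render_report(report: StudyReport, output_dir, plot: bool = False) -> List[Path]:
    """Write the consolidated study tables (and optional plots).

    Emits ``thermo_records.csv``, ``heat_capacity.csv`` and one fit JSON
    per (condition, temperature) under ``fits/``.  Returns the list of
    files written; rerunning on unchanged inputs reproduces identical
    bytes.
    """
    if not report.records:
        raise ValidationError("no records to report")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output dir {outdir} not writable: {exc}")

    written = []
    p = outdir / "thermo_records.csv"
    report.thermo_frame().to_csv(p, index=False, float_format="%.10g")
    written.append(p)
    p = outdir / "heat_capacity.csv"
    report.heatcap_frame().to_csv(p, index=False, float_format="%.10g")
    written.append(p)
    fitdir = outdir / "fits"
    fitdir.mkdir(exist_ok=True)
    for (label, temp), fit in sorted(report.fits.items()):
        safe = "".join(ch if ch.isalnum() else "_" for ch in label)
        p = fitdir / f"{safe}_{temp:.2f}K.json"
        p.write_text(json.dumps(fit.to_dict(), indent=1, sort_keys=True))
        written.append(p)
    if plot:
        from . import plots
        written += plots.plot_study(report, outdir)
    return written
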