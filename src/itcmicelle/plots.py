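"""Optional diagnostic plots (headless-safe, Agg backend)."""

from __future__ import annotations

from pathlib import Path
from typing import List

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_enthalpogram_fit(enthalpogram, fit, path) -> Path:
    """Points, fitted sigmoid, and the first-derivative curve."""
    from .fitting import sigmoid_derivative

    fig, (ax, axd) = plt.subplots(2, 1, sharex=True, figsize=(5, 6))
    c = enthalpogram.concentrations
    grid = np.linspace(c[0], c[-1], 400)
    ax.plot(c * 1e3, enthalpogram.heats / 1e3, "o", ms=4, label="data")
    ax.plot(grid * 1e3, fit(grid) / 1e3, "-", label="sigmoid fit")
    ax.axvline(fit.cmc * 1e3, ls=":", color="k")
    ax.set_ylabel("q (kJ mol$^{-1}$)")
    ax.legend(frameon=False)
    axd.plot(grid * 1e3, sigmoid_derivative(fit.params, grid), "-")
    axd.axvline(fit.cmc * 1e3, ls=":", color="k",
                label=f"CMC = {fit.cmc * 1e3:.2f} mM")
    axd.set_xlabel("[surfactant] (mM)")
    axd.set_ylabel("dq/dC")
    axd.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_decomposition_bars(records, path) -> Path:
    """ΔG°, ΔH°_mic and −TΔS° bar chart by condition."""
    labels = [f"{r.condition_label}\n{r.temperature:.0f} K" for r in records]
    x = np.arange(len(records))
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(records)), 4))
    w = 0.27
    ax.bar(x - w, [r.dg / 1e3 for r in records], w, label="ΔG°")
    ax.bar(x, [r.dh_mic / 1e3 for r in records], w, label="ΔH°")
    ax.bar(x + w, [r.minus_tds / 1e3 for r in records], w, label="−TΔS°")
    ax.set_xticks(x, labels, fontsize=7)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("kJ mol$^{-1}$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_study(report, outdir) -> List[Path]:
    outdir = Path(outdir)
    written = []
    for (label, temp), fit in sorted(report.fits.items()):
        safe = "".join(ch if ch.isalnum() else "_" for ch in label)
        p = outdir / f"fit_{safe}_{temp:.2f}K.png"
        written.append(
            plot_enthalpogram_fit(report.enthalpograms[(label, temp)],
                                  fit, p))
    if report.records:
        written.append(
            plot_decomposition_bars(report.records,
                                    outdir / "decomposition.png"))
    return written
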