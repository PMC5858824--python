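"""Optional diagnostic plots (sojourn densities, incidence fit, RR grid)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .duration import DurationSpec
from .incidence import IncidenceCurve, IncidencePoint, band_midpoints


def plot_duration_densities(specs: dict[str, DurationSpec], path: str | Path) -> Path:
    """Overlaid sojourn densities, one labelled line per spec."""
    t = np.linspace(0.01, 40.0, 600)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, spec in specs.items():
        ax.plot(t, spec.pdf(t), label=label)
    ax.set_xlabel("preclinical duration (years)")
    ax.set_ylabel("density (1/year)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_incidence_fit(
    points: list[IncidencePoint], curves: dict[str, IncidenceCurve], path: str | Path
) -> Path:
    """Registry band rates with the fitted continuous curves."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    markers = {"before": "s", "during": "o"}
    for period in ("before", "during"):
        sel = [p for p in points if p.period == period]
        if sel:
            ax.scatter(
                band_midpoints(sel), [p.rate for p in sel],
                marker=markers[period], s=18, label=f"{period} (points)",
            )
        if period in curves:
            age = np.linspace(0, 90, 400)
            ax.plot(age, curves[period].rate_per_100k(age), ls=":",
                    label=f"{period} (fit)")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("incidence per 100,000")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_rr_by_mode(long: pd.DataFrame, path: str | Path) -> Path:
    """Bias RR against duration mode, one line per sd (no-overdiagnosis rows)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    sel = long[(~long["overdiagnosis"]) & (long["status"] == "ok")]
    for sd, grp in sel.groupby("sd"):
        grp = grp.sort_values("mode")
        ax.plot(grp["mode"], grp["rr"], marker="o", label=f"sd = {sd}")
    ax.axhline(1.0, color="gray", lw=0.8)
    ax.set_xlabel("duration mode (years)")
    ax.set_ylabel("bias RR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
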