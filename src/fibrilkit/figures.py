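"""Quick-look figures for the three analysis stages (Agg backend, PNG out)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import afm, ftir, kinetics

__all__ = ["plot_kinetics", "plot_height_cdf", "plot_deconvolution"]


def plot_kinetics(
    replicate_sets: Mapping[str, kinetics.ReplicateSet],
    fits: Mapping[str, kinetics.SigmoidFit],
    path: str | Path,
) -> None:
    """Mean traces with error bars and fitted sigmoids, one panel for all."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, rset in replicate_sets.items():
        t = rset.mean_trace.times
        ax.errorbar(
            t,
            rset.mean_trace.intensities,
            yerr=rset.avg_dev_trace,
            fmt="o",
            ms=3,
            lw=0.8,
            alpha=0.6,
            label=label,
        )
        fit = fits.get(label)
        if fit is not None:
            tt = np.linspace(t[0], t[-1], 400)
            ax.plot(
                tt,
                kinetics.boltzmann_model(tt, fit.y1, fit.y2, fit.t_lag, fit.t_half),
                "-",
                lw=1.2,
            )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("ThT fluorescence (a.u.)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_height_cdf(
    distributions: Mapping[str, afm.HeightDistribution], path: str | Path
) -> None:
    """Cumulative per-object height distributions with z_90% markers."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, dist in distributions.items():
        ax.step(dist.heights, dist.cdf, where="post", label=label)
        z90 = afm.z_quantile(dist, 0.90)
        ax.axvline(z90, ls=":", lw=0.8, alpha=0.5)
    ax.axhline(0.9, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("object maximal height (nm)")
    ax.set_ylabel("cumulative fraction of objects")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_deconvolution(
    spectrum: ftir.Spectrum, model: ftir.PeakModel, path: str | Path
) -> None:
    """Preprocessed amide-I band, fitted envelope, and individual components."""
    fig, ax = plt.subplots(figsize=(7, 5))
    w = spectrum.wavenumbers
    ax.plot(w, spectrum.absorbance, "k.", ms=3, label="spectrum")
    ax.plot(w, model.evaluate(w), "r-", lw=1.2, label="fit")
    for comp in model.components:
        ax.fill_between(w, comp.evaluate(w), alpha=0.25)
    ax.set_xlabel(r"wavenumber (cm$^{-1}$)")
    ax.set_ylabel("absorbance (normalized)")
    ax.invert_xaxis()
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
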