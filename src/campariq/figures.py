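"""Publication-style figures: dose-response with CI band, amplitude CDF."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from campariq.photoconversion import DoseResponseFit


def dose_response_figure(
    doses: np.ndarray,
    median_rgrs: np.ndarray,
    fit: DoseResponseFit,
    path: str | Path,
) -> None:
    """Median RGR vs light dose with the zero-intercept fit and 95% CI band."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(doses, median_rgrs, "o", color="0.4", label="median RGR per recording")
    xs = np.linspace(0, float(np.max(doses)) * 1.05, 50)
    ax.plot(xs, fit.slope * xs, "k-", label=f"fit: slope {fit.slope:.2e}")
    ax.plot(xs, fit.ci95[0] * xs, "k--", lw=0.8)
    ax.plot(xs, fit.ci95[1] * xs, "k--", lw=0.8, label="95% CI")
    ax.set_xlabel("cumulative light dose (mJ/mm$^2$)")
    ax.set_ylabel("median RGR")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def amplitude_cdf_figure(summary: dict, path: str | Path) -> None:
    """Empirical CDF of per-cell peak response amplitudes (negative dips)."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.step(
        summary["peak_amplitude_cdf_x"],
        summary["peak_amplitude_cdf_y"],
        where="post",
        color="k",
    )
    ax.axvline(summary["median_peak_amplitude"], color="0.6", ls="--", lw=0.8)
    ax.set_xlabel(r"peak response amplitude ($\Delta$F/F$_0$)")
    ax.set_ylabel("cumulative fraction of cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
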