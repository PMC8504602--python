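"""Report figures: gamma maps, dose maps, and central profiles."""

from __future__ import annotations

import numpy as np

from .verification import VerificationReport


def plot_verification(report: VerificationReport, path=None):
    """Two-row summary figure for a verification report.

    Top row: reference (resampled measurement), calculated composite,
    and the gamma map of the first criterion; bottom row: central x and
    y profiles of both distributions.  Returns the figure; saves it when
    ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref, calc = report.reference, report.calculated
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    extent_ref = [ref.x_mm[0], ref.x_mm[-1], ref.y_mm[0], ref.y_mm[-1]]
    extent_calc = [calc.x_mm[0], calc.x_mm[-1], calc.y_mm[0], calc.y_mm[-1]]

    im = axes[0, 0].imshow(ref.values.T, origin="lower", extent=extent_ref)
    axes[0, 0].set_title("measured (resampled)")
    fig.colorbar(im, ax=axes[0, 0], label="Gy")
    im = axes[0, 1].imshow(calc.values.T, origin="lower", extent=extent_calc)
    axes[0, 1].set_title("calculated" + (" (corrected)" if report.corrected else " (uncorrected)"))
    fig.colorbar(im, ax=axes[0, 1], label="Gy")

    label, gamma = next(iter(report.gamma_results.items()))
    im = axes[0, 2].imshow(
        np.ma.masked_invalid(gamma.gamma).T, origin="lower", extent=extent_ref,
        vmin=0.0, vmax=2.0, cmap="coolwarm",
    )
    axes[0, 2].set_title(f"gamma {label}: {gamma.passing_rate_pct:.1f}% pass")
    fig.colorbar(im, ax=axes[0, 2], label="gamma")

    for col, axis in enumerate(("x", "y")):
        ax = axes[1, col]
        c_ref, v_ref = report.profiles[f"ref_{axis}"]
        c_cal, v_cal = report.profiles[f"calc_{axis}"]
        ax.plot(c_ref, v_ref, ".", ms=3, label="measured")
        ax.plot(c_cal, v_cal, "-", lw=1, label="calculated")
        ax.set_xlabel(f"{axis} (mm)")
        ax.set_ylabel("dose (Gy)")
        ax.legend()
    axes[1, 2].axis("off")
    axes[1, 2].text(0.05, 0.6, f"plan: {report.plan_label}\n"
                    + "\n".join(f"{k}: {v:.2f}%" for k, v in sorted(report.passing_rates.items())),
                    transform=axes[1, 2].transAxes)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
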