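"""Optional plotting helpers (requires matplotlib)."""

from __future__ import annotations

from .stability import MidpointResult, SpectrumSeries, centroid_curve


def plot_midpoint(series: SpectrumSeries, result: MidpointResult, path) -> None:
    """Centroid curve with its first derivative and the located midpoint."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = centroid_curve(series)
    unit = "°C" if series.axis_kind == "temperature_C" else "M"
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax1.plot(curve.axis_values, curve.centroid, "o-")
    ax1.set_ylabel("spectral centroid (nm)")
    ax2.plot(result.derivative_axis, result.derivative, "s-")
    ax2.axvline(result.midpoint, color="crimson", ls="--",
                label=f"{result.label} = {result.midpoint:.2f} {unit}")
    ax2.set_xlabel(f"axis ({unit})")
    ax2.set_ylabel("d centroid / d axis")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
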