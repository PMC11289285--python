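"""Small static figure helpers (polar tuning plots, tuning-curve fits)."""

from __future__ import annotations

import numpy as np

from .tuning import TuningResult
from .vonmises import TuningCurve, VonMisesFit, von_mises_profile


def polar_tuning(result: TuningResult, neuron: int, ax=None):
    """Polar plot of one cell's occupancy-normalised rate map.

    The arrow marks the mean resultant; its length relative to the outer
    ring is the tuning index.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    rates = result.bin_rates[neuron]
    theta = np.append(result.bin_angles, result.bin_angles[0])
    r = np.append(rates, rates[0])
    ax.plot(theta, r, lw=1.0)
    vec = result.vector[neuron]
    rmax = rates.max() if rates.max() > 0 else 1.0
    ax.annotate("", xy=(np.angle(vec), np.abs(vec) * rmax), xytext=(0, 0),
                arrowprops={"arrowstyle": "->", "color": "crimson"})
    ax.set_title(f"neuron {neuron}  index={result.index[neuron]:.2f}")
    return ax


def tuning_curve_fit(curve: TuningCurve, fit: VonMisesFit, ax=None):
    """Across-lap mean tuning curve with the fitted von Mises overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.bin_angles, curve.mean, "o", label="data")
    grid = np.linspace(0, 2 * np.pi, 200)
    ax.plot(grid, von_mises_profile(grid, fit.B, fit.A, fit.kappa, fit.phi),
            label=f"fit  R$^2$={fit.r2_cv:.2f}")
    ax.set_xlabel("belt angle (rad)")
    ax.set_ylabel(r"$\Delta$F/F")
    ax.legend(frameon=False)
    return ax
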