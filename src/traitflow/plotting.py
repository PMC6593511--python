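"""Optional matplotlib views of sampling curves and fits."""

from __future__ import annotations

from .curves import CurveFit, SamplingCurve

import numpy as np


def plot_sampling_curve(curve: SamplingCurve, fit: CurveFit | None = None, ax=None):
    """Scatter the subset values ("circles"), overlay means and the fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for n, vals in sorted(curve.points.items()):
        ax.plot([n] * len(vals), vals, "o", mfc="none", color="0.6", ms=3)
    ns, ys = curve.arrays()
    ax.plot(ns, ys, "s", color="k", label="mean")
    if fit is not None:
        grid = np.linspace(ns.min(), ns.max(), 200)
        ax.plot(grid, fit.predict(grid), "-", color="C3",
                label=f"{fit.model} fit (r$^2$={fit.r2:.2f})")
    ax.set_xlabel("number of genomes (n)")
    ax.set_ylabel({"core": "core genes", "specific": "new genes per genome",
                   "pan": "pan-genome size"}[curve.kind])
    ax.legend()
    return ax
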