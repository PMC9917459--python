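"""Diagnostic figures: per-ROI amplitude histograms with fitted mixtures."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .quantal import QuantalFit, _predicted_counts, build_histograms  # noqa: E402


def plot_roi_fit(
    amplitudes_by_condition: dict[str, np.ndarray],
    fit: QuantalFit,
    path: str | Path,
    bin_width: float | None = None,
) -> Path:
    """Histogram per condition with the fitted mixed-Gaussian overlay.

    One panel per calcium condition plus the pooled histogram; the model
    curve is the predicted bin occupancy at the fitted parameters (the
    failure point mass shows as the first bin).
    """
    conditions = list(amplitudes_by_condition)
    if bin_width is None:
        bin_width = max(fit.q / 3.0, 0.01) if np.isfinite(fit.q) else 0.02
    counts, pooled, edges = build_histograms(amplitudes_by_condition,
                                             bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    n_panels = len(conditions) + 1
    fig, axes = plt.subplots(1, n_panels, figsize=(3.2 * n_panels, 2.8),
                             sharex=True, sharey=False)
    axes = np.atleast_1d(axes)
    for ax, cond in zip(axes, conditions):
        ax.bar(centres, counts[cond], width=bin_width * 0.9,
               color="0.75", label="data")
        param = (fit.p_release.get(cond) if fit.model == "binomial"
                 else fit.lambda_rate.get(cond))
        if param is not None and np.isfinite(fit.q):
            pred = _predicted_counts(edges, fit.model, fit.n_sites, param,
                                     fit.q, fit.sigma_component, fit.scale)
            ax.step(edges[:-1], pred, where="post", color="C3",
                    label=fit.model)
        ks = fit.ks_p.get(cond)
        title = f"{cond} mM Ca"
        if ks is not None:
            title += f"  (K-S p={ks:.2f})"
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("peak dF/F")
    axes[0].set_ylabel("responses")
    axes[-1].bar(centres, pooled, width=bin_width * 0.9, color="#d4b106")
    axes[-1].set_title(f"pooled ({int(pooled.sum())} responses)", fontsize=9)
    axes[-1].set_xlabel("peak dF/F")
    fig.suptitle(
        f"{fit.model} fit: q={fit.q:.3f}, N={fit.n_sites}", fontsize=10)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
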