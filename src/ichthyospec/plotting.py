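"""Diagnostic plots: regression panel and per-bin density fits."""

from __future__ import annotations

import numpy as np


def plot_regression(result, pairs, path=None, ax=None):
    """Binned IAR vs temperature with the quadratic mean and 95% CI band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        pairs["temp_mean"], pairs["iar_mean"],
        xerr=pairs["temp_sd"], yerr=pairs["iar_sd"],
        fmt="o", color="k", ms=4, lw=0.8, capsize=0,
    )
    band = result.ci_band
    ax.plot(band["temp"], band["mean"], "k-")
    ax.plot(band["temp"], band["lo"], "k--", lw=0.8)
    ax.plot(band["temp"], band["hi"], "k--", lw=0.8)
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("IAR (ichthyoliths / cm$^2$ / Myr)")
    ax.set_title(f"$R^2$ = {result.r_squared:.2f}, F p = {result.p_value:.3g} (n = {result.n})")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_density_fits(model, reference, time_varying=None, path=None, max_panels=16):
    """Observed per-bin tooth densities with reference and time-varying fits."""
    import matplotlib.pyplot as plt

    B = min(len(model.observed), max_panels)
    ncol = 4
    nrow = int(np.ceil(B / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), sharex=True, sharey=True)
    axes = np.atleast_1d(axes).ravel()
    x = model.tooth_axis.bin_centers
    ref_density = model.predict_density(reference.params).density
    for b in range(B):
        ax = axes[b]
        ax.plot(x, model.F[b], "k--", lw=1, label="observed")
        ax.plot(x, ref_density, color="0.6", lw=1, label="reference")
        if time_varying is not None:
            r = time_varying
            if r.parameter_name == "total_pp":
                d = model.predict_density(reference.params, pp_multiplier=r.trajectory[b]).density
            else:
                d = model.predict_density(reference.params.replace(**{r.parameter_name: r.trajectory[b]})).density
            ax.plot(x, d, "C1-", lw=1, label=r.parameter_name)
        ax.set_xscale("log")
        ax.set_title(f"{model.bin_centers[b]:.1f} Ma", fontsize=8)
    for ax in axes[B:]:
        ax.set_visible(False)
    axes[0].legend(fontsize=7)
    fig.supxlabel("tooth length (um)")
    fig.supylabel("density (per um)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
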