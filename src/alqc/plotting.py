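"""Optional matplotlib renderings: score plots, acceptance plots, profiles.

All functions return the Figure; callers decide whether to save or show.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _new_axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=(6, 5))


def score_plot(scores: np.ndarray, meta: pd.DataFrame, pcs=(1, 2), ellipse=None, title=""):
    """PC score plot coloured by product, with an optional confidence ellipse."""
    fig, ax = _new_axes()
    i, j = pcs[0] - 1, pcs[1] - 1
    labels = meta["brand"].astype(str) + " (" + meta["channel"].astype(str) + ")"
    for label in labels.unique():
        sel = (labels == label).to_numpy()
        ax.scatter(scores[sel, i], scores[sel, j], s=18, label=label)
    if ellipse is not None:
        b = ellipse.boundary()
        ax.plot(b[:, 0], b[:, 1], "k--", lw=1, label=f"{ellipse.gamma:.0%} ellipse")
    ax.set_xlabel(f"PC{pcs[0]}")
    ax.set_ylabel(f"PC{pcs[1]}")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def acceptance_plot(model, records: pd.DataFrame, title=""):
    """DD-SIMCA distance plot ln(1+h/h0) vs ln(1+v/v0) with the boundary."""
    from .ddsimca import acceptance_boundary

    fig, ax = _new_axes()
    accepted = records["accepted"].to_numpy()
    ax.scatter(records.loc[accepted, "plot_x"], records.loc[accepted, "plot_y"],
               s=18, c="tab:green", label="accepted")
    ax.scatter(records.loc[~accepted, "plot_x"], records.loc[~accepted, "plot_y"],
               s=18, c="tab:red", label="rejected")
    b = acceptance_boundary(model)
    ax.plot(b[:, 0], b[:, 1], "k-", lw=1.2, label="acceptance boundary")
    ax.set_xlabel("ln(1 + h/h0)")
    ax.set_ylabel("ln(1 + v/v0)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def accuracy_profile_plot(profile, title=""):
    """Tolerance intervals and bias per level against the acceptance limits."""
    fig, ax = _new_axes()
    conc = [s.mu_T for s in profile.levels]
    bias = [s.relative_bias_pct for s in profile.levels]
    low = [s.tolerance_low_pct for s in profile.levels]
    high = [s.tolerance_high_pct for s in profile.levels]
    lim = profile.acceptance_limit_pct
    ax.plot(conc, bias, "o-", label="relative bias")
    ax.plot(conc, low, "v--", c="tab:blue", label="tolerance limits")
    ax.plot(conc, high, "^--", c="tab:blue")
    ax.axhline(lim, color="r", ls=":", label=f"acceptance ±{lim:g}%")
    ax.axhline(-lim, color="r", ls=":")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("concentration (mg/mL)")
    ax.set_ylabel("relative error (%)")
    ax.set_title(title or profile.compound)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def nemi_plot(profile, title="NEMI"):
    """Four-quadrant NEMI pictogram."""
    import matplotlib.patches as mpatches

    fig, ax = _new_axes()
    quads = [
        ("PBT", profile.pbt_green, 90, 180),
        ("Hazardous", profile.hazardous_green, 0, 90),
        ("Corrosive", profile.corrosive_green, 180, 270),
        ("Waste", profile.waste_green, 270, 360),
    ]
    for name, green, a0, a1 in quads:
        wedge = mpatches.Wedge((0, 0), 1.0, a0, a1,
                               facecolor="tab:green" if green else "white",
                               edgecolor="k")
        ax.add_patch(wedge)
        mid = np.deg2rad((a0 + a1) / 2)
        ax.text(0.55 * np.cos(mid), 0.55 * np.sin(mid), name,
                ha="center", va="center", fontsize=9)
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.tight_layout()
    return fig
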