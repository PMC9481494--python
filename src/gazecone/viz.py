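"""Optional per-participant fitted-curve figure (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .io import ResponseCountTable
from .psychometric import JointFitParams, find_crossings, predict_proportions


def plot_participant_fit(table: ResponseCountTable, params: JointFitParams, ax=None):
    """Observed response proportions with the fitted three-category curves.

    Dashed verticals mark the left/right crossings with the middle curve;
    the span between them is the cone width.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    props = table.proportions()
    grid = np.linspace(-50, 50, 401)
    pL, pM, pR = predict_proportions(params, grid)
    for curve, color, label in ((pL, "tab:blue", "left"),
                                (pM, "tab:gray", "middle"),
                                (pR, "tab:red", "right")):
        ax.plot(grid, curve, color=color, label=label)
    ax.plot(props["azimuth_deg"], props["p_left"], "o", color="tab:blue", ms=4)
    ax.plot(props["azimuth_deg"], props["p_middle"], "o", color="tab:gray", ms=4)
    ax.plot(props["azimuth_deg"], props["p_right"], "o", color="tab:red", ms=4)
    cone = find_crossings(params)
    if cone.status == "ok":
        ax.axvline(cone.x_left_cross, ls="--", color="k", lw=0.8)
        ax.axvline(cone.x_right_cross, ls="--", color="k", lw=0.8)
        ax.set_title(f"{table.participant_id} / {table.condition}: "
                     f"cone width {cone.width:.1f}\N{DEGREE SIGN}")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("response proportion")
    ax.legend(frameon=False)
    return ax
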