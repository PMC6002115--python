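"""Human-readable report tables and simple summary figures.

Tables round to one decimal; the CSV outputs of the pipeline keep full
precision.  Plotting is intentionally minimal: per-subject psychometric
curves and the group weight-vs-vibration figure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .integration import round_half_away

__all__ = ["summary_table", "plot_psychometric", "plot_weights"]


def summary_table(summary: dict) -> str:
    """Render the group summary dict as an aligned plain-text table."""
    lines = ["Group summary", "============="]
    order = [
        ("n_subjects", "subjects"),
        ("n_trials", "trials"),
        ("separation_deg", "visual-inertial PSE separation (deg)"),
        ("mean_sigma_inertial_no_vibration", "inertial sigma, no vibration (deg)"),
        ("mean_sigma_inertial_vibration", "inertial sigma, with vibration (deg)"),
        ("mean_w_I_opt_no_vibration", "mean optimal w_I, no vibration"),
        ("mean_w_I_emp_no_vibration", "mean empirical w_I, no vibration"),
        ("mean_w_I_opt_vibration", "mean optimal w_I, vibration"),
        ("mean_w_I_emp_vibration", "mean empirical w_I, vibration"),
    ]
    for key, label in order:
        val = summary.get(key)
        if val is None:
            continue
        if isinstance(val, float):
            val = round_half_away(val, 1) if abs(val) >= 1 else round(val, 2)
        lines.append(f"{label:<40s} {val}")
    gaze_bias = summary.get("gaze_bias")
    if gaze_bias:
        for modality, bias in sorted(gaze_bias.items()):
            direction = "opposite gaze" if bias > 0 else "toward gaze"
            lines.append(
                f"{modality + ' bias re gaze (deg)':<40s} {bias} ({direction})"
            )
    return "\n".join(lines)


def summary_to_frame(summary: dict) -> pd.DataFrame:
    """Flatten the summary dict to a two-column DataFrame for CSV export."""
    rows = []
    for key, val in summary.items():
        if isinstance(val, dict):
            for sub, v in val.items():
                rows.append({"statistic": f"{key}.{sub}", "value": v})
        else:
            rows.append({"statistic": key, "value": val})
    return pd.DataFrame(rows)


def plot_psychometric(results, ax=None, label=None):
    """Plot one fitted psychometric function with binned response rates.

    ``results`` is a :class:`~headingcues.psychometric.PsychometricResults`.
    Marker area scales with the number of presentations at each heading.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = results.model
    h, inv = np.unique(m.headings, return_inverse=True)
    n = np.bincount(inv)
    k = np.bincount(inv, weights=m.responses)
    ax.scatter(h, k / n, s=20 * n, alpha=0.6, edgecolor="k", linewidth=0.5)
    grid = np.linspace(h.min() - 5, h.max() + 5, 200)
    ax.plot(grid, results.predict(grid), label=label)
    ax.axhline(0.5, color="gray", lw=0.5, ls=":")
    ax.axvline(results.mu, color="gray", lw=0.5, ls=":")
    ax.set_xlabel("heading (deg, + = right)")
    ax.set_ylabel("P(respond right)")
    return ax


def plot_weights(weights: pd.DataFrame, ax=None):
    """Group mean optimal vs empirical inertial weight by vibration amplitude."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grp = weights.groupby("vibration_amplitude")[["w_I_opt", "w_I_emp"]].mean()
    ax.plot(grp.index, grp["w_I_emp"], "o-", label="empirical $w_I$")
    ax.plot(grp.index, grp["w_I_opt"], "s--", label="optimal $w_I$")
    ax.set_xlabel("vibration amplitude (cm, peak-to-peak)")
    ax.set_ylabel("inertial weight")
    ax.set_ylim(-0.05, 1.15)
    ax.legend()
    return ax
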