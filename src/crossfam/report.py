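"""Tabular and graphical activity reports.

Reporting follows the field's display conventions for amplicon editing
screens: on-target and off-target sites are visually distinguished, values
below a display floor are shown as an asterisk (0.3% for on-target views,
0.01% for off-target views), and off-target panels carry dashed reference
lines at 0.1% (the standard off-target benchmark) and 1%.  The CSV always
keeps full-precision values; the floors only affect the display column and
plots.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .activity import ActivityEstimate, activity_frame
from .config import ConfigTable

ON_TARGET_FLOOR = 0.003    # 0.3%
OFF_TARGET_FLOOR = 0.0001  # 0.01%
REFERENCE_LINES = (0.001, 0.01)  # 0.1% and 1%


def _display(rate: float, role: str) -> str:
    floor = ON_TARGET_FLOOR if role == "on_target" else OFF_TARGET_FLOOR
    if rate != rate:
        return "NA"
    if rate < floor:
        return "*"
    return f"{100 * rate:.3f}%"


def report_table(estimates: list[ActivityEstimate] | pd.DataFrame,
                 config: ConfigTable) -> pd.DataFrame:
    """Per-site, per-sample report with role annotation and display column."""
    roles = {row.site_name: row.role for row in config.rows}
    frame = estimates.copy() if isinstance(estimates, pd.DataFrame) else activity_frame(estimates)
    if "role" in frame.columns:
        frame = frame.drop(columns=["role"])
    frame.insert(2, "role", frame["site_name"].map(roles))
    frame["rate_pct"] = 100 * frame["rate"]
    frame["display"] = [
        _display(r, role) for r, role in zip(frame["rate"], frame["role"])
    ]
    return frame


def write_report(estimates: list[ActivityEstimate], config: ConfigTable,
                 path: str | Path) -> pd.DataFrame:
    frame = report_table(estimates, config)
    frame.to_csv(path, index=False, float_format="%.8g")
    return frame


def plot_activity(
    estimates: list[ActivityEstimate],
    config: ConfigTable,
    path: str | Path,
    corrected: bool = False,
) -> None:
    """Grouped bar chart of per-site activity with 0.95 CIs.

    Solid bars are on-target sites, hatched bars off-target sites; dashed
    horizontal lines mark 0.1% and 1%; sub-floor values are drawn as an
    asterisk at the floor.  Headless-safe (Agg backend).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = report_table(estimates, config)
    frame = frame[frame["sample"] != "mock"] if (frame["sample"] == "mock").any() else frame
    sites = [r.site_name for r in config.rows]
    samples = list(dict.fromkeys(frame["sample"]))
    roles = {r.site_name: r.role for r in config.rows}

    col = "corrected_rate" if corrected else "rate"
    lo_col = "corrected_ci_low" if corrected else "ci_low"
    hi_col = "corrected_ci_high" if corrected else "ci_high"

    fig, ax = plt.subplots(figsize=(1.2 + 1.2 * len(sites), 4))
    width = 0.8 / max(len(samples), 1)
    cmap = plt.get_cmap("tab10")
    for si, sample in enumerate(samples):
        sub = frame[frame["sample"] == sample].set_index("site_name")
        xs, ys, errs = [], [], []
        for xi, site in enumerate(sites):
            if site not in sub.index:
                continue
            row = sub.loc[site]
            rate = row[col]
            floor = ON_TARGET_FLOOR if roles[site] == "on_target" else OFF_TARGET_FLOOR
            x = xi + (si - (len(samples) - 1) / 2) * width
            if rate == rate and rate >= floor:
                xs.append(x)
                ys.append(100 * rate)
                errs.append((100 * max(rate - row[lo_col], 0), 100 * max(row[hi_col] - rate, 0)))
            else:
                ax.text(x, 100 * floor, "*", ha="center", va="bottom", fontsize=12)
        if xs:
            err_arr = list(zip(*errs))
            hatches = ["" if roles[s] == "on_target" else "//" for s in sites if s in sub.index]
            bars = ax.bar(xs, ys, width=width, color=cmap(si % 10),
                          yerr=err_arr, capsize=2, label=sample)
            for bar, site in zip(bars, [s for s in sites if s in sub.index]):
                if roles[site] != "on_target":
                    bar.set_hatch("//")
    for ref in REFERENCE_LINES:
        ax.axhline(100 * ref, linestyle="--", color="grey", linewidth=0.8)
    ax.set_yscale("log")
    ax.set_xticks(range(len(sites)))
    ax.set_xticklabels(sites, rotation=45, ha="right")
    ax.set_ylabel("editing activity (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
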