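"""Per-species diagnostic plots (raw banding points, fitted cohort
curves, detected autumn window)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .cohort import CohortTimingResults  # noqa: E402


def plot_cohort_diagnostic(records: pd.DataFrame, result: CohortTimingResults,
                           path: str | Path) -> None:
    """Latitude-by-day scatter per age class with fitted curves and the
    autumn window shaded; mirrors the standard banding-phenology panel."""
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {"HY": "tab:orange", "AHY": "tab:blue"}
    for age, grp in records.groupby("age_class"):
        ax.scatter(grp["julian_day"], grp["latitude"], s=4, alpha=0.25,
                   color=colors.get(age, "gray"), label=f"{age} (n={len(grp)})")
    if result.curves:
        for age, curve in result.curves.items():
            ax.plot(curve.days, curve.values, color=colors.get(age, "k"), lw=2)
    if result.window:
        ax.axvspan(*result.window, color="0.85", zorder=0)
    title = f"{result.species}: {result.classification}"
    if result.overlap_index is not None:
        title += f" (overlap {result.overlap_index:.2f})"
    ax.set(xlabel="Julian day", ylabel="latitude (deg N)", title=title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
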