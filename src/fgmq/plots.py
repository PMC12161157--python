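"""Small plotting helpers for the two diagnostic figures.

These mirror the pipeline's figure-data tables: the age profile of missing
age-at-FGM shares by module (where the self-/proxy-report jump between ages
14 and 15 is visible) and the age-at-FGM histogram whose spikes at 5, 10
and 15 show heaping.  Styling is deliberately plain.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_missingness_profile(profile, path) -> str:
    """Share of missing age at FGM by current age, one line per module."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for module, sub in profile.groupby("module"):
        sub = sub.sort_values("current_age")
        ax.plot(sub["current_age"], sub["share_missing_age"], marker="o",
                markersize=3, label=module)
    ax.set_xlabel("current age (years)")
    ax.set_ylabel("share with missing age at FGM")
    ax.legend(title="module")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_age_structure(age_counts, path) -> str:
    """Weighted age-at-FGM distribution per module (heaping shows as spikes)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for module, sub in age_counts.groupby("module"):
        agg = sub.groupby("age")["count"].sum()
        ax.step(agg.index, agg.values, where="mid", label=module)
    ax.set_xlabel("age at FGM (years)")
    ax.set_ylabel("weighted count")
    ax.legend(title="module")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
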