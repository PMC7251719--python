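"""Optional figures: incidence overlays, stacked exit-path bars, overdiagnosis by age."""

from __future__ import annotations

import numpy as np

from . import states as st


def plot_incidence_overlay(projected, observed, diagnosis=st.DIAG_DCIS, ax=None):
    """Projected vs observed age-adjusted incidence per calendar year."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    est = projected.age_adjusted_rate(diagnosis)
    obs = observed.age_adjusted_rate(diagnosis)
    ax.plot(est.index, est.values, label="projected")
    ax.plot(obs.index, obs.values, "o", ms=3, label="observed")
    ax.set_xlabel("calendar year")
    ax.set_ylabel(f"{diagnosis} age-adjusted rate per 100,000")
    ax.legend()
    return ax


def plot_progression_bars(proportions, ax=None):
    """Stacked P1/P2/P3 bars by age at entry."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(proportions))
    bottom = np.zeros(len(proportions))
    for path, color in zip(st.PATHS, ("tab:blue", "tab:red", "tab:green")):
        vals = proportions[path].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=path, color=color)
        bottom += vals
    ax.set_xticks(x, proportions["entry_age_group"])
    ax.set_ylabel("proportion of resolved exits")
    ax.legend()
    return ax


def plot_overdiagnosis_by_age(report, diagnosis=st.DIAG_DCIS, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = report.by_age_group
    df = df[df["diagnosis"] == diagnosis]
    ax.plot(df["age_group"], df["percentage"], marker="o")
    ax.set_xlabel("age group at detection")
    ax.set_ylabel(f"{diagnosis} overdiagnosis (%)")
    return ax
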