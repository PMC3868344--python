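"""Basic trace plots: ensemble means with 95% simulation envelopes."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .engine import EnsembleResult

__all__ = ["plot_ensemble"]


def plot_ensemble(ensemble: EnsembleResult, path=None):
    """Four-panel overview: reward components, cognitive weights, mood,
    daily intakes + abstinence index."""
    fig, axes = plt.subplots(4, 1, figsize=(9, 11), sharex=False)

    hours = ensemble.hourly_mean.index / 24.0
    for name, color in (("T0", "tab:red"), ("TS", "tab:blue")):
        axes[0].plot(hours, ensemble.hourly_mean[name], color=color, label=name)
        axes[0].fill_between(
            hours, ensemble.hourly_low[name], ensemble.hourly_high[name],
            color=color, alpha=0.2, linewidth=0,
        )
    minutes_d = ensemble.minute_mean.index / 1440.0
    axes[0].plot(minutes_d, ensemble.minute_mean["T"], color="tab:green", label="T")
    axes[0].set_ylabel("reward components")
    axes[0].legend(loc="upper left", fontsize=8)

    for name, color in (
        ("omega_s", "tab:orange"), ("omega_p", "tab:green"), ("omega_d", "tab:purple"),
    ):
        axes[1].plot(hours, ensemble.hourly_mean[name], color=color, label=name)
        axes[1].fill_between(
            hours, ensemble.hourly_low[name], ensemble.hourly_high[name],
            color=color, alpha=0.2, linewidth=0,
        )
    axes[1].set_ylabel("cognitive weights")
    axes[1].legend(loc="upper left", fontsize=8)

    axes[2].plot(minutes_d, ensemble.minute_mean["M"], color="k", lw=0.6)
    axes[2].fill_between(
        minutes_d, ensemble.minute_low["M"], ensemble.minute_high["M"],
        color="gray", alpha=0.3, linewidth=0,
    )
    axes[2].set_ylabel("mood M")

    days = range(ensemble.n_days)
    axes[3].plot(days, ensemble.daily_intakes.mean(axis=0), color="tab:blue",
                 label="mean intakes/day")
    axes[3].plot(days, ensemble.abstinence_index, color="tab:green",
                 label="abstinence index (%)")
    axes[3].set_xlabel("day")
    axes[3].legend(loc="upper left", fontsize=8)

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
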