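"""Plotting helpers for fitted models and cardiac traces."""

from __future__ import annotations

import numpy as np


def plot_coefficients(results, mass: float = 0.95, ax=None):
    """Forest plot: point estimates with HDI whiskers, one row per coefficient."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(results.params) + 1))
    names = list(results.params.index)
    y = np.arange(len(names))[::-1]
    est = results.params.to_numpy()
    if results.samples is not None:
        h = results.hdi(mass)
        ax.errorbar(
            est, y,
            xerr=np.vstack([est - h["lower"], h["upper"] - est]),
            fmt="o", color="k", ecolor="gray", capsize=3,
        )
    else:
        ax.plot(est, y, "ko")
    ax.axvline(0.0, color="r", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(names)
    ax.set_xlabel("coefficient (standardized scale)")
    ax.set_title(f"{results.model_name} ({results.kind}, {int(mass * 100)}% HDI)")
    return ax


def plot_trial_trace(beat_times, onset: float, ax=None):
    """Beat-stamped BPM around one trial with the baseline and Dhr windows."""
    import matplotlib.pyplot as plt

    from .cardiac import ibi_to_bpm

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    times, bpm = ibi_to_bpm(beat_times)
    ax.plot(np.asarray(times) - onset, bpm, "o-", ms=3)
    ax.axvspan(-1.0, 0.0, alpha=0.2, color="gray", label="baseline")
    ax.axvspan(5.0, 7.0, alpha=0.2, color="tab:blue", label="Dhr window")
    ax.set_xlabel("time from anticipation onset (s)")
    ax.set_ylabel("BPM")
    ax.legend(frameon=False)
    return ax
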