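"""Static figure export for traces and characteristic curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

__all__ = ["plot_traces", "plot_curve"]


def plot_traces(traces, ax=None, title=None):
    """Overlay current traces for all step potentials."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for tr in traces:
        ax.plot(tr.t, tr.I, lw=0.8, label=f"{tr.v_step:+.0f} mV")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("current density (pA/pF)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, ncol=2, frameon=False)
    return ax


def plot_curve(df, ycol, ax=None, label=None, ylabel=None):
    """Plot a characteristic curve (I-V, tau-V or SSI) from its DataFrame."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xcol = "v_step_mv" if "v_step_mv" in df.columns else "v_mv"
    ax.plot(df[xcol], df[ycol], "o-", label=label)
    ax.set_xlabel("step potential (mV)")
    ax.set_ylabel(ylabel or ycol)
    if label:
        ax.legend(frameon=False)
    return ax
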