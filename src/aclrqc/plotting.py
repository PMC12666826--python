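"""Diagnostic trace plots (load & displacement vs time with event markers)."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .metrics import PhaseSegmentation, RuptureEvent
from .trace_io import Trace

__all__ = ["plot_trace"]


def plot_trace(
    trace: Trace,
    seg: Optional[PhaseSegmentation] = None,
    event: Optional[RuptureEvent] = None,
    title: Optional[str] = None,
):
    """Two-panel QC plot: load vs time (top), displacement vs time (bottom).

    Phase boundaries are drawn as vertical lines and the rupture point, if
    given, is annotated on the load panel.  Returns the Figure.
    """
    fig, (ax_load, ax_disp) = plt.subplots(
        2, 1, sharex=True, figsize=(8, 5), constrained_layout=True
    )
    ax_load.plot(trace.time, trace.load, lw=0.8, color="tab:blue")
    ax_load.set_ylabel("load (N)")
    ax_disp.plot(trace.time, trace.displacement, lw=0.8, color="tab:orange")
    ax_disp.set_ylabel("displacement (mm)")
    ax_disp.set_xlabel("time (s)")
    if seg is not None:
        for start, _ in seg.intervals:
            for ax in (ax_load, ax_disp):
                ax.axvline(trace.time[min(start, trace.n_samples - 1)],
                           color="grey", lw=0.5, ls=":")
    if event is not None:
        t_ev = trace.time[event.index]
        ax_load.plot([t_ev], [event.load_at_rupture], "rv", ms=7)
        ax_load.annotate(
            f"rupture\n{event.load_at_rupture:.1f} N @ "
            f"{event.displacement_at_rupture:.2f} mm",
            xy=(t_ev, event.load_at_rupture),
            xytext=(8, 8),
            textcoords="offset points",
            fontsize=8,
            color="red",
        )
    if title:
        ax_load.set_title(title)
    return fig
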