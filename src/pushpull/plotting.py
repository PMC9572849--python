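"""Quick-look plots of simulated or recorded sessions."""

from __future__ import annotations

from .signals import force_magnitude

__all__ = ["plot_session_forces"]


def plot_session_forces(recording, ax=None, show_events: bool = True):
    """Plot both resultant-force magnitudes with waypoint-event markers.

    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    t = recording.time
    f_r = force_magnitude(
        recording.force["fxR"], recording.force["fyR"], recording.force["fzR"]
    )
    f_l = force_magnitude(
        recording.force["fxL"], recording.force["fyL"], recording.force["fzL"]
    )
    ax.plot(t, f_r, lw=0.6, label="F right")
    ax.plot(t, f_l, lw=0.6, label="F left")
    if show_events:
        for _, row in recording.events.iterrows():
            ax.axvline(row["time"], color="0.8", lw=0.4, zorder=0)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("resultant force [force units]")
    ax.legend(loc="upper right")
    return ax
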