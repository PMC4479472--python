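"""Diagnostic per-dive plot: depth, raw and filtered acceleration, variance.

One optional figure mirroring how detector behaviour is usually checked by
eye: the dive profile, the raw axis, the high-passed axis, and the moving
variance with threshold, detected peaks and annotated event windows.
"""

from __future__ import annotations

from .detector import DetectorParams, build_variance_cache, detect_from_cache
from .dives import Dive
from .signal_io import AccelTrace, DepthTrace


def plot_dive(
    accel: AccelTrace,
    depth: DepthTrace,
    dive: Dive,
    params: DetectorParams = DetectorParams(),
    events=None,
    ax=None,
):
    """Four-panel detector diagnostic for one dive; returns the figure."""
    import matplotlib.pyplot as plt

    from .detector import highpass

    fig, axes = plt.subplots(4, 1, figsize=(9, 8), sharex=True)
    fs = accel.sample_rate
    i0 = int((dive.start - accel.start_time) * fs)
    i1 = int((dive.end - accel.start_time) * fs) + 1
    t = accel.times()[i0:i1]
    raw = accel.axis(params.axis)[i0:i1]

    axes[0].plot(t, depth.depth[i0:i1], lw=0.8)
    axes[0].invert_yaxis()
    axes[0].set_ylabel("depth (m)")
    axes[1].plot(t, raw, lw=0.5)
    axes[1].set_ylabel(f"{params.axis} (g)")
    axes[2].plot(t, highpass(raw, fs, params.cutoff), lw=0.5)
    axes[2].set_ylabel("filtered (g)")

    cache = build_variance_cache(accel, depth, [dive], params)
    dv = cache[0]
    axes[3].plot(dv.t, dv.var, lw=0.8)
    axes[3].axhline(params.variance_threshold, ls="--", color="k", lw=0.8)
    for det in detect_from_cache(cache, params):
        axes[3].axvline(det.t_first_peak, color="r", lw=0.8)
    if events:
        for e in events:
            axes[3].axvspan(e.start, e.end, alpha=0.15, color="g")
    axes[3].set_ylabel("variance (g$^2$)")
    axes[3].set_xlabel("time (s)")
    axes[3].set_xlim(t[0], t[-1])
    fig.tight_layout()
    return fig
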