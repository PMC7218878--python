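"""Optional plotting layer: Bland-Altman scatter and BP trend lines.

Thin wrappers over matplotlib; the numeric reports in
:mod:`pttbp.evaluation` are the correctness surface, these are for eyes.
"""

from __future__ import annotations

import numpy as np

from .evaluation import LOA_Z, bland_altman


def bland_altman_plot(est, ref, ax=None, label: str = "BP"):
    """Difference-vs-mean scatter with bias and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    est = np.asarray(est, float)
    ref = np.asarray(ref, float)
    bias, sd, loa_low, loa_high, _ = bland_altman(est, ref)
    mean = (est + ref) / 2.0
    ax.scatter(mean, est - ref, s=12, alpha=0.6)
    for y, style in ((bias, "-"), (loa_low, "--"), (loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(f"mean of estimate and cuff {label} (mmHg)")
    ax.set_ylabel(f"estimate - cuff {label} (mmHg)")
    ax.set_title(f"bias {bias:.2f}, LoA ({loa_low:.2f}, {loa_high:.2f}) mmHg")
    return ax


def trend_plot(times, est, cuff_times=None, cuff=None, ax=None, label: str = "SBP"):
    """Estimated BP over time, optionally with cuff readings overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.asarray(times, float), np.asarray(est, float), label=f"estimated {label}")
    if cuff is not None:
        ax.plot(
            np.asarray(cuff_times, float),
            np.asarray(cuff, float),
            "o",
            markersize=4,
            label=f"cuff {label}",
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{label} (mmHg)")
    ax.legend()
    return ax
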