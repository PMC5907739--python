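"""Generic gap-distribution plot for a scenario comparison."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evalstats import MEASURES
from .experiment import ScenarioResult

__all__ = ["gap_distribution_plot"]


def gap_distribution_plot(result: ScenarioResult, spec: str = "interaction"):
    """Box plots of |train - test| gaps per measure, traditional CV vs PICV.

    Returns the matplotlib figure; annotations carry the one-sided KS
    p-value for each measure.
    """
    fig, axes = plt.subplots(1, len(MEASURES), figsize=(3.2 * len(MEASURES), 3.4))
    for ax, measure in zip(axes, MEASURES):
        trad = result.gap_samples[("traditional", spec, measure)].values
        picv = result.gap_samples[("picv", spec, measure)].values
        ax.boxplot([trad, picv], tick_labels=["traditional", "PICV"])
        _, p = result.ks[(spec, measure)]
        ax.set_title(f"{measure}\nKS p = {p:.3g}", fontsize=9)
        ax.set_ylabel("|train - test|")
    fig.suptitle(f"{result.label} ({spec})")
    fig.tight_layout()
    return fig
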