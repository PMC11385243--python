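"""Figure-style plots: HF histogram, burden strip charts, spectrum, score histograms."""

from __future__ import annotations

import numpy as np


def plot_hf_histogram(hfs, floor: float = 0.02, bins: int = 100, ax=None):
    """Histogram of heteroplasmic fractions with the detection floor marked."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.hist(np.asarray(list(hfs), dtype=float), bins=bins, color="steelblue")
    ax.axvline(floor, color="red", lw=1.5)
    ax.set_xlabel("heteroplasmic fraction")
    ax.set_ylabel("variants")
    return ax


def plot_burden_strip(burden, value: str = "normalized", by: str = "locus_class", ax=None, seed: int = 0):
    """Strip chart of per-cell burdens grouped by locus class or sample."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    rng = np.random.default_rng(seed)
    groups = list(dict.fromkeys(burden[by]))
    for i, g in enumerate(groups):
        y = burden.loc[burden[by] == g, value].to_numpy()
        x = i + rng.uniform(-0.15, 0.15, size=y.size)
        ax.plot(x, y, "o", ms=3, alpha=0.6)
    ax.set_xticks(range(len(groups)), groups, rotation=45, ha="right")
    ax.set_ylabel(value)
    return ax


def plot_spectrum(spectrum, ax=None):
    """Bar chart of the 12-class substitution spectrum (percent)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.bar(spectrum["substitution"], spectrum["percent"], color="grey")
    ax.set_ylabel("% of somatic variants")
    ax.tick_params(axis="x", rotation=60)
    return ax


def plot_score_histograms(scores_by_tool: dict, thresholds: dict, bins: int = 30, ax=None):
    """Overlaid pathogenicity-score histograms with their thresholds dotted."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for tool, scores in scores_by_tool.items():
        ax.hist(
            np.asarray(list(scores), dtype=float),
            bins=bins,
            alpha=0.5,
            label=tool,
        )
        if tool in thresholds:
            ax.axvline(thresholds[tool], color="red", ls=":")
    ax.set_xlabel("score")
    ax.set_ylabel("variants")
    ax.legend()
    return ax
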