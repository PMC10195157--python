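"""Plots for scan results: per-species enhancer conservation bars."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_conservation"]


def plot_conservation(records: Sequence, ax=None):
    """Grouped bar chart of conservation fractions per species and region.

    ``records`` is a sequence of :class:`caecevo.enhancer.ConservationRecord`
    (possibly covering several region ids); one bar group per species.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    regions = sorted({r.region_id for r in records})
    species = sorted({r.species for r in records})
    width = 0.8 / max(len(regions), 1)
    lookup = {(r.species, r.region_id): r.fraction for r in records}
    for k, region in enumerate(regions):
        xs = [i + k * width for i in range(len(species))]
        ys = [lookup.get((sp, region), 0.0) for sp in species]
        ax.bar(xs, ys, width=width, label=region)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(species))])
    ax.set_xticklabels(species, rotation=45, ha="right")
    ax.set_ylabel("conservation fraction")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    return ax
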