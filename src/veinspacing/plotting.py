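"""Minimal figure helpers: violin + point-swarm panels of r distributions."""

from __future__ import annotations

import numpy as np

from .analysis import PairSymmetryRecord, SpeciesResult

__all__ = ["plot_species_violin", "plot_pair_symmetry"]


def plot_species_violin(results: list[SpeciesResult], ax=None, truncate_at=None):
    """Violin (KDE) plus jittered point swarm of pooled r per species."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.6 * len(results)), 4))
    rng = np.random.default_rng(0)  # cosmetic jitter only
    for i, res in enumerate(results):
        if res.empty:
            continue
        r = res.r_values
        if truncate_at is not None:
            r = r[r <= truncate_at]
        den = res.density
        if den is not None and not den.degenerate:
            width = 0.4 * den.density / den.density.max()
            ax.fill_betweenx(den.grid, i - width, i + width,
                             color="firebrick", alpha=0.35, lw=1)
        ax.plot(i + rng.uniform(-0.25, 0.25, r.size), r, ".", ms=2, color="k")
        label = res.code
        if res.dip is not None:
            label += f"\np={res.dip.p_value:.3f}"
        ax.text(i, -0.12, label, ha="center", va="top", fontsize=7,
                transform=ax.get_xaxis_transform())
    ax.set_xticks([])
    ax.set_ylabel("r = d_opposite / d_same")
    return ax


def plot_pair_symmetry(records: list[PairSymmetryRecord], ax=None):
    """Irregular cases of one leaflet pair on the signed [-1, 1] axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for rec in records:
        ax.plot(rec.paired_coordinate, rec.r, "o",
                color="k" if rec.mirror_matched else "firebrick")
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_xlim(-1.05, 1.05)
    ax.set_xlabel("position (-1 = left tip, 0 = bases, +1 = right tip)")
    ax.set_ylabel("r")
    return ax
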