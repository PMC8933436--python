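"""Shared helpers for balanced two-locus designs used as oracles."""

import numpy as np

from diplomap.markers import MarkerMap
from diplomap.panels import DiploidPanel


def balanced_panel_and_codes(reps=60):
    """Balanced 3x3 two-locus panel plus standardized interaction contrasts.

    The contrasts (aa, da, ad, dd) are double-centered so each lies purely in
    the 4-df interaction space of the saturated two-way categorical model.
    """
    mmap = MarkerMap(np.array([1, 2]), np.array([100, 100]), np.array([1.0, 1.0]))
    cells = np.array(np.meshgrid([0, 1, 2], [0, 1, 2])).reshape(2, -1).T
    G = np.repeat(cells, reps, axis=0).astype(np.int8)
    n = G.shape[0]
    panel = DiploidPanel(
        mmap, G, np.zeros(n, int), np.zeros(n, int), np.zeros(n, np.int8), 0
    )
    x1 = G[:, 0].astype(float) - 1
    x2 = G[:, 1].astype(float) - 1
    h1 = (G[:, 0] == 1).astype(float)
    h1 -= h1.mean()
    h2 = (G[:, 1] == 1).astype(float)
    h2 -= h2.mean()
    codes = [x1 * x2, h1 * x2, x1 * h2, h1 * h2]
    codes = [(c - c.mean()) / c.std() for c in codes]
    return panel, codes
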