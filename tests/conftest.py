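"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by brute force so the
production code path is checked against something it does not share code
with: per-pixel distance scans for the cytoplasmic rings, and an exhaustive
grid search (with the linear parameters profiled out) for the 4PL fits.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import foxscreen as fx

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def clean_well():
    """20 well-separated cells, no noise, fixed N/C ratio 2.5."""
    states = fx.StateDistributions(median_resting=2.5, median_translocated=2.5, sd_log=0.0)
    spec = fx.WellSpec(
        n_cells=20, image_shape=(360, 360), translocation_fraction=0.0,
        noise=fx.NoiseSpec.off(), seed=42,
    )
    pair, truth = fx.render_well(spec, states=states)
    return spec, pair, truth


def ring_brute_force(labels: np.ndarray, gap: int, width: int):
    """Per-pixel nearest-nucleus ring partition, by exhaustive distance scan.

    For every background pixel the exact squared Euclidean distance to every
    labeled region is computed; the pixel joins the ring of the nearest label
    (ties: nearer region centroid, then lower label) when
    gap < d <= gap + width.
    """
    labs = np.unique(labels)
    labs = labs[labs > 0]
    coords = {int(l): np.argwhere(labels == l) for l in labs}
    cents = {l: c.mean(axis=0) for l, c in coords.items()}
    rings: dict[int, set[tuple[int, int]]] = {l: set() for l in coords}
    gap2, reach2 = gap * gap, (gap + width) ** 2
    for p in np.argwhere(labels == 0):
        d2 = {l: int(((c - p) ** 2).sum(axis=1).min()) for l, c in coords.items()}
        best = min(d2.values())
        if not (gap2 < best <= reach2):
            continue
        cand = sorted(
            (l for l in d2 if d2[l] == best),
            key=lambda l: (float(((cents[l] - p) ** 2).sum()), l),
        )
        rings[cand[0]].add((int(p[0]), int(p[1])))
    return {l: s for l, s in rings.items() if s}


def rings_as_sets(ringset) -> dict[int, set[tuple[int, int]]]:
    return {
        l: set(zip(map(int, rr), map(int, cc)))
        for l, (rr, cc) in ringset.rings.items()
    }


def grid_4pl_oracle(conc, response, direction="increasing", n_mid=200, n_hill=120):
    """Exhaustive (midpoint, hill) grid with bottom/top profiled by linear LS.

    Returns (rss, midpoint, hill). Independent of the package's optimizer.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    logc = np.log10(conc)
    hills = np.linspace(0.05, 8.0, n_hill)
    if direction == "decreasing":
        hills = -hills
    best = None
    for logm in np.linspace(logc.min() - 1.5, logc.max() + 1.5, n_mid):
        for hill in hills:
            f = 1.0 / (1.0 + 10.0 ** (hill * (logm - logc)))
            A = np.stack([1.0 - f, f], axis=1)
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((A @ coef - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, 10.0**logm, float(hill))
    return best
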