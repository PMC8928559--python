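"""Ecogeographic land characterization (ELC) maps.

An ELC map partitions a territory into categories meant to proxy distinct
adaptive scenarios: each of the three variable components (bioclimatic,
edaphic, geophysic) is clustered independently over the grid cells, and a
category is one realized combination (triple) of component clusters.

Cluster counts are chosen by the elbow rule on the within-cluster sum of
squares (WSS): k* is the smallest k >= 2 at which the decrease from k to
k+1 falls below half the decrease from k-1 to k, capped at ``max_k`` (6 by
default).  Layers are z-standardized before clustering so units do not
dominate distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .types import COMPONENTS, DimensionError, EnvironmentalStack, GridSpec

MAX_K_DEFAULT = 6


@dataclass
class ELCMap:
    """Category grid, per-component cluster grids, and the triple legend."""

    grid: GridSpec
    category_grid: np.ndarray
    component_grids: dict[str, np.ndarray]
    legend: dict[tuple[int, int, int], int]
    k: dict[str, int]
    wss: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_categories(self) -> int:
        return len(self.legend)

    def legend_table(self) -> pd.DataFrame:
        rows = [
            {"bioclimatic": b, "edaphic": e, "geophysic": g, "category": cat}
            for (b, e, g), cat in sorted(self.legend.items(), key=lambda kv: kv[1])
        ]
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Plain category plot (no cartography)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        shown = np.where(self.category_grid == 0, np.nan, self.category_grid)
        im = ax.imshow(shown, interpolation="nearest")
        ax.set_title(f"ELC map ({self.n_categories} categories)")
        return im


def elbow_k(wss: np.ndarray, rule: str = "ratio") -> int:
    """Pick k from a WSS curve (wss[i] is the value at k = i+1).

    ``ratio`` (default): smallest k >= 2 with
    [wss(k) - wss(k+1)] < 0.5 * [wss(k-1) - wss(k)]; ``absolute``: smallest
    k >= 2 with [wss(k) - wss(k+1)] < 0.5 * wss(k).  Falls back to the
    largest k evaluated if never satisfied.
    """
    max_k = len(wss)
    if max_k == 1 or wss[0] <= 1e-12:
        return 1
    for k in range(2, max_k):
        drop_next = wss[k - 1] - wss[k]
        if rule == "ratio":
            drop_prev = wss[k - 2] - wss[k - 1]
            if drop_next < 0.5 * drop_prev:
                return k
        elif rule == "absolute":
            if drop_next < 0.5 * wss[k - 1]:
                return k
        else:
            raise ValueError(f"unknown elbow rule {rule!r}")
    return max_k


def cluster_component(
    matrix: np.ndarray,
    max_k: int = MAX_K_DEFAULT,
    seed: int = 0,
    n_init: int = 25,
    rule: str = "ratio",
) -> tuple[int, np.ndarray, np.ndarray]:
    """Cluster a cells-by-variables matrix; choose k by the elbow rule.

    Variables are z-standardized (constant columns dropped from distance
    computations).  Returns (k*, assignments in 1..k*, wss array for
    k = 1..max_k).  ``max_k`` is reduced with a note when the matrix has
    fewer distinct rows.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise DimensionError("need a 2-D matrix with at least two complete cells")
    sd = X.std(axis=0)
    mean = X.mean(axis=0)
    Z = (X - mean) / np.where(sd > 0, sd, 1.0)

    n_distinct = len(np.unique(Z, axis=0))
    max_k = min(max_k, n_distinct)

    wss = np.empty(max_k)
    labels_for_k: dict[int, np.ndarray] = {}
    for k in range(1, max_k + 1):
        if k == 1:
            wss[0] = float(((Z - Z.mean(axis=0)) ** 2).sum())
            labels_for_k[1] = np.zeros(len(Z), dtype=int)
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels_for_k[k] = km.fit_predict(Z)
        wss[k - 1] = float(km.inertia_)

    k_star = elbow_k(wss, rule=rule)
    return k_star, labels_for_k[k_star] + 1, wss


def build_elc_map(
    stack: EnvironmentalStack,
    variables: dict[str, list[str]] | None = None,
    max_k: int = MAX_K_DEFAULT,
    seed: int = 0,
    rule: str = "ratio",
) -> ELCMap:
    """Cluster each component over the grid's valid cells and compose categories.

    ``variables`` maps component -> retained layer names (e.g. from the
    variable-selection stage); by default all layers of each component are
    used.  Cells that are no-data in any used layer get cluster 0 and
    category 0.
    """
    if variables is None:
        variables = {c: stack.names(c) for c in COMPONENTS}
    grid = stack.grid
    valid = np.ones((grid.n_rows, grid.n_cols), dtype=bool)
    for comp in COMPONENTS:
        for name in variables.get(comp, []):
            valid &= np.isfinite(stack.layers[name])

    component_grids: dict[str, np.ndarray] = {}
    k_map: dict[str, int] = {}
    wss_map: dict[str, np.ndarray] = {}
    rows, cols = np.nonzero(valid)
    for i, comp in enumerate(COMPONENTS):
        names = variables.get(comp, [])
        if not names:
            raise ValueError(f"no variables for component {comp!r}")
        matrix = np.column_stack([stack.layers[n][rows, cols] for n in names])
        k, labels, wss = cluster_component(matrix, max_k=max_k, seed=seed + i, rule=rule)
        grid_labels = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
        grid_labels[rows, cols] = labels
        component_grids[comp] = grid_labels
        k_map[comp] = k
        wss_map[comp] = wss

    elc = compose_categories(component_grids, grid)
    elc.k = k_map
    elc.wss = wss_map
    return elc


def compose_categories(
    component_grids: dict[str, np.ndarray], grid: GridSpec
) -> ELCMap:
    """Densely number the realized (bio, eda, geo) cluster triples.

    Categories are 1..n in row-major order over the sorted realized triples;
    cells with cluster 0 (no data) in any component get category 0.  The
    legend is a bijection between realized triples and category ids.
    """
    arrays = [np.asarray(component_grids[c]) for c in COMPONENTS]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays) or shape != (grid.n_rows, grid.n_cols):
        raise DimensionError("component grids and grid spec disagree on shape")

    valid = np.all([a > 0 for a in arrays], axis=0)
    triples = np.stack([a[valid] for a in arrays], axis=1)
    realized = sorted(map(tuple, np.unique(triples, axis=0)))
    legend = {triple: i + 1 for i, triple in enumerate(realized)}

    category = np.zeros(shape, dtype=int)
    flat = {t: c for t, c in legend.items()}
    it = np.nditer(valid, flags=["multi_index"])
    for v in it:
        if v:
            idx = it.multi_index
            category[idx] = flat[(arrays[0][idx], arrays[1][idx], arrays[2][idx])]

    return ELCMap(
        grid=grid,
        category_grid=category,
        component_grids={c: a for c, a in zip(COMPONENTS, arrays)},
        legend=legend,
        k={c: int(a.max()) for c, a in zip(COMPONENTS, arrays)},
    )


def assign_category(elc: ELCMap, populations: pd.DataFrame) -> pd.DataFrame:
    """Attach ``elc_category`` to populations by nearest-cell lookup.

    Populations on category-0 (no-data) cells or outside the grid get a
    missing category and ``elc_excluded = True``; they take no further part
    in selections.
    """
    out = populations.copy()
    cats = np.zeros(len(out), dtype=int)
    for i, (lon, lat) in enumerate(zip(out["lon"].to_numpy(), out["lat"].to_numpy())):
        idx = elc.grid.index_of(float(lon), float(lat))
        cats[i] = elc.category_grid[idx] if idx is not None else 0
    out["elc_category"] = pd.array([c if c > 0 else pd.NA for c in cats], dtype="Int64")
    out["elc_excluded"] = cats == 0
    return out
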