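"""Ranking ecogeographic variables by random-forest importance and pruning
correlated ones within each component.

The response for the forest is presence cells versus randomly drawn
background cells from the stack's valid extent (an alternative multiclass
response on taxon identity is available), and importance is the classical
mean decrease in accuracy (MDA): for every tree, out-of-bag accuracy before
minus after permuting one variable, averaged over trees.  Pruning keeps, per
component, the top-ranked variables whose pairwise Pearson correlation on
the occurrence sites stays below a threshold (|r| <= 0.5 with p < 0.05 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .types import EnvironmentalStack, ValidationError


@dataclass
class VariableRanking:
    """Per-variable importance, rank within component, and retention status."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: name, component, mda, rank, retained, dropped_because

    def retained(self, component: str | None = None) -> list[str]:
        t = self.table[self.table["retained"]]
        if component is not None:
            t = t[t["component"] == component]
        return t["name"].tolist()


def _oob_mda(forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-variable mean decrease accuracy over out-of-bag samples."""
    n_samples, n_features = X.shape
    decreases = np.zeros((len(forest.estimators_), n_features))
    for t_idx, (tree, sampled) in enumerate(zip(forest.estimators_, forest.estimators_samples_)):
        in_bag = np.zeros(n_samples, dtype=bool)
        in_bag[sampled] = True
        oob = np.nonzero(~in_bag)[0]
        if len(oob) == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base = np.mean(tree.predict(X_oob) == y_oob)
        for j in range(n_features):
            Xp = X_oob.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            decreases[t_idx, j] = base - np.mean(tree.predict(Xp) == y_oob)
    return decreases.mean(axis=0)


def rank_variables(
    occurrences: pd.DataFrame,
    stack: EnvironmentalStack,
    n_background: int | None = None,
    seed: int = 0,
    n_trees: int = 300,
    response: str = "presence",
    include_lonlat: bool = True,
) -> VariableRanking:
    """Rank variables by MDA from a forest explaining the occurrence distribution.

    Parameters
    ----------
    occurrences
        Characterized population table (env columns present, matching stack
        layer names).
    n_background
        Number of random background cells for the presence/background
        response; defaults to 10x the number of presences (capped at the
        number of available valid cells).
    response
        "presence" (presence vs background cells, default) or "taxon"
        (multiclass on taxon identity, occurrence sites only).
    include_lonlat
        Treat longitude/latitude as geophysic candidate variables.
    """
    rng = np.random.default_rng(seed)
    env_cols = [c for c in stack.names() if c in occurrences.columns]
    if len(env_cols) < 2 and not include_lonlat:
        raise ValidationError("need at least two candidate variables")
    component = {c: stack.component[c] for c in env_cols}

    pres = occurrences.dropna(subset=env_cols)
    X_parts = [pres[env_cols].to_numpy(dtype=float)]
    lonlat_cols: list[str] = []
    if include_lonlat:
        lonlat_cols = ["lon", "lat"]
        component["lon"] = "geophysic"
        component["lat"] = "geophysic"
        X_parts = [np.column_stack([pres[env_cols].to_numpy(dtype=float), pres[lonlat_cols].to_numpy(dtype=float)])]
    names = env_cols + lonlat_cols

    if response == "taxon":
        X = X_parts[0]
        y = pd.factorize(pres["taxon"])[0]
    elif response == "presence":
        valid = stack.valid_mask
        # background pool: valid cells not occupied by a presence
        occupied = set()
        for lon, lat in zip(pres["lon"], pres["lat"]):
            idx = stack.grid.index_of(float(lon), float(lat))
            if idx is not None:
                occupied.add(idx)
        rows, cols = np.nonzero(valid)
        free = np.array([i for i in range(len(rows)) if (rows[i], cols[i]) not in occupied])
        rows, cols = rows[free], cols[free]
        n_bg = n_background if n_background is not None else min(10 * len(pres), len(rows))
        n_bg = min(n_bg, len(rows))
        pick = rng.choice(len(rows), size=n_bg, replace=False)
        bg_vals = np.column_stack([stack.layers[c][rows[pick], cols[pick]] for c in env_cols])
        if include_lonlat:
            centers = np.array([stack.grid.cell_center(r, c) for r, c in zip(rows[pick], cols[pick])])
            bg_vals = np.column_stack([bg_vals, centers])
        X = np.vstack([X_parts[0], bg_vals])
        y = np.concatenate([np.ones(len(pres), dtype=int), np.zeros(n_bg, dtype=int)])
    else:
        raise ValidationError(f"unknown response {response!r}")

    # drop all-missing candidates with a warning flag rather than failing
    keep = [j for j in range(X.shape[1]) if np.isfinite(X[:, j]).any()]
    dropped_all_missing = [names[j] for j in range(X.shape[1]) if j not in keep]
    X = X[:, keep]
    names = [names[j] for j in keep]
    col_means = np.nanmean(X, axis=0)
    nan_mask = ~np.isfinite(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=False,
        bootstrap=True,
        random_state=int(rng.integers(2**31)),
        n_jobs=1,
    )
    forest.fit(X, y)
    mda = _oob_mda(forest, X, y, rng)

    table = pd.DataFrame({"name": names, "component": [component[n] for n in names], "mda": mda})
    # deterministic ordering: MDA descending, ties broken lexicographically
    table = table.sort_values(["component", "mda", "name"], ascending=[True, False, True])
    table["rank"] = table.groupby("component")["mda"].rank(method="first", ascending=False).astype(int)
    table["retained"] = True
    table["dropped_because"] = ""
    table = table.reset_index(drop=True)
    ranking = VariableRanking(table=table)
    ranking.table.attrs["dropped_all_missing"] = dropped_all_missing
    return ranking


def prune_correlated(
    ranking: VariableRanking,
    data: pd.DataFrame,
    top_n: int = 15,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
    pooled: bool = False,
) -> VariableRanking:
    """Greedy correlation pruning of the top-``top_n`` variables per component.

    Scanning in decreasing MDA order, a variable is retained iff, against
    every already-retained variable of the same group, |Pearson r| <=
    ``r_threshold`` or the correlation is not significant (p >= ``alpha``).
    Correlations are computed on the occurrence-site values in ``data``
    (lon/lat columns included when ranked).  With ``pooled`` the edaphic and
    geophysic components are pruned as one group.
    """
    table = ranking.table.copy()
    table["retained"] = False
    table["dropped_because"] = ""

    def group_key(comp: str) -> str:
        if pooled and comp in ("edaphic", "geophysic"):
            return "edaphic+geophysic"
        return comp

    table["_group"] = table["component"].map(group_key)
    for _, group in table.groupby("_group", sort=False):
        candidates = group.sort_values(["mda", "name"], ascending=[False, True]).head(top_n)
        kept: list[str] = []
        for _, row in candidates.iterrows():
            name = row["name"]
            if name not in data.columns or data[name].notna().sum() < 3:
                continue
            blocker = ""
            for other in kept:
                pair = data[[name, other]].dropna()
                r, p = stats.pearsonr(pair[name], pair[other])
                if abs(r) > r_threshold and p < alpha:
                    blocker = other
                    break
            if blocker:
                table.loc[table["name"] == name, "dropped_because"] = blocker
            else:
                kept.append(name)
                table.loc[table["name"] == name, "retained"] = True
    return VariableRanking(table=table.drop(columns="_group"))
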