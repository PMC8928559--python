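"""Environmental filtering: threshold-rule selection of candidate populations.

Three abiotic-stress subsets are produced from the characterized population
table:

* drought — annual De Martonne index below 15 (mid-low semi-arid) AND
  flowering-season index below 15, ranked most-arid-first by the flowering
  index;
* salinity — topsoil conductivity above 4 dS/m (moderately saline or worse);
  if empty, a fallback tier takes slightly saline soils (2 < ec < 4);
* waterlogging — poorly draining soil texture (Clay, Silty Clay, Sandy Clay,
  Silty Clay Loam) AND annual index above 25 (mid-high sub-humid or wetter).

Each subset is capped at 30 members with ELC categories represented
proportionally (largest-remainder quotas).  Populations without an ELC
category are excluded up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import POOR_DRAINAGE_TEXTURES
from .types import genebank_held

CAP_DEFAULT = 30


@dataclass
class SubsetSelection:
    """One trait's candidate subset plus the audit trail of applied criteria."""

    trait: str
    criteria: list[tuple[str, str, float]]
    members: pd.DataFrame  # pop_id, rank, rank_key, elc_category, ...
    capped: bool = False
    n_candidates: int = 0
    tier: int | None = None  # salinity: which criterion tier fired
    notes: str = ""

    @property
    def pop_ids(self) -> list[str]:
        return self.members["pop_id"].tolist()

    def __len__(self) -> int:
        return len(self.members)


def _eligible(populations: pd.DataFrame) -> pd.DataFrame:
    """Drop populations without an ELC category (no-data sites)."""
    df = populations
    if "elc_excluded" in df.columns:
        df = df[~df["elc_excluded"].astype(bool)]
    if "elc_category" in df.columns:
        df = df[df["elc_category"].notna()]
    return df


def _finish(
    trait: str,
    criteria: list[tuple[str, str, float]],
    candidates: pd.DataFrame,
    rank_keys: list[str],
    ascending: bool,
    cap: int,
) -> SubsetSelection:
    n = len(candidates)
    capped = n > cap
    if capped:
        members = proportional_subset(candidates, cap=cap, rank_keys=rank_keys, ascending=ascending)
    else:
        members = candidates.copy()
    order_cols = rank_keys + ["pop_id"]
    members = members.sort_values(order_cols, ascending=ascending).reset_index(drop=True)
    members["rank"] = np.arange(1, len(members) + 1)
    members["rank_key"] = members[rank_keys[0]] if rank_keys else np.nan
    return SubsetSelection(
        trait=trait,
        criteria=criteria,
        members=members,
        capped=capped,
        n_candidates=n,
    )


def select_drought(
    populations: pd.DataFrame, threshold: float = 15.0, cap: int = CAP_DEFAULT
) -> SubsetSelection:
    """Drought-tolerance candidates: IarDM < 15 then IarDMf < 15, most arid first."""
    df = _eligible(populations)
    criteria = [("iar_dm", "<", threshold), ("iar_dm_f", "<", threshold)]
    cand = df[(df["iar_dm"] < threshold) & (df["iar_dm_f"] < threshold)]
    return _finish("drought", criteria, cand, ["iar_dm_f", "iar_dm"], ascending=True, cap=cap)


def select_salinity(
    populations: pd.DataFrame,
    primary_ec: float = 4.0,
    fallback_low: float = 2.0,
    cap: int = CAP_DEFAULT,
) -> SubsetSelection:
    """Salinity-tolerance candidates; reports which criterion tier fired.

    Tier 1: ec > 4 dS/m (moderately saline soils or worse).  If no
    population qualifies, tier 2 takes slightly saline soils
    (2 < ec < 4), mirroring the fallback used when no site reaches the
    primary threshold.
    """
    df = _eligible(populations)
    tier1 = df[df["topsoil_ec"] > primary_ec]
    if len(tier1) > 0:
        sel = _finish(
            "salinity",
            [("topsoil_ec", ">", primary_ec)],
            tier1,
            ["topsoil_ec"],
            ascending=False,
            cap=cap,
        )
        sel.tier = 1
        return sel
    tier2 = df[(df["topsoil_ec"] > fallback_low) & (df["topsoil_ec"] < primary_ec)]
    sel = _finish(
        "salinity",
        [("topsoil_ec", ">", fallback_low), ("topsoil_ec", "<", primary_ec)],
        tier2,
        ["topsoil_ec"],
        ascending=False,
        cap=cap,
    )
    sel.tier = 2
    if len(tier2) == 0:
        sel.notes = "both tiers empty: no population on saline or slightly saline soil"
    return sel


def select_waterlogging(
    populations: pd.DataFrame, aridity_threshold: float = 25.0, cap: int = CAP_DEFAULT
) -> SubsetSelection:
    """Waterlogging candidates: poorly draining texture AND IarDM > 25, wettest first."""
    df = _eligible(populations)
    criteria = [
        ("texture_class", "in", float("nan")),
        ("iar_dm", ">", aridity_threshold),
    ]
    texture_ok = df["texture_class"].isin(POOR_DRAINAGE_TEXTURES)
    cand = df[texture_ok & (df["iar_dm"] > aridity_threshold)]
    sel = _finish("waterlogging", criteria, cand, ["iar_dm"], ascending=False, cap=cap)
    sel.notes = f"{int(texture_ok.sum())} populations passed the texture criterion"
    sel.n_texture_pass = int(texture_ok.sum())  # type: ignore[attr-defined]
    return sel


def proportional_subset(
    candidates: pd.DataFrame,
    cap: int = CAP_DEFAULT,
    rank_keys: list[str] | None = None,
    ascending: bool = True,
) -> pd.DataFrame:
    """Cap a candidate set with ELC categories proportionally represented.

    If the candidate count is within the cap, all are returned.  Otherwise
    per-category quotas are computed by largest-remainder (Hamilton)
    rounding of cap * n_cat / n_total; when the cap allows, every
    represented category keeps at least one member.  Quota ties are broken
    toward the larger category, then the smaller category id.  Quotas are
    filled in trait-rank order.
    """
    n = len(candidates)
    if n <= cap:
        return candidates.copy()
    if "elc_category" not in candidates.columns or candidates["elc_category"].isna().all():
        # no map available: plain rank-based truncation
        keys = (rank_keys or []) + ["pop_id"]
        return candidates.sort_values(keys, ascending=ascending).head(cap).reset_index(drop=True)
    counts = candidates.groupby("elc_category", observed=True).size()
    alloc = allocate_quotas(counts.to_dict(), cap)

    pieces = []
    keys = rank_keys or []
    for c in counts.index:
        group = candidates[candidates["elc_category"] == c]
        if keys:
            group = group.sort_values(keys + ["pop_id"], ascending=ascending)
        pieces.append(group.head(alloc[c]))
    return pd.concat(pieces).reset_index(drop=True)


def allocate_quotas(counts: dict, cap: int) -> dict:
    """Integer per-category quotas proportional to ``counts`` summing to ``cap``.

    Minimizes sum |alloc_c - cap*n_c/n| subject to 0 <= alloc_c <= n_c and,
    when the cap permits (cap >= number of categories), alloc_c >= 1 for
    every represented category.  The objective is separable and convex in
    each coordinate, so greedy marginal allocation is exactly optimal and
    coincides with largest-remainder (Hamilton) rounding when the bounds are
    slack.  Ties break toward the larger category, then the smaller
    category id.
    """
    cats = list(counts)
    n = sum(counts.values())
    quota = {c: cap * counts[c] / n for c in cats}
    floor_guarantee = 1 if cap >= len(cats) else 0
    alloc = {c: min(floor_guarantee, counts[c]) for c in cats}
    remaining = cap - sum(alloc.values())

    def marginal(c) -> float:
        a = alloc[c]
        return abs(a + 1 - quota[c]) - abs(a - quota[c])

    for _ in range(remaining):
        room = [c for c in cats if alloc[c] < counts[c]]
        winner = min(room, key=lambda c: (marginal(c), -counts[c], _cat_key(c)))
        alloc[winner] += 1
    return alloc


def _cat_key(c) -> float:
    try:
        return float(c)
    except (TypeError, ValueError):
        return float(hash(c) % 10**6)


def summarize_overlaps(
    selections: list[SubsetSelection],
    calibration_ids: list[str] | None = None,
    calibration_name: str = "rust",
) -> pd.DataFrame:
    """Cross-tabulate which populations appear in which selected subsets.

    Returns one row per population present in any subset, with boolean
    membership columns, the number of subsets containing it, and the
    genebank flag.  ``df.attrs['pairwise']`` holds the pairwise overlap
    counts.
    """
    membership: dict[str, set[str]] = {s.trait: set(s.pop_ids) for s in selections}
    if calibration_ids is not None:
        membership[calibration_name] = set(calibration_ids)
    all_ids = sorted(set().union(*membership.values())) if membership else []
    rows = []
    for pid in all_ids:
        entry = {"pop_id": pid, "genebank_held": genebank_held(pid)}
        for name, ids in membership.items():
            entry[name] = pid in ids
        entry["n_subsets"] = sum(pid in ids for ids in membership.values())
        rows.append(entry)
    report = pd.DataFrame(rows)

    names = list(membership)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = len(membership[a] & membership[b])
    report.attrs["pairwise"] = pairwise
    report.attrs["in_all"] = (
        sorted(set.intersection(*membership.values())) if len(membership) > 1 else all_ids
    )
    return report
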