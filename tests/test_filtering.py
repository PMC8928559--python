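"""Environmental filtering: criteria, ranking, proportional capping, overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from predchar.filtering import (
    allocate_quotas,
    proportional_subset,
    select_drought,
    select_salinity,
    select_waterlogging,
    summarize_overlaps,
)
from conftest import make_population_table


class TestDrought:
    def test_requires_both_indices_below_threshold(self):
        pops = make_population_table(iar_dm=[14.0, 14.0], iar_dm_f=[16.0, 12.0])
        sel = select_drought(pops)
        assert sel.pop_ids == ["ID_0001"]

    def test_ranked_most_arid_flowering_first(self):
        pops = make_population_table(iar_dm=[12, 12, 12], iar_dm_f=[13.0, 9.0, 11.0])
        sel = select_drought(pops)
        assert sel.members["iar_dm_f"].tolist() == [9.0, 11.0, 13.0]
        assert sel.members["rank"].tolist() == [1, 2, 3]

    def test_elc_excluded_populations_never_selected(self):
        pops = make_population_table(iar_dm=[10.0, 10.0], iar_dm_f=[10.0, 10.0])
        pops.loc[0, "elc_category"] = pd.NA
        sel = select_drought(pops)
        assert sel.pop_ids == ["ID_0001"]

    def test_empty_selection_allowed(self):
        pops = make_population_table(iar_dm=[30.0], iar_dm_f=[30.0])
        assert len(select_drought(pops)) == 0


class TestSalinity:
    def test_primary_tier_takes_moderately_saline(self):
        pops = make_population_table(ec=[5.0, 3.0, 1.0])
        sel = select_salinity(pops)
        assert sel.tier == 1 and sel.pop_ids == ["ID_0000"]

    def test_fallback_tier_fires_when_primary_empty(self):
        pops = make_population_table(ec=[3.1, 1.0, 0.5])
        sel = select_salinity(pops)
        assert sel.tier == 2 and sel.pop_ids == ["ID_0000"]

    def test_all_nonsaline_reports_empty_fallback(self):
        pops = make_population_table(ec=[1.0, 0.2])
        sel = select_salinity(pops)
        assert sel.tier == 2 and len(sel) == 0 and "empty" in sel.notes

    def test_fallback_bounds_strict(self):
        pops = make_population_table(ec=[2.0, 4.0, 2.5])
        sel = select_salinity(pops)
        assert sel.pop_ids == ["ID_0002"]


class TestWaterlogging:
    def test_texture_other_excluded_regardless_of_humidity(self):
        pops = make_population_table(texture=["Other", "Clay"], iar_dm=[40.0, 40.0])
        sel = select_waterlogging(pops)
        assert sel.pop_ids == ["ID_0001"]

    def test_aridity_boundary_strict(self):
        pops = make_population_table(texture=["Clay", "Clay"], iar_dm=[25.0, 25.01])
        sel = select_waterlogging(pops)
        assert sel.pop_ids == ["ID_0001"]

    def test_texture_pass_count_reported(self):
        pops = make_population_table(
            texture=["Clay", "Silty Clay", "Other"], iar_dm=[20.0, 30.0, 30.0]
        )
        sel = select_waterlogging(pops)
        assert sel.n_texture_pass == 2 and len(sel) == 1

    def test_joint_equals_sequential_filtering(self):
        rng = np.random.default_rng(2)
        pops = make_population_table(
            texture=list(rng.choice(["Clay", "Other"], 60)),
            iar_dm=list(rng.uniform(15, 40, 60)),
        )
        joint = set(select_waterlogging(pops).pop_ids)
        staged = pops[pops["texture_class"] == "Clay"]
        staged = staged[staged["iar_dm"] > 25.0]
        assert joint == set(staged["pop_id"])


class TestProportionalSubset:
    def make(self, category_counts):
        cats = [c for c, n in category_counts.items() for _ in range(n)]
        n = len(cats)
        df = make_population_table(iar_dm=list(np.linspace(5, 14, n)))
        df["elc_category"] = pd.array(cats, dtype="Int64")
        return df

    def test_under_cap_returns_all(self):
        df = self.make({1: 6, 2: 4})
        out = proportional_subset(df, cap=30)
        assert len(out) == 10

    def test_exact_proportionality(self):
        df = self.make({1: 40, 2: 20})
        out = proportional_subset(df, cap=30, rank_keys=["iar_dm"])
        counts = out["elc_category"].value_counts()
        assert counts[1] == 20 and counts[2] == 10

    def test_largest_remainder_on_uneven_split(self):
        df = self.make({1: 41, 2: 20})
        out = proportional_subset(df, cap=30, rank_keys=["iar_dm"])
        counts = out["elc_category"].value_counts()
        # quotas 20.16 / 9.84 -> 20 / 10
        assert counts[1] == 20 and counts[2] == 10

    def test_every_category_kept_when_cap_permits(self):
        df = self.make({1: 50, 2: 1, 3: 1})
        out = proportional_subset(df, cap=10, rank_keys=["iar_dm"])
        assert set(out["elc_category"]) == {1, 2, 3}

    def test_output_size_is_min_of_n_and_cap(self):
        for counts, cap in [({1: 5}, 30), ({1: 35}, 30), ({1: 20, 2: 25}, 8)]:
            df = self.make(counts)
            out = proportional_subset(df, cap=cap, rank_keys=["iar_dm"])
            assert len(out) == min(len(df), cap)

    def test_quota_fill_respects_rank_order(self):
        df = self.make({1: 40, 2: 20})
        out = proportional_subset(df, cap=30, rank_keys=["iar_dm"], ascending=True)
        for cat in (1, 2):
            chosen = out[out["elc_category"] == cat]["iar_dm"]
            pool = df[df["elc_category"] == cat]["iar_dm"]
            assert set(chosen) == set(sorted(pool)[: len(chosen)])


def quota_error(alloc, counts, cap):
    n = sum(counts.values())
    return sum(abs(alloc[c] - cap * counts[c] / n) for c in counts)


def brute_force_min_error(counts, cap):
    """Minimal allocation error over every feasible integer allocation."""
    cats = list(counts)
    best = np.inf
    floor1 = 1 if cap >= len(cats) else 0
    ranges = [range(min(floor1, counts[c]), counts[c] + 1) for c in cats]
    for combo in itertools.product(*ranges):
        if sum(combo) != cap:
            continue
        err = quota_error(dict(zip(cats, combo)), counts, cap)
        best = min(best, err)
    return best


class TestAllocateQuotas:
    @pytest.mark.parametrize(
        "counts,cap",
        [({1: 40, 2: 20}, 30), ({1: 41, 2: 20}, 30), ({1: 7, 2: 5, 3: 1}, 8), ({1: 9, 2: 2}, 4)],
    )
    def test_matches_minimal_error(self, counts, cap):
        alloc = allocate_quotas(counts, cap)
        assert sum(alloc.values()) == cap
        assert quota_error(alloc, counts, cap) == pytest.approx(
            brute_force_min_error(counts, cap)
        )


class TestOverlaps:
    def sel(self, trait, ids):
        from predchar.filtering import SubsetSelection

        return SubsetSelection(
            trait=trait, criteria=[], members=pd.DataFrame({"pop_id": ids})
        )

    def test_disjoint_subsets_no_overlap(self):
        report = summarize_overlaps([self.sel("drought", ["A"]), self.sel("salinity", ["B"])])
        assert all(v == 0 for v in report.attrs["pairwise"].values())

    def test_single_shared_population_counted_once(self):
        report = summarize_overlaps(
            [self.sel("drought", ["A", "B"]), self.sel("waterlogging", ["B", "C"])]
        )
        assert report.attrs["pairwise"][("drought", "waterlogging")] == 1
        row = report[report["pop_id"] == "B"].iloc[0]
        assert row["n_subsets"] == 2

    def test_calibration_subset_and_genebank_flag(self):
        report = summarize_overlaps(
            [self.sel("drought", ["ID_1", "GE_9"])], calibration_ids=["GE_9", "ID_7"]
        )
        assert report.attrs["pairwise"][("drought", "rust")] == 1
        ge = report[report["pop_id"] == "GE_9"].iloc[0]
        assert ge["genebank_held"]
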