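import numpy as np
import pandas as pd
import pytest

from stacksdm.occurrences import (
    allocate_proportional,
    clean,
    filter_rare,
    generate_pseudo_absences,
    presence_cells_for,
    spatial_thin,
    summarize_composition,
)


def rec(taxon, lon, lat, source="s1"):
    return {"taxon": taxon, "lon": lon, "lat": lat, "depth_m": -10.0, "source_id": source}


class TestClean:
    def test_each_drop_reason_counted(self, small_stack):
        records = pd.DataFrame(
            [
                rec("Ammonia tepida", 0.5, 0.5),
                rec("Ammonia tepida", 0.5, 0.5),  # exact duplicate
                rec("Elphidium advenum", 1.5, 2.5),
                rec("Elphidium advenum", 200.0, 2.5),  # lon out of range
                rec("Elphidium advenum", np.nan, 2.5),  # missing coordinate
                rec("Quinqueloculina sp.", 2.5, 2.5),  # not species level
                rec("Bolivina striatula", 9.5, 1.5),  # off the grid
            ]
        )
        out, report = clean(records, small_stack, return_report=True)
        assert report == {
            "input": 7,
            "duplicates": 1,
            "bad_coordinates": 2,
            "off_grid_or_nodata": 1,
            "not_species_level": 1,
            "retained": 2,
        }
        assert sorted(out["taxon"]) == ["Ammonia tepida", "Elphidium advenum"]

    def test_synonyms_applied_before_dedup(self, small_stack):
        records = pd.DataFrame(
            [rec("Ammonia beccarii", 0.5, 0.5), rec("Ammonia tepida", 0.5, 0.5)]
        )
        synonyms = pd.DataFrame(
            {"old_name": ["Ammonia beccarii"], "accepted_name": ["Ammonia tepida"]}
        )
        out = clean(records, small_stack, synonyms=synonyms)
        assert len(out) == 1
        assert out["taxon"].iloc[0] == "Ammonia tepida"

    def test_nodata_cell_dropped(self, grid4x4):
        from dataclasses import replace

        from stacksdm.envgrid import EnvLayer, EnvStack

        mask = np.ones((4, 4), bool)
        mask[0, 0] = False  # cell containing (0.5, 3.5)
        spec = replace(grid4x4, valid_mask=mask)
        vals = np.where(mask, 1.0, np.nan)
        stack = EnvStack([EnvLayer("x", spec, vals)])
        records = pd.DataFrame([rec("Ammonia tepida", 0.5, 3.5), rec("Ammonia tepida", 1.5, 0.5)])
        out = clean(records, stack)
        assert len(out) == 1
        assert out["lon"].iloc[0] == 1.5

    def test_clean_is_idempotent(self, small_stack):
        records = pd.DataFrame(
            [rec("Ammonia tepida", 0.5, 0.5), rec("Peneroplis sp", 1.5, 1.5), rec("Bolivina striatula", 2.5, 2.5)]
        )
        once = clean(records, small_stack)
        twice = clean(once, small_stack)
        pd.testing.assert_frame_equal(once, twice)


class TestSpatialThin:
    def test_one_record_per_species_per_cell(self, grid4x4):
        records = pd.DataFrame(
            [
                rec("Ammonia tepida", 0.2, 0.2),
                rec("Ammonia tepida", 0.8, 0.8),  # same cell (row 3, col 0)
                rec("Ammonia tepida", 1.5, 0.5),  # different cell
                rec("Bolivina striatula", 0.2, 0.2),  # other species, same cell
            ]
        )
        out = spatial_thin(records, grid4x4)
        assert len(out) == 3
        assert (out["taxon"] == "Ammonia tepida").sum() == 2

    def test_stable_under_row_shuffle(self, grid4x4):
        records = pd.DataFrame(
            [
                rec("Ammonia tepida", 0.2, 0.2, source="b"),
                rec("Ammonia tepida", 0.8, 0.8, source="a"),
                rec("Bolivina striatula", 1.5, 1.5, source="a"),
            ]
        )
        out1 = spatial_thin(records, grid4x4)
        shuffled = records.iloc[[2, 0, 1]].reset_index(drop=True)
        out2 = spatial_thin(shuffled, grid4x4)
        key = lambda df: sorted(map(tuple, df[["taxon", "lon", "lat", "source_id"]].values))
        assert key(out1) == key(out2)
        # the kept duplicate is the one with the smaller source_id
        assert out1[out1["taxon"] == "Ammonia tepida"]["source_id"].iloc[0] == "a"


class TestFilterRare:
    def test_default_minimum_four(self, grid4x4):
        rows = [rec("Ammonia tepida", 0.5 + i, 0.5) for i in range(4)]
        rows += [rec("Bolivina striatula", 0.5 + i, 1.5) for i in range(3)]
        out = filter_rare(pd.DataFrame(rows))
        assert set(out["taxon"]) == {"Ammonia tepida"}

    def test_empty_input_passes_through(self):
        out = filter_rare(pd.DataFrame(columns=["taxon", "lon", "lat", "depth_m", "source_id"]))
        assert len(out) == 0


class TestAllocateProportional:
    def test_exact_proportions(self):
        alloc = allocate_proportional(np.array([10, 20, 70]), 10)
        assert alloc.tolist() == [1, 2, 7]

    def test_remainders_go_to_largest_blocks(self):
        # floor allocations 0,0,0 with n=2: both remainders to the largest blocks
        alloc = allocate_proportional(np.array([5, 3, 1]), 2)
        assert alloc.sum() == 2
        assert alloc[0] >= alloc[1] >= alloc[2]

    def test_never_exceeds_eligibility(self):
        for n in range(0, 11):
            alloc = allocate_proportional(np.array([1, 9]), n)
            assert alloc.sum() == n
            assert (alloc <= np.array([1, 9])).all()

    def test_overdraw_raises(self):
        with pytest.raises(ValueError):
            allocate_proportional(np.array([2, 2]), 5)


class TestGeneratePseudoAbsences:
    def _records(self):
        return pd.DataFrame(
            [rec("Ammonia tepida", 0.5, 3.5), rec("Ammonia tepida", 1.5, 3.5)]
        )

    def test_disjoint_and_correct_counts(self, small_stack):
        pa = generate_pseudo_absences(
            "Ammonia tepida", self._records(), small_stack, n_absences=5, n_strata=2, seed=3
        )
        assert len(pa.presence_cells) == 2
        assert len(pa.absence_cells) == 5
        assert not set(pa.presence_cells) & set(pa.absence_cells)
        assert pa.X.shape == (7, 3)
        assert pa.y.tolist() == [1, 1, 0, 0, 0, 0, 0]

    def test_deterministic_under_seed(self, small_stack):
        a = generate_pseudo_absences("Ammonia tepida", self._records(), small_stack, 5, seed=7)
        b = generate_pseudo_absences("Ammonia tepida", self._records(), small_stack, 5, seed=7)
        assert a.absence_cells == b.absence_cells
        np.testing.assert_array_equal(a.X, b.X)

    def test_buffer_excludes_neighbourhood(self, small_stack):
        records = pd.DataFrame([rec("Ammonia tepida", 1.5, 2.5)])  # cell (1, 1)
        pa = generate_pseudo_absences(
            "Ammonia tepida", records, small_stack, n_absences=4, buffer_cells=1, seed=0
        )
        for r, c in pa.absence_cells:
            assert max(abs(r - 1), abs(c - 1)) > 1

    def test_X_matches_layer_values(self, small_stack):
        pa = generate_pseudo_absences("Ammonia tepida", self._records(), small_stack, 3, seed=1)
        arr = small_stack.to_array()  # (n_layers, rows, cols)
        for i, (r, c) in enumerate(pa.cells):
            np.testing.assert_allclose(pa.X[i], arr[:, r, c])

    def test_shortfall_raises_with_count(self, small_stack):
        with pytest.raises(ValueError, match="shortfall"):
            generate_pseudo_absences(
                "Ammonia tepida", self._records(), small_stack, n_absences=15, seed=0
            )

    def test_stratification_spreads_draws(self):
        from stacksdm.envgrid import EnvLayer, EnvStack, GridSpec

        spec = GridSpec(20, 20, 1.0, 0.0, 20.0)
        stack = EnvStack([EnvLayer("x", spec, np.zeros((20, 20)))])
        records = pd.DataFrame([rec("Ammonia tepida", 0.5, 19.5)])
        pa = generate_pseudo_absences(
            "Ammonia tepida", records, stack, n_absences=100, n_strata=2, seed=5
        )
        # 4 strata of ~100 cells each: each must receive about a quarter
        quad = [0, 0, 0, 0]
        for r, c in pa.absence_cells:
            quad[(r >= 10) * 2 + (c >= 10)] += 1
        assert min(quad) >= 20


class TestPresenceCells:
    def test_dedup_and_order(self, grid4x4):
        records = pd.DataFrame(
            [
                rec("Ammonia tepida", 0.5, 3.5),
                rec("Ammonia tepida", 0.6, 3.6),  # same cell
                rec("Ammonia tepida", 2.5, 1.5),
                rec("Bolivina striatula", 1.5, 1.5),
            ]
        )
        cells = presence_cells_for(records, "Ammonia tepida", grid4x4)
        assert cells == [(0, 0), (2, 2)]


class TestSummarizeComposition:
    def test_simple_shares(self):
        taxonomy = pd.DataFrame(
            {
                "species": ["A a", "B b", "C c", "D d"],
                "genus": ["A", "B", "C", "D"],
                "family": ["f1", "f1", "f2", "f2"],
                "superfamily": ["sf"] * 4,
                "order": ["O1", "O1", "O1", "O2"],
                "wall_type": ["hyaline", "hyaline", "porcelaneous", "agglutinated"],
            }
        )
        records = pd.DataFrame({"taxon": taxonomy["species"], "lon": 0, "lat": 0,
                                "depth_m": -1, "source_id": "s"})
        out = summarize_composition(records, taxonomy)
        orders = out[out["rank"] == "order"].set_index("group")
        assert orders.loc["O1", "n_species"] == 3
        assert orders.loc["O1", "share_pct"] == 75.0
        assert orders.loc["O2", "share_pct"] == 25.0
        for rank in ("order", "genus", "wall_type"):
            assert out[out["rank"] == rank]["n_species"].sum() == 4

    def test_half_up_rounding(self):
        # 1/8 = 12.5% must round to 12.5, 3/8 = 37.5; and 0.125*3 species
        taxonomy = pd.DataFrame(
            {
                "species": [f"G{i} s{i}" for i in range(8)],
                "genus": [f"G{i}" for i in range(8)],
                "family": ["f"] * 8,
                "superfamily": ["sf"] * 8,
                "order": ["O1"] * 1 + ["O2"] * 7,
                "wall_type": ["hyaline"] * 8,
            }
        )
        records = pd.DataFrame({"taxon": taxonomy["species"], "lon": 0, "lat": 0,
                                "depth_m": -1, "source_id": "s"})
        out = summarize_composition(records, taxonomy)
        orders = out[out["rank"] == "order"].set_index("group")
        assert orders.loc["O1", "share_pct"] == 12.5

    def test_missing_taxonomy_raises(self):
        taxonomy = pd.DataFrame(
            {"species": ["A a"], "genus": ["A"], "family": ["f"], "superfamily": ["sf"],
             "order": ["O"], "wall_type": ["hyaline"]}
        )
        records = pd.DataFrame({"taxon": ["A a", "Z z"], "lon": 0, "lat": 0,
                                "depth_m": -1, "source_id": "s"})
        with pytest.raises(ValueError, match="Z z"):
            summarize_composition(records, taxonomy)
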