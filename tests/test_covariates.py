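"""Derived covariates: rasterization, richness, insularity, diversity,
climate stability, majority labels and DD reclassification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon, box

import threatgrid as tg
from threatgrid.covariates import percentage_change


def flat_world(rows, cols, land_mask=None, area=100.0):
    """Minimal hand-built WorldGrid for geometry tests."""
    is_land = (
        np.ones((rows, cols), dtype=bool) if land_mask is None else land_mask
    )
    lab = np.where(is_land, 0, -1)
    return tg.WorldGrid(
        is_land=is_land,
        landmass_id=lab.copy(),
        ecoregion_id=lab.copy(),
        region_id=lab.copy(),
        cell_area_km2=area,
    )


class TestRasterizeRanges:
    def test_sliver_counts_as_presence(self):
        w = flat_world(2, 2)
        # covers ~1% of cell (0, 0) only
        geoms = pd.DataFrame(
            {"species_id": ["sp1"], "geometry": [box(0.0, 0.0, 0.1, 0.1)]}
        )
        presence = tg.rasterize_ranges(geoms, w)
        assert presence["cell_id"].tolist() == [0]

    def test_rectangle_spanning_four_cells(self):
        w = flat_world(3, 3)
        geoms = pd.DataFrame(
            {"species_id": ["sp1"], "geometry": [box(0.5, 0.5, 1.5, 1.5)]}
        )
        presence = tg.rasterize_ranges(geoms, w)
        # brute-force oracle: intersect against each cell rectangle
        expected = []
        for r in range(3):
            for c in range(3):
                if box(c, r, c + 1, r + 1).intersects(box(0.5, 0.5, 1.5, 1.5)):
                    expected.append(r * 3 + c)
        assert sorted(presence["cell_id"]) == sorted(expected)
        assert len(presence) == 4

    def test_boundary_touch_counts(self):
        w = flat_world(1, 2)
        geoms = pd.DataFrame(
            {"species_id": ["sp1"], "geometry": [box(0.0, 0.0, 1.0, 1.0)]}
        )
        presence = tg.rasterize_ranges(geoms, w)
        assert sorted(presence["cell_id"]) == [0, 1]

    def test_empty_input(self):
        w = flat_world(2, 2)
        geoms = pd.DataFrame({"species_id": [], "geometry": []})
        assert tg.rasterize_ranges(geoms, w).empty

    def test_invalid_geometry_skipped(self, caplog):
        w = flat_world(2, 2)
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        geoms = pd.DataFrame(
            {"species_id": ["bad", "good"], "geometry": [bowtie, Point(0.5, 0.5).buffer(0.2)]}
        )
        presence = tg.rasterize_ranges(geoms, w)
        assert set(presence["species_id"]) == {"good"}

    def test_presence_filter(self):
        w = flat_world(2, 2)
        g = box(0, 0, 2, 2)
        geoms = pd.DataFrame(
            {
                "species_id": ["keep", "vagrant"],
                "geometry": [g, g],
                "native": [True, True],
                "extant": [True, True],
                "breeding_or_resident": [True, False],
            }
        )
        presence = tg.rasterize_ranges(geoms, w)
        assert set(presence["species_id"]) == {"keep"}

    def test_sea_cells_excluded(self):
        mask = np.array([[True, False]])
        w = flat_world(1, 2, land_mask=mask)
        geoms = pd.DataFrame(
            {"species_id": ["sp1"], "geometry": [box(0, 0, 2, 1)]}
        )
        presence = tg.rasterize_ranges(geoms, w)
        assert presence["cell_id"].tolist() == [0]


class TestRichness:
    def test_status_counting(self):
        presence = pd.DataFrame(
            {
                "species_id": ["a", "b", "c", "d"],
                "cell_id": [0, 0, 0, 0],
                "status": ["LC", "VU", "CR", "DD"],
            }
        )
        out = tg.richness(presence)
        row = out[out["taxon"] == "combined"].iloc[0]
        assert (row["total_richness"], row["threatened_richness"], row["dd_richness"]) == (4, 2, 1)

    def test_no_threatened_gives_zero_layer(self):
        presence = pd.DataFrame(
            {
                "species_id": list("abc"),
                "cell_id": [0, 1, 2],
                "status": ["LC", "NT", "DD"],
            }
        )
        assert (tg.richness(presence)["threatened_richness"] == 0).all()

    def test_unknown_status_rejected(self):
        presence = pd.DataFrame(
            {"species_id": ["a"], "cell_id": [0], "status": ["EX"]}
        )
        with pytest.raises(ValueError, match="EX"):
            tg.richness(presence)

    def test_against_hash_count_oracle(self, rng):
        n_species, n_cells = 50, 100
        statuses = np.array(["LC", "NT", "VU", "EN", "CR", "DD"])
        rows = []
        status_of = {}
        for s in range(n_species):
            status_of[s] = rng.choice(statuses)
            for c in rng.choice(n_cells, size=rng.integers(1, 30), replace=False):
                rows.append({"species_id": s, "cell_id": int(c), "status": status_of[s]})
        presence = pd.DataFrame(rows)
        out = tg.richness(presence, per_taxon=False).set_index("cell_id")
        # independent tally
        oracle = {}
        for rec in presence.drop_duplicates(["species_id", "cell_id"]).itertuples():
            t, th, dd = oracle.get(rec.cell_id, (0, 0, 0))
            oracle[rec.cell_id] = (
                t + 1,
                th + (rec.status in {"VU", "EN", "CR"}),
                dd + (rec.status == "DD"),
            )
        for cell, (t, th, dd) in oracle.items():
            row = out.loc[cell]
            assert (row["total_richness"], row["threatened_richness"], row["dd_richness"]) == (t, th, dd)


class TestInsularity:
    def test_isolated_cell(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        w = flat_world(3, 3, land_mask=mask, area=3000.0)
        ins = tg.insularity(w)
        assert ins.loc[4] == 3000.0

    def test_component_additivity(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, :] = True  # one 3-cell component
        w = flat_world(3, 3, land_mask=mask, area=3000.0)
        ins = tg.insularity(w)
        assert (ins == 9000.0).all() and len(ins) == 3

    def test_matches_flood_fill_oracle(self, rng):
        mask = rng.random((30, 30)) < 0.4
        w = flat_world(30, 30, land_mask=mask, area=10.0)
        ins = tg.insularity(w)

        # independent BFS flood fill with 8-connectivity
        visited = np.zeros_like(mask)
        comp_area = np.full(mask.shape, np.nan)
        for r0 in range(30):
            for c0 in range(30):
                if mask[r0, c0] and not visited[r0, c0]:
                    stack, comp = [(r0, c0)], []
                    visited[r0, c0] = True
                    while stack:
                        r, c = stack.pop()
                        comp.append((r, c))
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                rr, cc = r + dr, c + dc
                                if (
                                    0 <= rr < 30
                                    and 0 <= cc < 30
                                    and mask[rr, cc]
                                    and not visited[rr, cc]
                                ):
                                    visited[rr, cc] = True
                                    stack.append((rr, cc))
                    for r, c in comp:
                        comp_area[r, c] = len(comp) * 10.0
        for cell_id, value in ins.items():
            assert value == comp_area[cell_id // 30, cell_id % 30]

    def test_constant_within_components(self, world):
        ins = tg.insularity(world)
        lm = pd.Series(
            world.landmass_id.ravel()[ins.index], index=ins.index
        )
        assert (ins.groupby(lm).nunique() == 1).all()


class TestShannonDiversity:
    def test_single_class_zero(self):
        assert tg.shannon_diversity([1.0]) == 0.0

    def test_uniform_four_classes(self):
        assert tg.shannon_diversity([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)

    def test_direct_evaluation(self):
        p = np.array([0.5, 0.25, 0.25])
        expected = -(p * np.log(p)).sum()
        assert tg.shannon_diversity(p) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_zero_padding_invariance(self):
        assert tg.shannon_diversity([0.5, 0.5, 0.0, 0.0]) == tg.shannon_diversity(
            [0.5, 0.5]
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            tg.shannon_diversity([0.5, -0.1])

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            tg.shannon_diversity([0.0, 0.0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=2, max_size=8)
    )
    def test_uniform_is_maximal(self, fractions):
        k = len(fractions)
        assert tg.shannon_diversity(fractions) <= np.log(k) + 1e-12


def make_stack(values):
    """values: dict cell -> [(T, P), ...] with equal step counts."""
    rows = []
    for cell, series in values.items():
        for t, (temp, precip) in enumerate(series):
            rows.append(
                {"cell_id": cell, "time_step": t, "temperature": temp, "precipitation": precip}
            )
    return pd.DataFrame(rows)


class TestClimateStability:
    def test_constant_climate_is_zero(self):
        stack = make_stack({0: [(5, 50)] * 4, 1: [(9, 10)] * 4})
        out = tg.climate_stability(stack)
        assert out.loc[0] == 0.0 and out.loc[1] == 0.0

    def test_pythagorean_transition(self):
        # 9 cells, 2 steps, engineered so the pooled z-transform leaves
        # cell 0 with (dT_z, dP_z) = (3, 4) -> distance 5
        y = np.sqrt(13.5 / 16.0)  # temperature filler: pooled var exactly 1
        p = np.sqrt(10.0) / 4.0  # precipitation filler, same construction
        cells = {0: [(-1.5, -2.0), (1.5, 2.0)]}
        for i in range(1, 9):
            sign = 1.0 if i % 2 else -1.0
            cells[i] = [(sign * y, sign * p)] * 2
        stack = make_stack(cells)
        out = tg.climate_stability(stack)
        assert out.loc[0] == pytest.approx(5.0, abs=1e-12)
        assert out.drop(0).abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        stack = make_stack(
            {
                c: [(rng.normal(), rng.normal(10, 3)) for _ in range(5)]
                for c in range(12)
            }
        )
        out = tg.climate_stability(stack)
        # naive per-transition loop with the same pooled z-transform
        t_mean, t_sd = stack["temperature"].mean(), stack["temperature"].std(ddof=0)
        p_mean, p_sd = stack["precipitation"].mean(), stack["precipitation"].std(ddof=0)
        for cell in range(12):
            sub = stack[stack["cell_id"] == cell].sort_values("time_step")
            tz = (sub["temperature"].to_numpy() - t_mean) / t_sd
            pz = (sub["precipitation"].to_numpy() - p_mean) / p_sd
            dists = [
                np.hypot(tz[i + 1] - tz[i], pz[i + 1] - pz[i])
                for i in range(len(tz) - 1)
            ]
            assert out.loc[cell] == pytest.approx(np.mean(dists), abs=1e-12)

    def test_symmetry_in_t_and_p(self, rng):
        stack = make_stack(
            {c: [(rng.normal(), rng.normal()) for _ in range(3)] for c in range(5)}
        )
        swapped = stack.rename(
            columns={"temperature": "precipitation", "precipitation": "temperature"}
        )
        pd.testing.assert_series_equal(
            tg.climate_stability(stack), tg.climate_stability(swapped)
        )

    def test_zero_variance_rejected(self):
        stack = make_stack({0: [(1, 10), (1, 20)], 1: [(1, 30), (1, 40)]})
        with pytest.raises(ValueError, match="variance"):
            tg.climate_stability(stack)

    def test_single_step_rejected(self):
        stack = make_stack({0: [(1, 2)]})
        with pytest.raises(ValueError, match="two time steps"):
            tg.climate_stability(stack)


class TestMajorityLabel:
    def test_greatest_coverage_wins(self):
        cov = pd.DataFrame({"A": [0.7], "B": [0.3]})
        assert tg.majority_label(cov).iloc[0] == "A"

    def test_tie_breaks_to_smallest_label(self):
        cov = pd.DataFrame({"B": [0.5], "A": [0.5]})
        assert tg.majority_label(cov).iloc[0] == "A"

    def test_all_zero_unlabelled(self):
        cov = pd.DataFrame({"A": [0.0], "B": [0.0]})
        assert tg.majority_label(cov).isna().iloc[0]

    def test_matches_argmax_oracle(self, rng):
        cov = pd.DataFrame(
            rng.random((100, 4)), columns=["r0", "r1", "r2", "r3"]
        )
        out = tg.majority_label(cov)
        expected = cov.columns[cov.to_numpy().argmax(axis=1)]
        assert (out.to_numpy() == expected.to_numpy()).all()


class TestReclassifyDD:
    def layer(self, n=1, dd=7, threatened=10):
        return pd.DataFrame(
            {
                "cell_id": range(n),
                "total_richness": [100] * n,
                "threatened_richness": [threatened] * n,
                "dd_richness": [dd] * n,
            }
        )

    def test_zero_fraction_is_identity(self):
        layer = self.layer()
        out = tg.reclassify_dd(layer, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, layer)

    def test_full_fraction_adds_all_dd(self):
        out = tg.reclassify_dd(self.layer(), 1.0, seed=1)
        assert out["threatened_richness"].iloc[0] == 17
        assert out["total_richness"].iloc[0] == 100

    def test_half_fraction_binomial_mean(self):
        layer = self.layer(n=10_000, dd=10)
        out = tg.reclassify_dd(layer, 0.5, seed=1)
        added = (out["threatened_richness"] - layer["threatened_richness"]).mean()
        assert added == pytest.approx(5.0, abs=0.1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tg.reclassify_dd(self.layer(), 1.5, seed=1)

    def test_reproducible(self):
        layer = self.layer(n=100)
        a = tg.reclassify_dd(layer, 0.5, seed=9)
        b = tg.reclassify_dd(layer, 0.5, seed=9)
        pd.testing.assert_frame_equal(a, b)


def test_percentage_change_basic():
    out = percentage_change([50.0, 0.0], [75.0, 10.0])
    assert out[0] == 50.0 and np.isnan(out[1])
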