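"""Zone assignment, density tables, and the Kruskal–Wallis/Dunn statistics."""
import numpy as np
import pandas as pd
import pytest

import plaqueniche as pn
from plaqueniche.zones import classify_distance


class TestZoneBoundaries:
    @pytest.mark.parametrize(
        "d,zone",
        [
            (0.0, "inside"),
            (0.001, "adjacent"),
            (69.0, "adjacent"),  # closed upper bound
            (69.0001, "outside"),
            (np.sqrt(60.0 ** 2 + 40.0 ** 2), "outside"),  # 72.11 µm
        ],
    )
    def test_boundary_semantics(self, d, zone):
        assert classify_distance(np.array([d]), 69.0)[0] == zone

    def test_assignment_against_brute_force(self, unit_scale):
        rng = np.random.default_rng(13)
        mask = rng.random((32, 32)) > 0.97
        mask[5, 5] = True
        field = pn.field_from_mask(mask, unit_scale)
        pts = pd.DataFrame(
            {
                "x": rng.uniform(0, 31, 300),
                "y": rng.uniform(0, 31, 300),
                "gene": "G",
            }
        )
        asg = pn.assign_zones(field, pts, zone_radius=8.0)
        # brute force via nearest-pixel rounding (the documented convention)
        rr = np.rint(pts["y"]).astype(int)
        cc = np.rint(pts["x"]).astype(int)
        fg = np.argwhere(mask)
        for i in range(len(pts)):
            dref = np.sqrt(((fg - (rr[i], cc[i])) ** 2).sum(axis=1)).min()
            expect = "inside" if dref == 0 else ("adjacent" if dref <= 8 else "outside")
            assert asg.loc[i, "zone"] == expect

    def test_no_plaques_all_outside(self, unit_scale):
        field = pn.field_from_mask(np.zeros((16, 16), bool), unit_scale)
        pts = pd.DataFrame({"x": [2.0, 8.0], "y": [3.0, 9.0], "gene": "G"})
        asg = pn.assign_zones(field, pts)
        assert (asg["zone"] == "outside").all()


class TestZoneAreas:
    def test_partition_sums_to_window(self, small_field):
        areas = pn.zone_areas(small_field)
        window = small_field.label_mask.size * small_field.scale.pixel_area_um2
        assert areas.sum() == pytest.approx(window, rel=1e-12)

    def test_single_pixel_plaque_adjacent_area_matches_count(self, unit_scale):
        mask = np.zeros((200, 200), bool)
        mask[100, 100] = True
        field = pn.field_from_mask(mask, unit_scale)
        areas = pn.zone_areas(field, zone_radius=69.0)
        expect = int(((field.distance > 0) & (field.distance <= 69.0)).sum())
        assert areas["adjacent"] == pytest.approx(expect * 1.0)
        assert areas["inside"] == pytest.approx(1.0)

    def test_no_plaques_everything_outside(self, unit_scale):
        field = pn.field_from_mask(np.zeros((16, 16), bool), unit_scale)
        areas = pn.zone_areas(field)
        assert areas["inside"] == 0 and areas["adjacent"] == 0
        assert areas["outside"] == pytest.approx(256.0)

    def test_per_plaque_partition_sums_to_window(self, small_field):
        pp = pn.per_plaque_zone_areas(small_field)
        window = small_field.label_mask.size * small_field.scale.pixel_area_um2
        assert pp["area_um2"].sum() == pytest.approx(window, rel=1e-12)


class TestZoneDensity:
    def test_density_is_count_over_area(self):
        asg = pd.DataFrame(
            {
                "gene": ["G"] * 10,
                "zone": ["adjacent"] * 10,
                "nearest_plaque_id": [1] * 10,
                "in_bounds": [True] * 10,
            }
        )
        areas = pd.Series({"inside": 10.0, "adjacent": 50.0, "outside": 100.0})
        dens = pn.zone_density(asg, areas)
        row = dens[(dens.gene == "G") & (dens.zone == "adjacent")].iloc[0]
        assert row["density"] == pytest.approx(0.2)
        inside = dens[(dens.gene == "G") & (dens.zone == "inside")].iloc[0]
        assert inside["transcript_count"] == 0

    def test_counts_conserved_over_zones(self, small_field):
        specs = [
            pn.EnrichmentSpec("A", 0.005, 3.0, 3.0),
            pn.EnrichmentSpec("B", 0.005),
        ]
        tbl, _ = pn.make_transcripts(small_field, specs, seed=21)
        asg = pn.assign_zones(small_field, tbl)
        dens = pn.zone_density(asg, pn.zone_areas(small_field))
        for g in ("A", "B"):
            total = int((tbl["gene"] == g).sum())
            assert dens.loc[dens.gene == g, "transcript_count"].sum() == total

    def test_union_density_identity(self, small_field):
        tbl, _ = pn.make_transcripts(
            small_field, [pn.EnrichmentSpec("A", 0.01, 2.0, 2.0)], seed=5
        )
        asg = pn.assign_zones(small_field, tbl)
        areas = pn.zone_areas(small_field)
        dens = pn.zone_density(asg, areas)
        # weighted average of zone densities = total / window area
        pooled = (dens["density"] * dens["zone_area_um2"]).sum() / areas.sum()
        assert pooled == pytest.approx(len(tbl) / areas.sum(), rel=1e-12)

    def test_zero_area_zone_flagged_degenerate(self, unit_scale):
        field = pn.field_from_mask(np.zeros((16, 16), bool), unit_scale)
        pts = pd.DataFrame({"x": [2.0], "y": [3.0], "gene": "G"})
        asg = pn.assign_zones(field, pts)
        dens = pn.zone_density(asg, pn.zone_areas(field))
        inside = dens[dens.zone == "inside"].iloc[0]
        assert inside["degenerate"] and np.isnan(inside["density"])

    def test_planted_fold_recovered_in_density_ratio(self, small_field):
        tbl, _ = pn.make_transcripts(
            small_field, [pn.EnrichmentSpec("G", 0.005, 5.0, 5.0)], seed=17
        )
        asg = pn.assign_zones(small_field, tbl)
        dens = pn.zone_density(asg, pn.zone_areas(small_field)).set_index("zone")
        ratio = dens.loc["adjacent", "density"] / dens.loc["outside", "density"]
        assert 3.5 <= ratio <= 6.5

    def test_null_gene_has_flat_densities(self, small_field):
        # fold 1 everywhere: max pairwise ratio stays near 1 once every zone
        # holds a few hundred points (smallest zone here is ~1.5e3 µm²)
        tbl, _ = pn.make_transcripts(
            small_field, [pn.EnrichmentSpec("G", 0.25)], seed=29
        )
        asg = pn.assign_zones(small_field, tbl)
        dens = pn.zone_density(asg, pn.zone_areas(small_field)).set_index("zone")
        d = dens["density"]
        assert d.max() / d.min() <= 1.3


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        omni, _ = pn.kruskal_dunn({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert omni["H"] == pytest.approx(0.0)
        assert omni["p"] == pytest.approx(1.0)

    def test_hand_computed_h(self):
        omni, pw = pn.kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert omni["H"] == pytest.approx(7.2)
        assert len(pw) == 3
        assert (pw["p_adj"] >= pw["p_raw"] - 1e-15).all()

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="'b'"):
            pn.kruskal_dunn({"a": [1, 2], "b": []})

    def test_bonferroni_at_least_as_conservative_as_holm(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i, 1, 10) for i, k in enumerate("abc")}
        _, holm = pn.kruskal_dunn(groups, adjust="holm")
        _, bonf = pn.kruskal_dunn(groups, adjust="bonferroni")
        assert (bonf["p_adj"] >= holm["p_adj"] - 1e-15).all()

    def test_null_rejection_rate_near_alpha(self):
        # same-distribution groups: type-I error close to nominal
        rng = np.random.default_rng(19)
        rej = 0
        n = 500
        for _ in range(n):
            groups = {k: rng.normal(0, 1, 12) for k in "abc"}
            omni, _ = pn.kruskal_dunn(groups, pairwise=False)
            rej += omni["p"] < 0.05
        assert 0.02 <= rej / n <= 0.08  # wide band for 500 reps
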