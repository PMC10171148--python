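import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crowdcontact.aggregation import (
    OUTPUT_COLUMNS,
    aggregate,
    cluster_poi_overlaps,
    fit_cluster_sizes,
    overlap_fraction,
    read_outputs,
    write_outputs,
)


class TestOverlapFraction:
    def test_bbox_fully_inside_disc(self):
        frac, area = overlap_fraction((-5, 5, -5, 5), (0.0, 0.0), 100.0)
        assert frac == pytest.approx(1.0, rel=1e-12)
        assert area == pytest.approx(100.0, rel=1e-12)

    def test_disjoint(self):
        frac, area = overlap_fraction((0, 10, 0, 10), (500.0, 0.0), 20.0)
        assert frac == 0.0 and area == 0.0

    def test_box_on_disc_edge_matches_sampling_oracle(self):
        # 20x20 m box centered on the rim of a 100 m disc
        from scipy.stats import qmc

        frac, _ = overlap_fraction((90, 110, -10, 10), (0.0, 0.0), 100.0)
        pts = qmc.Sobol(d=2, scramble=True, seed=4).random_base2(m=20)
        xs = 90 + pts[:, 0] * 20
        ys = -10 + pts[:, 1] * 20
        mc = float((xs**2 + ys**2 <= 100.0**2).mean())
        assert frac == pytest.approx(mc, abs=1e-3)

    def test_degenerate_bbox_point_in_disc(self):
        assert overlap_fraction((5, 5, 3, 3), (0.0, 0.0), 10.0)[0] == 1.0
        assert overlap_fraction((50, 50, 3, 3), (0.0, 0.0), 10.0)[0] == 0.0

    def test_fraction_always_in_unit_interval(self, rng):
        for _ in range(100):
            c = rng.uniform(-50, 50, 2)
            r = rng.uniform(0.1, 60)
            x0, y0 = rng.uniform(-50, 20, 2)
            frac, area = overlap_fraction(
                (x0, x0 + rng.uniform(0.1, 60), y0, y0 + rng.uniform(0.1, 60)),
                (c[0], c[1]),
                r,
            )
            assert 0.0 <= frac <= 1.0 and area >= 0.0


def _metrics_row(cid, date, x0, x1, y0, y1, sci, t_u=30.0, cbg_ix=0, origin=(28.0, -81.5)):
    return {
        "cluster_id": cid,
        "date": date,
        "cbg_ix": cbg_ix,
        "x_min": x0,
        "x_max": x1,
        "y_min": y0,
        "y_max": y1,
        "origin_lat": origin[0],
        "origin_lon": origin[1],
        "sci": sci,
        "t_u": t_u,
        "dropped": False,
    }


class TestAggregate:
    def test_cluster_fully_inside_one_poi(self, tiny_world):
        from crowdcontact.geometry import project

        poi = tiny_world.pois[0]
        lat0, lon0 = 28.0, -81.5
        px, py = project(poi.lat, poi.lon, lat0, lon0)
        m = pd.DataFrame(
            [_metrics_row("c1", 18262, px - 5, px + 5, py - 5, py + 5, sci=1000.0)]
        )
        overlaps = cluster_poi_overlaps(m, tiny_world)
        out = aggregate(m, overlaps, tiny_world)
        assert len(out) == 1
        row = out.iloc[0]
        assert row.SCI == pytest.approx(1000.0, rel=1e-9)
        assert row.POI_Type == poi.type and row.ZCTA5 == poi.zcta
        assert row.Number_of_Clusters == 1
        assert row.Cluster_Size_Mean == pytest.approx(10.0, rel=1e-9)  # sqrt(100)
        assert row.Cluster_Size_Variance == 0.0
        assert row.Avergage_Time == pytest.approx(30.0)

    def test_split_cluster_conserves_sci(self, tiny_world):
        # a bbox overlapping two same-type POIs: the summed rollup SCI over
        # both records equals fraction-weighted cluster SCI
        import dataclasses

        from crowdcontact.geometry import project
        from crowdcontact.world import World

        poi_a = tiny_world.pois[0]
        poi_b = dataclasses.replace(
            poi_a, id="poiX", lat=poi_a.lat + 0.0008, zcta=poi_a.zcta
        )
        world2 = World(
            tiny_world.cbgs,
            tiny_world.pois + [poi_b],
            tiny_world.zctas,
            tiny_world.users,
            tiny_world.default_utc_offset_min,
            tiny_world.region_name,
        )
        lat0, lon0 = 28.0, -81.5
        ax, ay = project(poi_a.lat, poi_a.lon, lat0, lon0)
        bx, by = project(poi_b.lat, poi_b.lon, lat0, lon0)
        # bbox spanning both POI discs entirely
        m = pd.DataFrame(
            [
                _metrics_row(
                    "c1",
                    18262,
                    min(ax, bx) - 2 * poi_a.radius_m,
                    max(ax, bx) + 2 * poi_a.radius_m,
                    min(ay, by) - 2 * poi_a.radius_m,
                    max(ay, by) + 2 * poi_a.radius_m,
                    sci=1000.0,
                )
            ]
        )
        overlaps = cluster_poi_overlaps(m, world2)
        assert len(overlaps) == 2
        out = aggregate(m, overlaps, world2)
        expected = float((overlaps["fraction"] * 1000.0).sum())
        assert out["SCI"].sum() == pytest.approx(expected, rel=1e-9)
        # both discs fully inside the bbox: conservation of disc areas
        bbox_area = float(
            (m.x_max[0] - m.x_min[0]) * (m.y_max[0] - m.y_min[0])
        )
        disc_area = 2 * np.pi * poi_a.radius_m**2
        assert expected == pytest.approx(1000.0 * disc_area / bbox_area, rel=1e-9)

    def test_rollup_sci_never_exceeds_cluster_total(self, small_run):
        total_cluster = small_run.metrics.loc[~small_run.metrics.dropped, "sci"].sum()
        assert small_run.poi_day["SCI"].sum() <= total_cluster + 1e-9

    def test_dropped_clusters_do_not_contribute(self, tiny_world):
        m = pd.DataFrame([_metrics_row("c1", 18262, -5, 5, -5, 5, sci=0.0)])
        m["dropped"] = True
        overlaps = cluster_poi_overlaps(m, tiny_world)
        assert len(aggregate(m, overlaps, tiny_world)) == 0


class TestFitClusterSizes:
    def test_f_distribution_self_consistency(self):
        sizes = stats.f.rvs(8, 21, scale=12.0, size=5000, random_state=11)
        report = fit_cluster_sizes(sizes)
        assert report.iloc[0]["family"] == "f"

    def test_lognormal_beats_chi_square(self):
        sizes = stats.lognorm.rvs(0.8, scale=20.0, size=5000, random_state=12)
        report = fit_cluster_sizes(sizes, families=["lognorm", "chi2"])
        ks = report.set_index("family")["ks_statistic"]
        assert ks["lognorm"] < ks["chi2"]

    def test_constant_sizes_refused(self):
        with pytest.raises(ValueError):
            fit_cluster_sizes(np.full(100, 7.0))

    def test_too_few_sizes_refused(self):
        with pytest.raises(ValueError):
            fit_cluster_sizes(np.arange(1.0, 20.0))

    def test_non_positive_sizes_excluded(self):
        sizes = np.concatenate([stats.gamma.rvs(3, size=200, random_state=1), [-1, 0]])
        report = fit_cluster_sizes(sizes, families=["gamma"])
        assert len(report) == 1


class TestWriteOutputs:
    def test_published_layout_and_header(self, small_run, tmp_path):
        write_outputs(
            small_run.poi_day, small_run.world.pois, tmp_path, region="Florida"
        )
        daily = tmp_path / "Florida" / "20200102"
        assert daily.exists()  # second run date, named YYYYMMDD in the state folder
        header = daily.read_text().splitlines()[0]
        assert (
            header
            == "ZCTA5,POI_Type,Number_of_Clusters,Cluster_Size_Mean,Cluster_Size_Variance,Avergage_Time,SCI"
        )
        poi_csv = (tmp_path / "POI.csv").read_text().splitlines()
        assert poi_csv[0] == "POI_Type,POI_Subtype,Radius"
        assert any(row.split(",")[2] == "30" for row in poi_csv[1:])

    def test_round_trip(self, small_run, tmp_path):
        write_outputs(small_run.poi_day, small_run.world.pois, tmp_path, region="Florida")
        back = read_outputs(tmp_path, "Florida")
        orig = small_run.poi_day.reset_index(drop=True)
        assert list(back.columns) == ["date"] + OUTPUT_COLUMNS
        for col in ("SCI", "Cluster_Size_Mean", "Cluster_Size_Variance", "Avergage_Time"):
            np.testing.assert_allclose(back[col], orig[col], rtol=1e-9)
        assert (back["ZCTA5"] == orig["ZCTA5"]).all()

    def test_refuses_overwrite(self, small_run, tmp_path):
        write_outputs(small_run.poi_day, small_run.world.pois, tmp_path, region="Florida")
        with pytest.raises(FileExistsError):
            write_outputs(small_run.poi_day, small_run.world.pois, tmp_path, region="Florida")
        write_outputs(
            small_run.poi_day, small_run.world.pois, tmp_path, region="Florida", overwrite=True
        )
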