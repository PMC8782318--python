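import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichescreen import rasters_io as rio
from nichescreen.rasters_io import (
    GridSpec,
    Layer,
    OccurrenceSet,
    PredictorCollection,
    extract,
    haversine_km,
    read_layer,
    sample_background,
    thin,
    write_layer,
)


def make_layer(values, name="x", cell=0.5, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(
        n_rows=values.shape[0], n_cols=values.shape[1],
        x_origin=0.0, y_origin=0.0, cell_size=cell, nodata_value=nodata,
    )
    return Layer(name=name, grid=grid, values=np.ma.masked_values(values, nodata))


class TestGridSpec:
    def test_compatibility_ignores_nodata(self):
        a = GridSpec(3, 4, 0.0, 0.0, 0.5, nodata_value=-9999.0)
        b = GridSpec(3, 4, 0.0, 0.0, 0.5, nodata_value=-1.0)
        c = GridSpec(3, 4, 0.0, 0.0, 0.5 + 1e-6)
        assert a.compatible(b)
        assert not a.compatible(c)

    def test_locate_is_half_open_on_top_right(self):
        g = GridSpec(2, 2, 0.0, 0.0, 1.0)
        assert g.locate(0.0, 0.0) == (1, 0)       # lower-left corner included
        assert g.locate(0.999, 1.999) == (0, 0)   # just inside the top-left cell
        assert g.locate(2.0, 1.0) is None          # right edge excluded
        assert g.locate(1.0, 2.0) is None          # top edge excluded

    def test_cell_center_roundtrip(self):
        g = GridSpec(5, 7, -3.0, 10.0, 0.25)
        for row, col in [(0, 0), (4, 6), (2, 3)]:
            x, y = g.cell_center(row, col)
            assert g.locate(x, y) == (row, col)

    @pytest.mark.parametrize("kwargs", [
        dict(n_rows=0, n_cols=1, x_origin=0, y_origin=0, cell_size=1.0),
        dict(n_rows=1, n_cols=1, x_origin=0, y_origin=0, cell_size=0.0),
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)


class TestRasterRoundTrip:
    def test_ascii_nodata_mask(self, tmp_path):
        path = tmp_path / "t.asc"
        path.write_text(
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1.0 2.0\n-9999 4.0\n"
        )
        layer = read_layer(path)
        assert layer.n_masked == 1
        assert layer.values[1, 1] == 4.0
        assert bool(layer.mask[1, 0])

    def test_ascii_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(7, 5)).round(4)
        vals[2, 3] = -9999.0
        layer = make_layer(vals, name="r")
        p1 = tmp_path / "a.asc"
        write_layer(layer, p1, precision=10)
        back = read_layer(p1)
        assert np.array_equal(back.mask, layer.mask)
        assert np.allclose(back.values.filled(0), layer.values.filled(0))
        # a second round trip is bit-identical on disk
        p2 = tmp_path / "b.asc"
        write_layer(back, p2, precision=10)
        assert p1.read_text().split("\n", 6)[6] == p2.read_text().split("\n", 6)[6]

    def test_geotiff_and_ascii_encode_same_values(self, tmp_path):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, size=(10, 10)).astype(np.float32).astype(float)
        vals[0, 0] = -9999.0
        layer = make_layer(vals, name="f")
        write_layer(layer, tmp_path / "f.asc", precision=10)
        write_layer(layer, tmp_path / "f.tif")
        a = read_layer(tmp_path / "f.asc")
        t = read_layer(tmp_path / "f.tif")
        assert a.grid.compatible(t.grid)
        assert np.array_equal(a.mask, t.mask)
        assert np.allclose(a.values.filled(0), t.values.filled(0), atol=1e-6)

    @pytest.mark.parametrize("bad", [
        "ncols 2\nnrows 2\nxllcorner 0\ncellsize 1\n1 2\n3 4\n",   # missing yllcorner
        "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n1 2 3\n",  # wrong count
    ])
    def test_malformed_ascii_raises_format_error(self, tmp_path, bad):
        p = tmp_path / "bad.asc"
        p.write_text(bad)
        with pytest.raises(rio.RasterFormatError):
            read_layer(p)

    @given(
        nr=st.integers(min_value=2, max_value=8),
        nc=st.integers(min_value=2, max_value=8),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=15, deadline=None)
    def test_roundtrip_random_fields(self, nr, nc, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(nr, nc))
        layer = make_layer(vals)
        d = tmp_path_factory.mktemp("rt")
        for suffix in (".asc", ".tif"):
            write_layer(layer, d / f"x{suffix}", precision=12)
            back = read_layer(d / f"x{suffix}")
            assert np.allclose(back.values.filled(9), layer.values.filled(9), atol=1e-6)


class TestExtract:
    def make_collection(self, tmp_path, layers):
        for layer in layers:
            write_layer(layer, tmp_path / f"{layer.name}.asc", precision=10)
        return PredictorCollection.from_directory(tmp_path)

    def test_constant_layer(self, tmp_path):
        coll = self.make_collection(tmp_path, [
            make_layer(np.full((3, 3), 7.0), "c"),
            make_layer(np.zeros((3, 3)), "z"),
        ])
        coords = np.array([[0.25, 0.25], [1.0, 1.0], [1.2, 0.7]])
        vals, ok = extract(coll, ["c"], coords)
        assert ok.all()
        assert np.all(vals == 7.0)

    def test_cell_center_hits_exact_value(self, tmp_path):
        ramp = np.arange(9, dtype=float).reshape(3, 3)
        coll = self.make_collection(tmp_path, [
            make_layer(ramp, "ramp"), make_layer(ramp * 0, "zero"),
        ])
        x, y = coll.grid.cell_center(1, 2)
        vals, ok = extract(coll, ["ramp"], [[x, y]])
        assert vals[0, 0] == ramp[1, 2]

    def test_nodata_in_any_layer_flags_row(self, tmp_path):
        a = np.ones((3, 3))
        b = np.ones((3, 3)); b[0, 0] = -9999.0
        coll = self.make_collection(tmp_path, [make_layer(a, "a"), make_layer(b, "b")])
        x, y = coll.grid.cell_center(0, 0)
        vals, ok = extract(coll, ["a", "b"], [[x, y]])
        assert not ok[0]
        assert np.isnan(vals[0, 1])
        # row remains usable for a-only extraction
        _, ok_a = extract(coll, ["a"], [[x, y]])
        assert ok_a[0]

    def test_unknown_variable_raises(self, tmp_path):
        coll = self.make_collection(tmp_path, [
            make_layer(np.ones((2, 2)), "a"), make_layer(np.ones((2, 2)), "b"),
        ])
        with pytest.raises(KeyError):
            extract(coll, ["nope"], [[0.1, 0.1]])

    def test_agrees_with_manual_indexing(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=(3, 3))
        coll = self.make_collection(tmp_path, [
            make_layer(vals, "v"), make_layer(vals * 2, "w"),
        ])
        g = coll.grid
        coords = [g.cell_center(r, c) for r in range(3) for c in range(3)]
        out, ok = extract(coll, ["v", "w"], coords)
        expected = np.column_stack([vals.ravel(), (vals * 2).ravel()])
        assert np.allclose(out, expected)


class TestSampleBackground:
    def make_collection(self, tmp_path, layers):
        for layer in layers:
            write_layer(layer, tmp_path / f"{layer.name}.asc", precision=10)
        return PredictorCollection.from_directory(tmp_path)

    def test_exhaustive_draw_covers_every_cell(self, tmp_path):
        coll = self.make_collection(tmp_path, [
            make_layer(np.ones((10, 10)), "a"), make_layer(np.ones((10, 10)), "b"),
        ])
        coords = sample_background(coll, 100, seed=0)
        assert len({tuple(c) for c in np.round(coords, 9)}) == 100

    def test_seed_determinism(self, tmp_path):
        coll = self.make_collection(tmp_path, [
            make_layer(np.ones((6, 6)), "a"), make_layer(np.ones((6, 6)), "b"),
        ])
        assert np.array_equal(sample_background(coll, 10, 5), sample_background(coll, 10, 5))

    def test_all_samples_valid_when_half_grid_is_nodata(self, tmp_path):
        a = np.ones((10, 10)); a[:5, :] = -9999.0
        b = np.ones((10, 10)); b[:, :2] = -9999.0
        coll = self.make_collection(tmp_path, [make_layer(a, "a"), make_layer(b, "b")])
        coords = sample_background(coll, 40, seed=1)
        vals, ok = extract(coll, ["a", "b"], coords)
        assert ok.all()  # brute-force validity of every sample

    def test_capacity_error_reports_valid_count(self, tmp_path):
        a = np.full((3, 3), -9999.0); a[0, 0] = 1.0
        coll = self.make_collection(tmp_path, [make_layer(a, "a"), make_layer(a, "b")])
        with pytest.raises(rio.CapacityError, match="1 valid"):
            sample_background(coll, 5, seed=0)


class TestThin:
    def test_two_close_points_keep_one(self):
        occ = OccurrenceSet("sp", [[0.0, 0.0], [0.045, 0.0]])  # ~5 km apart
        out = thin(occ, 16.0, seed=0)
        assert len(out) == 1

    def test_collinear_chain_all_survivors_spaced(self):
        # points every ~10 km along a meridian; buffer 16 km
        lats = np.arange(0, 0.9, 0.09)
        occ = OccurrenceSet("sp", np.column_stack([np.zeros_like(lats), lats]))
        for seed in (0, 1, 2):
            out = thin(occ, 16.0, seed=seed)
            d = haversine_km(out.points, out.points)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 16.0  # O(n^2) oracle
            assert len(out) >= len(occ) // 2  # alternating retention

    def test_already_thinned_input_unchanged(self):
        lats = np.arange(0, 1.0, 0.2)  # ~22 km spacing
        occ = OccurrenceSet("sp", np.column_stack([np.zeros_like(lats), lats]))
        out = thin(occ, 16.0, seed=3)
        assert np.array_equal(np.sort(out.points, axis=0), np.sort(occ.points, axis=0))

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        occ = OccurrenceSet("sp", rng.uniform(0, 0.5, size=(40, 2)))
        a = thin(occ, 16.0, seed=9)
        b = thin(occ, 16.0, seed=9)
        assert np.array_equal(a.points, b.points)

    def test_empty_input_warns_and_returns_empty(self, caplog):
        out = thin(OccurrenceSet("sp", np.empty((0, 2))), 16.0, seed=0)
        assert len(out) == 0


class TestOccurrencesCsv:
    def test_read_dedupes_and_ignores_extra_columns(self, tmp_path, caplog):
        p = tmp_path / "occ.csv"
        p.write_text(
            "species,longitude,latitude,elevation\n"
            "sp,1.0,2.0,100\nsp,1.0,2.0,100\nsp,1.5,2.5,200\n"
        )
        occ = rio.read_occurrences(p)
        assert len(occ) == 2
        assert occ.species == "sp"

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("species,longitude\nsp,1.0\n")
        with pytest.raises(ValueError, match="latitude"):
            rio.read_occurrences(p)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            rio.read_occurrences(tmp_path / "nope.csv")

    def test_write_read_roundtrip(self, tmp_path):
        occ = OccurrenceSet("sp", [[1.25, -3.5], [0.0, 0.0]])
        rio.write_occurrences(occ, tmp_path / "o.csv")
        back = rio.read_occurrences(tmp_path / "o.csv")
        assert np.allclose(back.points, occ.points)
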