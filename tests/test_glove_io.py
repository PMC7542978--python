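import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitglove.errors import (
    ChannelLookupError,
    FormatError,
    ParseError,
    SizeError,
    ValidationError,
)
from gaitglove.glove_io import (
    HandPointSeries,
    SensorRun,
    default_layout,
    read_points,
    read_run,
    select_channels,
    trim_run,
    write_points,
    write_run,
)
from gaitglove.synthetic import simulate_trajectory


def make_run(layout, n_frames=1000, fill=500.0, rate=50.0):
    data = np.full((n_frames, len(layout.labels)), fill)
    return SensorRun(
        data=data,
        rate=rate,
        subject_id="S01",
        hand="left",
        run_index=2,
        layout=layout,
    )


class TestLayout:
    def test_29_unique_labels(self, layout):
        assert len(layout.labels) == 29
        assert len(set(layout.labels)) == 29

    def test_subset_sizes(self, layout):
        assert len(layout.relevant19) == 19
        assert len(layout.graph12) == 12
        assert set(layout.relevant19) <= set(layout.labels)
        assert set(layout.graph12) <= set(layout.relevant19)

    def test_relevant19_excludes_orientation_and_p4_p5(self, layout):
        excluded = set(layout.labels) - set(layout.relevant19)
        orientation = {l for l, r in layout.roles.items() if r == "orientation"}
        assert orientation <= excluded
        assert {"P4", "P5"} <= excluded
        assert len(excluded) == 10

    def test_graph12_composition(self, layout):
        roles = {layout.roles[l] for l in layout.graph12}
        assert roles == {
            "finger_bend_MCP",
            "finger_bend_PIP",
            "thumb_bend_MCP",
            "thumb_bend_IP",
            "palm_arch",
            "thumb_cross",
        }


class TestRunRoundTrip:
    def test_write_read_identity(self, tmp_path, layout, rng):
        data = rng.uniform(0, 1000, size=(50, 29))
        run = SensorRun(data, 50.0, "S07", "right", 3, layout)
        path = write_run(run, tmp_path / "run.tsv")
        back = read_run(path, layout)
        np.testing.assert_array_equal(back.data, run.data)
        assert back.subject_id == "S07"
        assert back.hand == "right"
        assert back.run_index == 3
        assert back.rate == 50.0

    def test_read_1000x29(self, tmp_path, layout):
        path = write_run(make_run(layout), tmp_path / "r.tsv")
        assert read_run(path, layout).n_frames == 1000

    def test_column_permutation_normalized(self, tmp_path, layout, rng):
        data = rng.uniform(0, 1000, size=(5, 29))
        run = SensorRun(data, 50.0, "S01", "left", 1, layout)
        path = write_run(run, tmp_path / "r.tsv")
        # permute data columns in the file
        lines = path.read_text().splitlines()
        hdr_i = next(i for i, l in enumerate(lines) if not l.startswith("#"))
        perm = list(range(29))[::-1]
        cols = lines[hdr_i].split("\t")
        lines[hdr_i] = "\t".join([cols[0]] + [cols[1 + j] for j in perm])
        for i in range(hdr_i + 1, len(lines)):
            cells = lines[i].split("\t")
            lines[i] = "\t".join([cells[0]] + [cells[1 + j] for j in perm])
        path.write_text("\n".join(lines) + "\n")
        back = read_run(path, layout)
        np.testing.assert_allclose(back.data, data)

    def test_out_of_range_amplitude_rejected(self, tmp_path, layout):
        run = make_run(layout, n_frames=3)
        path = write_run(run, tmp_path / "r.tsv")
        text = path.read_text().replace("500.0", "1001.0", 1)
        path.write_text(text)
        with pytest.raises(ValidationError):
            read_run(path, layout)

    def test_missing_channel_named(self, tmp_path, layout):
        run = make_run(layout, n_frames=3)
        path = write_run(run, tmp_path / "r.tsv")
        path.write_text(path.read_text().replace("Tcross", "Xcross"))
        with pytest.raises(FormatError, match="Tcross|Xcross"):
            read_run(path, layout)

    def test_non_numeric_cell_located(self, tmp_path, layout):
        run = make_run(layout, n_frames=3)
        path = write_run(run, tmp_path / "r.tsv")
        path.write_text(path.read_text().replace("500.0", "oops", 1))
        with pytest.raises(ParseError, match="row 1"):
            read_run(path, layout)

    @settings(max_examples=20, deadline=None)
    @given(
        st.integers(min_value=1, max_value=20),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_roundtrip_property(self, tmp_path_factory, n, seed):
        layout = default_layout()
        data = np.random.default_rng(seed).uniform(0, 1000, size=(n, 29))
        run = SensorRun(data, 50.0, "S01", "left", 1, layout)
        d = tmp_path_factory.mktemp("rt")
        back = read_run(write_run(run, d / "r.tsv"), layout)
        np.testing.assert_array_equal(back.data, run.data)


class TestTrim:
    def test_keeps_last_800_of_1000(self, layout, rng):
        data = rng.uniform(0, 1000, size=(1000, 29))
        run = SensorRun(data, 50.0, "S01", "left", 1, layout)
        trimmed = trim_run(run, 800)
        assert trimmed.n_frames == 800
        np.testing.assert_array_equal(trimmed.data, data[200:])

    def test_keep_all_is_identity(self, layout):
        run = make_run(layout, n_frames=10)
        np.testing.assert_array_equal(trim_run(run, 10).data, run.data)

    def test_constant_channel_still_constant(self, layout):
        run = make_run(layout, n_frames=10, fill=123.0)
        assert np.all(trim_run(run, 5).data == 123.0)

    def test_too_many_frames_rejected(self, layout):
        with pytest.raises(SizeError):
            trim_run(make_run(layout, n_frames=10), 11)


class TestSelectChannels:
    def test_relevant19(self, layout):
        run = make_run(layout)
        sel = select_channels(run, layout.relevant19)
        assert sel.data.shape[1] == 19
        assert sel.layout.labels == layout.relevant19

    def test_identity(self, layout):
        run = make_run(layout, n_frames=5)
        sel = select_channels(run, layout.labels)
        np.testing.assert_array_equal(sel.data, run.data)

    def test_graph12(self, layout):
        sel = select_channels(make_run(layout, 5), layout.graph12)
        assert sel.data.shape[1] == 12

    def test_unknown_channel(self, layout):
        with pytest.raises(ChannelLookupError):
            select_channels(make_run(layout, 5), ("nope",))

    def test_composition_equals_one_step(self, layout, rng):
        data = rng.uniform(0, 1000, size=(8, 29))
        run = SensorRun(data, 50.0, "S01", "left", 1, layout)
        two_step = select_channels(
            select_channels(run, layout.relevant19), layout.graph12
        )
        one_step = select_channels(run, layout.graph12)
        np.testing.assert_array_equal(two_step.data, one_step.data)
        assert two_step.layout.labels == one_step.layout.labels


class TestPoints:
    def test_roundtrip(self, tmp_path, rng):
        series = simulate_trajectory(n_frames=40, noise_mm=1.0, seed=3)
        path = write_points(series, tmp_path / "pts.tsv")
        back = read_points(path)
        np.testing.assert_array_equal(back.points, series.points)
        assert back.point_names == series.point_names
        assert back.rate == pytest.approx(series.rate)

    def test_100_frames(self, tmp_path):
        series = simulate_trajectory(n_frames=100, seed=0)
        back = read_points(write_points(series, tmp_path / "p.tsv"))
        assert back.n_frames == 100
        assert back.points.shape == (100, 23, 3)

    def test_wrong_column_count_rejected(self, tmp_path):
        series = simulate_trajectory(n_frames=5, seed=0)
        path = write_points(series, tmp_path / "p.tsv")
        lines = path.read_text().splitlines()
        hdr_i = next(i for i, l in enumerate(lines) if not l.startswith("#"))
        lines[hdr_i] = "\t".join(lines[hdr_i].split("\t")[:-3])
        for i in range(hdr_i + 1, len(lines)):
            lines[i] = "\t".join(lines[i].split("\t")[:-3])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError):
            read_points(path)

    def test_path_length_preserved_through_roundtrip(self, tmp_path):
        series = simulate_trajectory(n_frames=80, noise_mm=0.3, seed=9)
        back = read_points(write_points(series, tmp_path / "p.tsv"))

        def path_len(s, name):
            xyz = s.point(name)
            return np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1))

        for tip in series.tip_points:
            assert path_len(back, tip) == pytest.approx(path_len(series, tip))

    def test_tip_points_invariant(self):
        series = simulate_trajectory(n_frames=10, seed=0)
        assert len(series.tip_points) == 5
        assert set(series.tip_points) <= set(series.point_names)
        with pytest.raises(ValidationError):
            HandPointSeries(
                points=series.points[:, :20, :],
                point_names=series.point_names[:20],
                rate=series.rate,
                subject_id="x",
                hand="left",
                run_index=1,
            )
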