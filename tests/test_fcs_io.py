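"""FCS reading/writing and sample merging."""

import struct

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import marrowmap as mm
from marrowmap.events import EventMatrix, read_csv, write_csv
from marrowmap.fcs import HEADER_LEN


def _matrix(values, channels=None, markers=None, **kw):
    values = np.asarray(values, dtype=float)
    channels = channels or [f"FL{i}" for i in range(values.shape[1])]
    return EventMatrix(values=values, channel_names=channels,
                       marker_names=markers or [], **kw)


def hand_built_fcs(tmp_path, datatype=b"F", version=b"FCS3.1"):
    """Assemble FCS bytes by hand: 2 events x 2 channels, little-endian f32."""
    payload = struct.pack("<4f", 1.0, 2.0, 3.0, 4.0)
    text = ("/$MODE/L/$DATATYPE/" + datatype.decode() +
            "/$BYTEORD/1,2,3,4/$TOT/2/$PAR/2"
            "/$P1N/FS/$P2N/SS/$P1B/32/$P2B/32/").encode()
    text_start = HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1
    header = version + b"    " + b"".join(
        str(x).rjust(8).encode()
        for x in (text_start, text_end, data_start, data_end, 0, 0)
    )
    path = tmp_path / "hand.fcs"
    path.write_bytes(header + text + payload)
    return path


class TestReadFcs:
    def test_hand_assembled_fcs31_bytes(self, tmp_path):
        """Bytes laid out by hand from the standard parse to [[1,2],[3,4]]."""
        events, meta = mm.read_fcs(hand_built_fcs(tmp_path))
        assert np.array_equal(events.values, [[1.0, 2.0], [3.0, 4.0]])
        assert events.channel_names == ["FS", "SS"]
        assert events.state == "raw"
        assert meta.n_events == 2 and meta.n_channels == 2

    def test_ascii_datatype_rejected(self, tmp_path):
        with pytest.raises(mm.UnsupportedDialectError):
            mm.read_fcs(hand_built_fcs(tmp_path, datatype=b"A"))

    def test_fcs2_rejected(self, tmp_path):
        with pytest.raises(mm.UnsupportedDialectError):
            mm.read_fcs(hand_built_fcs(tmp_path, version=b"FCS2.0"))

    def test_truncated_data_segment(self, tmp_path):
        path = hand_built_fcs(tmp_path)
        blob = path.read_bytes()
        path.write_bytes(blob[:-6])  # chop into the DATA segment
        with pytest.raises(mm.CorruptFileError):
            mm.read_fcs(path)


class TestWriteFcs:
    def test_roundtrip_preserves_names_and_values(self, tmp_path, rng):
        ev = _matrix(rng.uniform(0, 1e4, size=(5, 3)),
                     channels=["FL1", "FL2", "SSC"],
                     markers=["CD45", "CD34", ""])
        mm.write_fcs(ev, tmp_path / "x.fcs")
        back, meta = mm.read_fcs(tmp_path / "x.fcs")
        assert back.channel_names == ev.channel_names
        assert back.marker_names == ev.marker_names
        np.testing.assert_allclose(back.values, ev.values, rtol=1e-6)

    def test_zero_event_file(self, tmp_path):
        ev = _matrix(np.zeros((0, 2)))
        mm.write_fcs(ev, tmp_path / "empty.fcs")
        back, meta = mm.read_fcs(tmp_path / "empty.fcs")
        assert back.n_events == 0 and back.n_channels == 2
        assert meta.keyword_map["$TOT"] == "0"

    def test_nonfinite_rejected(self, tmp_path):
        ev = _matrix([[1.0, 2.0]])
        ev.values[0, 0] = np.nan
        with pytest.raises(mm.ValidationError):
            mm.write_fcs(ev, tmp_path / "bad.fcs")

    def test_truth_keyword_roundtrip(self, tmp_path):
        ev = _matrix([[1.0], [2.0]], truth=np.array(["a", "b"], dtype=object))
        mm.write_fcs(ev, tmp_path / "t.fcs", include_truth=True)
        back, _ = mm.read_fcs(tmp_path / "t.fcs")
        assert list(back.truth) == ["a", "b"]

    @given(
        arrays(
            np.float32,
            st.tuples(st.integers(1, 20), st.integers(1, 5)),
            elements=st.floats(-1e6, 1e6, width=32),
        )
    )
    def test_roundtrip_property(self, values):
        """read(write(E)) reproduces values within float32 rounding."""
        import tempfile, pathlib

        ev = _matrix(values.astype(float))
        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d) / "r.fcs"
            mm.write_fcs(ev, p)
            back, _ = mm.read_fcs(p)
        np.testing.assert_array_equal(
            back.values.astype(np.float32), ev.values.astype(np.float32)
        )


class TestMergeEvents:
    @pytest.fixture()
    def two_samples(self, panel, rng):
        chans = [c.name for c in panel.channels]
        marks = [c.marker for c in panel.channels]
        a = EventMatrix(rng.uniform(0, 100, (100, len(chans))), chans, marks,
                        sample_ids=np.array(["a"] * 100, dtype=object))
        b = EventMatrix(rng.uniform(0, 100, (200, len(chans))), chans, marks,
                        sample_ids=np.array(["b"] * 200, dtype=object))
        return a, b

    def test_concatenation(self, panel, two_samples):
        a, b = two_samples
        merged = mm.merge_events([a, b], panel)
        assert merged.n_events == 300
        assert set(merged.sample_ids) == {"a", "b"}
        np.testing.assert_array_equal(merged.values[:100], a.values)

    def test_permuted_columns_equal_unpermuted(self, panel, two_samples):
        a, b = two_samples
        perm = np.arange(b.n_channels)[::-1]
        b_perm = EventMatrix(
            b.values[:, perm],
            [b.channel_names[i] for i in perm],
            [b.marker_names[i] for i in perm],
            sample_ids=b.sample_ids,
        )
        direct = mm.merge_events([a, b], panel)
        shuffled = mm.merge_events([a, b_perm], panel)
        np.testing.assert_array_equal(direct.values, shuffled.values)

    def test_missing_channel_names_sample_and_channel(self, panel, two_samples):
        a, b = two_samples
        j = b.marker_names.index("CD38")
        keep = [i for i in range(b.n_channels) if i != j]
        b_short = EventMatrix(
            b.values[:, keep],
            [b.channel_names[i] for i in keep],
            [b.marker_names[i] for i in keep],
            sample_ids=b.sample_ids,
        )
        with pytest.raises(mm.ChannelMismatchError, match="CD38"):
            mm.merge_events([a, b_short], panel)

    def test_mixed_states_rejected(self, panel, two_samples):
        a, b = two_samples
        b2 = b.with_values(b.values, state="transformed")
        with pytest.raises(mm.ValidationError):
            mm.merge_events([a, b2], panel)

    def test_associativity(self, panel, two_samples, rng):
        a, b = two_samples
        c = EventMatrix(
            rng.uniform(0, 100, (50, a.n_channels)),
            a.channel_names, a.marker_names,
            sample_ids=np.array(["c"] * 50, dtype=object),
        )
        left = mm.merge_events([mm.merge_events([a, b], panel), c], panel)
        right = mm.merge_events([a, mm.merge_events([b, c], panel)], panel)
        np.testing.assert_array_equal(left.values, right.values)


class TestCsvDialect:
    def test_roundtrip_with_markers_and_truth(self, tmp_path, rng):
        ev = _matrix(
            rng.uniform(0, 10, (20, 2)),
            channels=["FL1", "FL2"],
            markers=["CD3", "CD4"],
            truth=np.array(["x"] * 20, dtype=object),
        )
        write_csv(ev, tmp_path / "e.csv")
        back = read_csv(tmp_path / "e.csv")
        np.testing.assert_allclose(back.values, ev.values)
        assert back.marker_names == ev.marker_names
        assert list(back.truth) == list(ev.truth)
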