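"""Compensation, arcsinh transform and channel selection/scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import marrowmap as mm
from marrowmap.events import EventMatrix
from marrowmap.panel import ChannelDef, PanelDefinition, ScalingStats


def two_channel_panel(spillover=None):
    return PanelDefinition(
        name="mini",
        channels=[
            ChannelDef("FL1", "CD1", "fluorescence"),
            ChannelDef("FL2", "CD2", "fluorescence"),
        ],
        spillover=spillover,
    )


def events_for(panel, values, state="raw"):
    return EventMatrix(
        values=np.asarray(values, dtype=float),
        channel_names=[c.name for c in panel.channels],
        marker_names=[c.marker for c in panel.channels],
        state=state,
    )


class TestCompensate:
    def test_identity_spillover_is_noop(self, rng):
        panel = two_channel_panel(np.eye(2))
        ev = events_for(panel, rng.uniform(0, 1e3, (50, 2)))
        out = mm.compensate(ev, panel)
        np.testing.assert_allclose(out.values, ev.values, atol=1e-9)
        assert out.state == "compensated"

    def test_hand_solved_two_channel_system(self):
        """S=[[1,.1],[0,1]]: observed (100,110) decompensates to (100,100)."""
        panel = two_channel_panel(np.array([[1.0, 0.1], [0.0, 1.0]]))
        ev = events_for(panel, [[100.0, 110.0]])
        out = mm.compensate(ev, panel)
        np.testing.assert_allclose(out.values, [[100.0, 100.0]], atol=1e-9)

    def test_singular_spillover_raises(self):
        panel = two_channel_panel()
        panel.spillover = np.array([[1.0, 1.0], [1.0, 1.0]])  # identical rows
        ev = events_for(panel, [[1.0, 2.0]])
        with pytest.raises(mm.NumericalError, match="spillover"):
            mm.compensate(ev, panel)

    def test_compensate_then_mix_recovers_observed(self, rng):
        panel = two_channel_panel(np.array([[1.0, 0.12], [0.05, 1.0]]))
        observed = rng.uniform(0, 1e4, (100, 2))
        comped = mm.compensate(events_for(panel, observed), panel)
        remixed = comped.values @ panel.spillover
        np.testing.assert_allclose(remixed, observed, rtol=1e-9)


class TestTransform:
    def test_zero_maps_to_zero(self):
        panel = two_channel_panel()
        out = mm.transform(events_for(panel, [[0.0, 0.0]]), panel)
        np.testing.assert_array_equal(out.values, [[0.0, 0.0]])

    def test_closed_form_arcsinh_one(self):
        """x = cofactor gives arcsinh(1) = ln(1 + sqrt(2))."""
        panel = two_channel_panel()
        out = mm.transform(events_for(panel, [[150.0, 150.0]]), panel)
        np.testing.assert_allclose(out.values, np.log(1 + np.sqrt(2)), rtol=1e-9)
        np.testing.assert_allclose(out.values, 0.881374, atol=1e-6)

    def test_inverse_roundtrip(self, rng):
        panel = two_channel_panel()
        ev = events_for(panel, rng.uniform(-100, 1e4, (200, 2)))
        back = mm.inverse_transform(mm.transform(ev, panel), panel)
        np.testing.assert_allclose(back.values, ev.values, rtol=1e-9, atol=1e-9)

    def test_nonpositive_cofactor_rejected(self):
        panel = two_channel_panel()
        panel.cofactors = {"FL1": -5.0}
        with pytest.raises(mm.ConfigurationError):
            mm.transform(events_for(panel, [[1.0, 1.0]]), panel)

    @given(st.lists(st.floats(-1e5, 1e5), min_size=2, max_size=30, unique=True))
    def test_strictly_increasing(self, xs):
        panel = two_channel_panel()
        xs = sorted(xs)
        vals = np.column_stack([xs, xs])
        out = mm.transform(events_for(panel, vals), panel)
        assert np.all(np.diff(out.values[:, 0]) > 0)


class TestSelectAndScale:
    def test_eleven_clustering_dimensions(self, panel, rng):
        """10 fluorescences + SSC survive; FSC and TIME are dropped."""
        ev = EventMatrix(
            rng.uniform(0, 1e3, (100, len(panel.channels))),
            [c.name for c in panel.channels],
            [c.marker for c in panel.channels],
            state="transformed",
        )
        scaled, stats = mm.select_and_scale(ev, panel)
        assert scaled.n_channels == 11
        assert stats.channels[-1] == "SSC" or "SSC" in stats.channels
        assert "FSC" not in stats.channels and "TIME" not in stats.channels

    def test_self_computed_stats_standardize(self, panel, rng):
        ev = EventMatrix(
            rng.normal(5, 2, (500, len(panel.channels))),
            [c.name for c in panel.channels],
            [c.marker for c in panel.channels],
            state="transformed",
        )
        scaled, _ = mm.select_and_scale(ev, panel)
        assert np.allclose(np.median(scaled.values, axis=0), 0, atol=1e-9)
        assert np.allclose(scaled.values.std(axis=0), 1, atol=1e-6)

    def test_frozen_stats_reused_verbatim(self, panel, rng):
        base = EventMatrix(
            rng.normal(5, 2, (300, len(panel.channels))),
            [c.name for c in panel.channels],
            [c.marker for c in panel.channels],
            state="transformed",
        )
        _, stats = mm.select_and_scale(base, panel)
        other = base.with_values(base.values * 3 + 1)
        out1, s1 = mm.select_and_scale(other, panel, stats=stats)
        out2, s2 = mm.select_and_scale(other, panel, stats=stats)
        assert s1 is stats and s2 is stats
        assert out1.values.tobytes() == out2.values.tobytes()

    def test_constant_channel_floored(self, panel, caplog):
        vals = np.ones((50, len(panel.channels)))
        ev = EventMatrix(
            vals,
            [c.name for c in panel.channels],
            [c.marker for c in panel.channels],
            state="transformed",
        )
        with caplog.at_level("WARNING"):
            scaled, stats = mm.select_and_scale(ev, panel)
        assert np.all(stats.spread >= 1e-6)
        assert np.allclose(scaled.values, 0.0)
        assert any("floored" in r.message for r in caplog.records)

    def test_mismatched_stats_rejected(self, panel, rng):
        ev = EventMatrix(
            rng.normal(0, 1, (20, len(panel.channels))),
            [c.name for c in panel.channels],
            [c.marker for c in panel.channels],
            state="transformed",
        )
        bad = ScalingStats(channels=["x", "y"], location=np.zeros(2), spread=np.ones(2))
        with pytest.raises(mm.ConfigurationError):
            mm.select_and_scale(ev, panel, stats=bad)
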