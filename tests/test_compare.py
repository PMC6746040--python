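"""Patient mapping, excess/deficit flagging and backgating."""

import numpy as np
import pandas as pd
import pytest

import marrowmap as mm
from marrowmap.events import EventMatrix
from marrowmap.simulate import (
    blast_from_nodes,
    default_populations,
    generate_sample,
    near_empty_nodes,
    spike_abnormal,
)


@pytest.fixture()
def fresh_normal(panel):
    return generate_sample(default_populations(), 10_000, seed=314, panel=panel,
                           sample_id="patient")


class TestMapSample:
    def test_occupancy_sums_to_one(self, full_template, fresh_normal):
        mapped = mm.map_sample(full_template, fresh_normal)
        assert mapped.occupancy.sum() == pytest.approx(1.0, abs=1e-9)
        assert mapped.event_count == fresh_normal.n_events

    def test_constituent_sample_matches_stored_row(self, full_template, full_cohort):
        donor = full_cohort[5]
        mapped = mm.map_sample(full_template, donor)
        stored = full_template.occupancy.loc[str(donor.sample_ids[0])].to_numpy()
        np.testing.assert_array_equal(mapped.occupancy, stored)

    def test_missing_channel_named_in_error(self, full_template, fresh_normal):
        j = fresh_normal.marker_names.index("CD117")
        keep = [i for i in range(fresh_normal.n_channels) if i != j]
        crippled = EventMatrix(
            fresh_normal.values[:, keep],
            [fresh_normal.channel_names[i] for i in keep],
            [fresh_normal.marker_names[i] for i in keep],
            sample_ids=fresh_normal.sample_ids,
        )
        with pytest.raises(mm.ChannelMismatchError, match="CD117"):
            mm.map_sample(full_template, crippled)

    def test_mapping_never_alters_the_template(self, full_template, full_ranges,
                                               fresh_normal):
        before = full_template.content_hash()
        for _ in range(3):
            mapped = mm.map_sample(full_template, fresh_normal)
            mm.compare_to_reference(mapped, full_template, full_ranges)
        assert full_template.content_hash() == before


class TestCompareToReference:
    def test_blast_spike_13_7_percent_recovered(self, panel, full_template,
                                                full_ranges):
        """A 13.7% blast spike into near-empty nodes is flagged and its
        summed excess burden lands within one point of 13.7."""
        blast = blast_from_nodes(full_template, near_empty_nodes(full_template, 1))
        sample = generate_sample(default_populations(), 10_000, seed=99, panel=panel)
        spiked = spike_abnormal(sample, blast, 0.137, seed=100, panel=panel)
        report = mm.compare_to_reference(
            mm.map_sample(full_template, spiked), full_template, full_ranges
        )
        assert report.excess_nodes
        assert report.excess_burden_pct == pytest.approx(13.7, abs=1.0)

    def test_granulocytic_removal_flags_deficit(self, panel, full_template,
                                                full_ranges):
        """Losing granulocytic maturation empties its nodes below the
        deficit threshold."""
        kept = [p for p in default_populations()
                if p.name not in ("Gran", "IG1", "IG2", "PrMy")]
        total = sum(p.frequency for p in kept)
        for p in kept:
            p.frequency /= total
        sample = generate_sample(kept, 10_000, seed=55, panel=panel)
        report = mm.compare_to_reference(
            mm.map_sample(full_template, sample), full_template, full_ranges
        )
        assert "Granulocytic" in report.deficit_labels
        assert len(report.deficit_nodes) >= 5

    def test_burden_monotone_in_spike_fraction(self, panel, full_template,
                                               full_ranges):
        blast = blast_from_nodes(full_template, near_empty_nodes(full_template, 1))
        burdens = []
        for f in (0.005, 0.0144, 0.05, 0.137):
            sample = generate_sample(default_populations(), 8_000, seed=7, panel=panel)
            spiked = spike_abnormal(sample, blast, f, seed=8, panel=panel)
            report = mm.compare_to_reference(
                mm.map_sample(full_template, spiked), full_template, full_ranges
            )
            burdens.append(report.excess_burden_pct)
        assert all(b2 >= b1 for b1, b2 in zip(burdens, burdens[1:]))

    def test_flags_consistent_with_thresholds(self, full_template, full_ranges,
                                              fresh_normal):
        report = mm.compare_to_reference(
            mm.map_sample(full_template, fresh_normal), full_template, full_ranges
        )
        t = report.table
        th = report.thresholds
        ex = t["flag"] == "excess"
        assert np.all(t.loc[ex, "z"] > th.z_hi)
        assert np.all(t.loc[ex, "occupancy"] > th.min_excess)
        de = t["flag"] == "deficit"
        assert np.all(t.loc[de, "normal_mean"] > th.min_deficit_base)
        assert np.all(
            t.loc[de, "occupancy"] < th.deficit_fraction * t.loc[de, "normal_mean"]
        )
        assert report.excess_burden_pct == pytest.approx(
            100.0 * t.loc[ex, "occupancy"].sum()
        )

    def test_node_count_mismatch_rejected(self, full_template, fresh_normal):
        mapped = mm.map_sample(full_template, fresh_normal)
        truncated = mm.NormalRanges(
            node_ids=np.arange(50),
            mean=np.full(50, 0.02),
            sd=np.full(50, 0.01),
            min=np.zeros(50),
            max=np.full(50, 0.1),
            sd_floor=1e-6,
        )
        with pytest.raises(mm.ConfigurationError):
            mm.compare_to_reference(mapped, full_template, truncated)


class TestBackgate:
    def test_one_row_per_event_on_original_scale(self, full_template, fresh_normal):
        mapped = mm.map_sample(full_template, fresh_normal)
        table = mm.backgate_table(mapped, fresh_normal, full_template, "CD45", "SSC")
        assert len(table) == fresh_normal.n_events
        j = fresh_normal.column_index("CD45")
        np.testing.assert_array_equal(table["CD45"].to_numpy(),
                                      fresh_normal.values[:, j])
        k = fresh_normal.column_index("SSC")
        np.testing.assert_array_equal(table["SSC"].to_numpy(),
                                      fresh_normal.values[:, k])

    def test_unknown_channel_rejected(self, full_template, fresh_normal):
        mapped = mm.map_sample(full_template, fresh_normal)
        with pytest.raises(mm.ValidationError):
            mm.backgate_table(mapped, fresh_normal, full_template, "CD999", "SSC")

    def test_flag_column_present_with_report(self, full_template, full_ranges,
                                             fresh_normal):
        mapped = mm.map_sample(full_template, fresh_normal)
        report = mm.compare_to_reference(mapped, full_template, full_ranges)
        table = mm.backgate_table(
            mapped, fresh_normal, full_template, "CD45", "SSC", report
        )
        assert set(table["flag"]).issubset({"none", "excess", "deficit"})
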