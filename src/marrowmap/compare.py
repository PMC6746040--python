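"""Mapping patient samples onto a frozen reference and flagging anomalies.

A patient sample is pushed through the template's own preprocessing
(compensation, arcsinh, the *frozen* scaling statistics) and assigned to
the template's nodes — the codebook, scaling and tree are never altered.
Per node, the sample's occupancy is compared with the normal ranges:

* **excess** — occupancy z-score above ``z_hi`` and occupancy above a
  floor: the node holds more cells than any healthy marrow, the
  blast-excess / residual-disease signature;
* **deficit** — a node that is well-populated in normals holds almost
  nothing: the lost-maturation signature.

The summed occupancy of excess-flagged nodes, as a percentage of all
analyzed events, is the sample's abnormal (blast/MRD) burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventMatrix
from .exceptions import ConfigurationError, ValidationError
from .preprocess import compensate, select_and_scale, transform
from .reference import NormalRanges, ReferenceTemplate, occupancy_fractions
from .som import assign_bmu


@dataclass
class Thresholds:
    """Flagging thresholds; defaults printed in every report."""

    z_hi: float = 3.0
    min_excess: float = 0.0005        # occupancy floor for an excess call
    min_deficit_base: float = 0.005   # normal mean below which deficit is not assessed
    deficit_fraction: float = 0.2     # occupancy below this multiple of normal mean

    def to_dict(self) -> dict:
        return {
            "z_hi": self.z_hi,
            "min_excess": self.min_excess,
            "min_deficit_base": self.min_deficit_base,
            "deficit_fraction": self.deficit_fraction,
        }


@dataclass
class MappedSample:
    """A patient sample assigned onto a frozen reference."""

    sample_id: str
    assignments: np.ndarray          # per-event node id
    occupancy: np.ndarray            # per-node fraction, sums to 1
    event_count: int

    def __post_init__(self) -> None:
        if abs(float(self.occupancy.sum()) - 1.0) > 1e-9:
            raise ValidationError("occupancy does not sum to 1")
        if len(self.assignments) != self.event_count:
            raise ValidationError("assignments do not cover all events")


@dataclass
class ComparisonReport:
    """Per-node comparison against normal ranges plus summary figures."""

    sample_id: str
    table: pd.DataFrame              # node_id, occupancy, normal stats, z, fc, flag
    thresholds: Thresholds
    excess_burden_pct: float
    deficit_labels: list[str] = field(default_factory=list)

    @property
    def excess_nodes(self) -> list[int]:
        t = self.table
        return t.loc[t["flag"] == "excess", "node_id"].astype(int).tolist()

    @property
    def deficit_nodes(self) -> list[int]:
        t = self.table
        return t.loc[t["flag"] == "deficit", "node_id"].astype(int).tolist()

    def summary(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "excess_burden_pct": self.excess_burden_pct,
            "n_excess_nodes": len(self.excess_nodes),
            "n_deficit_nodes": len(self.deficit_nodes),
            "deficit_labels": self.deficit_labels,
            "thresholds": self.thresholds.to_dict(),
        }


def map_sample(template: ReferenceTemplate, events: EventMatrix) -> MappedSample:
    """Assign a raw patient sample onto the frozen reference.

    Uses the template's spillover, cofactors and frozen scaling
    statistics, so a sample that contributed to the reference reproduces
    its stored occupancy row exactly.
    """
    if events.state != "raw":
        raise ConfigurationError(f"map_sample expects raw events, got {events.state}")
    panel = template.panel
    comped = compensate(events, panel)
    transformed = transform(comped, panel)
    scaled, _ = select_and_scale(transformed, panel, stats=template.model.scaling)
    assignments = assign_bmu(scaled, template.model)
    occ = occupancy_fractions(assignments, template.n_nodes)
    sid = str(events.sample_ids[0]) if events.n_events else "sample0"
    return MappedSample(
        sample_id=sid,
        assignments=assignments,
        occupancy=occ,
        event_count=events.n_events,
    )


def compare_to_reference(
    mapped: MappedSample,
    template: ReferenceTemplate,
    ranges: NormalRanges,
    thresholds: Thresholds | None = None,
) -> ComparisonReport:
    """Flag node-occupancy excess and deficit against normal ranges.

    Per node: ``z = (occupancy - normal mean) / sd`` with the floored sd
    from the ranges (nodes empty in every normal donor get a tiny floored
    sd, so any real occupancy there yields a large finite z — the
    residual-disease case).  The log2 fold change uses a pseudocount of
    one event (1 / patient event count).
    """
    if thresholds is None:
        thresholds = Thresholds()
    if len(ranges.mean) != template.n_nodes or len(mapped.occupancy) != template.n_nodes:
        raise ConfigurationError("node counts of sample, template and ranges differ")
    occ = mapped.occupancy
    z = (occ - ranges.mean) / ranges.sd
    pseudo = 1.0 / max(mapped.event_count, 1)
    log2fc = np.log2((occ + pseudo) / (ranges.mean + pseudo))
    excess = (z > thresholds.z_hi) & (occ > thresholds.min_excess)
    deficit = (
        (ranges.mean > thresholds.min_deficit_base)
        & (occ < thresholds.deficit_fraction * ranges.mean)
        & ~excess
    )
    flag = np.where(excess, "excess", np.where(deficit, "deficit", "none"))
    table = pd.DataFrame(
        {
            "node_id": np.arange(template.n_nodes),
            "occupancy": occ,
            "normal_mean": ranges.mean,
            "normal_sd": ranges.sd,
            "z": z,
            "log2_fold_change": log2fc,
            "flag": flag,
        }
    )
    burden = 100.0 * float(occ[excess].sum())
    deficit_labels = sorted(
        {
            lb
            for node in np.flatnonzero(deficit)
            for lb in template.node_labels.get(int(node), [])
        }
    )
    return ComparisonReport(
        sample_id=mapped.sample_id,
        table=table,
        thresholds=thresholds,
        excess_burden_pct=burden,
        deficit_labels=deficit_labels,
    )


def backgate_table(
    mapped: MappedSample,
    events: EventMatrix,
    template: ReferenceTemplate,
    channel_x: str,
    channel_y: str,
    report: ComparisonReport | None = None,
) -> pd.DataFrame:
    """Per-event table for classical biparametric backgating displays.

    One row per event with the two requested channels on the original
    measurement scale, the node assignment, the node's labels and (when
    a report is given) its excess/deficit flag — everything needed to
    draw a CD45/SSC plot colored by node or by abnormality.
    """
    if events.n_events != mapped.event_count:
        raise ValidationError("events do not match the mapped sample")
    ix = events.column_index(channel_x)
    iy = events.column_index(channel_y)
    labels = [
        ";".join(template.node_labels.get(int(n), [])) for n in mapped.assignments
    ]
    out = pd.DataFrame(
        {
            channel_x: events.values[:, ix],
            channel_y: events.values[:, iy],
            "node_id": mapped.assignments,
            "labels": labels,
        }
    )
    if report is not None:
        flag_of = report.table.set_index("node_id")["flag"]
        out["flag"] = flag_of.loc[mapped.assignments].to_numpy()
    return out
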