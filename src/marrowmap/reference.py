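"""Frozen per-panel reference templates built from normal-marrow cohorts.

``build_reference`` runs the whole construction pipeline on a cohort of
normal samples — merge, compensate, arcsinh-transform, select the 11
clustering dimensions and freeze their scaling, train the 100-node SOM,
build and lay out the MST — then records node-level statistics on the
merged cohort and one occupancy row per donor.  The finished
:class:`ReferenceTemplate` is immutable in use: mapping patient samples
never alters the codebook, scaling or tree.

Normal occupancy ranges (:class:`NormalRanges`, per-node mean/sd/min/max
across donors with a floored sd) operationalize "how full is this node
in healthy marrow", the yardstick patient samples are compared against.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .events import EventMatrix
from .exceptions import ValidationError
from .fcs import merge_events
from .mst import MSTGraph, build_mst, layout_mst
from .panel import PanelDefinition, ScalingStats
from .preprocess import compensate, select_and_scale, transform
from .som import SOMModel, assign_bmu, train_som

logger = logging.getLogger(__name__)

#: Quantile grid stored per marker so phenotype bins can be re-derived
#: from a saved template without the original events.
QUANTILE_GRID = np.round(np.linspace(0.0, 1.0, 201), 3)



def _csv_exact(df: pd.DataFrame, path, index: bool = False) -> None:
    """CSV write with shortest-roundtrip float repr (lossless reload)."""
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: repr(float(v)))
    out.to_csv(path, index=index)


@dataclass
class ReferenceConfig:
    """Tunable construction parameters for a reference template."""

    grid_rows: int = 10
    grid_cols: int = 10
    som_params: dict = field(default_factory=dict)
    spread_floor: float = 1e-6


@dataclass
class NormalRanges:
    """Per-node occupancy statistics across the normal donors."""

    node_ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    sd_floor: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "mean": self.mean,
                "sd": self.sd,
                "min": self.min,
                "max": self.max,
            }
        )


@dataclass
class ReferenceTemplate:
    """Frozen per-panel reference: model + tree + normal statistics."""

    panel: PanelDefinition
    model: SOMModel
    tree: MSTGraph
    merged_stats: pd.DataFrame            # one row per node
    occupancy: pd.DataFrame               # donors x nodes, fractions
    marker_quantiles: pd.DataFrame        # QUANTILE_GRID x markers
    node_labels: dict[int, list[str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.model.n_nodes
        if self.occupancy.shape[1] != n:
            raise ValidationError("occupancy column count does not match node count")
        rows = self.occupancy.to_numpy().sum(axis=1)
        if len(rows) and not np.allclose(rows, 1.0, atol=1e-9):
            raise ValidationError("occupancy rows must each sum to 1")

    @property
    def n_nodes(self) -> int:
        return self.model.n_nodes

    def content_hash(self) -> str:
        """Deterministic digest of everything that defines the mapping."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.model.codebook).tobytes())
        h.update(np.ascontiguousarray(self.model.scaling.location).tobytes())
        h.update(np.ascontiguousarray(self.model.scaling.spread).tobytes())
        h.update(json.dumps(sorted(self.tree.edges), sort_keys=True).encode())
        h.update(self.occupancy.to_csv().encode())
        return h.hexdigest()

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Persist as a directory bundle of CSV/JSON/YAML files."""
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        self.panel.save_yaml(root / "panel.yaml")
        cb = pd.DataFrame(self.model.codebook, columns=self.model.scaling.channels)
        cb.insert(0, "node_id", np.arange(self.n_nodes))
        _csv_exact(cb, root / "codebook.csv")
        _csv_exact(
            pd.DataFrame(
                {
                    "channel": self.model.scaling.channels,
                    "location": self.model.scaling.location,
                    "spread": self.model.scaling.spread,
                }
            ),
            root / "scaling.csv",
        )
        _csv_exact(
            pd.DataFrame(self.tree.edges, columns=["node_a", "node_b", "weight"]),
            root / "mst_edges.csv",
        )
        lay = self.tree.layout
        _csv_exact(
            pd.DataFrame(
                {
                    "node_id": sorted(lay),
                    "x": [lay[k][0] for k in sorted(lay)],
                    "y": [lay[k][1] for k in sorted(lay)],
                }
            ),
            root / "layout.csv",
        )
        _csv_exact(self.merged_stats, root / "node_stats.csv")
        _csv_exact(self.occupancy, root / "occupancy.csv", index=True)
        _csv_exact(self.marker_quantiles, root / "marker_quantiles.csv", index=True)
        with open(root / "node_labels.json", "w") as fh:
            json.dump({str(k): v for k, v in self.node_labels.items()}, fh, indent=1)
        prov = dict(self.provenance)
        prov.update(
            {
                "grid_rows": self.model.grid_rows,
                "grid_cols": self.model.grid_cols,
                "spread_floor": self.model.scaling.spread_floor,
                "training_meta": self.model.training_meta,
            }
        )
        with open(root / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ReferenceTemplate":
        root = Path(path)
        panel = PanelDefinition.load_yaml(root / "panel.yaml")
        with open(root / "provenance.json") as fh:
            prov = json.load(fh)
        cb = pd.read_csv(root / "codebook.csv", float_precision="round_trip")
        scaling_df = pd.read_csv(root / "scaling.csv", float_precision="round_trip")
        scaling = ScalingStats(
            channels=scaling_df["channel"].tolist(),
            location=scaling_df["location"].to_numpy(),
            spread=scaling_df["spread"].to_numpy(),
            spread_floor=float(prov.get("spread_floor", 1e-6)),
        )
        model = SOMModel(
            grid_rows=int(prov["grid_rows"]),
            grid_cols=int(prov["grid_cols"]),
            codebook=cb.drop(columns="node_id").to_numpy(),
            scaling=scaling,
            training_meta=prov.get("training_meta", {}),
        )
        edges_df = pd.read_csv(root / "mst_edges.csv", float_precision="round_trip")
        tree = MSTGraph(
            n_nodes=model.n_nodes,
            edges=[
                (int(a), int(b), float(w))
                for a, b, w in edges_df.itertuples(index=False)
            ],
        )
        lay_df = pd.read_csv(root / "layout.csv", float_precision="round_trip")
        tree.layout = {
            int(r.node_id): (float(r.x), float(r.y))
            for r in lay_df.itertuples(index=False)
        }
        with open(root / "node_labels.json") as fh:
            labels = {int(k): list(v) for k, v in json.load(fh).items()}
        prov2 = {
            k: v
            for k, v in prov.items()
            if k not in ("grid_rows", "grid_cols", "spread_floor", "training_meta")
        }
        return cls(
            panel=panel,
            model=model,
            tree=tree,
            merged_stats=pd.read_csv(root / "node_stats.csv", float_precision="round_trip"),
            occupancy=pd.read_csv(root / "occupancy.csv", index_col=0,
                                  float_precision="round_trip").rename(
                columns=int
            ),
            marker_quantiles=pd.read_csv(root / "marker_quantiles.csv", index_col=0,
                                         float_precision="round_trip"),
            node_labels=labels,
            provenance=prov2,
        )


# ----------------------------------------------------------------------


def occupancy_fractions(assignments: np.ndarray, n_nodes: int) -> np.ndarray:
    """Per-node occupancy fractions of one sample (sums to 1)."""
    if len(assignments) == 0:
        raise ValidationError("cannot compute occupancy of an empty sample")
    counts = np.bincount(assignments, minlength=n_nodes).astype(float)
    return counts / counts.sum()


def compute_node_stats(
    events: EventMatrix,
    assignments: np.ndarray,
    model: SOMModel,
    panel: PanelDefinition | None = None,
) -> pd.DataFrame:
    """Node-level counts, percentages and intensity summaries.

    ``events`` must be in the transformed state, restricted or
    restrictable to the clustering channels.  Medians and means are
    computed in transformed space; medians are additionally
    back-transformed to the measurement scale (``median_raw_*``).  Empty
    nodes report count 0 and NaN intensities.
    """
    if len(assignments) != events.n_events:
        raise ValidationError("assignments length does not match event count")
    n_nodes = model.n_nodes
    counts = np.bincount(assignments, minlength=n_nodes).astype(int)
    total = max(counts.sum(), 1)
    rows: dict[str, np.ndarray] = {
        "node_id": np.arange(n_nodes),
        "count": counts,
        "percentage": 100.0 * counts / total,
    }
    if panel is not None:
        chans = panel.clustering_channels()
        cols = [events.column_index(c.display) for c in chans]
        cofs = [panel.cofactor(c) for c in chans]
        names = [c.display for c in chans]
    else:
        cols = list(range(events.n_channels))
        cofs = [None] * len(cols)
        names = events.display_names()
    med = np.full((n_nodes, len(cols)), np.nan)
    mean = np.full((n_nodes, len(cols)), np.nan)
    order = np.argsort(assignments, kind="stable")
    sorted_assign = assignments[order]
    boundaries = np.searchsorted(sorted_assign, np.arange(n_nodes + 1))
    vals = events.values[:, cols]
    for node in range(n_nodes):
        lo, hi = boundaries[node], boundaries[node + 1]
        if hi > lo:
            block = vals[order[lo:hi]]
            med[node] = np.median(block, axis=0)
            mean[node] = block.mean(axis=0)
    for j, nm in enumerate(names):
        rows[f"median_t_{nm}"] = med[:, j]
        rows[f"mean_t_{nm}"] = mean[:, j]
        if cofs[j] is not None:
            rows[f"median_raw_{nm}"] = np.sinh(med[:, j]) * cofs[j]
    return pd.DataFrame(rows)


def compute_normal_ranges(
    template: ReferenceTemplate,
    sd_floor: float | None = None,
    sd_confidence: float = 0.95,
) -> NormalRanges:
    """Mean/sd/min/max node occupancy across the normal donors.

    The per-node spread follows clinical reference-range practice for
    small cohorts: the sample sd is replaced by its one-sided upper
    confidence limit ``s * sqrt((n-1) / chi2_{1-sd_confidence, n-1})``
    (a tolerance-interval correction; ~1.39x for 19 donors at 95%), and
    two floors are applied:

    * a per-node binomial counting floor ``sqrt(p (1 - p) / n_donor)``:
      a donor's occupancy fraction estimated from ``n_donor`` events
      cannot be known more precisely than its sampling error, so an sd
      estimate below it is an underestimate by chance and would produce
      spurious excess calls;
    * an absolute floor, defaulting to 1 / (total merged events), which
      keeps z-scores finite (and very large) for nodes empty in every
      normal donor — the residual-disease case.
    """
    from scipy.stats import chi2

    occ = template.occupancy.to_numpy()
    if occ.size == 0:
        raise ValidationError("occupancy matrix is empty")
    if sd_floor is None:
        total = int(template.provenance.get("n_merged_events", 0))
        if total <= 0:
            total = int(occ.shape[0] * 10_000)
        sd_floor = 1.0 / total
    total = int(template.provenance.get("n_merged_events", occ.shape[0] * 10_000))
    n_donor = max(total // max(occ.shape[0], 1), 1)
    mean = occ.mean(axis=0)
    counting = np.sqrt(np.clip(mean * (1.0 - mean), 0.0, None) / n_donor)
    n = occ.shape[0]
    if n < 2:
        logger.warning("fewer than 2 normal samples: all occupancy sds floored")
        sd = np.maximum(counting, sd_floor)
    else:
        ucl = np.sqrt((n - 1) / chi2.ppf(1.0 - sd_confidence, n - 1))
        sd = np.maximum.reduce([occ.std(axis=0, ddof=1) * ucl, counting,
                                np.full(occ.shape[1], sd_floor)])
    return NormalRanges(
        node_ids=np.arange(occ.shape[1]),
        mean=occ.mean(axis=0),
        sd=sd,
        min=occ.min(axis=0),
        max=occ.max(axis=0),
        sd_floor=float(sd_floor),
    )


def build_reference(
    samples: list[EventMatrix],
    panel: PanelDefinition,
    config: ReferenceConfig | None = None,
    seed: int = 0,
) -> ReferenceTemplate:
    """Construct a frozen reference template from a cohort of normal samples.

    Pipeline: merge -> compensate -> transform -> select_and_scale (the
    scaling statistics are computed on the merged cohort and frozen) ->
    train SOM -> build/lay out MST -> per-donor occupancy rows and
    merged node statistics.  Deterministic given (inputs, seed).
    """
    if config is None:
        config = ReferenceConfig()
    if len(samples) < 2:
        raise ValidationError("a reference needs at least 2 normal samples")
    if len(samples) < 5:
        logger.warning(
            "only %d normal samples; occupancy ranges will be unstable", len(samples)
        )

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    merged = _stage("merge", merge_events, samples, panel)
    comped = _stage("compensate", compensate, merged, panel)
    transformed = _stage("transform", transform, comped, panel)
    scaled, stats = _stage(
        "scale", select_and_scale, transformed, panel, None, config.spread_floor
    )
    model = _stage(
        "train_som",
        train_som,
        scaled,
        (config.grid_rows, config.grid_cols),
        config.som_params,
        seed,
        stats,
    )
    tree = _stage("build_mst", build_mst, model)
    _stage("layout", layout_mst, tree, seed)
    assignments = _stage("assign", assign_bmu, scaled, model)

    sample_order = list(dict.fromkeys(merged.sample_ids.tolist()))
    occ_rows = []
    for sid in sample_order:
        mask = merged.sample_ids == sid
        occ_rows.append(occupancy_fractions(assignments[mask], model.n_nodes))
    occupancy = pd.DataFrame(
        np.vstack(occ_rows), index=sample_order, columns=np.arange(model.n_nodes)
    )

    merged_stats = compute_node_stats(transformed, assignments, model, panel)

    markers = [c.display for c in panel.clustering_channels()]
    qvals = {}
    for m in markers:
        col = transformed.column_index(m)
        qvals[m] = np.quantile(transformed.values[:, col], QUANTILE_GRID)
    marker_quantiles = pd.DataFrame(qvals, index=QUANTILE_GRID)

    provenance = {
        "sample_ids": sample_order,
        "seed": seed,
        "software_version": __version__,
        "n_merged_events": int(merged.n_events),
    }
    template = ReferenceTemplate(
        panel=panel,
        model=model,
        tree=tree,
        merged_stats=merged_stats,
        occupancy=occupancy,
        marker_quantiles=marker_quantiles,
        provenance=provenance,
    )
    # purity diagnostics when synthetic truth is available
    if merged.truth is not None:
        template.provenance["truth_available"] = True
        template._truth_assignments = (merged.truth, assignments)  # type: ignore[attr-defined]
    return template
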