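"""Node phenotype summaries and rule-based population labeling.

The reference paradigm leaves population naming to an operator who
inspects each node's marker profile.  This module makes that step
reproducible: every marker's merged-cohort intensity distribution is cut
into four qualitative expression levels (``neg``/``lo``/``pos``/``hi``)
at three quantile edges, each node receives the level of its median, and
user-declared :class:`PhenotypeRule` objects (conjunctions of
marker-level clauses) attach population labels to nodes.

Default bin edges are the 20th/50th/80th percentiles.  Markers that are
positive on only a small minority of marrow cells (CD34, CD117, CD56,
...) would have all three default edges inside their negative mode, so
the default configuration overrides their edges with upper-tail
quantiles; edges are configurable per marker.

The bundled rule set (:data:`DEFAULT_RULES`) encodes plausible lineage
criteria for the default synthetic panel; it is a fixture for the
simulator's populations, not an authoritative clinical gating scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigurationError
from .reference import ReferenceTemplate

logger = logging.getLogger(__name__)

LEVELS = ("neg", "lo", "pos", "hi")

#: Quantile triplets (neg|lo, lo|pos, pos|hi edges); "*" is the default,
#: rare-positive markers get upper-tail overrides.
DEFAULT_BIN_QUANTILES: dict[str, tuple[float, float, float]] = {
    "*": (0.20, 0.50, 0.80),
    "CD34": (0.975, 0.988, 0.997),
    "CD117": (0.915, 0.970, 0.995),
    "HLA-DR": (0.835, 0.880, 0.950),
    "CD7": (0.700, 0.750, 0.970),
    "CD56": (0.930, 0.970, 0.995),
    "CD19": (0.900, 0.945, 0.990),
    "CD123": (0.930, 0.970, 0.995),
    "CD14": (0.850, 0.900, 0.970),
    "CD16": (0.500, 0.600, 0.900),
}


@dataclass
class PhenotypeRule:
    """One population label: a conjunction of marker-level clauses.

    A ``pos`` clause accepts node levels ``pos`` or ``hi``; ``neg``,
    ``lo`` and ``hi`` clauses accept exactly their own level.
    """

    label: str
    clauses: list[tuple[str, str]]
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ConfigurationError(f"rule {self.label!r} has no clauses")
        for marker, level in self.clauses:
            if level not in LEVELS:
                raise ConfigurationError(
                    f"rule {self.label!r}: unknown level {level!r} for {marker}"
                )

    def matches(self, levels: dict[str, str]) -> bool:
        for marker, wanted in self.clauses:
            got = levels.get(marker)
            if got is None:
                return False
            if wanted == "pos":
                if got not in ("pos", "hi"):
                    return False
            elif got != wanted:
                return False
        return True


@dataclass
class NodePhenotype:
    """Expression level and supporting median per marker for one node."""

    node_id: int
    levels: dict[str, str] = field(default_factory=dict)   # empty node -> {}
    medians: dict[str, float] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return bool(self.levels)


def marker_bin_edges(
    template: ReferenceTemplate,
    quantiles: dict[str, tuple[float, float, float]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-marker intensity values of the three bin edges.

    Edges are interpolated from the quantile grid the template stored at
    build time, so they can be re-derived without the original events.
    """
    q = dict(DEFAULT_BIN_QUANTILES)
    if quantiles:
        q.update(quantiles)
    grid = template.marker_quantiles.index.to_numpy(dtype=float)
    edges = {}
    for marker in template.marker_quantiles.columns:
        trip = q.get(marker, q["*"])
        if not (0 <= trip[0] <= trip[1] <= trip[2] <= 1):
            raise ConfigurationError(f"bin quantiles for {marker} are not ordered")
        vals = template.marker_quantiles[marker].to_numpy(dtype=float)
        edges[marker] = np.interp(np.asarray(trip), grid, vals)
    return edges


def summarize_node_phenotypes(
    template: ReferenceTemplate,
    quantiles: dict[str, tuple[float, float, float]] | None = None,
) -> list[NodePhenotype]:
    """Assign each node a ``neg``/``lo``/``pos``/``hi`` level per marker.

    The level is the bin of the node's median intensity (transformed
    scale) within the merged cohort's marker distribution.  Empty nodes
    get no levels (undefined).
    """
    edges = marker_bin_edges(template, quantiles)
    stats = template.merged_stats
    out = []
    for _, row in stats.iterrows():
        node = int(row["node_id"])
        if row["count"] == 0:
            out.append(NodePhenotype(node_id=node))
            continue
        levels, medians = {}, {}
        for marker, e in edges.items():
            med = float(row[f"median_t_{marker}"])
            levels[marker] = LEVELS[int(np.searchsorted(e, med, side="right"))]
            medians[marker] = med
        out.append(NodePhenotype(node_id=node, levels=levels, medians=medians))
    return out


def label_nodes(
    template: ReferenceTemplate,
    rules: list[PhenotypeRule],
    quantiles: dict[str, tuple[float, float, float]] | None = None,
) -> dict[int, list[str]]:
    """Attach every matching rule label to every node.

    Pure function of the template statistics and the rules: repeated
    calls give identical results.  Multiple matching labels are kept,
    sorted by (priority, label); rules with identical clause sets are
    reported as ambiguous.
    """
    markers = set(template.marker_quantiles.columns)
    for rule in rules:
        for marker, _ in rule.clauses:
            if marker not in markers:
                raise ConfigurationError(
                    f"rule {rule.label!r} references unknown marker {marker!r}"
                )
    seen_clauses: dict[tuple, str] = {}
    for rule in rules:
        key = tuple(sorted(rule.clauses))
        if key in seen_clauses:
            logger.warning(
                "rules %r and %r have identical clauses; both labels will be applied",
                seen_clauses[key],
                rule.label,
            )
        else:
            seen_clauses[key] = rule.label
    phenotypes = summarize_node_phenotypes(template, quantiles)
    labels: dict[int, list[str]] = {}
    for ph in phenotypes:
        hits = [r for r in rules if ph.defined and r.matches(ph.levels)]
        hits.sort(key=lambda r: (r.priority, r.label))
        labels[ph.node_id] = [r.label for r in hits]
    return labels


def label_components(template: ReferenceTemplate, labels: dict[int, list[str]]):
    """Connected components of same-labeled nodes on the MST, per label."""
    import networkx as nx

    g = template.tree.to_graph()
    out: dict[str, list[set[int]]] = {}
    all_labels = sorted({lb for v in labels.values() for lb in v})
    for lb in all_labels:
        nodes = [n for n, v in labels.items() if lb in v]
        sub = g.subgraph(nodes)
        out[lb] = [set(c) for c in nx.connected_components(sub)]
    return out


# ----------------------------------------------------------------------
# Rule fixtures for the default synthetic AML-B-like panel.  The three
# progenitor rules mirror the classical CD34/CD38 ladder of the most
# immature marrow compartment; the lineage rules are tuned to the
# simulator's phenotype table and are explicitly non-authoritative.

DEFAULT_PROGENITOR_RULES: list[PhenotypeRule] = [
    PhenotypeRule("Ber1 (CD34+CD38-)", [("CD34", "pos"), ("CD38", "neg")]),
    PhenotypeRule("Ber2 (CD34+CD38+)", [("CD34", "pos"), ("CD38", "pos")]),
    PhenotypeRule("MonoBer (CD34lo CD38+)", [("CD34", "lo"), ("CD38", "pos")]),
]

DEFAULT_RULES: list[PhenotypeRule] = DEFAULT_PROGENITOR_RULES + [
    PhenotypeRule("Granulocytic", [("SSC", "pos"), ("CD34", "neg"), ("HLA-DR", "neg"),
                                   ("CD7", "neg"), ("CD19", "neg")]),
    PhenotypeRule("Eosinophils", [("SSC", "pos"), ("CD45", "pos")]),
    PhenotypeRule("ProGR", [("CD117", "pos"), ("HLA-DR", "lo"), ("SSC", "lo"),
                            ("CD34", "neg")]),
    PhenotypeRule("MyMo", [("CD117", "neg"), ("HLA-DR", "lo"), ("SSC", "lo"),
                           ("CD13", "pos"), ("CD34", "neg")]),
    PhenotypeRule("Monocytic", [("HLA-DR", "pos"), ("CD33", "pos"), ("CD34", "neg"),
                                ("CD19", "neg"), ("SSC", "lo")]),
    PhenotypeRule("Basophils", [("CD13", "pos"), ("SSC", "lo"), ("HLA-DR", "neg"),
                                ("CD45", "lo"), ("CD38", "pos")]),
    PhenotypeRule("T/NK cells", [("CD7", "pos"), ("CD45", "hi"), ("CD34", "neg")]),
    PhenotypeRule("B cells", [("CD19", "pos"), ("CD45", "hi")]),
    PhenotypeRule("Hematogones", [("CD19", "pos"), ("CD45", "lo"), ("CD38", "pos")]),
    PhenotypeRule("Plasma cells", [("CD19", "lo"), ("CD38", "pos"), ("CD45", "lo"),
                                   ("HLA-DR", "neg")]),
    PhenotypeRule("pDC", [("HLA-DR", "pos"), ("CD33", "neg"), ("CD7", "neg"),
                          ("CD19", "neg"), ("CD34", "neg"), ("SSC", "lo")]),
]

#: Which default label(s) each simulated population may fall under —
#: used by purity diagnostics and tests, not by the labeling itself.
#: Populations on lineage boundaries (granulocyte progenitors,
#: myelomonocytes) legitimately end up under their parent lineage's
#: label when a map merges them with an adjacent maturation stage.
POPULATION_LABELS: dict[str, tuple[str, ...]] = {
    "Gran": ("Granulocytic",), "IG1": ("Granulocytic",),
    "IG2": ("Granulocytic",), "PrMy": ("Granulocytic",),
    "Eo": ("Eosinophils",),
    "ProGR": ("ProGR", "Granulocytic"),
    "MyMo": ("MyMo", "Granulocytic", "Monocytic"),
    "Baso": ("Basophils",),
    "Mo": ("Monocytic",), "Mo3": ("Monocytic",), "PrMo": ("Monocytic",),
    "MonoBer": ("MonoBer (CD34lo CD38+)",),
    "LyT-CD4": ("T/NK cells",), "LyT-CD8": ("T/NK cells",),
    "NK": ("T/NK cells",),
    "LyB": ("B cells",), "HTG": ("Hematogones",), "PC": ("Plasma cells",),
    "pDC": ("pDC",),
    "Ber1": ("Ber1 (CD34+CD38-)",), "Ber2": ("Ber2 (CD34+CD38+)",),
}


# ----------------------------------------------------------------------
# YAML round-trip for rule files


def rules_to_yaml(rules: list[PhenotypeRule], path) -> None:
    payload = [
        {"label": r.label, "priority": r.priority,
         "clauses": [{"marker": m, "level": lv} for m, lv in r.clauses]}
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def rules_from_yaml(path) -> list[PhenotypeRule]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        PhenotypeRule(
            label=item["label"],
            clauses=[(c["marker"], c["level"]) for c in item["clauses"]],
            priority=int(item.get("priority", 0)),
        )
        for item in payload
    ]
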