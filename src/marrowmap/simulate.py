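"""Synthetic normal bone-marrow cohorts and AML-spiked samples.

No public dataset accompanies the reference paradigm, so this module
generates list-mode data with the population structure of adult bone
marrow: 21 leukocyte subsets (granulocytic and monocytic maturation
stages, lymphoid subsets, rare progenitors) drawn as Gaussians in
arcsinh-transformed marker space, inverse-transformed to the raw
measurement scale and pushed through the panel's spillover matrix so the
full compensate/transform pipeline is exercised.

All numeric phenotype parameters (frequencies, marker levels,
intensities) are hand-authored fixtures chosen for qualitative realism
and internal consistency; they are synthetic design choices, not
measurements from any published cohort.  Each generated event keeps a
hidden population-of-origin label for purity diagnostics and tests.

Inter-donor variation: per-sample population frequencies are drawn from
a Dirichlet distribution centred on the base frequencies, with a
concentration parameter controlling donor-to-donor spread (default 150,
giving roughly 25-35 % coefficients of variation for mid-sized subsets,
in line with the spread seen between healthy adult marrows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventMatrix
from .exceptions import ValidationError
from .panel import PanelDefinition, default_panel

# ----------------------------------------------------------------------
# Phenotype fixtures

#: Transformed-space intensity for each qualitative expression level.
LEVEL_VALUES = {"n": 0.2, "l": 1.6, "p": 3.2, "h": 4.4}

#: Default Gaussian spread per channel class, transformed space.
FLUOR_SD = 0.30
SSC_SD = 0.22

#: (frequency, SSC mean, marker levels).  Markers absent from a row are
#: negative.  Population names follow the usual short labels for normal
#: marrow subsets (Gran = neutrophilic granulocytes, IG = immature
#: granulocytes, PrMy = promyelocytes, ProGR = granulocyte progenitors,
#: Mo = monocytes, Mo3 = nonclassical monocytes, PrMo = promonocytes,
#: MonoBer = monocyte progenitors, MyMo = myelomonocytes, HTG =
#: hematogones, PC = plasma cells, pDC = plasmacytoid dendritic cells,
#: Ber1/Ber2 = the most immature CD34/CD38-defined progenitors).
NORMAL_MARROW: dict[str, tuple[float, float, dict[str, str]]] = {
    "Gran":    (0.450, 4.20, {"CD45": "l", "CD38": "l", "CD13": "p", "CD33": "l",
                              "CD16": "p", "CD10": "p", "CD64": "l"}),
    "IG1":     (0.039, 4.35, {"CD45": "l", "CD38": "p", "CD117": "l", "CD13": "l",
                              "CD33": "p", "CD64": "l"}),
    "IG2":     (0.030, 4.25, {"CD45": "l", "CD38": "l", "CD13": "p", "CD33": "p",
                              "CD16": "l", "CD64": "l"}),
    "PrMy":    (0.015, 4.50, {"CD45": "l", "CD38": "p", "CD117": "p", "CD13": "p",
                              "CD33": "h", "CD64": "p"}),
    "ProGR":   (0.008, 3.30, {"CD45": "l", "CD38": "p", "CD117": "p", "CD13": "p",
                              "CD33": "p", "HLA-DR": "l"}),
    "Eo":      (0.020, 4.60, {"CD45": "p", "CD38": "l", "CD13": "l", "CD33": "l",
                              "CD10": "l"}),
    "Baso":    (0.006, 1.60, {"CD45": "l", "CD38": "p", "CD13": "p", "CD33": "l",
                              "CD123": "p"}),
    "Mo":      (0.055, 2.60, {"CD45": "p", "CD38": "p", "CD13": "p", "CD33": "h",
                              "HLA-DR": "p", "CD14": "h", "CD64": "h"}),
    "Mo3":     (0.005, 2.45, {"CD45": "h", "CD38": "l", "CD13": "p", "CD33": "p",
                              "HLA-DR": "p", "CD14": "l", "CD16": "p", "CD64": "l"}),
    "PrMo":    (0.010, 2.90, {"CD45": "l", "CD38": "p", "CD117": "l", "CD13": "l",
                              "CD33": "h", "HLA-DR": "p", "CD14": "l", "CD64": "p"}),
    "MyMo":    (0.020, 3.50, {"CD45": "l", "CD38": "p", "CD13": "p", "CD33": "p",
                              "HLA-DR": "l", "CD14": "p", "CD64": "p"}),
    "MonoBer": (0.005, 2.20, {"CD45": "l", "CD34": "l", "CD38": "p", "CD117": "l",
                              "CD13": "l", "CD33": "p", "HLA-DR": "p"}),
    "LyT-CD4": (0.140, 1.20, {"CD45": "h", "CD38": "l", "CD7": "p", "CD3": "p",
                              "CD5": "p", "CD2": "p", "CD4": "p"}),
    "LyT-CD8": (0.080, 1.20, {"CD45": "h", "CD38": "l", "CD7": "p", "CD3": "p",
                              "CD5": "p", "CD2": "p", "CD8": "p"}),
    "NK":      (0.035, 1.30, {"CD45": "h", "CD38": "l", "CD7": "p", "CD56": "p",
                              "CD2": "p", "CD16": "p"}),
    "LyB":     (0.050, 1.10, {"CD45": "h", "CD19": "p", "CD20": "p", "CD22": "p",
                              "HLA-DR": "p", "CD81": "p"}),
    "HTG":     (0.012, 1.00, {"CD45": "l", "CD19": "p", "CD38": "h", "CD10": "p",
                              "CD20": "l", "CD22": "p", "CD81": "h"}),
    "PC":      (0.004, 1.50, {"CD45": "l", "CD19": "l", "CD38": "h", "CD81": "p"}),
    "pDC":     (0.004, 1.40, {"CD45": "l", "CD123": "h", "HLA-DR": "p", "CD4": "l"}),
    "Ber1":    (0.004, 1.60, {"CD45": "l", "CD34": "h", "CD117": "p", "CD13": "l",
                              "CD33": "l", "HLA-DR": "p"}),
    "Ber2":    (0.008, 1.70, {"CD45": "l", "CD34": "p", "CD38": "p", "CD117": "p",
                              "CD13": "l", "CD33": "p", "HLA-DR": "p"}),
}

#: Synthetic leukemic blast phenotypes (aberrant marker combinations on
#: an immature CD34+ backbone), used for spike-in experiments.
BLAST_PHENOTYPES: dict[str, tuple[float, dict[str, str]]] = {
    # CD34+ myeloid blasts with aberrant CD7
    "blast-cd7": (1.90, {"CD45": "l", "CD34": "p", "CD38": "l", "CD117": "p",
                         "CD13": "p", "CD33": "p", "HLA-DR": "p", "CD7": "p"}),
    # HLA-DR-negative blasts with aberrant CD56
    "blast-cd56": (2.10, {"CD45": "l", "CD34": "p", "CD38": "p", "CD117": "p",
                          "CD13": "p", "CD33": "h", "CD56": "p", "CD123": "p"}),
}


@dataclass
class PopulationSpec:
    """One simulated population: frequency plus Gaussian parameters.

    ``means``/``sds`` are keyed by marker display name in transformed
    space; ``"SSC"`` is the side-scatter channel.  Diagonal covariance by
    default; ``cov`` (full covariance over the panel's clustering
    channels) supports harder tests.
    """

    name: str
    frequency: float
    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    cov: np.ndarray | None = None

    def mean_for(self, marker: str) -> float:
        return self.means.get(marker, LEVEL_VALUES["n"])

    def sd_for(self, marker: str) -> float:
        if marker in self.sds:
            return self.sds[marker]
        return SSC_SD if marker == "SSC" else FLUOR_SD


@dataclass
class CohortSpec:
    """Normal cohort layout: 19 donors of 10,000 events by default."""

    n_samples: int = 19
    events_per_sample: int = 10_000
    concentration: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.concentration <= 0:
            raise ValidationError("concentration must be > 0")


def _spec_from_levels(
    name: str, freq: float, ssc: float, levels: dict[str, str]
) -> PopulationSpec:
    means = {m: LEVEL_VALUES[lv] for m, lv in levels.items()}
    means["SSC"] = ssc
    return PopulationSpec(name=name, frequency=freq, means=means)


def default_populations() -> list[PopulationSpec]:
    """The 21-population normal-marrow fixture."""
    return [
        _spec_from_levels(name, freq, ssc, levels)
        for name, (freq, ssc, levels) in NORMAL_MARROW.items()
    ]


def blast_population(kind: str = "blast-cd7", frequency: float = 1.0) -> PopulationSpec:
    """A synthetic leukemic blast spec for :func:`spike_abnormal`."""
    if kind not in BLAST_PHENOTYPES:
        raise ValidationError(
            f"unknown blast phenotype {kind!r}; available: {sorted(BLAST_PHENOTYPES)}"
        )
    ssc, levels = BLAST_PHENOTYPES[kind]
    return _spec_from_levels(kind, frequency, ssc, levels)


# ----------------------------------------------------------------------
# Observation model


def _observe(
    transformed: np.ndarray,
    markers: list[str],
    panel: PanelDefinition,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Map transformed clustering-space draws to raw instrument values.

    Inverse arcsinh per channel, then spillover mixing across the
    fluorescence detectors, plus FSC (linear, correlated with SSC) and a
    TIME channel.  Returns (values, channel_names, marker_names) in the
    panel's channel order.
    """
    n = transformed.shape[0]
    cols: dict[str, np.ndarray] = {}
    for j, m in enumerate(markers):
        cols[m] = transformed[:, j]
    ssc_t = cols["SSC"]

    values = np.zeros((n, len(panel.channels)))
    names, marks = [], []
    fluor_raw = {}
    for ch in panel.channels:
        if ch.role == "fluorescence":
            fluor_raw[ch.display] = np.sinh(cols[ch.display]) * panel.cofactor(ch)
    # spillover: observed = true @ S
    fl_chs = panel.fluorescence_channels()
    true = np.column_stack([fluor_raw[c.display] for c in fl_chs])
    observed = true @ panel.spillover if panel.spillover is not None else true
    fl_iter = iter(range(observed.shape[1]))
    for k, ch in enumerate(panel.channels):
        names.append(ch.name)
        marks.append(ch.marker)
        if ch.role == "fluorescence":
            values[:, k] = observed[:, next(fl_iter)]
        elif ch.role == "side_scatter":
            values[:, k] = np.sinh(ssc_t) * panel.cofactor(ch)
        elif ch.role == "forward_scatter":
            values[:, k] = 350.0 + 70.0 * ssc_t + rng.normal(0.0, 45.0, size=n)
        else:  # time
            values[:, k] = np.arange(n, dtype=float)
    return values, names, marks


def generate_sample(
    spec: list[PopulationSpec],
    n_events: int = 10_000,
    seed: int = 0,
    panel: PanelDefinition | None = None,
    sample_id: str = "sample0",
) -> EventMatrix:
    """Draw one synthetic marrow sample on the raw measurement scale.

    Per-population event counts are multinomial in the spec frequencies;
    events are Gaussian in transformed space, inverse-transformed,
    spillover-mixed and shuffled.  The population of origin is kept in
    the hidden ``truth`` array.
    """
    if panel is None:
        panel = default_panel()
    freqs = np.array([p.frequency for p in spec], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"population frequencies sum to {freqs.sum()}, not 1")
    if np.any(freqs < 0):
        raise ValidationError("population frequencies must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, freqs)
    markers = [c.display for c in panel.clustering_channels()]

    blocks, truth = [], []
    for pop, k in zip(spec, counts):
        if k == 0:
            continue
        if pop.cov is not None:
            mean = np.array([pop.mean_for(m) for m in markers])
            block = rng.multivariate_normal(mean, pop.cov, size=k)
        else:
            block = np.column_stack(
                [rng.normal(pop.mean_for(m), pop.sd_for(m), size=k) for m in markers]
            )
        blocks.append(block)
        truth.extend([pop.name] * k)
    transformed = np.vstack(blocks) if blocks else np.zeros((0, len(markers)))
    truth_arr = np.array(truth, dtype=object)
    order = rng.permutation(len(truth_arr))
    transformed, truth_arr = transformed[order], truth_arr[order]

    values, names, marks = _observe(transformed, markers, panel, rng)
    return EventMatrix(
        values=values,
        channel_names=names,
        marker_names=marks,
        sample_ids=np.array([sample_id] * len(truth_arr), dtype=object),
        state="raw",
        truth=truth_arr,
    )


def generate_cohort(
    cohort: CohortSpec,
    base_spec: list[PopulationSpec] | None = None,
    panel: PanelDefinition | None = None,
) -> list[EventMatrix]:
    """Draw a cohort of normal donors with Dirichlet frequency variation.

    Per-donor frequencies ~ Dirichlet(concentration x base frequencies);
    each donor gets an independent child seed spawned from the master
    seed, so the cohort is reproducible as a whole and per donor.
    """
    if base_spec is None:
        base_spec = default_populations()
    if panel is None:
        panel = default_panel()
    base = np.array([p.frequency for p in base_spec])
    if abs(base.sum() - 1.0) > 1e-9:
        raise ValidationError("base frequencies must sum to 1")
    master = np.random.default_rng(cohort.seed)
    child_seeds = master.integers(0, 2**31 - 1, size=cohort.n_samples)
    samples = []
    for i in range(cohort.n_samples):
        rng = np.random.default_rng(int(child_seeds[i]))
        freqs = rng.dirichlet(cohort.concentration * base)
        spec_i = [
            PopulationSpec(
                name=p.name,
                frequency=float(f),
                means=dict(p.means),
                sds=dict(p.sds),
                cov=p.cov,
            )
            for p, f in zip(base_spec, freqs)
        ]
        samples.append(
            generate_sample(
                spec_i,
                n_events=cohort.events_per_sample,
                seed=int(child_seeds[i]) + 1,
                panel=panel,
                sample_id=f"normal{i + 1:02d}",
            )
        )
    return samples


def spike_abnormal(
    events: EventMatrix,
    blast_spec: PopulationSpec,
    fraction: float,
    seed: int = 0,
    panel: PanelDefinition | None = None,
) -> EventMatrix:
    """Replace a random fraction of events with draws from a blast spec.

    The realized blast share is ``round(fraction * n) / n``.  Blasts pass
    through the same observation model (inverse transform + spillover) as
    normal events; the truth array is updated.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    if events.state != "raw":
        raise ValidationError("spike_abnormal expects raw events")
    if panel is None:
        panel = default_panel()
    n = events.n_events
    k = int(round(fraction * n))
    out = events.copy()
    if out.truth is None:
        out.truth = np.array(["?"] * n, dtype=object)
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    markers = [c.display for c in panel.clustering_channels()]
    block = np.column_stack(
        [rng.normal(blast_spec.mean_for(m), blast_spec.sd_for(m), size=k) for m in markers]
    )
    values, names, _ = _observe(block, markers, panel, rng)
    col_of = {nm: j for j, nm in enumerate(names)}
    vals = out.values
    for j, nm in enumerate(out.channel_names):
        if nm in col_of and nm.upper() != "TIME":
            vals[idx, j] = values[:, col_of[nm]]
    out.truth[idx] = blast_spec.name
    return out


# ----------------------------------------------------------------------
# Template-guided blast synthesis.  A leukemia-associated immunophenotype
# is, by definition, a marker combination that healthy marrow leaves
# (nearly) unoccupied.  Given a reference template, the helpers below
# pick the nodes emptiest across the normal cohort and synthesize blasts
# around those positions — the residual-disease scenario in which a
# small leukemic population occupies nodes that hold almost nothing in
# any normal donor.

def near_empty_nodes(template, k: int = 2) -> list[int]:
    """Ids of the ``k`` nodes with the lowest mean normal occupancy."""
    occ = template.occupancy.to_numpy().mean(axis=0)
    return [int(i) for i in np.argsort(occ, kind="stable")[:k]]


def blast_from_nodes(
    template,
    node_ids: list[int],
    name: str = "blast",
    sd: float = 0.15,
) -> PopulationSpec:
    """Blast spec centred on the mean of the given nodes' phenotypes.

    Codebook vectors live in scaled space; they are mapped back to
    transformed space through the template's frozen scaling so the spec
    plugs into :func:`generate_sample`/:func:`spike_abnormal` like any
    other population.
    """
    if not node_ids:
        raise ValidationError("need at least one target node")
    scaling = template.model.scaling
    centre_scaled = template.model.codebook[list(node_ids)].mean(axis=0)
    centre = centre_scaled * scaling.spread + scaling.location
    means = dict(zip(scaling.channels, centre))
    sds = {m: sd for m in scaling.channels}
    return PopulationSpec(name=name, frequency=1.0, means=means, sds=sds)
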